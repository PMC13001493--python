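# petmind

Coupling of individual-level **metabolic connectivity** (MC) and
**morphometric similarity** (MIND) networks across the adult lifespan.

Dynamic FDG-PET characterises each cortical region by a time–activity
curve (TAC); structural MRI characterises it by the distribution of
vertex-wise morphometric features. This package asks how strongly the two
network representations agree — globally, regionally, and per subject —
and whether that agreement changes with age. It is aimed at molecular
neuroimaging groups who already have parcellated TACs and FreeSurfer-style
vertex features and want a tested, reproducible implementation of the
coupling analysis, including its permutation nulls and cohort inference.

## The statistics at the core

**Metabolic connectivity.** For regions *i*, *j* with TAC vectors
`x_i, x_j ∈ R^F`:

    w_ij = 1 − d_ij / max_{k<l} d_kl,   d_ij = ‖x_i − x_j‖₂

Weights lie in [0, 1]; distances are max-scaled within subject; raw
amplitudes are used deliberately (no SUV scaling or frame weighting).

**Morphometric similarity.** Each region is a cloud of vertices in the
5-dimensional space of (thickness, curvature, sulcal depth, area, volume),
z-scored with moments pooled over all vertices within the subject. With
the Wang–Kulkarni–Verdú k-nearest-neighbour divergence estimator

    D̂(P‖Q) = (d/n) Σ_i log(ν_k(i)/ρ_k(i)) + log(m/(n−1))

the similarity is `MIND_ij = 1 / (1 + D̂(P_i‖P_j) + D̂(P_j‖P_i)) ∈ (0, 1]`.

**Coupling.** Global: Spearman ρ between the strict upper triangles.
Local: per-region Spearman ρ between matched connectivity profiles.
Strength: Pearson r between weighted-degree maps. Both matrices can be
residualised against an exponential distance model `w(d) = a·e^(−bd) + c`
fit to centroid distances before correlating.

**Nulls and inference.** Spin permutations (hemisphere-mirrored random
rotations of the spherical parcel coordinates) preserve spatial
autocorrelation for map-level tests; a derangement null re-pairs subjects'
MC and MIND matrices to test subject specificity; cohort GLMs regress
z-scored coupling on z(age) + sex + z(TIV) with percentile-bootstrap CIs
and Benjamini–Hochberg FDR across regions.

A synthetic cohort generator plants all of this structure — a shared
bolus-like TAC template, latent region embeddings driving both
modalities, an exponential distance decay, and a per-subject mixing
weight `λ_s = intercept + slope·z(age_s)` that makes MC–MIND alignment
age-dependent — so every stage is verifiable without human data.

## Worked example

```python
import numpy as np, petmind as pm

cfg = pm.SyntheticConfig(n_subjects=20, n_regions=60,
                         n_vertices_per_region=(15, 30),
                         alignment_age_slope=0.6, seed=7)
cohort, tacs, feats, geom, truth = pm.generate_cohort(cfg)

rho, mc_list, mind_list = [], [], []
for sid in cohort["subject_id"]:
    mc = pm.compute_mc(tacs[sid])
    mind = pm.compute_mind(pm.standardize_features(feats[sid]))
    mc_list.append(mc); mind_list.append(mind)
    rho.append(pm.global_coupling(mc, mind)[0])
rho = np.array(rho)

group = pm.couple_matrices(pm.group_mean_matrix(mc_list),
                           pm.group_mean_matrix(mind_list),
                           geom, dist_correct=True)
mm  = pm.subject_mismatch_test(mc_list, mind_list, n_perm=1000, seed=0)
res = pm.fit_glm(rho, cohort)
ci  = pm.bootstrap_ci(rho, cohort, n_boot=1000, seed=0)
```

prints (via the obvious f-strings):

```
group rho = 0.540 (dist-corrected 0.541)
subject rho = 0.446 +/- 0.094
strength r = 0.593
mismatch p = 0.0010
beta_age = 0.959, 95% CI [0.812, 1.132], p = 6.95e-08
```

Read: the group-average networks agree strongly (ρ = 0.54) and the
agreement is not a distance artefact (residualised ρ essentially
unchanged); each subject's own MC matches their own MIND better than any
re-pairing (mismatch p at the Monte-Carlo floor); and, because the
generator planted a positive age slope on the mixing weight, the cohort
GLM recovers a significantly positive standardized age effect on global
coupling.

The same stages are available from the shell:

```bash
petmind simulate --out data --seed 9
petmind mc   --tacs data/sub-000_tacs.tsv     --out sub-000_mc.tsv
petmind mind --features data/sub-000_features.tsv --k 3 --out sub-000_mind.tsv
petmind couple --mc sub-000_mc.tsv --mind sub-000_mind.tsv \
               --geom data/geometry.tsv --dist-correct --out coup/
petmind run-all --config cfg.yaml      # whole pipeline + manifest
```

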