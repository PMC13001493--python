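# Methods

This note documents the models, the estimator choices, and the design
decisions taken where more than one defensible option existed. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Metabolic connectivity

MC edges are one minus the Euclidean distance between two regions'
time–activity curves, scaled by the maximum distance over all region
pairs of that subject. Consequences worth being explicit about:

* **Within-subject scaling.** The maximum is taken per subject, so edge
  weights are relative to that subject's most dissimilar pair. This keeps
  each matrix in [0, 1] with an exactly-zero minimum edge, but means raw
  weights are not directly comparable across subjects; all cross-subject
  analyses here use rank (Spearman) statistics or per-subject summaries,
  which are invariant to this.
* **No normalisation.** TACs enter raw. A uniform multiplicative factor
  cancels through the max-scaling, but any non-uniform amplitude change
  (regional baseline shifts, injected-dose differences interacting with
  regional kinetics) changes the matrix. This amplitude sensitivity is a
  property of the framework, is covered by a test, and is the reason the
  pipeline never silently rescales inputs.
* The diagonal is stored as 1 but flagged (`diagonal_convention`) and is
  excluded from every statistic: vectorisation takes the strict upper
  triangle and nodal strength sums off-diagonal entries only.

## Morphometric similarity

Similarity is the inverse one-plus transform of the symmetrised
Kullback–Leibler divergence between two regions' vertex clouds in the
5-feature space, estimated with the Wang–Kulkarni–Verdú k-nearest-
neighbour estimator.

* **k = 3 by default.** k = 1 is the classical choice but has high
  variance at the region sizes typical of fine parcellations; larger k
  increases bias. The order is exposed in `MINDConfig`.
* **Pooled z-scoring.** The five features have incommensurate units, and
  the estimator's Euclidean neighbour search needs a common scale.
  Moments are pooled over all vertices of all regions within the subject
  (not per region), because between-region mean differences *are* the
  signal and per-region scaling would erase them. Pooled z-scoring is a
  diagonal affine map applied to every region alike; Gaussian KL is
  invariant under shared affine maps, so the transform standardises
  units without moving the estimand.
* **Degenerate geometry.** Zero neighbour distances (duplicated
  vertices, common in decimated meshes) are floored at 1e−12 with a
  logged count; negative divergence estimates (estimator noise near 0)
  are clipped to 0 by default so the output stays in (0, 1].
* **One-pass computation.** `compute_mind` computes all directed
  divergences with per-target-region distance blocks and partial sorts;
  this is algebraically identical to calling `knn_kl` per ordered pair
  (a test asserts exact agreement) but ~N× faster.

## Distance correction

Edge weights in both modalities decay with inter-centroid distance.
Before attributing coupling to shared microstructure, both matrices can
be residualised against `w(d) = a·e^(−bd) + c`, fit by nonlinear least
squares to the upper-triangle weights. Exponential fits are sensitive to
initialisation, so the fit starts from a₀ = range(w), c₀ = min(w),
b₀ = 1/median(d), restarts over fixed b₀ multipliers {1, ½, 2, ⅕, 5}
with bounds a, b ≥ 0, and keeps the lowest-SSE solution. If every start
fails, residuals fall back to a linear fit and `converged=False` is
reported honestly. With a free intercept the residuals sum to zero at
the optimum, which a test asserts.

## Null models

* **Spin test.** Uniform SO(3) rotations are applied to the
  left-hemisphere spherical coordinates and the x-mirrored rotation to
  the right, and each parcel takes the value of the parcel whose original
  coordinate is nearest its rotated position, within hemisphere. Nearest-
  neighbour reassignment can reuse a source parcel; the duplication rate
  is recorded rather than forced to zero, because bijective variants
  subtly distort the preserved autocorrelation. Default sidedness is
  two-sided. p-values use the add-one convention, p ≥ 1/(n_spins+1).
* **Subject-mismatch test.** The observed statistic is the mean over
  subjects of within-subject global coupling; permutations draw uniform
  derangements (rejection sampling, acceptance ≈ 1/e) so no subject
  keeps their own matrix. "Exceeding" is implemented as ≥, which is
  conservative under ties; the test is one-sided (greater) because
  subject specificity is directional. Rank transforms are computed once
  per matrix so each permutation costs one dot product per subject.

## Cohort inference

The response (global or per-region coupling) and continuous predictors
(age, TIV) are z-scored; sex stays binary {0, 1}. Betas are therefore
standardized, and the whole analysis is invariant to covariate units (a
test rescales age to months). Partial correlations use
r = t/√(t² + df), identical to residual-on-residual correlation; each
predictor is adjusted for the other two (for the age effect: sex and
TIV). Confidence intervals are percentile bootstrap over subjects, with
the full estimator (including within-resample z-scoring) re-run on each
resample; degenerate resamples (e.g. one sex) are redrawn and counted.
Percentile rather than BCa because it is the simplest seed-reproducible
choice and the coverage requirement (90–99% at n = 66) is met, as the
suite verifies. Regional age-term p-values are Benjamini–Hochberg
adjusted across regions; regions with undefined coupling for some
subjects are fitted on complete cases with per-region n reported.

## Synthetic cohort generator

The generator emulates the *statistical* structure of a PET/MRI aging
cohort, not its physics:

* **TACs.** A shared template — gamma-variate uptake `t²e^(−t/τ)`
  (τ = 600 s, peak normalised to 1) plus an irreversible-trapping
  plateau (amplitude 0.5) — modulated by each region's latent embedding
  through an orthonormal basis of smooth gamma-variate curves, plus
  i.i.d. frame noise (default SD 0.01 ≈ 1% of peak; bolus regional TACs
  are smooth). Default schedule: 10×6 s, 8×15 s, 9×60 s, 12×240 s = 39
  frames over 3600 s, fully configurable.
* **Latent structure.** Region embeddings (default 5-D) combine a
  non-spatial core with a spatial component drawn from a Gaussian
  process with covariance `exp(−b·d)` over centroids. The spatial
  variance fraction is a/(a+c) of the configured decay triple, so a
  planted (a, b, c) yields edge weights that decay with distance at rate
  b; the asymptotic baseline c emerges from the non-spatial part rather
  than being set pointwise. Because *both* modalities share the spatial
  component, a cohort with decay but no latent alignment still shows
  spurious MC–MIND coupling — exactly the artefact distance correction
  must remove, and a test verifies it does.
* **Planted age effect.** Per subject, the metabolic embedding is
  `λ_s·(morphometric) + (1−λ_s)·(independent)` with
  `λ_s = intercept + slope·z(age_s)`, clipped to [0, 1] (with clipping
  disabled the generator refuses configurations that leave [0, 1],
  naming the offending subject age). Subject-specific deviations of both
  embeddings (default SD 0.3) give each individual an idiosyncratic
  network, which is what makes the mismatch null informative.
* **Covariates.** Ages uniform on the configured range (default
  37.9–86.3 y, preserving leverage at both ends), sex alternating, TIV
  log-normal (median 1.45×10⁶ mm³, log-SD 0.08) with a +5% male offset —
  enough structure for a non-degenerate three-predictor GLM.
* **Geometry.** Fibonacci lattices on each unit hemisphere, mirrored
  across x = 0; centroids are sphere coordinates scaled to 70 mm.
  Laminar-class labels are z-coordinate quartile bands standing in for a
  cortical-type atlas: spatially contiguous and hemisphere-symmetric,
  which is what class-level spin comparisons need.

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: compartmental kinetics and arterial
input functions; partial-volume effects and their age interaction;
non-Gaussian, spatially folded cortical geometry; heteroscedastic frame
noise; site or scanner effects; correlated covariates (age–TIV
collinearity). Recovery of the planted effect demonstrates the
estimators and inference machinery are correct, not that real
metabolic–morphometric coupling has any particular magnitude.

## Problem sizes in the checks

The test suite and acceptance script use cohorts of 66 subjects with 120
regions and 10–24 vertices per region, 500–1000 spins and permutations,
and 300–2000 bootstrap resamples — sizes chosen so the full suite runs
on one CPU in minutes while keeping every statistical check adequately
powered. All knobs scale up through configuration; the real-data
defaults (360 regions, 10,000 spins/resamples) are the documented
defaults of the respective functions.

## Known limitations

* Within-subject max-scaling of MC makes raw edge weights
  subject-relative (see above); only rank-based cross-subject statistics
  are supported interpretations.
* The kNN divergence estimator is biased at small region sizes; MIND
  values from regions with tens of vertices are noisy, and k must be
  well below the smallest region size.
* The spin test assumes parcels are reasonably represented by single
  spherical points; very anisotropic parcels weaken the null's fidelity.
* The partial-correlation effect size for age adjusts for sex and TIV;
  other adjustment sets are computable but not built in.
* The derangement null requires ≥ 3 subjects and treats subjects as
  exchangeable under the null; strong family structure would violate it.
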