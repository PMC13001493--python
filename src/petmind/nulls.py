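"""Permutation null models preserving spatial and subject structure.

Two nulls are provided:

* **Spin test** — regional cortical maps are spatially autocorrelated, so
  naive permutation inflates significance. The spin test draws uniform
  random 3-D rotations, applies each rotation to the left-hemisphere
  spherical parcel coordinates and the x-mirrored rotation to the right,
  and reassigns each parcel the value of the parcel whose original
  coordinate is nearest its rotated position (within hemisphere). This
  scrambles the map while preserving its spatial smoothness. Nearest-
  neighbour reassignment may use a source parcel more than once; the
  duplication rate is recorded.

* **Subject-mismatch test** — tests whether within-subject MC-MIND
  coupling is subject-specific: each permutation pairs every subject's
  metabolic matrix with a *different* subject's morphometric matrix (a
  derangement), and the mean global coupling over mismatched pairs forms
  the null for the observed mean over matched pairs.

Both tests use the add-one Monte-Carlo p-value convention, so p is never
zero and is floored at 1/(n+1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import KDTree

from .coupling import fit_distance_decay, vectorize_upper
from .datatypes import ParcelGeometry, SimilarityMatrix, check_matched_regions
from .errors import ValidationError

logger = logging.getLogger(__name__)

SIDEDNESS = ("two_sided", "greater", "less")


@dataclass
class SpinNull:
    """Spin-permutation null for the correlation of two regional maps."""

    n_spins: int
    permutations: np.ndarray  # (n_spins, N) source-parcel indices
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    sidedness: str
    seed: int | None
    duplication_rate: float  # mean fraction of parcels not uniquely assigned


@dataclass
class MismatchNull:
    """Derangement null for mean within-subject coupling."""

    n_perm: int
    observed_mean: float
    null_means: np.ndarray
    p_value: float
    seed: int | None


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A rotation matrix drawn from the Haar (uniform) measure on SO(3)."""
    return stats.special_ortho_group.rvs(3, random_state=rng)


def spin_permutations(geom: ParcelGeometry, n_spins: int, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Generate hemisphere-mirrored spin permutations.

    Returns an (n_spins, N) array of source indices — spun_map[p] =
    map[perm[s, p]] — together with the mean duplication rate.
    """
    geom.validate()
    n = geom.n_regions
    mirror = np.diag([-1.0, 1.0, 1.0])
    idx = {h: geom.hemisphere_indices(h) for h in ("L", "R")}
    coords = {h: geom.sphere_xyz[idx[h]] for h in ("L", "R")}
    trees = {h: KDTree(coords[h]) for h in ("L", "R")}
    perms = np.empty((n_spins, n), dtype=np.intp)
    dup = 0.0
    for s in range(n_spins):
        rot = random_rotation(rng)
        rot_by_hemi = {"L": rot, "R": mirror @ rot @ mirror}
        for h in ("L", "R"):
            rotated = coords[h] @ rot_by_hemi[h].T
            nearest = trees[h].query(rotated)[1]
            perms[s, idx[h]] = idx[h][nearest]
        dup += 1.0 - np.unique(perms[s]).size / n
    return perms, dup / n_spins


def _pearson_vector(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between vector `a` and every row of `B`."""
    a_c = a - a.mean()
    B_c = B - B.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(a_c) * np.linalg.norm(B_c, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (B_c @ a_c) / denom


def _mc_pvalue(observed: float, null: np.ndarray, sidedness: str) -> float:
    n = null.size
    if sidedness == "two_sided":
        count = int(np.sum(np.abs(null) >= abs(observed)))
    elif sidedness == "greater":
        count = int(np.sum(null >= observed))
    elif sidedness == "less":
        count = int(np.sum(null <= observed))
    else:
        raise ValidationError(f"sidedness must be one of {SIDEDNESS}, got {sidedness!r}")
    return (1 + count) / (n + 1)


def spin_test(
    map_a: np.ndarray,
    map_b: np.ndarray,
    geom: ParcelGeometry,
    n_spins: int = 10_000,
    sidedness: str = "two_sided",
    seed: int | None = None,
) -> SpinNull:
    """Spatial-autocorrelation-preserving test of the correlation between
    two regional maps.

    The observed statistic is the Pearson r between ``map_a`` and
    ``map_b``; the null distribution correlates ``map_a`` with spun
    versions of ``map_b``.
    """
    map_a = np.asarray(map_a, dtype=float)
    map_b = np.asarray(map_b, dtype=float)
    if map_a.shape != (geom.n_regions,) or map_b.shape != (geom.n_regions,):
        raise ValidationError("maps must be 1-D with one value per parcel in the geometry")
    if not (np.all(np.isfinite(map_a)) and np.all(np.isfinite(map_b))):
        raise ValidationError("maps must be finite")
    if n_spins < 100:
        raise ValidationError("n_spins must be >= 100 for a usable null")
    if sidedness not in SIDEDNESS:
        raise ValidationError(f"sidedness must be one of {SIDEDNESS}")
    rng = np.random.default_rng(seed)
    perms, dup_rate = spin_permutations(geom, n_spins, rng)
    observed = float(stats.pearsonr(map_a, map_b)[0])
    null_stats = _pearson_vector(map_a, map_b[perms])
    p = _mc_pvalue(observed, null_stats, sidedness)
    if dup_rate > 0:
        logger.info("spin_test: mean duplication rate %.3f under nearest-neighbour reassignment",
                    dup_rate)
    return SpinNull(n_spins=n_spins, permutations=perms, observed_stat=observed,
                    null_stats=null_stats, p_value=p, sidedness=sidedness, seed=seed,
                    duplication_rate=dup_rate)


def random_derangement(n: int, rng: np.random.Generator, max_tries: int = 100_000) -> np.ndarray:
    """Uniform random derangement by rejection sampling (acceptance ~ 1/e)."""
    if n < 2:
        raise ValidationError("derangements require n >= 2")
    for _ in range(max_tries):
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm
    raise RuntimeError("failed to sample a derangement")  # pragma: no cover


def _ranked_unit(vec: np.ndarray) -> np.ndarray:
    """Average-rank transform, centred and scaled to unit norm, so that a
    dot product of two transformed vectors is their Spearman rho."""
    r = stats.rankdata(vec)
    r = r - r.mean()
    norm = np.linalg.norm(r)
    if norm == 0:
        raise ValidationError("constant edge-weight vector; Spearman undefined")
    return r / norm


def subject_mismatch_test(
    mc_list: list[SimilarityMatrix],
    mind_list: list[SimilarityMatrix],
    n_perm: int = 1000,
    seed: int | None = None,
    dist_correct: bool = False,
    geom: ParcelGeometry | None = None,
) -> MismatchNull:
    """Derangement null for the mean within-subject global coupling.

    The observed statistic is the mean over subjects of the Spearman
    correlation between matched MC/MIND upper triangles; each permutation
    re-pairs matrices by a uniform random derangement. One-sided by
    construction: p is the add-one proportion of null means >= observed
    (ties count against significance).
    """
    n_sub = len(mc_list)
    if n_sub != len(mind_list):
        raise ValidationError("mc_list and mind_list must have the same length")
    if n_sub < 3:
        raise ValidationError("subject-mismatch test needs >= 3 subjects "
                              "(no informative derangement space below that)")
    for mc_m, mind_m in zip(mc_list, mind_list):
        check_matched_regions(mc_m, mc_list[0])
        check_matched_regions(mind_m, mc_list[0])
    if dist_correct:
        if geom is None:
            raise ValidationError("distance correction requires parcel geometry")
        mc_list = [fit_distance_decay(m, geom).residual_matrix for m in mc_list]
        mind_list = [fit_distance_decay(m, geom).residual_matrix for m in mind_list]

    # rank-transform once; every pairwise Spearman is then a dot product
    mc_ranks = np.vstack([_ranked_unit(vectorize_upper(m)) for m in mc_list])
    mind_ranks = np.vstack([_ranked_unit(vectorize_upper(m)) for m in mind_list])
    cross = mc_ranks @ mind_ranks.T  # cross[s, t] = spearman(MC_s, MIND_t)
    observed = float(np.mean(np.diag(cross)))

    rng = np.random.default_rng(seed)
    null_means = np.empty(n_perm)
    rows = np.arange(n_sub)
    for i in range(n_perm):
        perm = random_derangement(n_sub, rng)
        null_means[i] = cross[rows, perm].mean()
    p = _mc_pvalue(observed, null_means, "greater")
    return MismatchNull(n_perm=n_perm, observed_mean=observed, null_means=null_means,
                        p_value=p, seed=seed)
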