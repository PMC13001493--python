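"""Coupling between metabolic connectivity and morphometric similarity.

Correspondence between the two networks is quantified at three scales:

* **global** — Spearman correlation between the vectorised strict upper
  triangles of the two matrices (the diagonal never enters);
* **local** — for each region, the Spearman correlation between its row
  in one matrix and the matched row in the other, with the self entry
  removed;
* **strength** — Pearson correlation between the two nodal-strength
  (weighted degree) maps.

Because edge weights in both modalities decay with inter-regional
distance, a spatially trivial association could masquerade as coupling.
Each matrix can therefore be residualised against an exponential
distance-decay model w(d) = a*exp(-b*d) + c fit to its upper-triangle
weights versus centroid Euclidean distances; coupling recomputed on the
residuals is reported as the distance-corrected value.

Group-level matrices are elementwise means of subject matrices.
Group-then-couple and couple-then-average are distinct statistics and are
reported separately (see :func:`couple_group` vs per-subject results
summarised by :func:`summarize_cohort`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform

from .datatypes import ParcelGeometry, SimilarityMatrix, check_matched_regions
from .errors import DegenerateInputError, ValidationError
from .mc import nodal_strength

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# vectorisation helpers


def vectorize_upper(m: SimilarityMatrix) -> np.ndarray:
    """Strict upper triangle in row-major order (length N(N-1)/2)."""
    m.validate()
    return m.off_diagonal()


def devectorize_upper(vec: np.ndarray, region_ids: list[str], modality: str = "residual",
                      diagonal: float = 0.0) -> SimilarityMatrix:
    """Inverse of :func:`vectorize_upper`; diagonal filled with `diagonal`."""
    n = len(region_ids)
    expected = n * (n - 1) // 2
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (expected,):
        raise ValidationError(f"expected vector of length {expected}, got {vec.shape}")
    values = squareform(vec)
    np.fill_diagonal(values, diagonal)
    return SimilarityMatrix(region_ids=list(region_ids), values=values, modality=modality,
                            diagonal_convention="excluded")


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def global_coupling(mc: SimilarityMatrix, mind: SimilarityMatrix) -> tuple[float, float]:
    """Spearman rho (with t-approximation p) between upper-triangle vectors.

    Ties receive average ranks (scipy default).
    """
    check_matched_regions(mc, mind)
    return _spearman(vectorize_upper(mc), vectorize_upper(mind))


# ---------------------------------------------------------------------------
# distance-decay residualisation


@dataclass
class DecayFit:
    """Result of fitting w(d) = a*exp(-b*d) + c to edge weights.

    ``residual_matrix`` holds w_ij - w_hat(d_ij), symmetrised, with the
    diagonal excluded from statistics. ``converged`` is honest: when all
    nonlinear starts fail, residuals come from a linear fallback fit and
    converged is False.
    """

    a: float
    b: float
    c: float
    converged: bool
    residual_matrix: SimilarityMatrix

    def predict(self, d: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-self.b * np.asarray(d, dtype=float)) + self.c


def _exp_decay(d, a, b, c):
    return a * np.exp(-b * d) + c


def fit_distance_decay(m: SimilarityMatrix, geom: ParcelGeometry) -> DecayFit:
    """Nonlinear least-squares fit of edge weight on centroid distance.

    Exponential fits are sensitive to initialisation, so the fit restarts
    from b0 = 1/median(d) jittered over fixed multipliers and keeps the
    lowest-SSE converged solution, with bounds a >= 0, b >= 0.
    """
    m.validate()
    geom.validate()
    check_matched_regions(m, geom)
    w = vectorize_upper(m)
    d = pdist(geom.centroid_xyz)
    if w.size < 10:
        raise ValidationError(f"need >= 10 edges to fit a decay model, got {w.size}")
    if np.any(d <= 0):
        raise ValidationError("centroid distances must be strictly positive (duplicate centroids?)")

    spread = float(np.ptp(w))
    a0 = spread if spread > 0 else 1e-6
    c0 = float(np.min(w))
    b0 = 1.0 / float(np.median(d))
    best = None
    for mult in (1.0, 0.5, 2.0, 0.2, 5.0):
        try:
            popt, _ = optimize.curve_fit(
                _exp_decay, d, w, p0=[a0, b0 * mult, c0],
                bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        sse = float(np.sum((w - _exp_decay(d, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is not None:
        a, b, c = (float(x) for x in best[1])
        resid = w - _exp_decay(d, a, b, c)
        converged = True
    else:  # linear fallback: w ~ slope*d + intercept
        logger.warning("distance-decay fit failed to converge; using linear fallback residuals")
        slope, intercept = np.polyfit(d, w, deg=1)
        a, b, c = 0.0, 0.0, float(intercept)
        resid = w - (slope * d + intercept)
        converged = False
    residual_matrix = devectorize_upper(resid, list(m.region_ids), modality="residual")
    return DecayFit(a=a, b=b, c=c, converged=converged, residual_matrix=residual_matrix)


# ---------------------------------------------------------------------------
# per-subject / group coupling


@dataclass
class CouplingResult:
    """MC-MIND correspondence for one subject (or the group average)."""

    subject_id: str
    global_rho: float
    global_p: float
    strength_r: float
    strength_p: float
    local_rho: np.ndarray
    region_ids: list[str] = field(default_factory=list)
    global_rho_distcorr: float | None = None
    global_p_distcorr: float | None = None


def local_coupling(mc: SimilarityMatrix, mind: SimilarityMatrix) -> np.ndarray:
    """Row-wise Spearman coupling: for each region, correlate its MC and
    MIND connectivity profiles with the self entry removed.

    Regions with a constant profile in either modality get NaN (logged);
    cohort summaries handle them pairwise.
    """
    check_matched_regions(mc, mind)
    mc.validate()
    mind.validate()
    n = mc.n_regions
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        a = mc.values[i, keep]
        b = mind.values[i, keep]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            logger.warning("local_coupling: constant profile for region %s; set to NaN",
                           mc.region_ids[i])
            out[i] = np.nan
        else:
            out[i] = stats.spearmanr(a, b)[0]
    return out


def strength_correlation(mc: SimilarityMatrix, mind: SimilarityMatrix) -> tuple[float, float]:
    """Pearson correlation between the two nodal-strength maps."""
    check_matched_regions(mc, mind)
    s_mc = nodal_strength(mc)
    s_mind = nodal_strength(mind)
    if np.ptp(s_mc) == 0 or np.ptp(s_mind) == 0:
        raise DegenerateInputError("nodal strengths are constant; Pearson r undefined")
    r, p = stats.pearsonr(s_mc, s_mind)
    return float(r), float(p)


def couple_matrices(
    mc: SimilarityMatrix,
    mind: SimilarityMatrix,
    geom: ParcelGeometry | None = None,
    dist_correct: bool = False,
    subject_id: str | None = None,
) -> CouplingResult:
    """All coupling statistics for one MC/MIND pair.

    With ``dist_correct`` and a geometry, both matrices are residualised
    against their own exponential distance-decay fits and the global
    Spearman recomputed on residuals (reported alongside, not instead of,
    the uncorrected value).
    """
    rho, p = global_coupling(mc, mind)
    r, rp = strength_correlation(mc, mind)
    local = local_coupling(mc, mind)
    result = CouplingResult(
        subject_id=subject_id or "group",
        global_rho=rho, global_p=p,
        strength_r=r, strength_p=rp,
        local_rho=local, region_ids=list(mc.region_ids),
    )
    if dist_correct:
        if geom is None:
            raise ValidationError("distance correction requires parcel geometry")
        res_mc = fit_distance_decay(mc, geom).residual_matrix
        res_mind = fit_distance_decay(mind, geom).residual_matrix
        result.global_rho_distcorr, result.global_p_distcorr = global_coupling(res_mc, res_mind)
    return result


def group_mean_matrix(matrices: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Elementwise mean of subject matrices (group-level network)."""
    if not matrices:
        raise ValidationError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        check_matched_regions(first, m)
        if m.modality != first.modality:
            raise ValidationError("cannot average matrices of different modalities")
    values = np.mean([m.values for m in matrices], axis=0)
    # the exact-zero minimum of individual MC matrices is not preserved by
    # averaging; tag group averages as residual-free but validate only shape
    out = SimilarityMatrix(region_ids=list(first.region_ids), values=values,
                           modality=first.modality, diagonal_convention=first.diagonal_convention)
    if first.modality == "MC":
        # averaging keeps [0,1] but the exactly-zero edge generally vanishes;
        # bypass that single invariant by tagging the convention explicitly.
        out = SimilarityMatrix(region_ids=list(first.region_ids), values=values,
                               modality="residual", diagonal_convention=first.diagonal_convention)
    return out


# ---------------------------------------------------------------------------
# cohort summary


@dataclass
class CouplingSummary:
    """Across-subject summary of local coupling maps."""

    region_ids: list[str]
    mean_local_rho: np.ndarray
    mad_local_rho: np.ndarray
    class_means: dict[str, float] | None = None


def median_absolute_deviation(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Unscaled MAD: median of absolute deviations from the median.

    NaNs are ignored pairwise. No normal-consistency factor is applied.
    """
    med = np.nanmedian(x, axis=axis, keepdims=True)
    return np.nanmedian(np.abs(x - med), axis=axis)


def summarize_cohort(results: list[CouplingResult], geom: ParcelGeometry | None = None) -> CouplingSummary:
    """Elementwise mean and MAD of local coupling across subjects, plus
    laminar-class means of the subject-mean map when labels are present.
    """
    if len(results) < 2:
        raise ValidationError("cohort summary needs >= 2 subjects")
    region_ids = results[0].region_ids
    for r in results[1:]:
        if r.region_ids != region_ids:
            raise ValidationError("region order mismatch across subjects")
    stacked = np.vstack([r.local_rho for r in results])  # subjects x regions
    with np.errstate(invalid="ignore"):
        mean_map = np.nanmean(stacked, axis=0)
    mad_map = median_absolute_deviation(stacked, axis=0)
    class_means = None
    if geom is not None:
        if geom.laminar_class is None:
            logger.warning("geometry has no laminar-class labels; class means omitted")
        else:
            check_matched_regions(results[0], geom)
            class_means = {}
            for cls in np.unique(geom.laminar_class):
                idx = np.flatnonzero(geom.laminar_class == cls)
                class_means[str(cls)] = float(np.nanmean(mean_map[idx]))
    return CouplingSummary(region_ids=list(region_ids), mean_local_rho=mean_map,
                           mad_local_rho=mad_map, class_means=class_means)
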