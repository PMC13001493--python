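"""Synthetic multi-subject cohort with a planted age-by-coupling effect.

The generator emulates the statistical structure the downstream analysis
assumes, without simulating images or kinetics:

* Each region carries a latent embedding. A *morphometric* embedding
  drives the vertex-wise feature means (so regions with similar
  embeddings are morphometrically similar), and a *metabolic* embedding
  modulates the regional time-activity curves around a shared bolus-like
  template (so regions with similar embeddings have similar TACs).
* Per subject, the metabolic embedding is a convex mixture
  ``lambda_s * (morphometric) + (1 - lambda_s) * (independent)`` with
  ``lambda_s = alignment_intercept + alignment_age_slope * z(age_s)``
  (clipped to [0, 1]). The mixing weight is the planted ground truth: the
  more a subject's metabolic structure borrows from their morphometric
  structure, the stronger their MC-MIND coupling, and the slope plants a
  linear age effect on that coupling.
* A spatial latent component, drawn from a Gaussian process with
  covariance exp(-b * d_mm) over parcel centroids, is shared by both
  embeddings. This injects the exponential distance decay (rate ``b``)
  observed in real edge weights, with the relative amplitude governed by
  a/(a+c) of the configured decay triple; the asymptotic baseline ``c``
  emerges from the non-spatial components rather than being set directly.
* Subject-specific deviations of both embeddings give each individual an
  idiosyncratic network, which is what the subject-mismatch null detects.

Parcels are placed by a Fibonacci lattice on each unit hemisphere
(mirrored across x = 0), giving reproducible quasi-uniform coverage for
spin tests; volumetric centroids are the sphere coordinates scaled to a
brain-like radius. Laminar-class labels are assigned by z-coordinate
bands as a stand-in for a cortical-type atlas.

The TAC template is a gamma-variate uptake ``u(t) = t^2 * exp(-t/tau)``
(tau = 600 s) normalised to peak 1 plus an irreversible-trapping plateau
— qualitatively bolus-FDG-like without compartment modelling.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FEATURE_NAMES, ParcelGeometry, TACSet, VertexFeatureSet
from .errors import ConfigurationError, ValidationError

#: Bolus acquisition schedule: (frame duration s, repetitions).
DEFAULT_FRAME_SCHEDULE: tuple[tuple[float, int], ...] = ((6, 10), (15, 8), (60, 9), (240, 12))

LAMINAR_CLASSES = ("idiotypic", "unimodal", "heteromodal", "paralimbic")

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))
_TAC_TAU = 600.0  # s, gamma-variate time constant
_PLATEAU_AMPLITUDE = 0.5  # trapping plateau relative to uptake peak


@dataclass
class SyntheticConfig:
    """Study-condition parameters for cohort generation.

    Defaults mirror the acquisition this pipeline targets: 66 subjects
    aged ~38-86 years, a 360-parcel two-hemisphere parcellation, and a
    39-frame bolus schedule (10x6 s, 8x15 s, 9x60 s, 12x240 s).
    """

    n_subjects: int = 66
    n_regions: int = 360
    n_vertices_per_region: tuple[int, int] = (40, 120)
    frame_schedule: tuple[tuple[float, int], ...] = DEFAULT_FRAME_SCHEDULE
    latent_dim: int = 5
    alignment_intercept: float = 0.5
    alignment_age_slope: float = 0.3
    tac_noise_sd: float = 0.01          # activity units; TAC template peaks at 1
    feature_noise_sd: float = 1.0       # vertex scatter in feature z-units
    distance_decay: tuple[float, float, float] = (0.5, 0.05, 0.1)  # (a, b 1/mm, c)
    age_range: tuple[float, float] = (37.9, 86.3)
    subject_latent_sd: float = 0.3      # SD of per-subject embedding deviations
    tac_signal_scale: float = 0.15      # latent modulation amplitude on TACs
    feature_loading_scale: float = 0.8  # SD of region feature means in z-units
    brain_radius_mm: float = 70.0
    min_vertices: int = 10
    clip_mixing: bool = True
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_regions < 4 or self.n_regions % 2:
            raise ConfigurationError("n_regions must be even and >= 4 (two hemispheres)")
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        lo, hi = self.n_vertices_per_region
        if lo > hi or lo < max(2, self.min_vertices):
            raise ConfigurationError(
                f"n_vertices_per_region {self.n_vertices_per_region} must be a valid range "
                f"with lower bound >= {max(2, self.min_vertices)}"
            )
        if not self.frame_schedule:
            raise ConfigurationError("frame_schedule must be non-empty")
        for dur, reps in self.frame_schedule:
            if dur <= 0 or reps < 1:
                raise ConfigurationError(f"invalid frame-schedule entry ({dur}, {reps})")
        if self.latent_dim < 1:
            raise ConfigurationError("latent_dim must be >= 1")
        if min(self.tac_noise_sd, self.feature_noise_sd, self.subject_latent_sd) < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if not 0.0 <= self.alignment_intercept <= 1.0:
            raise ConfigurationError("alignment_intercept must lie in [0, 1]")
        a, b, c = self.distance_decay
        if a < 0 or b < 0:
            raise ConfigurationError("distance_decay a and b must be >= 0")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError("age_range must be (lo, hi) with lo < hi")
        n_frames = sum(reps for _, reps in self.frame_schedule)
        if n_frames < 2 * self.latent_dim:
            raise ConfigurationError(
                f"{n_frames} frames cannot carry {self.latent_dim} latent basis curves; "
                "reduce latent_dim or extend the schedule"
            )
        return self


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    latent_embeddings: np.ndarray          # regions x latent_dim group morphometric embedding
    per_subject_mixing: np.ndarray         # lambda_s in [0, 1]
    planted_decay: tuple[float, float, float]
    seeds_used: list[int] = field(default_factory=list)


def frame_midtimes(frame_schedule) -> np.ndarray:
    """Mid-frame times (s) of a (duration, repetitions) schedule."""
    if not len(frame_schedule):
        raise ValidationError("frame schedule is empty")
    durations = []
    for dur, reps in frame_schedule:
        if dur <= 0:
            raise ValidationError(f"non-positive frame duration {dur}")
        if reps < 1:
            raise ValidationError(f"non-positive repetition count {reps}")
        durations.extend([float(dur)] * int(reps))
    durations = np.asarray(durations)
    ends = np.cumsum(durations)
    return ends - durations / 2.0


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the x > 0 hemisphere (Fibonacci lattice)."""
    i = np.arange(n)
    x = (i + 0.5) / n               # in (0, 1): strictly positive-x half sphere
    r = np.sqrt(1.0 - x**2)
    phi = _GOLDEN_ANGLE * i
    return np.column_stack([x, r * np.cos(phi), r * np.sin(phi)])


def make_geometry(n_regions: int, brain_radius_mm: float = 70.0) -> ParcelGeometry:
    """Two mirrored hemispheric parcel sets with laminar-class bands."""
    if n_regions < 4 or n_regions % 2:
        raise ConfigurationError("n_regions must be even and >= 4")
    half = n_regions // 2
    right = fibonacci_hemisphere(half)
    left = right * np.array([-1.0, 1.0, 1.0])
    sphere = np.vstack([left, right])
    hemisphere = np.array(["L"] * half + ["R"] * half, dtype=object)
    region_ids = [f"{h}_{i:03d}" for h, n in (("L", half), ("R", half)) for i in range(n)]
    # laminar classes as z-bands, symmetric across hemispheres
    edges = np.quantile(right[:, 2], [0.25, 0.5, 0.75])
    band = np.searchsorted(edges, sphere[:, 2])
    laminar = np.array([LAMINAR_CLASSES[b] for b in band], dtype=object)
    return ParcelGeometry(
        region_ids=region_ids,
        centroid_xyz=sphere * brain_radius_mm,
        sphere_xyz=sphere,
        hemisphere=hemisphere,
        laminar_class=laminar,
    ).validate()


def tac_template(t: np.ndarray) -> np.ndarray:
    """Gamma-variate uptake (peak 1) plus irreversible-trapping plateau."""
    t = np.asarray(t, dtype=float)
    u = t**2 * np.exp(-t / _TAC_TAU)
    peak = (2 * _TAC_TAU) ** 2 * np.exp(-2.0)
    return u / peak + _PLATEAU_AMPLITUDE * (1.0 - np.exp(-t / _TAC_TAU))


def _latent_basis(t: np.ndarray, n_curves: int) -> np.ndarray:
    """Orthonormal smooth temporal basis (frames x n_curves) carrying the
    latent modulation; gamma-variate bumps with log-spaced time constants,
    QR-orthonormalised with a deterministic sign convention."""
    taus = np.geomspace(30.0, 3000.0, n_curves)
    raw = np.column_stack([
        (t / tau) ** (1 + (i % 3)) * np.exp(-t / tau) for i, tau in enumerate(taus)
    ])
    q, r = np.linalg.qr(raw)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return q * signs


def _spatial_latent(rng: np.random.Generator, centroids: np.ndarray, b: float,
                    dim: int) -> np.ndarray:
    """Latent columns with inter-region covariance exp(-b * distance)."""
    n = centroids.shape[0]
    if b == 0.0:
        return rng.standard_normal((n, dim))
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    cov = np.exp(-b * d) + 1e-8 * np.eye(n)
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal((n, dim))


def mixing_weights(ages: np.ndarray, intercept: float, slope: float,
                   clip: bool = True) -> np.ndarray:
    """Per-subject alignment weights lambda_s from the age map."""
    ages = np.asarray(ages, dtype=float)
    z = (ages - ages.mean()) / ages.std(ddof=1)
    lam = intercept + slope * z
    out_of_range = (lam < 0) | (lam > 1)
    if np.any(out_of_range) and not clip:
        bad_age = ages[out_of_range][0]
        raise ConfigurationError(
            f"alignment weight {lam[out_of_range][0]:.3f} outside [0, 1] for subject "
            f"age {bad_age:.1f}; enable clip_mixing or shrink the slope/intercept"
        )
    return np.clip(lam, 0.0, 1.0)


def generate_cohort(config: SyntheticConfig):
    """Generate a full synthetic cohort.

    Returns
    -------
    cohort : DataFrame (subject_id, age, sex, tiv)
    tacs : dict subject_id -> TACSet
    features : dict subject_id -> VertexFeatureSet (raw, unstandardized)
    geom : ParcelGeometry
    truth : SyntheticTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_sub, n_reg, dim = config.n_subjects, config.n_regions, config.latent_dim
    a_dec, b_dec, c_dec = config.distance_decay

    geom = make_geometry(n_reg, config.brain_radius_mm)
    t = frame_midtimes(config.frame_schedule)
    base = tac_template(t)
    basis = _latent_basis(t, dim)

    # cohort covariates -----------------------------------------------------
    ages = rng.uniform(*config.age_range, size=n_sub)
    sex = np.arange(n_sub) % 2
    tiv = np.exp(rng.normal(np.log(1.45e6), 0.08, size=n_sub)) * np.where(sex == 1, 1.05, 1.0)
    subject_ids = [f"sub-{i:03d}" for i in range(n_sub)]
    cohort = pd.DataFrame({"subject_id": subject_ids, "age": ages, "sex": sex, "tiv": tiv})

    lam = mixing_weights(ages, config.alignment_intercept, config.alignment_age_slope,
                         clip=config.clip_mixing)

    # latent structure ------------------------------------------------------
    structured = a_dec + c_dec
    w_spatial = a_dec / structured if structured > 0 else 0.0
    morph_core = rng.standard_normal((n_reg, dim))
    metab_core = rng.standard_normal((n_reg, dim))
    spatial = _spatial_latent(rng, geom.centroid_xyz, b_dec, dim)
    loading = rng.standard_normal((dim, len(FEATURE_NAMES))) \
        * (config.feature_loading_scale / np.sqrt(dim))

    sqrt_ws, sqrt_wc = np.sqrt(w_spatial), np.sqrt(1.0 - w_spatial)
    group_morph = sqrt_wc * morph_core + sqrt_ws * spatial

    # per-subject data ------------------------------------------------------
    tacs: dict[str, TACSet] = {}
    features: dict[str, VertexFeatureSet] = {}
    lo, hi = config.n_vertices_per_region
    for s, sid in enumerate(subject_ids):
        morph_s = morph_core + config.subject_latent_sd * rng.standard_normal((n_reg, dim))
        metab_s = metab_core + config.subject_latent_sd * rng.standard_normal((n_reg, dim))
        struct = lam[s] * morph_s + (1.0 - lam[s]) * metab_s
        metab_latent = sqrt_wc * struct + sqrt_ws * spatial
        morph_latent = sqrt_wc * morph_s + sqrt_ws * spatial

        activities = base[None, :] + config.tac_signal_scale * (metab_latent @ basis.T)
        activities = activities + rng.normal(0.0, config.tac_noise_sd, size=activities.shape)
        tacs[sid] = TACSet(subject_id=sid, region_ids=list(geom.region_ids),
                           activities=activities, frame_midtimes=t.copy()).validate()

        counts = rng.integers(lo, hi + 1, size=n_reg)
        means = morph_latent @ loading
        feats = {}
        for r, region in enumerate(geom.region_ids):
            feats[region] = means[r] + config.feature_noise_sd * \
                rng.standard_normal((counts[r], len(FEATURE_NAMES)))
        features[sid] = VertexFeatureSet(subject_id=sid, features=feats,
                                         standardized=False).validate(config.min_vertices)

    truth = SyntheticTruth(latent_embeddings=group_morph, per_subject_mixing=lam,
                           planted_decay=(a_dec, b_dec, c_dec), seeds_used=[config.seed])
    return cohort, tacs, features, geom, truth
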