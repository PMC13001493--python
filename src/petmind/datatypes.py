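"""Core in-memory containers shared across the pipeline.

The pipeline moves four kinds of objects between stages:

* :class:`TACSet` — one subject's regional PET time-activity curves,
* :class:`VertexFeatureSet` — one subject's vertex-wise morphometric
  features grouped by cortical region,
* :class:`SimilarityMatrix` — a symmetric region-by-region edge-weight
  matrix (metabolic connectivity, morphometric similarity, or residuals
  of a distance-decay fit),
* :class:`ParcelGeometry` — parcel centroids, spherical coordinates,
  hemisphere membership and optional laminar-class labels.

Cohort covariates are carried as a plain :class:`pandas.DataFrame` with
columns ``subject_id``, ``age`` (years), ``sex`` (binary 0/1) and ``tiv``
(total intracranial volume).

Every container validates its own invariants via ``validate()``; stages
call it on entry so malformed data fails early with a named culprit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Canonical order of the five vertex-wise morphometric features.
FEATURE_NAMES: tuple[str, ...] = ("thickness", "curvature", "sulc", "area", "volume")

#: Tags a SimilarityMatrix may carry.
MODALITIES: tuple[str, ...] = ("MC", "MIND", "residual")

SYMMETRY_TOL = 1e-12


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(np.asarray(arr)))
        raise ValidationError(f"{name} contains non-finite values at indices {bad[:5].tolist()}")


@dataclass
class TACSet:
    """Regional time-activity curves for one subject.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    region_ids : list of str
        Ordered region labels; the order is shared across all subjects and
        must match :class:`ParcelGeometry`.
    activities : ndarray, shape (n_regions, n_frames)
        Activity concentration per region and frame (e.g. kBq/mL). Raw
        amplitudes are meaningful: no normalisation is applied downstream.
    frame_midtimes : ndarray, shape (n_frames,)
        Mid-frame acquisition times in seconds, strictly increasing.
    """

    subject_id: str
    region_ids: list[str]
    activities: np.ndarray
    frame_midtimes: np.ndarray

    def __post_init__(self) -> None:
        self.activities = np.asarray(self.activities, dtype=float)
        self.frame_midtimes = np.asarray(self.frame_midtimes, dtype=float)

    @property
    def n_regions(self) -> int:
        return self.activities.shape[0]

    @property
    def n_frames(self) -> int:
        return self.activities.shape[1]

    def validate(self) -> "TACSet":
        if self.activities.ndim != 2:
            raise ValidationError("activities must be a 2-D (regions x frames) array")
        n, f = self.activities.shape
        if n < 2 or f < 2:
            raise ValidationError(f"need >=2 regions and >=2 frames, got {n} x {f}")
        if len(self.region_ids) != n:
            raise ValidationError("region_ids length does not match activity rows")
        if self.frame_midtimes.shape != (f,):
            raise ValidationError("frame_midtimes length does not match activity columns")
        if not np.all(np.diff(self.frame_midtimes) > 0):
            raise ValidationError("frame_midtimes must be strictly increasing")
        if not np.all(np.isfinite(self.activities)):
            r, c = np.argwhere(~np.isfinite(self.activities))[0]
            raise ValidationError(
                f"non-finite activity for region {self.region_ids[r]!r} at frame index {c}"
            )
        return self


@dataclass
class VertexFeatureSet:
    """Vertex-wise morphometric features for one subject, grouped by region.

    ``features`` maps each region id to an ``(n_vertices, 5)`` array whose
    columns follow :data:`FEATURE_NAMES`. The ``standardized`` flag records
    whether pooled within-subject z-scoring has been applied; similarity
    construction requires it.
    """

    subject_id: str
    features: dict[str, np.ndarray]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.features = {r: np.asarray(m, dtype=float) for r, m in self.features.items()}

    @property
    def region_ids(self) -> list[str]:
        return list(self.features.keys())

    def n_vertices(self) -> dict[str, int]:
        return {r: m.shape[0] for r, m in self.features.items()}

    def pooled(self) -> np.ndarray:
        """All vertices of all regions stacked into one (V, 5) array."""
        return np.vstack(list(self.features.values()))

    def validate(self, min_vertices: int = 1) -> "VertexFeatureSet":
        if not self.features:
            raise ValidationError("feature set is empty")
        for region, mat in self.features.items():
            if mat.ndim != 2 or mat.shape[1] != len(FEATURE_NAMES):
                raise ValidationError(
                    f"region {region!r}: expected (n_vertices, {len(FEATURE_NAMES)}) matrix, "
                    f"got shape {mat.shape}"
                )
            if mat.shape[0] < min_vertices:
                raise ValidationError(
                    f"region {region!r} has {mat.shape[0]} vertices; need >= {min_vertices}"
                )
            _check_finite(mat, f"features of region {region!r}")
        return self


@dataclass
class SimilarityMatrix:
    """Symmetric region-by-region edge-weight matrix.

    ``modality`` tags the construction ("MC", "MIND" or "residual");
    ``diagonal_convention`` records whether the stored diagonal is the
    conventional 1 ("one") or meaningless ("excluded"). In either case the
    diagonal never enters downstream statistics: vectorisation takes the
    strict upper triangle and nodal strength sums off-diagonal entries.
    """

    region_ids: list[str]
    values: np.ndarray
    modality: str
    diagonal_convention: str = "one"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        """Strict-upper-triangle values (row-major order)."""
        n = self.n_regions
        return self.values[np.triu_indices(n, k=1)]

    def validate(self) -> "SimilarityMatrix":
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"similarity matrix must be square, got shape {v.shape}")
        if len(self.region_ids) != v.shape[0]:
            raise ValidationError("region_ids length does not match matrix size")
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.diagonal_convention not in ("one", "excluded"):
            raise ValidationError(f"unknown diagonal convention {self.diagonal_convention!r}")
        _check_finite(v, "similarity values")
        asym = np.max(np.abs(v - v.T)) if v.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValidationError(f"matrix asymmetric: max |v - v.T| = {asym:.3e} > {SYMMETRY_TOL}")
        off = self.off_diagonal()
        if self.modality == "MC" and off.size:
            if off.min() < -SYMMETRY_TOL or off.max() > 1 + SYMMETRY_TOL:
                raise ValidationError("MC off-diagonal weights must lie in [0, 1]")
            if not np.any(off == 0.0):
                raise ValidationError(
                    "MC matrix must contain an exactly-zero weight (the maximum-distance pair)"
                )
        if self.modality == "MIND" and off.size:
            if off.min() <= 0 or off.max() > 1 + SYMMETRY_TOL:
                raise ValidationError("MIND off-diagonal weights must lie in (0, 1]")
        return self

    def reordered(self, order: np.ndarray) -> "SimilarityMatrix":
        """Return a copy with regions permuted by integer index array `order`."""
        order = np.asarray(order)
        return SimilarityMatrix(
            region_ids=[self.region_ids[i] for i in order],
            values=self.values[np.ix_(order, order)],
            modality=self.modality,
            diagonal_convention=self.diagonal_convention,
        )


@dataclass
class ParcelGeometry:
    """Parcel geometry: volumetric centroids, spherical coordinates,
    hemisphere membership and optional laminar-class labels.

    ``sphere_xyz`` rows are unit vectors on the registration sphere and
    drive the spin-permutation null; ``centroid_xyz`` (mm) drives the
    exponential distance-decay correction.
    """

    region_ids: list[str]
    centroid_xyz: np.ndarray
    sphere_xyz: np.ndarray
    hemisphere: np.ndarray
    laminar_class: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centroid_xyz = np.asarray(self.centroid_xyz, dtype=float)
        self.sphere_xyz = np.asarray(self.sphere_xyz, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        if self.laminar_class is not None:
            self.laminar_class = np.asarray(self.laminar_class, dtype=object)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def hemisphere_indices(self, hemi: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)

    def validate(self) -> "ParcelGeometry":
        n = self.n_regions
        if self.centroid_xyz.shape != (n, 3) or self.sphere_xyz.shape != (n, 3):
            raise ValidationError("centroid_xyz and sphere_xyz must both be (n_regions, 3)")
        _check_finite(self.centroid_xyz, "centroid_xyz")
        _check_finite(self.sphere_xyz, "sphere_xyz")
        norms = np.linalg.norm(self.sphere_xyz, axis=1)
        if np.max(np.abs(norms - 1.0)) > 1e-9:
            raise ValidationError("sphere_xyz rows must be unit-norm (tolerance 1e-9)")
        if self.hemisphere.shape != (n,):
            raise ValidationError("hemisphere must have one label per region")
        if not set(np.unique(self.hemisphere)) <= {"L", "R"}:
            raise ValidationError("hemisphere labels must be 'L' or 'R'")
        for hemi in ("L", "R"):
            if len(self.hemisphere_indices(hemi)) == 0:
                raise ValidationError(f"hemisphere {hemi!r} has no parcels")
        if self.laminar_class is not None and self.laminar_class.shape != (n,):
            raise ValidationError("laminar_class must have one label per region")
        return self


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort covariate table (subject_id, age, sex, tiv)."""
    required = {"subject_id", "age", "sex", "tiv"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
    if cohort["subject_id"].duplicated().any():
        dup = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"duplicate subject_id {dup!r} in cohort table")
    if not set(cohort["sex"].unique()) <= {0, 1}:
        raise ValidationError("sex must be coded 0/1")
    if (cohort["tiv"] <= 0).any():
        raise ValidationError("tiv must be positive")
    if cohort[["age", "tiv"]].isna().any().any():
        raise ValidationError("cohort covariates contain missing values")
    return cohort


def check_matched_regions(a, b) -> None:
    """Raise unless two containers carry identical region order."""
    if list(a.region_ids) != list(b.region_ids):
        raise ValidationError("region order mismatch between inputs")
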