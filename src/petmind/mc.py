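"""Metabolic connectivity from regional time-activity curves.

Individual-level metabolic connectivity (MC) treats each cortical region's
dynamic FDG-PET time-activity curve (TAC) as a point in frame space and
defines the edge weight between two regions as one minus their Euclidean
distance after scaling by the maximum distance over all region pairs:

    w_ij = 1 - d_ij / max_{k<l} d_kl,   d_ij = ||TAC_i - TAC_j||_2

so weights lie in [0, 1], the most dissimilar pair gets exactly 0, and
higher values mean more similar glucose-uptake kinetics. Distances are
max-scaled *within* each subject, so weights are relative to that
subject's most dissimilar pair.

The raw TAC amplitudes enter the distance directly: there is deliberately
no SUV scaling, frame weighting, or curve normalisation, which makes the
measure sensitive to global amplitude changes (a documented property of
the framework, covered by a test).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datatypes import SimilarityMatrix, TACSet
from .errors import DegenerateInputError, ValidationError


def compute_mc(tacs: TACSet) -> SimilarityMatrix:
    """Compute the metabolic connectivity matrix for one subject.

    Parameters
    ----------
    tacs : TACSet
        Regional TACs; validated on entry.

    Returns
    -------
    SimilarityMatrix
        Symmetric matrix with modality "MC", off-diagonal weights in
        [0, 1] (minimum exactly 0), and diagonal stored as 1 under the
        "one" convention (the diagonal never enters statistics).

    Raises
    ------
    DegenerateInputError
        If all TACs are identical (maximum pairwise distance is zero).
    """
    tacs.validate()
    dist = pdist(tacs.activities, metric="euclidean")
    d_max = dist.max()
    if d_max == 0.0:
        raise DegenerateInputError(
            "all time-activity curves are identical; the max-scaled distance is undefined"
        )
    weights = squareform(1.0 - dist / d_max)
    np.fill_diagonal(weights, 1.0)
    return SimilarityMatrix(
        region_ids=list(tacs.region_ids),
        values=weights,
        modality="MC",
        diagonal_convention="one",
    ).validate()


def nodal_strength(m: SimilarityMatrix, atol: float = 1e-9) -> np.ndarray:
    """Weighted degree: per-region sum of off-diagonal edge weights.

    The diagonal is excluded regardless of the matrix's storage convention.
    """
    v = np.asarray(m.values, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValidationError("nodal_strength expects a square matrix")
    asym = np.max(np.abs(v - v.T)) if v.size else 0.0
    if asym > atol:
        raise ValidationError(f"matrix asymmetric beyond tolerance: {asym:.3e} > {atol}")
    return v.sum(axis=1) - np.diag(v)
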