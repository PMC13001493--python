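import numpy as np
import pandas as pd
import pytest

import petmind as pm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort shared across read-only tests."""
    cfg = pm.SyntheticConfig(
        n_subjects=10, n_regions=20, n_vertices_per_region=(12, 20),
        alignment_age_slope=0.4, seed=7,
    )
    cohort, tacs, features, geom, truth = pm.generate_cohort(cfg)
    return {"config": cfg, "cohort": cohort, "tacs": tacs, "features": features,
            "geom": geom, "truth": truth}


@pytest.fixture(scope="session")
def small_matrices(small_cohort):
    """Per-subject MC and MIND matrices for the shared cohort."""
    mc, mind = {}, {}
    for sid in small_cohort["cohort"]["subject_id"]:
        mc[sid] = pm.compute_mc(small_cohort["tacs"][sid])
        mind[sid] = pm.compute_mind(
            pm.standardize_features(small_cohort["features"][sid]))
    return mc, mind


def random_similarity(rng, n, modality="residual", region_ids=None):
    """A random symmetric matrix for oracle tests."""
    values = rng.uniform(0.05, 0.95, size=(n, n))
    values = (values + values.T) / 2
    np.fill_diagonal(values, 1.0)
    return pm.SimilarityMatrix(
        region_ids=region_ids or [f"r{i}" for i in range(n)],
        values=values, modality=modality, diagonal_convention="one")


@pytest.fixture
def cohort_table(rng):
    n = 66
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "age": rng.uniform(38, 86, n),
        "sex": np.arange(n) % 2,
        "tiv": rng.normal(1.45e6, 1e5, n).clip(1e6),
    })
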