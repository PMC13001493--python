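"""Morphometric similarity: standardization, kNN KL estimator, MIND matrices."""

import numpy as np
import pytest

import petmind as pm
from petmind.datatypes import FEATURE_NAMES
from petmind.errors import ConfigurationError, DegenerateInputError, ValidationError


def gaussian_region_set(rng, means, n_vertices=200, subject="s0"):
    feats = {f"r{i}": mu + rng.standard_normal((n_vertices, 5))
             for i, mu in enumerate(np.atleast_2d(means))}
    return pm.VertexFeatureSet(subject_id=subject, features=feats, standardized=False)


class TestStandardize:
    def test_pooled_moments_after_standardization(self, rng):
        raw = gaussian_region_set(rng, [np.zeros(5), np.ones(5) * 3])
        std = pm.standardize_features(raw)
        pooled = std.pooled()
        np.testing.assert_allclose(pooled.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(pooled.std(axis=0, ddof=1), 1.0, atol=1e-10)
        assert std.standardized

    def test_idempotent_on_standardized_input(self, rng):
        std = pm.standardize_features(gaussian_region_set(rng, [np.zeros(5), np.ones(5)]))
        again = pm.standardize_features(
            pm.VertexFeatureSet("s0", std.features, standardized=False))
        for region in std.region_ids:
            np.testing.assert_allclose(again.features[region], std.features[region],
                                       atol=1e-12)

    def test_constant_feature_names_culprit(self, rng):
        raw = gaussian_region_set(rng, [np.zeros(5), np.ones(5)])
        for mat in raw.features.values():
            mat[:, 2] = 7.0  # sulcal depth constant
        with pytest.raises(DegenerateInputError, match="sulc"):
            pm.standardize_features(raw)

    def test_between_region_mean_differences_survive_pooling(self, rng):
        raw = gaussian_region_set(rng, [np.zeros(5), np.full(5, 4.0)])
        std = pm.standardize_features(raw)
        m0 = std.features["r0"].mean(axis=0)
        m1 = std.features["r1"].mean(axis=0)
        assert np.all(m1 - m0 > 1.0)  # ordering of region means preserved


class TestKnnKL:
    def test_identical_gaussians_near_zero(self):
        rng = np.random.default_rng(0)
        p = rng.standard_normal((2000, 5))
        q = rng.standard_normal((2000, 5))
        assert pm.knn_kl(p, q, k=3) == pytest.approx(0.0, abs=0.1)

    def test_shifted_gaussian_matches_closed_form(self):
        # KL(N(0,I2) || N((1,0),I2)) = 0.5 * ||mu||^2 = 0.5 nats
        rng = np.random.default_rng(1)
        p = rng.standard_normal((5000, 2))
        q = rng.standard_normal((5000, 2)) + [1.0, 0.0]
        assert pm.knn_kl(p, q, k=3, clip_negative=False) == pytest.approx(0.5, abs=0.1)

    def test_clip_contract(self, rng):
        # same distribution, tiny n: raw estimate may dip below zero but the
        # clipped value never does
        for seed in range(10):
            r = np.random.default_rng(seed)
            p, q = r.standard_normal((30, 3)), r.standard_normal((30, 3))
            assert pm.knn_kl(p, q, k=3, clip_negative=True) >= 0.0

    def test_sample_size_guards(self, rng):
        with pytest.raises(ValidationError):
            pm.knn_kl(rng.normal(size=(3, 2)), rng.normal(size=(50, 2)), k=3)
        with pytest.raises(ValidationError):
            pm.knn_kl(rng.normal(size=(50, 2)), rng.normal(size=(2, 2)), k=3)
        with pytest.raises(ValidationError):
            pm.knn_kl(rng.normal(size=(50, 2)), rng.normal(size=(50, 3)), k=3)

    def test_coincident_points_floored_not_infinite(self):
        p = np.zeros((10, 2))
        p[5:] = 1.0
        q = np.ones((10, 2))
        est = pm.knn_kl(p, q, k=2)
        assert np.isfinite(est)

    def test_error_decreases_with_sample_size(self):
        """Estimator consistency: mean |error| against the 0.5-nat closed
        form shrinks monotonically over n in {250, 1000, 4000}."""
        errors = []
        for n in (250, 1000, 4000):
            errs = []
            for seed in range(20):
                r = np.random.default_rng(seed)
                p = r.standard_normal((n, 2))
                q = r.standard_normal((n, 2)) + [1.0, 0.0]
                errs.append(abs(pm.knn_kl(p, q, k=3, clip_negative=False) - 0.5))
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]


class TestComputeMIND:
    def test_contract_symmetric_unit_diagonal_unit_interval(self, small_cohort):
        feats = next(iter(small_cohort["features"].values()))
        mind = pm.compute_mind(pm.standardize_features(feats))
        v = mind.values
        np.testing.assert_array_equal(v, v.T)
        np.testing.assert_array_equal(np.diag(v), 1.0)
        off = mind.off_diagonal()
        assert off.min() > 0.0 and off.max() <= 1.0

    def test_same_distribution_regions_approach_one(self, rng):
        raw = gaussian_region_set(rng, [np.zeros(5), np.zeros(5)], n_vertices=2000)
        mind = pm.compute_mind(pm.standardize_features(raw))
        assert mind.values[0, 1] >= 0.95

    def test_separated_gaussians_match_closed_form_similarity(self):
        """Two unit Gaussians one unit apart in 2 of 5 dims have symmetric
        KL = ||dmu||^2 = 2 nats, hence MIND = 1/3. Per-feature z-scoring is
        affine, and the Gaussian KL is affine-invariant, so pooling does
        not move the target."""
        rng = np.random.default_rng(5)
        mu = np.zeros(5)
        mu2 = np.array([1.0, 1.0, 0, 0, 0])
        raw = gaussian_region_set(rng, [mu, mu2], n_vertices=4000)
        std = pm.standardize_features(raw)
        expected = 1.0 / (1.0 + 2.0)
        got = pm.compute_mind(std).values[0, 1]
        assert got == pytest.approx(expected, abs=0.08)

    def test_monotone_decrease_with_separation(self):
        """Larger mean separation gives smaller expected MIND (20 seeds)."""
        vals = {sep: [] for sep in (0.5, 1.5, 3.0)}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            for sep in vals:
                raw = gaussian_region_set(
                    rng, [np.zeros(5), np.full(5, sep / np.sqrt(5))], n_vertices=400)
                vals[sep].append(pm.compute_mind(pm.standardize_features(raw)).values[0, 1])
        means = [np.mean(vals[s]) for s in (0.5, 1.5, 3.0)]
        assert means[0] > means[1] > means[2]

    def test_blockwise_path_equals_pairwise_estimator(self, rng):
        """compute_mind's one-pass order-statistic path must agree exactly
        with independent per-pair knn_kl calls."""
        raw = gaussian_region_set(rng, np.eye(5)[:4] * 2.0, n_vertices=30)
        std = pm.standardize_features(raw)
        cfg = pm.MINDConfig(k=3)
        mind = pm.compute_mind(std, cfg)
        regions = std.region_ids
        for i in range(4):
            for j in range(i + 1, 4):
                d_ij = pm.knn_kl(std.features[regions[i]], std.features[regions[j]], k=3)
                d_ji = pm.knn_kl(std.features[regions[j]], std.features[regions[i]], k=3)
                expected = 1.0 / (1.0 + d_ij + d_ji)
                assert mind.values[i, j] == pytest.approx(expected, rel=1e-10)

    def test_permutation_equivariance(self, rng):
        raw = gaussian_region_set(rng, rng.normal(size=(5, 5)), n_vertices=40)
        std = pm.standardize_features(raw)
        mind = pm.compute_mind(std)
        order = [3, 1, 4, 0, 2]
        permuted_feats = pm.VertexFeatureSet(
            "s0", {std.region_ids[i]: std.features[std.region_ids[i]] for i in order},
            standardized=True)
        mind_p = pm.compute_mind(permuted_feats)
        np.testing.assert_allclose(mind_p.values,
                                   mind.values[np.ix_(order, order)], atol=1e-12)

    def test_small_region_names_culprit(self, rng):
        feats = {"big": rng.standard_normal((20, 5)), "tiny": rng.standard_normal((3, 5))}
        std = pm.VertexFeatureSet("s0", feats, standardized=True)
        with pytest.raises(ValidationError, match="tiny"):
            pm.compute_mind(std, pm.MINDConfig(k=3))

    def test_unstandardized_input_rejected(self, rng):
        raw = gaussian_region_set(rng, [np.zeros(5), np.ones(5)], n_vertices=20)
        with pytest.raises(ValidationError, match="standardize"):
            pm.compute_mind(raw)

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigurationError):
            pm.MINDConfig(k=0).validate()
        with pytest.raises(ConfigurationError):
            pm.MINDConfig(symmetrize="max").validate()
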