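"""Coupling statistics, distance-decay residualization, cohort summaries."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import petmind as pm
from petmind.errors import DegenerateInputError, ValidationError
from tests.conftest import random_similarity


def brute_spearman(x, y):
    """Independent oracle: rank by hand (average ranks) then Pearson."""
    def ranks(v):
        order = np.argsort(v)
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1)
        # average tied ranks
        for val in np.unique(v):
            mask = v == val
            r[mask] = r[mask].mean()
        return r
    return np.corrcoef(ranks(np.asarray(x)), ranks(np.asarray(y)))[0, 1]


def matrix_from_upper(upper, n, region_ids=None, modality="residual"):
    values = squareform(np.asarray(upper, dtype=float))
    np.fill_diagonal(values, 1.0)
    return pm.SimilarityMatrix(region_ids or [f"r{i}" for i in range(n)], values, modality)


class TestVectorize:
    def test_row_major_strict_upper(self):
        m = matrix_from_upper([0.1, 0.2, 0.3], 3)
        np.testing.assert_allclose(pm.vectorize_upper(m), [0.1, 0.2, 0.3])

    def test_length_combinatorics(self, rng):
        m = random_similarity(rng, 4)
        assert pm.vectorize_upper(m).shape == (6,)

    def test_round_trip_bijection(self, rng):
        m = random_similarity(rng, 6)
        vec = pm.vectorize_upper(m)
        back = pm.devectorize_upper(vec, m.region_ids, diagonal=1.0)
        np.testing.assert_array_equal(back.values, m.values)
        assert back.region_ids == m.region_ids


class TestGlobalCoupling:
    def test_identity_gives_rho_one(self, rng):
        m = random_similarity(rng, 6)
        assert pm.global_coupling(m, m)[0] == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self):
        mc = matrix_from_upper([0.1, 0.4, 0.2, 0.9, 0.3, 0.5], 4)
        mind = matrix_from_upper(1 - np.array([0.1, 0.4, 0.2, 0.9, 0.3, 0.5]), 4)
        assert pm.global_coupling(mc, mind)[0] == pytest.approx(-1.0)

    def test_matches_brute_force_rank_pearson(self):
        mc = matrix_from_upper([0.1, 0.4, 0.2, 0.9, 0.3, 0.5], 4)
        mind = matrix_from_upper([0.2, 0.5, 0.1, 0.8, 0.4, 0.3], 4)
        rho, _ = pm.global_coupling(mc, mind)
        assert rho == pytest.approx(
            brute_spearman([0.1, 0.4, 0.2, 0.9, 0.3, 0.5],
                           [0.2, 0.5, 0.1, 0.8, 0.4, 0.3]), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        a, b = random_similarity(rng, 8), random_similarity(rng, 8)
        rho0 = pm.global_coupling(a, b)[0]
        warped = pm.SimilarityMatrix(b.region_ids, np.expm1(2 * b.values) / 10, "residual")
        assert pm.global_coupling(a, warped)[0] == pytest.approx(rho0, abs=1e-12)

    def test_constant_vector_rejected(self):
        flat = matrix_from_upper([0.3] * 6, 4)
        other = matrix_from_upper([0.1, 0.4, 0.2, 0.9, 0.3, 0.5], 4)
        with pytest.raises(DegenerateInputError):
            pm.global_coupling(flat, other)

    def test_region_order_mismatch_rejected(self, rng):
        a = random_similarity(rng, 5)
        b = random_similarity(rng, 5, region_ids=[f"x{i}" for i in range(5)])
        with pytest.raises(ValidationError):
            pm.global_coupling(a, b)


class TestDistanceDecay:
    @staticmethod
    def planted_matrix(geom, a, b, c):
        d = squareform(pdist(geom.centroid_xyz))
        values = a * np.exp(-b * d) + c
        np.fill_diagonal(values, 1.0)
        return pm.SimilarityMatrix(list(geom.region_ids), values, "residual")

    def test_noiseless_parameter_recovery(self):
        geom = pm.make_geometry(40)
        m = self.planted_matrix(geom, 0.5, 0.05, 0.1)
        fit = pm.fit_distance_decay(m, geom)
        assert fit.converged
        assert fit.a == pytest.approx(0.5, abs=1e-4)
        assert fit.b == pytest.approx(0.05, abs=1e-4)
        assert fit.c == pytest.approx(0.1, abs=1e-4)
        assert np.max(np.abs(fit.residual_matrix.off_diagonal())) < 1e-6

    def test_constant_weights_degenerate_flat_fit(self):
        geom = pm.make_geometry(20)
        m = self.planted_matrix(geom, 0.0, 0.0, 0.3)
        fit = pm.fit_distance_decay(m, geom)
        assert fit.a == pytest.approx(0.0, abs=1e-6)
        assert fit.c == pytest.approx(0.3, abs=1e-6)
        assert np.max(np.abs(fit.residual_matrix.off_diagonal())) < 1e-6

    def test_residuals_sum_to_zero_at_optimum(self, rng):
        geom = pm.make_geometry(30)
        d = squareform(pdist(geom.centroid_xyz))
        values = 0.4 * np.exp(-0.03 * d) + 0.2 + rng.normal(0, 0.02, d.shape)
        values = (values + values.T) / 2
        np.fill_diagonal(values, 1.0)
        m = pm.SimilarityMatrix(list(geom.region_ids), values, "residual")
        fit = pm.fit_distance_decay(m, geom)
        # stationarity in the free intercept c forces zero-sum residuals
        assert abs(fit.residual_matrix.off_diagonal().sum()) < 1e-8

    def test_too_few_edges_rejected(self, rng):
        geom = pm.make_geometry(4)
        m = random_similarity(rng, 4, region_ids=list(geom.region_ids))
        with pytest.raises(ValidationError):
            pm.fit_distance_decay(m, geom)


class TestLocalCoupling:
    def test_identity_gives_ones(self, rng):
        m = random_similarity(rng, 6)
        np.testing.assert_allclose(pm.local_coupling(m, m), 1.0)

    def test_reversed_row_gives_minus_one(self):
        mc = matrix_from_upper([0.1, 0.2, 0.3, 0.5, 0.6, 0.7], 4)
        mind_vals = mc.values.copy()
        # reverse the rank order of region 0's profile (rows/cols 0)
        mind_vals[0, 1:] = [0.3, 0.2, 0.1]
        mind_vals[1:, 0] = [0.3, 0.2, 0.1]
        mind = pm.SimilarityMatrix(mc.region_ids, mind_vals, "residual")
        assert pm.local_coupling(mc, mind)[0] == pytest.approx(-1.0)

    def test_matches_brute_force_rowwise(self, rng):
        a, b = random_similarity(rng, 6), random_similarity(rng, 6)
        local = pm.local_coupling(a, b)
        for i in range(6):
            keep = [j for j in range(6) if j != i]
            expected = brute_spearman(a.values[i, keep], b.values[i, keep])
            assert local[i] == pytest.approx(expected, abs=1e-12)

    def test_constant_row_yields_nan(self, rng):
        a = random_similarity(rng, 5)
        vals = a.values.copy()
        vals[0, 1:] = 0.5
        vals[1:, 0] = 0.5
        flat = pm.SimilarityMatrix(a.region_ids, vals, "residual")
        out = pm.local_coupling(flat, a)
        assert np.isnan(out[0]) and np.all(np.isfinite(out[1:]))


class TestStrengthCorrelation:
    def test_identity_and_anticorrelation(self, rng):
        m = random_similarity(rng, 6)
        assert pm.strength_correlation(m, m)[0] == pytest.approx(1.0)
        neg = pm.SimilarityMatrix(m.region_ids, 1.0 - m.values + np.diag(np.ones(6)) * 0,
                                  "residual")
        # affine negation of strengths
        assert pm.strength_correlation(m, neg)[0] == pytest.approx(-1.0)

    def test_matches_brute_force_pearson_on_strengths(self, rng):
        a, b = random_similarity(rng, 6), random_similarity(rng, 6)
        s_a = [a.values[i].sum() - a.values[i, i] for i in range(6)]
        s_b = [b.values[i].sum() - b.values[i, i] for i in range(6)]
        expected = np.corrcoef(s_a, s_b)[0, 1]
        assert pm.strength_correlation(a, b)[0] == pytest.approx(expected, abs=1e-12)


class TestCohortSummary:
    @staticmethod
    def results_from_maps(maps):
        return [pm.CouplingResult(subject_id=f"s{i}", global_rho=0.0, global_p=1.0,
                                  strength_r=0.0, strength_p=1.0,
                                  local_rho=np.asarray(m, dtype=float),
                                  region_ids=[f"r{j}" for j in range(len(m))])
                for i, m in enumerate(maps)]

    def test_identical_subjects_have_zero_mad(self):
        res = self.results_from_maps([[0.1, 0.2, 0.3]] * 4)
        summary = pm.summarize_cohort(res)
        np.testing.assert_allclose(summary.mad_local_rho, 0.0)

    def test_hand_mad(self):
        res = self.results_from_maps([[1.0], [2.0], [3.0]])
        summary = pm.summarize_cohort(res)
        # median 2, absolute deviations {1, 0, 1}, median -> 1 (unscaled)
        assert summary.mad_local_rho[0] == pytest.approx(1.0)

    def test_class_means_match_brute_force(self, small_cohort, small_matrices):
        mc, mind = small_matrices
        geom = small_cohort["geom"]
        results = [pm.couple_matrices(mc[s], mind[s], subject_id=s)
                   for s in small_cohort["cohort"]["subject_id"]]
        summary = pm.summarize_cohort(results, geom)
        assert summary.class_means is not None
        for cls, mean in summary.class_means.items():
            idx = np.flatnonzero(geom.laminar_class == cls)
            expected = np.nanmean(summary.mean_local_rho[idx])
            assert mean == pytest.approx(expected, abs=1e-12)

    def test_nan_entries_excluded_pairwise(self):
        res = self.results_from_maps([[0.2, np.nan], [0.4, 0.6], [0.6, 0.8]])
        summary = pm.summarize_cohort(res)
        assert summary.mean_local_rho[1] == pytest.approx(0.7)

    def test_single_subject_rejected(self):
        with pytest.raises(ValidationError):
            pm.summarize_cohort(self.results_from_maps([[0.1]]))


class TestDistanceCorrectionBehaviour:
    def test_correction_removes_distance_driven_coupling(self):
        """With planted decay and no latent alignment, MC-MIND coupling is
        carried by shared spatial structure; distance residualization must
        shrink it (checked over a handful of replicate cohorts)."""
        shrunk = 0
        n_rep = 5
        for seed in range(n_rep):
            cfg = pm.SyntheticConfig(n_subjects=2, n_regions=60,
                                     n_vertices_per_region=(10, 14),
                                     alignment_intercept=0.0, alignment_age_slope=0.0,
                                     distance_decay=(0.8, 0.04, 0.1),
                                     subject_latent_sd=0.0, seed=100 + seed)
            cohort, tacs, feats, geom, _ = pm.generate_cohort(cfg)
            sid = cohort["subject_id"][0]
            mc = pm.compute_mc(tacs[sid])
            mind = pm.compute_mind(pm.standardize_features(feats[sid]))
            res = pm.couple_matrices(mc, mind, geom, dist_correct=True)
            if abs(res.global_rho_distcorr) < abs(res.global_rho):
                shrunk += 1
        assert shrunk >= n_rep - 1

    def test_correction_preserves_latent_alignment_without_decay(self):
        cfg = pm.SyntheticConfig(n_subjects=2, n_regions=60,
                                 n_vertices_per_region=(12, 16),
                                 alignment_intercept=1.0, alignment_age_slope=0.0,
                                 distance_decay=(0.0, 0.0, 0.1),
                                 tac_noise_sd=0.002, seed=11)
        cohort, tacs, feats, geom, _ = pm.generate_cohort(cfg)
        sid = cohort["subject_id"][0]
        mc = pm.compute_mc(tacs[sid])
        mind = pm.compute_mind(pm.standardize_features(feats[sid]))
        res = pm.couple_matrices(mc, mind, geom, dist_correct=True)
        assert res.global_rho_distcorr == pytest.approx(res.global_rho, abs=0.05)
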