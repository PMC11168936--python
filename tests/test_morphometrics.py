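"""GPA alignment, shape PCA and RRPP permutation inference."""

import numpy as np
import pandas as pd
import pytest

from organgeo.morphometrics import (gpa_align, mean_shape,
                                    pairwise_group_comparison,
                                    procrustes_anova_rrpp, procrustes_distance,
                                    shape_pca)
from tests.conftest import random_rotation


def bumped_configs(n, k=30, amps=None, noise=0.01, seed=0):
    """Open-curve configurations whose bump amplitude is the shape signal."""
    rng = np.random.default_rng(seed)
    base = np.linspace(0, 1, k)[:, None] * np.array([1.0, 0, 0])
    bump = np.sin(np.linspace(0, np.pi, k))[:, None] * np.array([0, 1.0, 0])
    if amps is None:
        amps = rng.uniform(0.2, 1.0, size=n)
    return [base + a * bump + noise * rng.normal(size=(k, 3)) for a in amps], amps


class TestGPA:
    def test_rigid_scale_invariance(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        Y = 2.5 * (X @ random_rotation(1).T) + np.array([10.0, -5.0, 3.0])
        assert procrustes_distance(X, Y) < 1e-10

    def test_two_shape_closed_form(self):
        # optimal-superposition residual for two centred unit-size shapes:
        # d² = 2 − 2·Σσᵢ with σ the (reflection-corrected) singular values
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        Y = rng.normal(size=(10, 3))
        Xc = X - X.mean(0); Xc /= np.sqrt((Xc**2).sum())
        Yc = Y - Y.mean(0); Yc /= np.sqrt((Yc**2).sum())
        U, S, Vt = np.linalg.svd(Yc.T @ Xc)
        if np.linalg.det(U @ Vt) < 0:
            S[-1] *= -1
        expected = np.sqrt(max(2 - 2 * S.sum(), 0.0))
        assert procrustes_distance(X, Y) == pytest.approx(expected, abs=1e-10)

    def test_single_configuration_consensus(self):
        X = np.random.default_rng(4).normal(size=(20, 3))
        a = gpa_align([X])
        Xc = X - X.mean(0)
        Xc /= np.sqrt((Xc**2).sum())
        np.testing.assert_allclose(a.consensus, a.configurations[0], atol=1e-12)
        assert procrustes_distance(a.consensus, Xc) < 1e-10

    def test_mismatched_k_reports_specimen(self):
        X = np.random.default_rng(5).normal(size=(20, 3))
        Y = np.random.default_rng(6).normal(size=(21, 3))
        with pytest.raises(ValueError, match="configuration 1"):
            gpa_align([X, Y])

    def test_objective_nonincreasing_and_unit_size(self):
        configs, _ = bumped_configs(8, seed=7)
        a = gpa_align(configs)
        for c in a.configurations:
            assert np.sqrt((c**2).sum()) == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(c.mean(axis=0), 0.0, atol=1e-9)


class TestMeanShape:
    def test_idempotent_on_identical_shapes(self):
        X = np.random.default_rng(8).normal(size=(15, 3))
        a = gpa_align([X.copy() for _ in range(4)])
        np.testing.assert_allclose(np.asarray(mean_shape(a)),
                                   a.configurations[0], atol=1e-8)

    def test_two_shape_midpoint(self):
        configs, _ = bumped_configs(2, noise=0.0, amps=np.array([0.3, 0.7]))
        a = gpa_align(configs)
        m = np.asarray(mean_shape(a))
        np.testing.assert_allclose(
            m, 0.5 * (a.configurations[0] + a.configurations[1]), atol=1e-12)

    def test_empty_group_rejected(self):
        configs, _ = bumped_configs(3, seed=9)
        a = gpa_align(configs)
        with pytest.raises(ValueError, match="empty"):
            mean_shape(a, np.array([], dtype=int))


class TestShapePCA:
    def test_variance_conserved(self):
        configs, _ = bumped_configs(12, seed=10)
        a = gpa_align(configs)
        pca = shape_pca(a)
        Y = a.flat()
        total = ((Y - Y.mean(0)) ** 2).sum() / (len(Y) - 1)
        assert pca.explained_variance.sum() == pytest.approx(total, rel=1e-9)
        assert pca.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_pc1_tracks_generator_parameter(self):
        configs, amps = bumped_configs(20, noise=0.002, seed=11)
        a = gpa_align(configs)
        pca = shape_pca(a)
        r = np.corrcoef(pca.scores[:, 0], amps)[0, 1]
        assert abs(r) > 0.9

    def test_extreme_at_zero_is_consensus(self):
        configs, _ = bumped_configs(6, seed=12)
        pca = shape_pca(gpa_align(configs))
        np.testing.assert_allclose(np.asarray(pca.extreme_shape(0, 0.0)),
                                   pca.consensus, atol=1e-12)


class TestRrppAnova:
    def strong_effect_set(self, n_per=10, seed=0):
        amps = np.r_[np.full(n_per, 1.0), np.full(n_per, 0.2)]
        configs, _ = bumped_configs(2 * n_per, amps=amps, noise=0.01, seed=seed)
        meta = pd.DataFrame({"sex": ["f"] * n_per + ["m"] * n_per,
                             "noisecov": np.random.default_rng(seed).normal(size=2 * n_per)})
        return gpa_align(configs, metadata=meta)

    def test_p_floor_at_1000_iterations(self):
        a = self.strong_effect_set()
        tab = procrustes_anova_rrpp(a, ["sex"], iterations=1000, seed=1)
        assert tab["sex"]["p"] == pytest.approx(0.001)

    def test_noise_covariate_not_significant(self):
        a = self.strong_effect_set(seed=3)
        tab = procrustes_anova_rrpp(a, ["sex", "noisecov"], iterations=500, seed=2)
        assert tab["noisecov"]["p"] > 0.05
        assert tab["sex"]["p"] <= 0.01

    def test_constant_covariate_aliased(self):
        a = self.strong_effect_set()
        a.metadata["const"] = 1.0
        with pytest.raises(ValueError, match="aliased|constant"):
            procrustes_anova_rrpp(a, ["sex", "const"], iterations=10, seed=0)

    def test_seed_determinism(self):
        a = self.strong_effect_set(seed=4)
        t1 = procrustes_anova_rrpp(a, ["sex", "noisecov"], iterations=100, seed=9)
        t2 = procrustes_anova_rrpp(a, ["sex", "noisecov"], iterations=100, seed=9)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_ss_decomposition_balanced_single_factor(self):
        # one factor, balanced: term SS + residual SS = total SS
        a = self.strong_effect_set(seed=5)
        tab = procrustes_anova_rrpp(a, ["sex"], iterations=10, seed=0)
        total = tab["Total"]["SS"]
        assert tab["sex"]["SS"] + tab["Residuals"]["SS"] == pytest.approx(
            total, rel=1e-9)

    def test_null_p_values_roughly_uniform(self):
        # under a pure-noise design p should be uniform on {1/N,...,1}
        from scipy import stats

        ps = []
        for i in range(120):
            rng = np.random.default_rng(200 + i)
            configs = [rng.normal(size=(8, 3)) for _ in range(12)]
            meta = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6})
            al = gpa_align(configs, metadata=meta)
            tab = procrustes_anova_rrpp(al, ["g"], iterations=100, seed=i)
            ps.append(tab["g"]["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPairwise:
    def test_matrix_symmetric_zero_diagonal(self):
        amps = np.r_[np.full(6, 1.0), np.full(6, 0.5), np.full(6, 0.2)]
        configs, _ = bumped_configs(18, amps=amps, noise=0.01, seed=6)
        meta = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6 + ["c"] * 6})
        res = pairwise_group_comparison(gpa_align(configs, metadata=meta), "g",
                                        iterations=100, seed=0)
        D = res.distances.to_numpy()
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)

    def test_dimorphic_cohort_significant(self):
        amps = np.r_[np.full(10, 1.0), np.full(10, 0.2)]
        configs, _ = bumped_configs(20, amps=amps, noise=0.01, seed=8)
        meta = pd.DataFrame({"sex": ["f"] * 10 + ["m"] * 10})
        res = pairwise_group_comparison(gpa_align(configs, metadata=meta),
                                        "sex", iterations=1000, seed=1)
        assert res.p_values.loc["f", "m"] == pytest.approx(0.001)

    def test_shuffled_labels_not_significant(self):
        rng = np.random.default_rng(13)
        configs = [rng.normal(size=(10, 3)) for _ in range(16)]
        meta = pd.DataFrame({"g": ["a", "b"] * 8})
        res = pairwise_group_comparison(gpa_align(configs, metadata=meta), "g",
                                        iterations=200, seed=2)
        assert res.p_values.loc["a", "b"] > 0.05
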