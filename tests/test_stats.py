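"""Multivariate association models, FDR, permutation and spin nulls."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import gradientkit as gk
from gradientkit.stats import DesignMatrix, design_matrix


def make_design(n, rng, columns=("age", "sex", "bmi")):
    cov = pd.DataFrame({
        "age": rng.uniform(22, 36, n),
        "sex": rng.integers(0, 2, n),
        "bmi": rng.lognormal(3.25, 0.19, n),
    })
    return cov, design_matrix(cov, columns=columns)


class TestHotellingGLM:
    def test_univariate_equals_squared_t(self):
        rng = np.random.default_rng(0)
        n = 40
        cov, X = make_design(n, rng)
        y = 0.1 * cov["bmi"].to_numpy() + rng.standard_normal(n)
        sm = gk.hotelling_glm(y[:, None, None], X, term="bmi")
        # univariate OLS oracle
        import statsmodels.api as smapi
        fit = smapi.OLS(y, X.values).fit()
        t = fit.tvalues[X.columns.index("bmi")]
        p = fit.pvalues[X.columns.index("bmi")]
        assert sm.statistic[0] == pytest.approx(t**2, rel=1e-10)
        assert sm.p_value[0] == pytest.approx(p, rel=1e-10)

    def test_exactly_null_response_gives_zero_statistic(self):
        rng = np.random.default_rng(1)
        n = 30
        cov, X = make_design(n, rng)
        # Y is an exact linear function of age only: bmi coefficient is 0
        Y = np.outer(cov["age"], [1.0, -2.0])[:, None, :]
        sm = gk.hotelling_glm(Y, X, term="bmi")
        assert sm.statistic[0] == pytest.approx(0.0, abs=1e-8)
        assert sm.p_value[0] == pytest.approx(1.0)

    def test_null_rejection_rate_calibrated(self):
        """Gaussian responses independent of BMI: ~5% of 1000 parcels
        rejected at alpha = 0.05."""
        rng = np.random.default_rng(2)
        n = 60
        cov, X = make_design(n, rng)
        Y = rng.standard_normal((n, 1000, 3))
        sm = gk.hotelling_glm(Y, X, term="bmi")
        rate = np.mean(sm.p_value < 0.05)
        assert 0.035 <= rate <= 0.065

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        n = 50
        cov, X = make_design(n, rng)
        Y = rng.standard_normal((n, 1000, 3))
        sm = gk.hotelling_glm(Y, X, term="bmi")
        assert scipy.stats.kstest(sm.p_value, "uniform").pvalue > 0.01

    def test_rank_deficient_design_rejected(self):
        n = 20
        data = pd.DataFrame({
            "intercept": np.ones(n),
            "a": np.arange(n, dtype=float),
            "b": 2.0 * np.arange(n),
        })
        with pytest.raises(ValueError, match="rank deficient"):
            DesignMatrix(data=data)

    def test_too_many_responses_rejected(self):
        rng = np.random.default_rng(4)
        cov, X = make_design(8, rng)
        Y = rng.standard_normal((8, 2, 6))
        with pytest.raises(ValueError, match="few subjects"):
            gk.hotelling_glm(Y, X, term="bmi")


def brute_bh(p, q):
    """Step-up rule written directly from its definition."""
    p = np.asarray(p)
    order = np.argsort(p)
    m = len(p)
    thresh = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            thresh = rank
    reject = np.zeros(m, bool)
    reject[order[:thresh]] = True
    return reject


class TestFdrBH:
    def test_worked_example_all_rejected(self):
        qv, rej = gk.fdr_bh([0.01, 0.02, 0.03, 0.04], 0.05)
        assert rej.all()

    def test_all_ones_none_rejected(self):
        qv, rej = gk.fdr_bh(np.ones(10), 0.05)
        assert not rej.any()
        assert np.allclose(qv, 1.0)

    def test_single_pvalue(self):
        qv, rej = gk.fdr_bh([0.04], 0.05)
        assert rej[0] and qv[0] == pytest.approx(0.04)

    def test_empty_input(self):
        qv, rej = gk.fdr_bh([], 0.05)
        assert qv.size == 0 and rej.size == 0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0),
                    min_size=1, max_size=50))
    def test_matches_bruteforce_stepup(self, p):
        _, rej = gk.fdr_bh(np.asarray(p), 0.05)
        assert np.array_equal(rej, brute_bh(p, 0.05))


class TestPermutationTest:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(30)
        r, p = gk.partial_correlation_permutation(x, x, None, n_perm=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.005

    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(30)
        r, p = gk.partial_correlation_permutation(x, -x, None, n_perm=999, seed=0)
        assert r == pytest.approx(-1.0)
        assert p <= 0.005

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        r1, p1 = gk.partial_correlation_permutation(x, y, None, n_perm=500, seed=3)
        r2, p2 = gk.partial_correlation_permutation(
            2.5 * x - 1.0, 0.3 * y + 7.0, None, n_perm=500, seed=3
        )
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert p1 == p2

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gk.partial_correlation_permutation(
                np.ones(20), np.arange(20.0), None, n_perm=100
            )

    def test_covariate_adjustment_removes_confound(self):
        # x and y only related through the covariate c
        rng = np.random.default_rng(8)
        c = rng.standard_normal(200)
        x = c + 0.3 * rng.standard_normal(200)
        y = c + 0.3 * rng.standard_normal(200)
        covars = DesignMatrix(data=pd.DataFrame(
            {"intercept": np.ones(200), "c": c}))
        r_raw, _ = gk.partial_correlation_permutation(x, y, None, n_perm=200, seed=1)
        r_adj, _ = gk.partial_correlation_permutation(x, y, covars, n_perm=200, seed=1)
        assert r_raw > 0.7
        assert abs(r_adj) < 0.2


class TestSpinNulls:
    def test_identity_rotation_returns_input(self, small_atlas):
        vals = np.arange(40.0)
        out = gk.rotate_parcel_map(vals, small_atlas, Rotation.identity())
        assert np.array_equal(out, vals)

    def test_values_drawn_from_input_multiset(self, small_atlas):
        rng = np.random.default_rng(9)
        vals = rng.standard_normal(40)
        spins = gk.spin_nulls(vals, small_atlas, n_rotations=20, seed=0)
        assert spins.shape == (20, 40)
        for row in spins:
            assert set(row) <= set(vals)

    def test_mean_null_correlation_near_zero(self, small_atlas):
        rng = np.random.default_rng(10)
        vals = rng.standard_normal(40)
        spins = gk.spin_nulls(vals, small_atlas, n_rotations=500, seed=1)
        rs = [np.corrcoef(vals, row)[0, 1] for row in spins]
        assert abs(np.mean(rs)) < 0.05

    def test_preserves_spatial_autocorrelation(self, small_atlas):
        """Rotations keep neighbouring parcels more similar than a free
        shuffle of a smooth map does."""
        smooth = small_atlas.centroids[:, 2]  # latitude: smooth on sphere
        d = small_atlas.centroids @ small_atlas.centroids.T
        np.fill_diagonal(d, -np.inf)
        nn = d.argmax(axis=1)  # nearest neighbour of each parcel

        def neighbour_corr(rows):
            return np.mean([np.corrcoef(row, row[nn])[0, 1] for row in rows])

        spins = gk.spin_nulls(smooth, small_atlas, n_rotations=50, seed=2)
        rng = np.random.default_rng(3)
        shuffles = np.array([rng.permutation(smooth) for _ in range(50)])
        assert neighbour_corr(spins) > neighbour_corr(shuffles) + 0.3

    def test_seeded_determinism(self, small_atlas):
        vals = np.arange(40.0)
        a = gk.spin_nulls(vals, small_atlas, n_rotations=10, seed=4)
        b = gk.spin_nulls(vals, small_atlas, n_rotations=10, seed=4)
        assert np.array_equal(a, b)


class TestGroupHotelling:
    def test_identical_groups_zero_statistic(self):
        rng = np.random.default_rng(11)
        n = 30
        groups = np.repeat([0, 1], 15)
        base = rng.standard_normal((15, 2, 3))
        Y = np.concatenate([base, base])  # identical group distributions
        sm = gk.group_hotelling(Y, groups)
        assert np.all(sm.statistic < 1e-10)

    def test_agrees_with_hotelling_glm(self):
        rng = np.random.default_rng(12)
        n = 40
        groups = rng.integers(0, 2, n)
        cov = pd.DataFrame({"age": rng.uniform(22, 36, n),
                            "sex": rng.integers(0, 2, n)})
        Y = rng.standard_normal((n, 5, 3))
        a = gk.group_hotelling(Y, groups, cov)
        data = pd.DataFrame({"intercept": np.ones(n), "age": cov["age"],
                             "sex": cov["sex"], "group": groups.astype(float)})
        b = gk.hotelling_glm(Y, DesignMatrix(data=data), term="group")
        assert np.allclose(a.statistic, b.statistic)
        assert np.allclose(a.p_value, b.p_value)

    def test_planted_group_shift_recovered(self):
        rng = np.random.default_rng(13)
        n = 80
        groups = np.repeat([0, 1], n // 2)
        Y = rng.standard_normal((n, 20, 3))
        Y[groups == 1, :5, :] += 1.0  # shift first 5 parcels
        sm = gk.group_hotelling(Y, groups)
        assert sm.significant[:5].all()
        assert sm.significant[5:].sum() <= 2

    def test_tiny_group_rejected(self):
        Y = np.zeros((10, 2, 3))
        groups = np.array([0] * 9 + [1])
        with pytest.raises(ValueError, match="too small"):
            gk.group_hotelling(Y, groups)


class TestStratifyMap:
    def _statmap(self, stats):
        stats = np.asarray(stats, float)
        return gk.StatMap(statistic=stats, p_value=np.ones_like(stats),
                          q_value=np.ones_like(stats),
                          significant=np.zeros_like(stats, bool))

    def test_constant_map(self, small_atlas):
        out = gk.stratify_map(self._statmap(np.full(40, 3.3)), small_atlas,
                              by="module_label")
        assert np.allclose(out.to_numpy(), 3.3)

    def test_matches_groupby_bruteforce(self, small_atlas):
        rng = np.random.default_rng(14)
        stats = rng.standard_normal(40)
        out = gk.stratify_map(self._statmap(stats), small_atlas,
                              by="hierarchy_label")
        for label in set(small_atlas.hierarchy_labels):
            manual = np.mean([s for s, l in zip(stats, small_atlas.hierarchy_labels)
                              if l == label])
            assert out[label] == pytest.approx(manual)

    def test_unknown_stratifier_rejected(self, small_atlas):
        with pytest.raises(ValueError):
            gk.stratify_map(self._statmap(np.zeros(40)), small_atlas, by="foo")


class TestSplitHalf:
    def _cohort_embeddings(self, effect, seed=0):
        rng = np.random.default_rng(seed)
        n = 60
        cov = pd.DataFrame({
            "age": rng.uniform(22, 36, n),
            "sex": rng.integers(0, 2, n),
            "bmi": rng.lognormal(3.25, 0.19, n),
        })
        z = (cov["bmi"] - cov["bmi"].mean()) / cov["bmi"].std()
        Y = rng.standard_normal((n, 20, 3))
        Y[:, :5, 0] += effect * z.to_numpy()[:, None]
        return Y, cov

    def test_single_replicate_deterministic(self):
        Y, cov = self._cohort_embeddings(effect=0.0)
        a = gk.split_half_reproducibility(Y, cov, n_train=30, n_rep=1, seed=5)
        b = gk.split_half_reproducibility(Y, cov, n_train=30, n_rep=1, seed=5)
        assert np.array_equal(a["train"], b["train"])
        assert np.array_equal(a["test"], b["test"])

    def test_planted_effect_detected_in_both_splits(self):
        Y, cov = self._cohort_embeddings(effect=1.5, seed=1)
        out = gk.split_half_reproducibility(Y, cov, n_train=30, n_rep=20, seed=2)
        for half in ("train", "test"):
            assert out[half][:5].mean() > out[half][5:].mean()

    def test_undersized_complement_rejected(self):
        Y, cov = self._cohort_embeddings(effect=0.0)
        with pytest.raises(ValueError):
            gk.split_half_reproducibility(Y, cov, n_train=58, n_rep=1)
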