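"""Bootstrap machinery, t-tests, ANOVA, Bayes factors, correlations."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fluencynet import (
    anova_2x2,
    bf10_bic,
    casewise_bootstrap,
    compare_independent,
    compare_paired,
    descriptive_stats,
    random_network_test,
)
from fluencynet.errors import UndefinedStatisticError


# ---------------------------------------------------------------------------
# t-tests


class TestIndependentComparison:
    def test_hand_example(self):
        # pooled sd 1, mean diff -1, se = sqrt(2/3) -> t = -1.2247, d = -1
        res = compare_independent(np.array([1., 2., 3.]),
                                  np.array([2., 3., 4.]))
        assert res.t == pytest.approx(-math.sqrt(1.5), abs=1e-4)
        assert res.d == pytest.approx(-1.0)
        assert res.df == 4

    def test_identical_distributions_null(self):
        a = np.array([1., 2., 3., 4.])
        res = compare_independent(a, a.copy())
        assert res.t == 0.0
        assert res.d == 0.0
        assert res.p == pytest.approx(1.0)
        assert res.ci95[0] < 0 < res.ci95[1]

    def test_zero_pooled_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            compare_independent(np.ones(5), np.ones(5))

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 40), rng.normal(0.4, 1, 40)
        res = compare_independent(a, b)
        import scipy.stats as st
        t, p = st.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)
        assert res.df == 78


class TestPairedComparison:
    def test_hand_example(self):
        # pairs (1,2),(2,2),(3,5): diffs -1,0,-2 -> mean -1, sd 1, t=-sqrt(3)
        res = compare_paired(np.array([1., 2., 3.]), np.array([2., 2., 5.]))
        assert res.t == pytest.approx(-math.sqrt(3))
        assert res.df == 2
        assert res.d == pytest.approx(-1.0)

    def test_equal_series_degenerate(self):
        a = np.array([1., 2., 3.])
        with pytest.raises(UndefinedStatisticError):
            compare_paired(a, a.copy())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_paired(np.ones(3), np.zeros(4))


# ---------------------------------------------------------------------------
# Bayes factors


class TestBayesFactors:
    def test_equal_bics_give_one(self):
        assert bf10_bic(10.0, 10.0) == 1.0

    def test_inverse_formula(self):
        assert bf10_bic(2 * math.log(3), 0.0) == pytest.approx(3.0)

    def test_reciprocal_identity(self):
        b0, b1 = 12.34, -4.5
        assert bf10_bic(b0, b1) * bf10_bic(b1, b0) == pytest.approx(
            1.0, rel=1e-14)

    def test_comparison_bf_positive_and_directional(self):
        rng = np.random.default_rng(8)
        same = compare_independent(rng.normal(0, 1, 200),
                                   rng.normal(0, 1, 200))
        far = compare_independent(rng.normal(0, 1, 200),
                                  rng.normal(2, 1, 200))
        assert same.bf10 > 0
        assert far.bf10 > 3 > same.bf10


# ---------------------------------------------------------------------------
# ANOVA


class TestAnova:
    def _cells(self, low_t1, low_t2, high_t1, high_t2):
        return {("low", "T1"): np.asarray(low_t1, float),
                ("low", "T2"): np.asarray(low_t2, float),
                ("high", "T1"): np.asarray(high_t1, float),
                ("high", "T2"): np.asarray(high_t2, float)}

    def test_constant_cells_undefined(self):
        cells = self._cells(*[np.ones(5)] * 4)
        with pytest.raises(UndefinedStatisticError):
            anova_2x2(cells)

    def test_knowledge_blocks_capture_all_variance(self):
        cells = self._cells(np.zeros(6), np.zeros(6), np.ones(6), np.ones(6))
        res = anova_2x2(cells)
        assert res.effect("knowledge").eta_squared == pytest.approx(1.0)
        assert res.effect("timepoint").eta_squared == pytest.approx(0, abs=1e-12)

    def test_df_bookkeeping(self):
        rng = np.random.default_rng(1)
        cells = self._cells(*(rng.normal(size=10) for _ in range(4)))
        res = anova_2x2(cells)
        for e in res.effects:
            assert e.df_num == 1
            assert e.df_den == 4 * 10 - 4

    def test_matches_closed_form_balanced_decomposition(self):
        rng = np.random.default_rng(2)
        arrays = {k: rng.normal(size=8) for k in
                  [("low", "T1"), ("low", "T2"), ("high", "T1"),
                   ("high", "T2")]}
        res = anova_2x2(arrays)
        # balanced 2x2 closed form: SS_A = 2n * sum_a (mean_a - grand)^2
        n = 8
        grand = np.mean([v.mean() for v in arrays.values()])
        m_low = (arrays[("low", "T1")].mean() + arrays[("low", "T2")].mean()) / 2
        m_high = (arrays[("high", "T1")].mean() + arrays[("high", "T2")].mean()) / 2
        ss_know = 2 * n * ((m_low - grand) ** 2 + (m_high - grand) ** 2)
        ss_total = sum(float(((v - grand) ** 2).sum())
                       for v in arrays.values())
        assert res.effect("knowledge").eta_squared == pytest.approx(
            ss_know / ss_total, abs=1e-10)
        assert sum(e.eta_squared for e in res.effects) <= 1.0

    def test_eta_squared_in_unit_interval(self):
        rng = np.random.default_rng(5)
        cells = self._cells(rng.normal(0, 1, 12), rng.normal(0.2, 1, 12),
                            rng.normal(0.7, 1, 12), rng.normal(1.0, 1, 12))
        for e in anova_2x2(cells).effects:
            assert 0.0 <= e.eta_squared <= 1.0


# ---------------------------------------------------------------------------
# random-network baseline


class TestRandomNetworkTest:
    def test_minimum_p_floor_at_m19(self):
        # caveman-like graph far more clustered than G(n, m)
        g = nx.connected_caveman_graph(4, 5)
        rep = random_network_test(g, M=19, seed=0, metrics=("cc",))
        assert rep["cc"].p_value == pytest.approx(1 / 20)

    def test_p_respects_floor_invariant(self):
        g = nx.gnm_random_graph(15, 30, seed=3)
        rep = random_network_test(g, M=49, seed=1, metrics=("cc", "q"))
        for r in rep.values():
            assert 1 / 50 <= r.p_value <= 1.0

    def test_edgeless_graph_infeasible_for_path_metrics(self):
        from fluencynet.errors import IntegrityError
        with pytest.raises(IntegrityError):
            random_network_test(nx.empty_graph(6), M=19, seed=0,
                                metrics=("aspl",))

    def test_too_few_graphs_rejected(self):
        with pytest.raises(ValueError):
            random_network_test(nx.complete_graph(5), M=10, seed=0)


# ---------------------------------------------------------------------------
# case-wise bootstrap


def _clustered_matrix(n_participants=24, seed=0):
    """Binary response matrix with two production blocks."""
    rng = np.random.default_rng(seed)
    half = n_participants // 2
    X = np.zeros((n_participants, 12), dtype=int)
    X[:half, :7] = (rng.random((half, 7)) < 0.7).astype(int)
    X[half:, 5:] = (rng.random((half, 7)) < 0.7).astype(int)
    X[:, 5] = 1  # shared core so nothing is zero-produced
    return pd.DataFrame(X, columns=[f"w{i:02d}" for i in range(12)],
                        index=[f"p{i:02d}" for i in range(n_participants)])


class TestCasewiseBootstrap:
    def test_same_seed_is_bit_identical(self):
        m = _clustered_matrix()
        a = casewise_bootstrap(m, B=20, seed=7, louvain_runs=2)
        b = casewise_bootstrap(m, B=20, seed=7, louvain_runs=2)
        pd.testing.assert_frame_equal(a.values, b.values)
        assert a.values.shape == (20, 3)

    def test_different_seeds_differ(self):
        m = _clustered_matrix()
        a = casewise_bootstrap(m, B=10, seed=1, louvain_runs=2)
        b = casewise_bootstrap(m, B=10, seed=2, louvain_runs=2)
        assert not a.values.equals(b.values)

    def test_too_few_participants_rejected(self):
        from fluencynet.errors import EmptyResultError
        with pytest.raises(EmptyResultError):
            casewise_bootstrap(_clustered_matrix().iloc[:3], B=5, seed=0)

    def test_bootstrap_mean_tracks_full_sample_metric(self):
        from fluencynet import cosine_similarity, metric_set, tmfg
        m = _clustered_matrix(n_participants=60, seed=4)
        dist = casewise_bootstrap(m, B=100, seed=5, louvain_runs=2)
        full = metric_set(tmfg(cosine_similarity(m)), seed=0)
        cc = dist.metric("cc")
        assert abs(cc.mean() - full.cc) <= 3 * cc.std(ddof=1)


# ---------------------------------------------------------------------------
# descriptive correlations


class TestDescriptiveStats:
    def test_perfectly_linear_pairs(self):
        s = pd.Series([1., 2., 3.], index=list("abc"))
        out = descriptive_stats(s, fluency={"f": s * 2 + 1}, grades=None)
        row = out[(out.var1 == "score") & (out.var2 == "f")].iloc[0]
        assert row.r == pytest.approx(1.0)

    def test_negative_hand_example(self):
        x = pd.Series([1., 2., 3.], index=list("abc"))
        y = pd.Series([6., 4., 2.], index=list("abc"))
        out = descriptive_stats(x, fluency={"y": y})
        assert out.iloc[0].r == pytest.approx(-1.0)

    def test_matches_brute_force_covariance(self):
        rng = np.random.default_rng(12)
        idx = [f"p{i}" for i in range(200)]
        x = pd.Series(rng.normal(10, 3, 200), index=idx)
        y = pd.Series(x * 0.5 + rng.normal(0, 2, 200), index=idx)
        out = descriptive_stats(x, fluency={"y": y})
        xv, yv = x.to_numpy(), y.to_numpy()
        r_brute = (np.mean((xv - xv.mean()) * (yv - yv.mean()))
                   / (xv.std() * yv.std()))
        assert out.iloc[0].r == pytest.approx(r_brute, abs=1e-12)

    def test_grades_log_transformed_and_pairwise_complete(self):
        idx = [f"p{i}" for i in range(6)]
        score = pd.Series([10, 12, 15, 20, 22, 25.], index=idx)
        grades = pd.Series([1, 2, np.nan, 4, 8, 9.], index=idx)
        out = descriptive_stats(score, grades=grades)
        row = out[(out.var1 == "score") & (out.var2 == "grade")].iloc[0]
        assert row.n == 5
        import scipy.stats as st
        mask = grades.notna()
        expect, _ = st.pearsonr(score[mask], np.log(grades[mask]))
        assert row.r == pytest.approx(expect, abs=1e-12)

    def test_constant_variable_reported_missing(self):
        s = pd.Series([1., 2., 3., 4.])
        out = descriptive_stats(s, fluency={"c": pd.Series([5., 5., 5., 5.])})
        assert np.isnan(out.iloc[0].r)

    def test_nonpositive_grades_rejected(self):
        s = pd.Series([1., 2., 3.])
        with pytest.raises(ValueError):
            descriptive_stats(s, grades=pd.Series([0., 1., 2.]))
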