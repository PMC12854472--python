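import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ggdrift.ancestral import estimate_ancestral_states
from ggdrift.datasets import HOMINOID_TRAIT_COUNT, hominoid_branch_table, hominoid_tree
from ggdrift.io import AnalysisConfig, BranchParams
from ggdrift.rates import (
    REGIMES,
    branch_rates,
    classify_rate,
    ggd,
    mahalanobis_sq,
    rate_thresholds,
    rates_table,
    regime_rank,
    scale_by_ne_t,
)

SHADE_OF_REGIME = {
    "very_slow": "S",
    "slow": "S",
    "neutral": "N",
    "fast": "F",
    "very_fast": "F",
}


class TestMahalanobis:
    def test_null_difference(self):
        z = np.array([1.0, 2.0, 3.0])
        assert mahalanobis_sq(z, z, np.eye(3)) == 0.0

    def test_euclidean_special_case(self):
        assert mahalanobis_sq(np.array([3.0, 4.0]), np.zeros(2), np.eye(2)) == pytest.approx(25.0)

    def test_hand_quadratic_form(self):
        W = np.array([[1.0, 0.5], [0.5, 1.0]])
        W_inv = np.linalg.inv(W)
        assert mahalanobis_sq(np.ones(2), np.zeros(2), W_inv) == pytest.approx(4.0 / 3.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            mahalanobis_sq(np.ones(2), np.ones(3), np.eye(2))


class TestGGD:
    def test_published_human_branch(self):
        assert round(scale_by_ne_t(669.03, 0.18), 2) == pytest.approx(120.43)

    def test_zero_d2(self):
        assert scale_by_ne_t(0.0, 0.5) == 0.0

    def test_published_bonobo_branch(self):
        assert round(scale_by_ne_t(150.91, 0.27), 2) == pytest.approx(40.75)

    def test_ggd_via_params(self, simple_params):
        # simple_params has Ne/t = 1 (mean), 0.5 (lower), 2 (upper)
        assert ggd(10.0, simple_params, "mean") == pytest.approx(10.0)
        assert ggd(10.0, simple_params, "lower") == pytest.approx(5.0)
        assert ggd(10.0, simple_params, "upper") == pytest.approx(20.0)

    def test_negative_d2_rejected(self):
        with pytest.raises(ValueError):
            scale_by_ne_t(-1.0, 0.5)

    @given(d2=st.floats(0, 1e4), ne_t=st.floats(1e-3, 1e3))
    def test_linearity(self, d2, ne_t):
        assert scale_by_ne_t(2 * d2, ne_t) == pytest.approx(2 * scale_by_ne_t(d2, ne_t))
        assert scale_by_ne_t(d2, 2 * ne_t) == pytest.approx(2 * scale_by_ne_t(d2, ne_t))


class TestClassify:
    def test_chi_square_mean_is_neutral(self):
        assert classify_rate(46.0, df=46) == "neutral"

    def test_published_human_value_very_fast(self):
        # independent quantile oracle
        assert 120.43 > stats.chi2.ppf(0.999, 46)
        assert classify_rate(120.43, df=46) == "very_fast"

    def test_published_bonobo_value_neutral(self):
        assert stats.chi2.ppf(0.05, 46) < 40.75 < stats.chi2.ppf(0.95, 46)
        assert classify_rate(40.75, df=46) == "neutral"

    def test_thresholds_against_oracle(self):
        q = rate_thresholds(46)
        np.testing.assert_allclose(q, stats.chi2.ppf([0.001, 0.05, 0.95, 0.999], 46))

    def test_halved_convention(self):
        q = rate_thresholds(46, tail_convention="halved")
        np.testing.assert_allclose(q, stats.chi2.ppf([0.0005, 0.025, 0.975, 0.9995], 46))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_rate(1.0, df=0)
        with pytest.raises(ValueError):
            classify_rate(1.0, df=5, alpha_levels=(0.001, 0.05))

    @given(
        g1=st.floats(0, 200),
        g2=st.floats(0, 200),
        df=st.integers(1, 60),
    )
    def test_monotone_in_ggd(self, g1, g2, df):
        lo, hi = sorted([g1, g2])
        assert regime_rank(classify_rate(lo, df)) <= regime_rank(classify_rate(hi, df))

    def test_all_regimes_reachable(self):
        q = rate_thresholds(6)
        values = [q[0] / 2, (q[0] + q[1]) / 2, 6.0, (q[2] + q[3]) / 2, q[3] * 2]
        assert [classify_rate(v, 6) for v in values] == list(REGIMES)


class TestPublishedTable:
    """The printed 28-branch table is internally consistent with the GGD
    arithmetic and the default two-tailed regime convention."""

    @pytest.fixture
    def table(self):
        return hominoid_branch_table()

    @pytest.mark.parametrize("which", ["mean", "lower", "upper"])
    def test_ggd_arithmetic_2dp(self, table, which):
        # printed Ne/t is rounded to 2 dp, so allow +-0.005 on the ratio
        for _, row in table.iterrows():
            recomputed = scale_by_ne_t(row["d2"], row[f"ne_t_{which}"])
            tol = 0.005 + 0.005 * row["d2"]
            assert abs(row[f"ggd_{which}"] - recomputed) <= tol, (
                row["ancestor"], row["descendant"], which)

    @pytest.mark.parametrize("which", ["mean", "lower", "upper"])
    def test_regime_concordance(self, table, which):
        for _, row in table.iterrows():
            regime = classify_rate(row[f"ggd_{which}"], df=HOMINOID_TRAIT_COUNT)
            assert SHADE_OF_REGIME[regime] == row[f"shade_{which}"], (
                row["ancestor"], row["descendant"], which, regime)


class TestBranchRates:
    def _setup(self, tree, tip_values):
        means = pd.DataFrame(tip_values, index=tree.tip_labels)
        anc = estimate_ancestral_states(tree, means)
        params = {
            str(n): BranchParams(
                node_id=str(n), Ne_mean=10000, Ne_lower=5000, Ne_upper=20000,
                divergence_time=250000, generation_length=25,
            )
            for n in tree.internal_nodes
        }
        return means, anc, params

    def test_15_tip_tree_gives_28_results(self, rng):
        tree = hominoid_tree()
        vals = {f"x{k}": rng.normal(size=15) for k in range(3)}
        means, anc, params = self._setup(tree, vals)
        # name internal nodes by their Newick labels (1-14)
        name = lambda n: tree.node_label.get(n, tree.tip_label.get(n, str(n)))
        params = {name(n): bp for n, bp in zip(tree.internal_nodes, params.values())}
        results = branch_rates(
            tree, anc, means, lambda a, c: np.eye(3), params,
            node_name=name,
        )
        assert len(results) == 28
        descs = {r.descendant for r in results}
        assert "Homo_sapiens" in descs and "13" in descs

    def test_equal_tips_all_very_slow(self):
        tree = hominoid_tree()
        vals = {"x": np.ones(15), "y": np.full(15, 2.0)}
        means, anc, params = self._setup(tree, vals)
        name = lambda n: tree.node_label.get(n, tree.tip_label.get(n, str(n)))
        params = {name(n): bp for n, bp in zip(tree.internal_nodes, params.values())}
        results = branch_rates(tree, anc, means, lambda a, c: np.eye(2), params,
                               node_name=name)
        assert all(r.d2 == pytest.approx(0.0, abs=1e-18) for r in results)
        assert all(r.regime["mean"] == "very_slow" for r in results)

    def test_doubling_ne_doubles_ggd_never_lowers_regime(self, rng, small_trees):
        tree = small_trees[3]
        vals = {f"x{k}": rng.normal(size=5) for k in range(2)}
        means, anc, params = self._setup(tree, vals)
        doubled = {
            k: BranchParams(
                node_id=k, Ne_mean=2 * bp.Ne_mean, Ne_lower=2 * bp.Ne_lower,
                Ne_upper=2 * bp.Ne_upper, divergence_time=bp.divergence_time,
                generation_length=bp.generation_length,
            )
            for k, bp in params.items()
        }
        r1 = branch_rates(tree, anc, means, lambda a, c: np.eye(2), params)
        r2 = branch_rates(tree, anc, means, lambda a, c: np.eye(2), doubled)
        for a, b in zip(r1, r2):
            for w in ("mean", "lower", "upper"):
                assert b.ggd[w] == pytest.approx(2 * a.ggd[w], rel=1e-12)
                assert regime_rank(b.regime[w]) >= regime_rank(a.regime[w])

    def test_missing_params_error(self, rng, small_trees):
        tree = small_trees[1]
        vals = {"x": rng.normal(size=3)}
        means, anc, _ = self._setup(tree, vals)
        with pytest.raises(KeyError, match="demographic"):
            branch_rates(tree, anc, means, lambda a, c: np.eye(1), {})

    def test_rates_table_output(self, rng, small_trees, tmp_path):
        tree = small_trees[1]
        vals = {"x": rng.normal(size=3)}
        means, anc, params = self._setup(tree, vals)
        results = branch_rates(tree, anc, means, lambda a, c: np.eye(1), params)
        out = tmp_path / "rates.tsv"
        df = rates_table(results, out)
        assert len(df) == 4
        back = pd.read_csv(out, sep="\t")
        assert "ggd_mean_2dp" in back.columns
        assert set(back["regime_mean"]).issubset(set(REGIMES))
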