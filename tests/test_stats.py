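"""Statistical layer: routing, effect sizes, FDR, ART-ANOVA, QC-FC."""

import numpy as np
import pandas as pd
import pytest

from dotconn.stats import (
    art_anova,
    auto_compare_groups,
    bh_fdr,
    chi_squared,
    correlate,
    hedges_g,
    partial_correlation,
    qc_fc,
    two_way_anova,
)
from tests import oracles


class TestHedgesG:
    def test_identical_samples_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert hedges_g(x, x) == 0.0

    def test_unit_shift_by_hand(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 3.0, 4.0])
        # d = -1, J = 1 - 3/15 = 0.8 -> g = -0.8
        assert hedges_g(a, b) == pytest.approx(-0.8)
        assert hedges_g(b, a) == pytest.approx(0.8)

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(20), rng.standard_normal(25) + 0.5
        g0 = hedges_g(x, y)
        assert hedges_g(3 * x + 7, 3 * y + 7) == pytest.approx(g0)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            hedges_g(np.ones(5), np.ones(5))


class TestBhFdr:
    def test_step_up_by_hand(self):
        adj = bh_fdr([0.002, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.008, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.04] * 5), [0.04] * 5)

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=12).tolist()
        np.testing.assert_allclose(bh_fdr(p), oracles.bh_adjust(p))

    def test_never_below_raw(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=30)
        assert np.all(bh_fdr(p) >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestChiSquared:
    def test_table_matching_expectation_is_zero(self):
        res = chi_squared([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table_by_hand(self):
        res = chi_squared([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        table = rng.integers(1, 40, size=(3, 4))
        res = chi_squared(table)
        assert res.statistic == pytest.approx(oracles.chi2_stat(table))

    def test_home_testing_proportions(self):
        # 2x3 table from printed group sizes and home-testing percentages:
        # 11/22, 15/22, 16/21 tested at home
        table = [[11, 11], [15, 7], [16, 5]]
        res = chi_squared(table)
        assert res.statistic == pytest.approx(3.41, abs=0.01)
        assert res.p == pytest.approx(0.18, abs=0.01)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_squared([[0, 0], [5, 5]])


class TestAutoCompareGroups:
    def test_gaussian_samples_route_parametric(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.standard_normal(50) for k in ("a", "b", "c")}
        res = auto_compare_groups(groups)
        assert res.parametric
        assert res.omnibus.test == "anova"
        assert set(res.pairwise["test"]) == {"welch-t"}

    def test_heavy_tailed_samples_route_nonparametric(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.standard_cauchy(50) for k in ("a", "b")}
        res = auto_compare_groups(groups)
        assert not res.parametric
        assert res.omnibus.test == "mann-whitney"

    def test_zero_variance_group_warns_nonparametric(self):
        rng = np.random.default_rng(5)
        groups = {"a": np.ones(10), "b": rng.standard_normal(10)}
        with pytest.warns(UserWarning, match="zero variance"):
            res = auto_compare_groups(groups)
        assert not res.parametric

    def test_null_family_rarely_significant(self):
        """Under the null, BH-corrected pairwise families stay clean in ≥93%
        of repetitions (the family-wise error of BH at alpha = 0.05)."""
        rng = np.random.default_rng(6)
        clean = 0
        n_rep = 100
        for _ in range(n_rep):
            groups = {k: rng.standard_normal(15) for k in ("a", "b", "c")}
            res = auto_compare_groups(groups)
            if (res.pairwise["p_fdr"] > 0.05).all():
                clean += 1
        assert clean >= 93

    def test_effect_detected_with_sign(self):
        rng = np.random.default_rng(7)
        res = auto_compare_groups(
            {"lo": rng.standard_normal(30), "hi": rng.standard_normal(30) + 2.0}
        )
        row = res.pairwise.iloc[0]
        assert row["p_fdr"] < 0.001
        assert row["g"] < -1  # lo - hi


class TestCorrelate:
    def test_linear_relation_pearson(self):
        x = np.linspace(0, 1, 30)
        res = correlate(x, 2 * x + 1, route="pearson")
        assert res.coefficient == pytest.approx(1.0)

    def test_rank_reversal_spearman(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(size=40)
        res = correlate(x, -np.argsort(np.argsort(x)).astype(float), route="spearman")
        assert res.coefficient == pytest.approx(-1.0)

    def test_null_calibration(self):
        rng = np.random.default_rng(9)
        rs = []
        for _ in range(200):
            res = correlate(rng.standard_normal(100), rng.standard_normal(100), route="pearson")
            rs.append(res.coefficient)
        assert abs(np.mean(rs)) < 0.03

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.ones(10), np.arange(10.0))


class TestPartialCorrelation:
    def test_formula_arithmetic(self):
        # r_xy = r_xz = r_yz = 0.5 -> (0.5 - 0.25)/0.75 = 1/3; build exact data
        # via the closed form instead: feed correlations directly
        from dotconn.stats import partial_correlation as pc

        # construct series with the prescribed sample correlations
        rng = np.random.default_rng(10)
        z = rng.standard_normal(5000)
        e1, e2 = rng.standard_normal((2, 5000))
        x = 0.5 * z + np.sqrt(1 - 0.25) * e1
        y = 0.5 * z + np.sqrt(1 - 0.25) * e2
        res = pc(x, y, z)
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert res.coefficient == pytest.approx(expected)
        assert (0.5 - 0.25) / 0.75 == pytest.approx(1 / 3)

    def test_uncorrelated_covariate_equals_plain_r(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(2000)
        y = 0.6 * x + 0.8 * rng.standard_normal(2000)
        z = rng.standard_normal(2000)
        res = partial_correlation(x, y, z)
        assert res.coefficient == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.02)

    def test_collinear_covariate_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(x, np.random.default_rng(0).standard_normal(10), x)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        x, y, z = rng.standard_normal((3, 60))
        ours = partial_correlation(x, y, z)
        theirs = pg.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        assert ours.coefficient == pytest.approx(float(theirs["r"].iloc[0]), abs=1e-10)
        assert ours.p == pytest.approx(float(theirs["p_val"].iloc[0]), abs=1e-8)


class TestAnova:
    def _factorial(self, rng, n=20, shift_a=0.0, la=3, lb=3):
        y, a, b = [], [], []
        for i in range(la):
            for j in range(lb):
                y.append(rng.standard_normal(n) + shift_a * i)
                a.extend([f"A{i}"] * n)
                b.extend([f"B{j}"] * n)
        return np.concatenate(y), np.array(a), np.array(b)

    def test_art_detects_pure_main_effect(self):
        rng = np.random.default_rng(5)
        y, a, b = self._factorial(rng, shift_a=3.0)
        res = art_anova(y, a, b)
        assert res["A"].p < 0.01
        assert res["A:B"].p > 0.05

    def test_art_aligned_ranks_sum_property(self):
        # ranks of the aligned responses are a permutation of 1..n
        from scipy.stats import rankdata

        rng = np.random.default_rng(6)
        y, a, b = self._factorial(rng, n=5)
        n = len(y)
        assert rankdata(y).sum() == n * (n + 1) / 2  # rank invariant the ART relies on

    def test_art_null_calibration(self):
        """Type-I error of each ART effect within [0.03, 0.07] at alpha=0.05."""
        rng = np.random.default_rng(7)
        rejections = {"A": 0, "B": 0, "A:B": 0}
        n_rep = 500
        for _ in range(n_rep):
            y, a, b = self._factorial(rng, n=20, la=2, lb=2)
            res = art_anova(y, a, b)
            for k in rejections:
                rejections[k] += res[k].p < 0.05
        for k, cnt in rejections.items():
            assert 0.03 <= cnt / n_rep <= 0.07, (k, cnt / n_rep)

    def test_balanced_matches_statsmodels(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(8)
        y, a, b = self._factorial(rng, n=8, shift_a=1.0)
        table, _ = two_way_anova(y, a, b)
        df = pd.DataFrame({"y": y, "a": a, "b": b})
        ref = anova_lm(smf.ols("y ~ C(a) * C(b)", data=df).fit(), typ=2)
        assert table[table.effect == "A"]["F"].iloc[0] == pytest.approx(ref.loc["C(a)", "F"])
        assert table[table.effect == "A:B"]["F"].iloc[0] == pytest.approx(
            ref.loc["C(a):C(b)", "F"]
        )

    def test_unbalanced_layout_supported(self):
        rng = np.random.default_rng(9)
        y, a, b = self._factorial(rng, n=6, shift_a=2.0)
        keep = np.ones(len(y), dtype=bool)
        keep[:2] = False  # make one cell smaller
        table, tukey = two_way_anova(y[keep], a[keep], b[keep])
        assert table[table.effect == "A"]["p"].iloc[0] < 0.01
        assert len(tukey) == 3  # three pairwise group comparisons

    def test_sparse_cell_rejected(self):
        y = np.arange(8.0)
        a = np.array(["x"] * 4 + ["y"] * 4)
        b = np.array(["u", "u", "u", "v", "u", "u", "u", "u"])  # cell (y,v) empty
        with pytest.raises(ValueError):
            art_anova(y, a, b)


class TestQcFc:
    def _cms(self, n_subj, rng):
        from tests.test_graph import cm_from

        return [
            cm_from(rng.standard_normal((80, 5)), networks=list("abcde"))
            for _ in range(n_subj)
        ]

    def test_constant_burdens_empty_with_warning(self):
        rng = np.random.default_rng(10)
        cms = self._cms(5, rng)
        centroids = {p: np.array([p, 0.0, 0.0]) for p in range(1, 6)}
        with pytest.warns(UserWarning, match="constant"):
            out = qc_fc(cms, [5.0] * 5, centroids)
        assert out.empty

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(11)
        centroids = {p: np.array([10.0 * p, 0.0, 0.0]) for p in range(1, 6)}
        means = []
        for _ in range(50):
            cms = self._cms(8, rng)
            burdens = rng.uniform(0, 30, size=8)
            means.append(qc_fc(cms, burdens, centroids)["r"].mean())
        assert abs(np.mean(means)) < 0.05

    def test_sorted_by_distance_and_deterministic(self):
        rng = np.random.default_rng(12)
        cms = self._cms(6, rng)
        centroids = {p: np.array([3.0 * p**2, 0.0, 0.0]) for p in range(1, 6)}
        burdens = rng.uniform(0, 30, size=6)
        out1 = qc_fc(cms, burdens, centroids)
        out2 = qc_fc(cms, burdens, centroids)
        assert out1["distance"].is_monotonic_increasing
        pd.testing.assert_frame_equal(out1, out2)
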