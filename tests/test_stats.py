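"""Agreement statistics against independent references and frozen hand values."""

import numpy as np
import pytest
from scipy import stats as sps

from cpetvt import (
    ValidationError,
    agreement_report,
    bland_altman,
    icc_absolute_agreement,
    t_tests,
    tost_paired,
)


def anova_icc_oracle(x):
    """Independent ICC(2,1) from an explicit sum-of-squares decomposition."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestBlandAltman:
    def test_identical_pairs(self):
        ba = bland_altman([150.0, 200.0, 250.0], [150.0, 200.0, 250.0])
        assert ba.bias == 0.0 and ba.sd_diff == 0.0
        assert (ba.loa_low, ba.loa_high) == (0.0, 0.0)

    def test_hand_computed_example(self):
        ba = bland_altman([10.0, 20.0, 30.0], [12.0, 19.0, 33.0])
        assert ba.bias == pytest.approx(-1.3333, abs=1e-4)
        assert ba.sd_diff == pytest.approx(2.0817, abs=1e-4)
        assert ba.loa_low == pytest.approx(-5.4134, abs=1e-4)
        assert ba.loa_high == pytest.approx(2.7468, abs=1e-4)

    def test_loa_width_is_2x196_sd(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 40))
        ba = bland_altman(x, y)
        assert ba.loa_high - ba.loa_low == pytest.approx(2 * 1.96 * ba.sd_diff)

    def test_needs_two_pairs(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0], [2.0])


class TestTost:
    def test_symmetric_example(self):
        # mean 0, sample SD exactly 10, n = 25
        d = 10.0 * np.array([1.0] * 12 + [-1.0] * 12 + [0.0])
        assert float(d.mean()) == 0.0 and float(d.std(ddof=1)) == pytest.approx(10.0)
        res = tost_paired(d, bound=25.0)
        assert res.t_lower == pytest.approx(12.5)
        assert res.t_upper == pytest.approx(-12.5)
        assert res.df == 24
        assert res.equivalent

    def test_mean_on_the_bound_is_not_equivalent(self):
        res = tost_paired([20.0, 30.0], bound=25.0)
        assert res.t_upper == pytest.approx(0.0)
        assert res.p_upper == pytest.approx(0.5)
        assert not res.equivalent

    def test_df_convention(self):
        rng = np.random.default_rng(1)
        assert tost_paired(rng.normal(0, 5, 133), bound=25.0).df == 132

    def test_negation_symmetry(self):
        rng = np.random.default_rng(2)
        d = rng.normal(3, 8, 30)
        a = tost_paired(d, bound=25.0)
        b = tost_paired(-d, bound=25.0)
        assert b.t_lower == pytest.approx(-a.t_upper)
        assert b.t_upper == pytest.approx(-a.t_lower)
        assert b.p_equiv == pytest.approx(a.p_equiv)

    @pytest.mark.parametrize("mean,equivalent", [(5.0, True), (40.0, False)])
    def test_zero_variance_cases(self, mean, equivalent):
        res = tost_paired([mean] * 10, bound=25.0)
        assert res.equivalent is equivalent
        assert res.p_equiv < 1e-300 if equivalent else res.p_equiv == 1.0

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.weightstats import ttost_paired

        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(150, 30, 20)
            y = x + rng.normal(2, 10, 20)
            mine = tost_paired(x - y, bound=25.0)
            p_ref, lower, upper = ttost_paired(x, y, -25.0, 25.0)
            assert mine.p_equiv == pytest.approx(p_ref, abs=1e-10)
            assert mine.t_lower == pytest.approx(lower[0], abs=1e-10)
            assert mine.t_upper == pytest.approx(upper[0], abs=1e-10)


class TestIcc:
    def test_identical_raters_give_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0], [9.0, 9.0]])
        assert icc_absolute_agreement(x).icc == pytest.approx(1.0)

    def test_matches_anova_oracle(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
        assert icc_absolute_agreement(x).icc == pytest.approx(anova_icc_oracle(x), abs=1e-12)

    def test_constant_rater_against_spread_is_near_zero(self):
        rng = np.random.default_rng(4)
        x = np.column_stack([np.full(20, 5.0), rng.normal(5, 3, 20)])
        assert abs(icc_absolute_agreement(x).icc) < 0.3

    def test_shift_invariance_and_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(100, 20, size=(12, 2))
            x[:, 1] += rng.normal(0, 10, 12)
            r = icc_absolute_agreement(x)
            r_shift = icc_absolute_agreement(x + 37.5)
            assert r_shift.icc == pytest.approx(r.icc, abs=1e-9)
            assert -1 < r.icc <= 1

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(6)
        x = rng.normal(150, 40, 15)
        m = np.column_stack([x, x + rng.normal(5, 12, 15)])
        mine = icc_absolute_agreement(m)
        df = pd.DataFrame(
            {"s": np.repeat(np.arange(15), 2), "r": np.tile([0, 1], 15), "v": m.ravel()}
        )
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="v")
        ref_icc = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert mine.icc == pytest.approx(ref_icc, abs=1e-10)

    def test_zero_total_variance_is_undefined(self):
        with pytest.raises(ValidationError):
            icc_absolute_agreement(np.full((5, 2), 3.0))


class TestTTests:
    def test_identical_independent_groups(self):
        x = np.array([1.0, 2.0, 3.0])
        res = t_tests(x, x, paired=False)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_constant_paired_difference_is_degenerate(self):
        with pytest.raises(ValidationError):
            t_tests([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], paired=True)

    def test_matches_scipy(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 18)
        y = rng.normal(0.5, 1.2, 18)
        mine_p = t_tests(x, y, paired=True)
        ref_p = sps.ttest_rel(x, y)
        assert mine_p.statistic == pytest.approx(ref_p.statistic, abs=1e-10)
        assert mine_p.p_value == pytest.approx(ref_p.pvalue, abs=1e-10)
        mine_i = t_tests(x, y, paired=False)
        ref_i = sps.ttest_ind(x, y, equal_var=True)
        assert mine_i.statistic == pytest.approx(ref_i.statistic, abs=1e-10)
        assert mine_i.p_value == pytest.approx(ref_i.pvalue, abs=1e-10)


class TestAgreementReport:
    def test_direction_convention(self):
        rng = np.random.default_rng(8)
        visual = rng.normal(150, 30, 25)
        automated = visual + 7.0 + rng.normal(0, 5, 25)
        rep = agreement_report(visual, automated)
        assert rep.direction == "automated-visual"
        assert rep.bland_altman.bias == pytest.approx(float((automated - visual).mean()))
        flipped = agreement_report(visual, automated, direction="visual-automated")
        assert flipped.bland_altman.bias == pytest.approx(-rep.bland_altman.bias)

    def test_report_serializes(self):
        rng = np.random.default_rng(9)
        v = rng.normal(150, 30, 20)
        a = v + rng.normal(0, 8, 20)
        d = agreement_report(v, a).to_dict()
        assert set(d) >= {"bias", "loa_low", "loa_high", "tost", "icc", "t_test"}
        assert d["loa_low"] <= d["bias"] <= d["loa_high"]
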