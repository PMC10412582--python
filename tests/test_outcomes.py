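import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from chemoscore import (
    adjust_fdr,
    controlled_compare,
    correlate_medians,
    cox_ph,
    derive_dcb,
    group_compare,
    km_logrank,
    response_rates,
)


class TestDeriveDcb:
    @pytest.mark.parametrize(
        "duration,progressed,expected",
        [(200, False, "DCB"), (200, True, "NCB"), (183, False, "NCB"), (184, False, "DCB")],
    )
    def test_rule(self, duration, progressed, expected):
        assert derive_dcb(duration, progressed) == expected

    def test_vectorized(self):
        out = derive_dcb(pd.Series([200.0, 100.0]), pd.Series([False, False]))
        assert out.tolist() == ["DCB", "NCB"]


class TestResponseRates:
    def test_printed_per_group_counts(self):
        groups = pd.Series(["hi"] * 28 + ["med"] * 44 + ["lo"] * 10)
        dcb = pd.Series(
            ["DCB"] * 10 + ["NCB"] * 18 + ["DCB"] * 7 + ["NCB"] * 37 + ["NCB"] * 10
        )
        out = response_rates(dcb, groups)
        rates = out["rates"]
        assert round(100 * rates.loc["hi", "rate"]) == 36
        assert round(100 * rates.loc["med", "rate"]) == 16
        assert rates.loc["lo", "rate"] == 0.0
        assert out["p_value"] == pytest.approx(0.029, abs=0.0005)


class TestKmLogrank:
    def test_identical_groups_p_one_equal_medians(self):
        time = pd.Series([5.0, 8.0, 12.0, 20.0] * 2)
        event = pd.Series([1, 1, 0, 1] * 2)
        groups = pd.Series(["A"] * 4 + ["B"] * 4)
        out = km_logrank(time, event, groups)
        assert out["p_value"] == pytest.approx(1.0)
        assert out["medians"]["A"] == out["medians"]["B"]

    def test_uncensored_medians_equal_empirical(self):
        time = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = pd.Series([1] * 6)
        groups = pd.Series(["A", "A", "A", "B", "B", "B"])
        out = km_logrank(time, event, groups)
        assert out["medians"]["A"] == 2.0
        assert out["medians"]["B"] == 5.0

    def test_curves_start_at_one_and_never_increase(self):
        rng = np.random.default_rng(3)
        time = pd.Series(rng.exponential(10, 60) + 0.1)
        event = pd.Series(rng.integers(0, 2, 60))
        groups = pd.Series(["A"] * 30 + ["B"] * 30)
        out = km_logrank(time, event, groups)
        for curve in out["curves"].values():
            vals = curve.iloc[:, 0].to_numpy()
            assert vals[0] == 1.0
            assert (np.diff(vals) <= 1e-12).all()

    def test_median_not_reached_reported_as_nan(self):
        time = pd.Series([10.0, 11.0, 12.0, 10.0, 11.0, 12.0])
        event = pd.Series([0, 0, 0, 1, 1, 1])  # group A fully censored
        groups = pd.Series(["A"] * 3 + ["B"] * 3)
        out = km_logrank(time, event, groups)
        assert np.isnan(out["medians"]["A"])
        assert out["medians"]["B"] == 11.0


def cox_binary_oracle(times, events, x):
    """1-D maximizer of the Cox partial likelihood for a single binary covariate."""
    order = np.argsort(times)
    times, events, x = np.asarray(times)[order], np.asarray(events)[order], np.asarray(x)[order]

    def neg_loglik(beta):
        ll = 0.0
        for i in range(len(times)):
            if events[i]:
                risk = times >= times[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return -ll

    res = minimize_scalar(neg_loglik, bounds=(-8, 8), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


class TestCoxPh:
    def test_binary_covariate_matches_partial_likelihood_oracle(self):
        times = [1.0, 4.0, 2.0, 5.0, 3.0, 6.0]
        events = [1, 1, 1, 1, 1, 1]
        x = [1.0, 1.0, 0.0, 0.0, 1.0, 0.0]
        df = pd.DataFrame({"t": times, "e": events, "x": x})
        out = cox_ph(df, "t", "e", ["x"])
        beta_oracle = cox_binary_oracle(times, events, x)
        assert out["converged"]
        assert out["summary"].loc["x", "coef"] == pytest.approx(beta_oracle, abs=1e-6)

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"t": [1.0, 2.0], "e": [1, 1], "x": [1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            cox_ph(df, "t", "e", ["x"])

    def test_small_tumor_types_excluded_from_multivariate(self):
        rng = np.random.default_rng(11)
        n = 40
        df = pd.DataFrame(
            {
                "t": rng.exponential(10, n) + 0.1,
                "e": 1,
                "x": rng.integers(0, 2, n).astype(float),
                "tumor_type": ["A"] * 20 + ["B"] * 18 + ["C"] * 2,
            }
        )
        out = cox_ph(df, "t", "e", ["x", "tumor_type"], tumor_type_col="tumor_type")
        assert out["n"] == 38  # type C (< 3 patients) dropped


class TestGroupCompare:
    def test_identical_distributions_p_one(self):
        vals = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = pd.Series(["a"] * 3 + ["b"] * 3)
        assert group_compare(vals, groups)["p_value"] == pytest.approx(1.0)

    def test_extreme_separation_matches_permutation_enumeration(self):
        vals = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        groups = pd.Series(["a"] * 3 + ["b"] * 3)
        out = group_compare(vals, groups)
        assert out["p_value"] == pytest.approx(0.1)  # 2/20 orderings
        assert out["direction"] == "b"

    def test_power_at_one_sd_shift(self):
        rng = np.random.default_rng(12)
        vals = pd.Series(np.r_[rng.normal(0, 1, 200), rng.normal(1, 1, 200)])
        groups = pd.Series(["a"] * 200 + ["b"] * 200)
        assert group_compare(vals, groups)["p_value"] < 1e-3


class TestAdjustFdr:
    def test_single_p_unchanged(self):
        assert adjust_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_arithmetic(self):
        out = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(13)
        raw = np.sort(rng.uniform(size=10))
        adj = adjust_fdr(raw)
        assert (adj >= raw - 1e-15).all()
        assert (np.diff(adj) >= -1e-15).all()


class TestControlledCompare:
    def test_noiseless_planted_effects_recovered(self):
        rng = np.random.default_rng(14)
        n = 60
        group = pd.Series(rng.integers(0, 2, n).astype(str))
        covariate = pd.Series(rng.normal(size=n), name="cov")
        response = 1.0 * (group == "1") + 2.0 * covariate + 0.5
        out = controlled_compare(response, group, covariate.to_frame())
        assert out["estimate"] == pytest.approx(1.0, abs=1e-6)

    def test_balanced_orthogonal_covariate_leaves_estimate_unadjusted(self):
        group = pd.Series(["a", "a", "b", "b"] * 2)
        covariate = pd.DataFrame({"c": [0.0, 1.0, 0.0, 1.0] * 2})
        response = pd.Series([1.0, 2.0, 3.0, 4.0] * 2)
        out = controlled_compare(response, group, covariate)
        unadjusted = response[group == "b"].mean() - response[group == "a"].mean()
        assert out["estimate"] == pytest.approx(unadjusted, abs=1e-12)

    def test_null_group_with_explaining_covariate_not_significant(self):
        rng = np.random.default_rng(15)
        covariate = pd.Series(rng.normal(size=100), name="c")
        response = 3 * covariate + rng.normal(0, 0.1, 100)
        group = pd.Series(rng.integers(0, 2, 100).astype(str))
        out = controlled_compare(response, group, covariate.to_frame())
        assert out["p_value"] > 0.05


class TestCorrelateMedians:
    def test_perfectly_monotone(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0])
        assert correlate_medians(x, x**3)["rho"] == pytest.approx(1.0)
        assert correlate_medians(x, -x)["rho"] == pytest.approx(-1.0)

    def test_small_fixture_matches_rank_pearson(self):
        x = pd.Series([3.0, 1.0, 4.0, 1.5, 5.0])
        y = pd.Series([2.0, 0.5, 3.5, 2.5, 4.0])
        rx, ry = x.rank(), y.rank()
        hand = np.corrcoef(rx, ry)[0, 1]
        assert correlate_medians(x, y)["rho"] == pytest.approx(hand, abs=1e-12)
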