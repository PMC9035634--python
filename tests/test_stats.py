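"""Group-comparison statistics and the HEP->LPP linkage procedure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from heplpp.stats import (
    chi_square,
    linkage_analysis,
    partial_correlation,
    stepwise_regression,
    two_sample_t,
    zscore,
)
from heplpp.synth import SimConfig, simulate_measured_effects


class TestTwoSampleT:
    def test_identical_summaries_give_zero(self):
        res = two_sample_t((10.0, 2.0, 20), (10.0, 2.0, 20))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_printed_state_anxiety_value(self):
        """Pooled t from the published group summaries (MDD first)."""
        res = two_sample_t((54.7, 11.2, 27), (30.3, 5.5, 27))
        assert round(res.statistic, 3) == -10.161
        assert res.df == 52

    def test_raw_and_summary_paths_agree(self, rng):
        a = rng.normal(5, 2, size=40)
        b = rng.normal(6, 3, size=35)
        r_raw = two_sample_t(a, b)
        r_sum = two_sample_t(
            (a.mean(), a.std(ddof=1), a.size), (b.mean(), b.std(ddof=1), b.size)
        )
        assert r_raw.statistic == pytest.approx(r_sum.statistic, abs=1e-10)
        assert r_raw.p_value == pytest.approx(r_sum.p_value, abs=1e-10)

    def test_matches_scipy_both_variants(self, rng):
        a = rng.normal(0, 1, size=25)
        b = rng.normal(0.5, 2, size=30)
        for variant, equal_var in (("student", True), ("welch", False)):
            ours = two_sample_t(a, b, variant=variant)
            ref = spstats.ttest_ind(b, a, equal_var=equal_var)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_antisymmetry_and_affine_invariance(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(size=22) + 0.5
        assert two_sample_t(a, b).statistic == pytest.approx(
            -two_sample_t(b, a).statistic, rel=1e-12
        )
        assert two_sample_t(3 * a + 7, 3 * b + 7).statistic == pytest.approx(
            two_sample_t(a, b).statistic, rel=1e-10
        )

    def test_zero_variance_cases(self):
        assert two_sample_t((1.0, 0.0, 5), (1.0, 0.0, 5)).statistic == 0.0
        assert two_sample_t((1.0, 0.0, 5), (2.0, 0.0, 5)).statistic == np.inf


class TestChiSquare:
    def test_perfect_independence(self):
        assert chi_square([[10, 10], [10, 10]]).statistic == 0.0

    def test_printed_sex_ratio_value(self):
        res = chi_square([[16, 11], [15, 12]])
        assert round(res.statistic, 3) == 0.076
        assert round(res.p_value, 3) == 0.783
        assert res.df == 1

    def test_matches_hand_formula(self, rng):
        table = rng.integers(5, 40, size=(2, 2)).astype(float)
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        by_hand = float(((table - expected) ** 2 / expected).sum())
        assert chi_square(table).statistic == pytest.approx(by_hand, rel=1e-12)

    def test_invariance_under_swaps(self):
        t = np.array([[16, 11], [15, 12]])
        base = chi_square(t).statistic
        assert chi_square(t[::-1]).statistic == pytest.approx(base)
        assert chi_square(t[:, ::-1]).statistic == pytest.approx(base)

    def test_zero_margin_undefined(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square([[0, 0], [5, 7]])


class TestPartialCorrelation:
    def test_empty_controls_equals_pearson(self, rng):
        x, y = rng.normal(size=(2, 30))
        r, p = partial_correlation(x, y)
        ref_r, ref_p = spstats.pearsonr(x, y)
        assert r == pytest.approx(ref_r, abs=1e-12)
        assert p == pytest.approx(ref_p, rel=1e-6)

    def test_y_equal_to_control_gives_zero(self, rng):
        x = rng.normal(size=30)
        c = rng.normal(size=30)
        r, _ = partial_correlation(x, c, controls=c)
        assert abs(r) < 1e-10

    def test_inverse_correlation_matrix_oracle(self, rng):
        """r_xy.z from the inverse of the (x, y, z...) correlation matrix."""
        n = 60
        z = rng.normal(size=(n, 3))
        x = z @ [0.5, -0.2, 0.1] + rng.normal(size=n)
        y = z @ [0.3, 0.4, 0.0] + 0.5 * x + rng.normal(size=n)
        r, _ = partial_correlation(x, y, z)
        corr = np.corrcoef(np.column_stack([x, y, z]).T)
        prec = np.linalg.inv(corr)
        expected = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert r == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 40
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=["x", "y", "c1", "c2"])
        df["y"] += 0.6 * df["x"] + 0.3 * df["c1"]
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        r, p = partial_correlation(df["x"], df["y"], df[["c1", "c2"]])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_collinear_controls_rejected(self, rng):
        x, y = rng.normal(size=(2, 30))
        c = rng.normal(size=30)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(x, y, np.column_stack([c, 2 * c]))


class TestZscore:
    def test_simple_example(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1])

    def test_idempotent_and_moments(self, rng):
        v = rng.normal(3, 7, size=50)
        z = zscore(v)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)
        np.testing.assert_allclose(zscore(z), z, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore([2.0, 2.0, 2.0])


class TestStepwise:
    def _data(self, rng, n=60, k=4, true=None):
        X = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])
        y = rng.normal(size=n)
        if true:
            for name, b in true.items():
                y = y + b * X[name]
        return y, X

    def test_liberal_thresholds_give_full_model(self, rng):
        import statsmodels.api as sm

        y, X = self._data(rng, true={"x0": 1.0})
        model = stepwise_regression(y, X, p_enter=1.0, p_remove=1.0000001)
        assert set(model.predictors) == set(X.columns)
        full = sm.OLS(y, sm.add_constant(X)).fit()
        assert model.r_squared == pytest.approx(full.rsquared, rel=1e-10)

    def test_zero_entry_threshold_gives_intercept_only(self, rng):
        y, X = self._data(rng, true={"x0": 2.0})
        model = stepwise_regression(y, X, p_enter=0.0)
        assert model.empty
        assert model.predictors == []

    def test_single_true_predictor_recovered(self, rng):
        n = 27
        X = pd.DataFrame({"x0": rng.normal(size=n)})
        y = 1.0 * X["x0"].to_numpy() + rng.normal(0, 0.1, size=n)
        model = stepwise_regression(y, X)
        assert model.predictors == ["x0"]
        assert abs(model.coef["x0"] - 1.0) < 3 * model.se["x0"]

    def test_two_candidate_rule_trace(self, rng):
        """Hand-trace the forward/backward rules against exhaustive OLS."""
        import statsmodels.api as sm

        n = 50
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = 0.9 * X["a"].to_numpy() + 0.5 * X["b"].to_numpy() + rng.normal(size=n)
        # trace step 1: single-candidate fits
        p_single = {
            c: float(sm.OLS(y, sm.add_constant(X[[c]])).fit().pvalues[c]) for c in X
        }
        first = min(p_single, key=p_single.get)
        assert p_single[first] <= 0.05
        # trace step 2: add the other, check it stays
        other = [c for c in X if c != first][0]
        both = sm.OLS(y, sm.add_constant(X[[first, other]])).fit()
        expected = [first, other] if both.pvalues[other] <= 0.05 else [first]
        model = stepwise_regression(y, X)
        assert model.predictors == expected

    def test_null_spurious_inclusion_rate(self, rng):
        """With k independent null candidates the inclusion probability per
        run is ~1-(1-alpha)^k; observed rate must sit in that vicinity."""
        k, reps = 4, 200
        hits = 0
        for _ in range(reps):
            y, X = self._data(rng, n=40, k=k)
            if not stepwise_regression(y, X).empty:
                hits += 1
        expected = 1 - (1 - 0.05) ** k  # ~0.185
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(hits / reps - expected) < 4 * se + 0.02

    def test_too_many_candidates_rejected(self, rng):
        y, X = self._data(rng, n=5, k=4)
        with pytest.raises(ValueError, match="candidates"):
            stepwise_regression(y, X)


@pytest.fixture(scope="module")
def table():
    return simulate_measured_effects(SimConfig(), seed=11)


class TestLinkage:
    def test_patient_coupling_detected(self, table):
        rep = linkage_analysis(
            table,
            hep_cols=["hep_frontocentral", "hep_left_frontal", "hep_centroparietal"],
            lpp_cols=["lpp_frontocentral_sad"],
        )
        mdd = rep["partial_correlations"]["MDD"][("hep_frontocentral", "lpp_frontocentral_sad")]
        assert mdd["significant"] and mdd["r"] > 0

    def test_stepwise_first_entrant_is_coupled_cluster(self, table):
        rep = linkage_analysis(
            table,
            hep_cols=["hep_frontocentral", "hep_left_frontal", "hep_centroparietal"],
            lpp_cols=["lpp_frontocentral_sad"],
        )
        model = rep["stepwise_models"]["lpp_frontocentral_sad"]
        assert model.predictors[0] == "hep_frontocentral"

    def test_missing_covariates_listed(self, table):
        with pytest.raises(ValueError, match="bmi"):
            linkage_analysis(
                table.drop(columns=["bmi"]),
                hep_cols=["hep_frontocentral"],
                lpp_cols=["lpp_frontocentral_sad"],
            )
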