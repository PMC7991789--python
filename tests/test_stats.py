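"""Group statistics, correction families, partial correlation."""

import numpy as np
import pandas as pd
import pytest

from fconn.stats import (
    correct,
    gender_chisq,
    group_metric_anova,
    oneway_anova,
    partial_corr,
    residualize,
)
from oracles import oracle_anova_f, oracle_chi2, oracle_partial_corr_invcov


class TestResidualize:
    def test_metric_equal_to_age_vanishes(self, rng):
        age = rng.normal(40, 10, 50)
        gender = rng.choice(["M", "F"], 50)
        np.testing.assert_allclose(residualize(age, age, gender), 0.0, atol=1e-10)

    def test_orthogonal_metric_mean_centered_only(self, rng):
        n = 200
        age = np.linspace(20, 60, n)
        gender = np.array(["M", "F"] * (n // 2))
        metric = rng.normal(size=n)
        resid = residualize(metric, age, gender)
        # projection removes at most the small sample association
        assert np.corrcoef(resid, metric - metric.mean())[0, 1] > 0.97

    def test_residuals_orthogonal_to_covariates(self, rng):
        age = rng.normal(40, 10, 80)
        gender = rng.choice(["M", "F"], 80)
        resid = residualize(rng.normal(size=80), age, gender)
        assert abs(np.corrcoef(resid, age)[0, 1]) < 1e-10

    def test_constant_covariate_dropped_with_warning(self, rng, caplog):
        with caplog.at_level("WARNING", logger="fconn.stats"):
            residualize(rng.normal(size=20), np.full(20, 30.0), rng.choice(["M", "F"], 20))
        assert any("constant" in m for m in caplog.messages)


class TestAnova:
    def test_equal_means_f_near_zero(self):
        v = np.tile([1.0, 2.0, 3.0], 3)
        g = np.repeat(["a", "b", "c"], 3)
        f, p = oneway_anova(v, g)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_extreme_separation(self, rng):
        v = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10)])
        g = np.repeat(["a", "b", "c"], 10)
        _, p = oneway_anova(v, g)
        assert p < 1e-10

    def test_nine_value_fixture_matches_sum_of_squares_oracle(self):
        v = np.array([3.0, 1.0, 2.0, 5.0, 4.0, 6.0, 9.0, 7.0, 8.0])
        g = np.repeat(["a", "b", "c"], 3)
        f, _ = oneway_anova(v, g)
        assert f == pytest.approx(oracle_anova_f(v, g), abs=1e-12)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            oneway_anova(np.array([1.0, 2.0, 3.0]), np.array(["a", "a", "b"]))


class TestGenderChisq:
    def test_reported_three_group_table(self):
        chi2, p = gender_chisq(np.array([[18, 25], [16, 26], [10, 31]]))
        assert chi2 == pytest.approx(3.0981, abs=1e-4)
        assert p == pytest.approx(0.2124, abs=1e-4)

    def test_equal_rows_no_association(self):
        chi2, p = gender_chisq(np.array([[10, 20], [10, 20], [10, 20]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_matches_expected_frequency_oracle(self, rng):
        table = rng.integers(5, 40, (3, 2))
        chi2, _ = gender_chisq(table)
        assert chi2 == pytest.approx(oracle_chi2(table), abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            gender_chisq(np.array([[0, 0], [5, 5], [4, 6]]))


class TestCorrection:
    @pytest.mark.parametrize(
        "family,threshold",
        [(7, 0.05 / 7), (40, 0.00125), (8, 0.00625), (64, 0.05 / 64)],
    )
    def test_bonferroni_printed_denominators(self, family, threshold):
        res = correct(np.array([0.01, 0.0001]), method="bonferroni", family_size=family)
        assert res.threshold == pytest.approx(threshold, rel=1e-12)

    def test_bonferroni_decisions(self):
        res = correct(np.array([0.002, 0.0009]), family_size=40)
        np.testing.assert_array_equal(res.reject, [False, True])

    def test_fdr_step_up_rule(self):
        res = correct(np.array([0.01, 0.02, 0.03, 0.8]), method="fdr")
        np.testing.assert_array_equal(res.reject, [True, True, True, False])

    def test_small_family_warned(self, caplog):
        with caplog.at_level("WARNING", logger="fconn.stats"):
            correct(np.array([0.1] * 10), family_size=7)
        assert any("smaller" in m for m in caplog.messages)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match="p values"):
            correct(np.array([1.5]))


class TestPartialCorr:
    def test_constant_covariate_reduces_to_pearson(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        res = partial_corr(x, y, np.full((50, 1), 3.0))
        assert res.partial_r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_identity_gives_unit_correlation(self, rng):
        x = rng.normal(size=40)
        cov = rng.normal(size=(40, 2))
        res = partial_corr(x, x, cov)
        assert res.partial_r == pytest.approx(1.0, abs=1e-12)
        assert res.p == 0.0

    def test_matches_inverse_correlation_oracle(self, rng):
        data = rng.normal(size=(200, 5))
        data[:, 1] += 0.5 * data[:, 0] + 0.3 * data[:, 2]
        res = partial_corr(data[:, 0], data[:, 1], data[:, 2:])
        assert res.partial_r == pytest.approx(
            oracle_partial_corr_invcov(data, 0, 1), abs=1e-10
        )

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=["x", "y", "a", "b"])
        df["y"] += 0.4 * df["x"] + 0.2 * df["a"]
        res = partial_corr(df["x"], df["y"], df[["a", "b"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["a", "b"])
        assert res.partial_r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.p == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-8)

    def test_significance_uses_family_denominator(self, rng):
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60) * 0.9
        cov = rng.normal(size=(60, 2))
        res = partial_corr(x, y, cov, family_size=64)
        assert res.family_size == 64
        assert res.significant == (res.p < 0.05 / 64)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError, match="covariates"):
            partial_corr(np.ones(4), np.ones(4), rng.normal(size=(4, 2)))


class TestGroupMetricPipeline:
    def test_planted_metric_flagged_others_not(self):
        rng = np.random.default_rng(7)
        n_per = 40
        groups = np.repeat(["HC", "FCNAD", "FCAD"], n_per)
        age = rng.normal(40, 10, 3 * n_per)
        gender = rng.choice(["M", "F"], 3 * n_per)
        metrics = pd.DataFrame(
            {
                "gamma": np.concatenate(
                    [rng.normal(1.0, 0.1, n_per), rng.normal(0.8, 0.1, 2 * n_per)]
                ),
                "cp": rng.normal(0.5, 0.05, 3 * n_per),
            }
        )
        results = group_metric_anova(metrics, groups, age, gender, family_size=7)
        by_name = {r.metric: r for r in results}
        assert by_name["gamma"].significant
        assert by_name["gamma"].posthoc[("FCAD", "HC")][1] < 0.01
        assert not by_name["cp"].significant
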