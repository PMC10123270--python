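"""Statistics pipeline: correlation, agreement, OLS models, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from axilen.cohort import EmmetropiaEquation, GeneratorConfig, IncrementEquation, generate_cohort
from axilen.stats import (
    bland_altman,
    compute_derived,
    descriptive_table,
    fit_linear_model,
    group_summary,
    pearson_with_t,
    run_adjusted_models,
    run_diagnostics,
    subgroup_model,
)


def brute_force_pearson(x, y):
    """Independent oracle: direct covariance / SD formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def normal_equations(X, y):
    """Independent OLS oracle: solve X'X beta = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestPearson:
    def test_matches_brute_force_oracle(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        res = pearson_with_t(x, y)
        assert res.r == pytest.approx(brute_force_pearson(x, y), abs=1e-12)
        # p-value agrees with scipy's independent implementation
        assert res.p == pytest.approx(sps.pearsonr(x, y).pvalue, abs=1e-12)

    def test_t_r_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = pearson_with_t(x, y)
        assert res.df == 38
        assert res.t == pytest.approx(res.r * np.sqrt(res.df) / np.sqrt(1 - res.r**2))

    def test_perfect_correlations(self):
        x = np.arange(5.0)
        assert pearson_with_t(x, x).r == pytest.approx(1.0)
        assert pearson_with_t(x, x[::-1]).r == pytest.approx(-1.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_t([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="mismatch"):
            pearson_with_t([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="at least 3"):
            pearson_with_t([1, 2], [3, 4])


class TestBlandAltman:
    def test_hand_computed_example(self):
        res = bland_altman([1, 2, 3, 4], [1.1, 2.1, 2.9, 4.1])
        assert res.bias == pytest.approx(-0.05, abs=1e-12)
        assert res.sd_diff == pytest.approx(0.10, abs=1e-12)
        assert res.loa_low == pytest.approx(-0.246, abs=1e-12)
        assert res.loa_high == pytest.approx(0.146, abs=1e-12)

    def test_identical_series_gives_zero_limits(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0

    def test_loa_arithmetic_and_direction_swap(self):
        rng = np.random.default_rng(1)
        m = rng.normal(26, 1.5, 50)
        e = m + rng.normal(0.3, 0.6, 50)
        fwd = bland_altman(m, e)
        rev = bland_altman(e, m)
        assert fwd.loa_low == fwd.bias - 1.96 * fwd.sd_diff
        assert fwd.loa_high == fwd.bias + 1.96 * fwd.sd_diff
        # swapping the convention negates the bias and mirrors the limits
        assert rev.bias == pytest.approx(-fwd.bias)
        assert rev.loa_low == pytest.approx(-fwd.loa_high)
        assert rev.loa_high == pytest.approx(-fwd.loa_low)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])


class TestComputeDerived:
    def test_cohort_mean_record(self, toy_cohort):
        t = toy_cohort.copy()
        t.loc[0, ["cr_mm", "ser_d", "al_mm"]] = [7.78, -6.04, 26.01]
        out = compute_derived(t)
        row = out.iloc[0]
        assert row["al_morgan_mm"] == pytest.approx(26.26, abs=0.005)
        assert row["al_emmetropia_mm"] == pytest.approx(23.64, abs=0.005)
        assert row["delta_al_mm"] == pytest.approx(26.01 - row["al_emmetropia_mm"])

    def test_zero_ser_collapses_to_emmetropia(self, toy_cohort):
        out = compute_derived(toy_cohort.assign(ser_d=0.0))
        assert np.allclose(out["al_morgan_mm"], out["al_emmetropia_mm"])

    def test_empty_table(self, toy_cohort):
        out = compute_derived(toy_cohort.iloc[0:0])
        assert out.empty and "delta_al_mm" in out.columns

    def test_domain_error_names_record(self, toy_cohort):
        t = toy_cohort.copy()
        t.loc[2, "ser_d"] = -90.0  # drives reciprocal length negative
        with pytest.raises(ValueError, match="S3"):
            compute_derived(t)


class TestLinearModel:
    def test_exact_line(self, toy_cohort):
        t = toy_cohort.iloc[:3].copy()
        t["y"] = 2 * t["ssi"] + 1
        res = fit_linear_model(t, "y", ["ssi"])
        assert res.coef("ssi") == pytest.approx(2.0, abs=1e-10)
        assert res.coef("intercept") == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(res.residuals, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, toy_cohort):
        t = compute_derived(toy_cohort)
        res = fit_linear_model(t, "al_mm", ["age", "gender", "cct_um", "ssi"])
        X = np.column_stack(
            [
                np.ones(len(t)),
                t["age"],
                (t["gender"] == "male").astype(float),
                t["cct_um"],
                t["ssi"],
            ]
        )
        beta = normal_equations(X, t["al_mm"].to_numpy())
        assert res.terms["estimate"].to_numpy() == pytest.approx(beta, abs=1e-10)
        # SEs from the residual variance, independently
        resid = t["al_mm"].to_numpy() - X @ beta
        s2 = resid @ resid / (len(t) - X.shape[1])
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        assert res.terms["se"].to_numpy() == pytest.approx(se, abs=1e-10)

    def test_ci_uses_t_critical(self, toy_cohort):
        res = fit_linear_model(toy_cohort, "al_mm", ["ssi"])
        tcrit = sps.t.ppf(0.975, res.n - 2)
        row = res.terms.loc["ssi"]
        assert row["ci_low"] == pytest.approx(row["estimate"] - tcrit * row["se"], abs=1e-10)
        assert row["ci_high"] == pytest.approx(row["estimate"] + tcrit * row["se"], abs=1e-10)

    def test_male_coded_one(self, toy_cohort):
        t = toy_cohort.copy()
        t["y"] = np.where(t["gender"] == "male", 10.0, 0.0)
        res = fit_linear_model(t, "y", ["gender"])
        assert res.coef("male_gender") == pytest.approx(10.0, abs=1e-10)

    def test_rank_deficiency_names_terms(self, toy_cohort):
        t = toy_cohort.copy()
        t["ssi2"] = t["ssi"] * 2
        with pytest.raises(ValueError, match="ssi"):
            fit_linear_model(t, "al_mm", ["ssi", "ssi2"])

    def test_underdetermined_raises(self, toy_cohort):
        with pytest.raises(ValueError, match="too small"):
            fit_linear_model(toy_cohort.iloc[:3], "al_mm", ["age", "gender", "cct_um", "ssi"])


class TestAdjustedModels:
    def test_termwise_additivity_is_exact(self, recovery_cohort):
        m1, m2, m3 = run_adjusted_models(recovery_cohort)
        total = m2.terms["estimate"] + m3.terms["estimate"]
        assert m1.terms["estimate"].to_numpy() == pytest.approx(
            total.to_numpy(), abs=1e-10
        )

    def test_structural_coefficients_recovered(self, recovery_cohort):
        _, _, m3 = run_adjusted_models(recovery_cohort)
        for term, truth in (("ssi", -2.49), ("age", 0.07), ("male_gender", 0.23), ("cct_um", 0.0)):
            est, se = m3.coef(term), m3.se(term)
            assert abs(est - truth) < 2 * se, f"{term}: {est} vs {truth} (se {se})"

    def test_noise_free_cohort_gives_unit_r_squared(self):
        cfg = GeneratorConfig(
            n=200,
            seed=21,
            ser_noise_sd=0.0,
            emmetropia=EmmetropiaEquation(residual_sd=0.0),
            increment=IncrementEquation(residual_sd=0.0),
        )
        t = generate_cohort(cfg)
        _, m2, m3 = run_adjusted_models(t)
        assert m2.r_squared == pytest.approx(1.0, abs=1e-9)
        assert m3.r_squared == pytest.approx(1.0, abs=1e-9)


class TestSubgroup:
    def test_threshold_below_min_equals_full_fit(self, recovery_cohort):
        full = run_adjusted_models(recovery_cohort)[2]
        sub = subgroup_model(recovery_cohort, al_threshold=0.0)
        assert sub.terms["estimate"].to_numpy() == pytest.approx(
            full.terms["estimate"].to_numpy(), abs=1e-12
        )

    def test_threshold_above_max_raises_with_size(self, recovery_cohort):
        with pytest.raises(ValueError, match="only 0 records"):
            subgroup_model(recovery_cohort, al_threshold=100.0)

    def test_long_eye_subgroup_attenuates_ssi_effect(self, recovery_cohort):
        # selecting on the outcome's sum truncates dAL, shrinking the
        # SSI coefficient toward zero while keeping its sign
        full = run_adjusted_models(recovery_cohort)[2]
        sub = subgroup_model(recovery_cohort, al_threshold=26.0)
        assert sub.coef("ssi") < 0
        assert abs(sub.coef("ssi")) < abs(full.coef("ssi"))
        assert sub.n == int((recovery_cohort["al_mm"] >= 26.0).sum())


class TestGroupSummary:
    def test_four_groups_on_synthetic_cohort(self, recovery_cohort):
        g = group_summary(recovery_cohort)
        assert len(g) == 4
        assert g.loc["AL >= 26 mm", "mean_delta_al_mm"] > g.loc["AL < 26 mm", "mean_delta_al_mm"]
        assert g["n"].iloc[:2].sum() == len(recovery_cohort)

    def test_empty_group_reported_absent(self, toy_cohort):
        t = compute_derived(toy_cohort)
        t["al_mm"] = 24.0  # every eye short
        t = compute_derived(t)
        g = group_summary(t)
        assert g.loc["AL >= 26 mm", "n"] == 0
        assert np.isnan(g.loc["AL >= 26 mm", "mean_delta_al_mm"])

    def test_boundary_conventions(self, toy_cohort):
        t = compute_derived(toy_cohort)
        t.loc[t.index[0], "al_mm"] = 26.0
        t.loc[t.index[0], "ser_d"] = -6.0
        t = compute_derived(t)
        g = group_summary(t)
        # AL = 26 joins the long group; SER = -6.00 joins the severe group
        assert g.loc["AL >= 26 mm", "n"] >= 1
        assert g.loc["SER <= -6.00 D", "n"] >= 1

    def test_single_record(self, toy_cohort):
        t = compute_derived(toy_cohort.iloc[[0]])
        g = group_summary(t)
        assert g["n"].iloc[:2].tolist() in ([1, 0], [0, 1])


class TestDiagnostics:
    @staticmethod
    def _fit_with_resid(noise_fn, n=500, seed=13):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.5, 1.2, n)
        t = pd.DataFrame(
            {
                "subject_id": [str(i) for i in range(n)],
                "eye": "OD",
                "gender": "female",
                "x": x,
                "y": 25.0 - 2.0 * x + noise_fn(rng, 25.0 - 2.0 * x),
            }
        )
        return fit_linear_model(t, "y", ["x"])

    def test_iid_normal_residuals_pass_all_checks(self):
        fit = self._fit_with_resid(lambda rng, mu: rng.normal(0, 0.5, mu.size))
        checks = run_diagnostics(fit)
        assert len(checks) == 4
        assert all(c.computed for c in checks)
        assert all(c.passed for c in checks)

    def test_variance_proportional_to_fit_fails_homoscedasticity(self):
        fit = self._fit_with_resid(
            lambda rng, mu: rng.normal(0, 0.08 * (mu - mu.min() + 0.05), mu.size)
        )
        checks = {c.name: c for c in run_diagnostics(fit)}
        assert checks["homoscedasticity"].passed is False

    def test_degenerate_residuals_reported_not_computed(self, toy_cohort):
        t = toy_cohort.copy()
        t["y"] = 2 * t["ssi"] + 1  # perfect fit, residuals ~ 0
        fit = fit_linear_model(t, "y", ["ssi"])
        checks = run_diagnostics(fit)
        assert all(not c.computed for c in checks)
        assert all(c.passed is None for c in checks)


class TestDescriptiveTable:
    def test_gender_counts_and_percent(self):
        n = 267
        t = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "eye": "OD",
                "age": 22.0,
                "gender": ["female"] * 145 + ["male"] * 122,
                "ser_d": -6.0,
                "ssi": 0.82,
                "cct_um": 544.0,
                "cr_mm": 7.78,
                "al_mm": 26.0,
            }
        )
        table = descriptive_table(compute_derived(t))
        assert table.loc["Female", "display"] == "145 (54%)"
        assert table.loc["Male", "display"] == "122 (46%)"

    def test_mean_sd_formatting(self, toy_cohort):
        table = descriptive_table(compute_derived(toy_cohort))
        # age rounds to integers, optical variables to two decimals
        assert "(" in table.loc["Age, years", "display"]
        assert "." not in table.loc["Age, years", "display"]
        al_disp = table.loc["AL (OD), mm", "display"]
        assert al_disp.count(".") == 2

    def test_single_record_sd_zero(self, toy_cohort):
        table = descriptive_table(compute_derived(toy_cohort.iloc[[0]]))
        assert table.loc["AL (OD), mm", "sd"] == 0.0

    def test_empty_table_raises(self, toy_cohort):
        with pytest.raises(ValueError):
            descriptive_table(toy_cohort.iloc[0:0])
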