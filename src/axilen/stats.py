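"""Statistical pipeline: derived variables, correlation, Bland-Altman
agreement, simple and covariate-adjusted OLS models, subgroup analysis,
group summaries, and regression diagnostics.

OLS fitting and the diagnostic tests delegate to statsmodels/scipy; this
module fixes the coding conventions (male = 1), the model specifications,
and the reporting format (95% CIs, significance stars, p-value floors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import acorr_ljungbox, het_breuschpagan
from statsmodels.stats.stattools import durbin_watson

from .morgan import DEFAULT_CONSTANTS, MorganConstants, al_emmetropia, al_morgan

__all__ = [
    "CorrelationResult",
    "BlandAltmanResult",
    "RegressionResult",
    "DiagnosticCheck",
    "compute_derived",
    "pearson_with_t",
    "bland_altman",
    "fit_linear_model",
    "run_adjusted_models",
    "subgroup_model",
    "group_summary",
    "run_diagnostics",
    "descriptive_table",
    "significance_stars",
    "format_p",
]

#: Term ordering used in all adjusted-model tables.
ADJUSTED_TERMS = ["age", "male_gender", "cct_um", "ssi"]


def significance_stars(p: float) -> str:
    """Star code for a p-value: *** < 0.001, ** < 0.01, * < 0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def format_p(p: float) -> str:
    """p to three decimals with a '<0.001' floor."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its t statistic.

    Satisfies t == r * sqrt(df) / sqrt(1 - r^2) with df = n - 2.
    """

    r: float
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between a measured and an estimated quantity.

    Direction convention: ``difference = measured - estimate`` (stored in
    ``direction``), so a negative bias means the estimate runs high.
    Limits of agreement are ``bias +/- multiplier * sd_diff`` exactly.
    """

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    multiplier: float = 1.96
    direction: str = "measured - estimate"
    n: int = 0


@dataclass
class DiagnosticCheck:
    """One regression-assumption check, flagged pass/fail at alpha = 0.05."""

    name: str
    statistic: Optional[float]
    p_value: Optional[float]
    passed: Optional[bool]  # None when not computed
    computed: bool = True
    note: str = ""


@dataclass
class RegressionResult:
    """One fitted ordinary-least-squares model.

    ``terms`` is a DataFrame indexed by term name with columns
    ``estimate``, ``se``, ``ci_low``, ``ci_high``, ``p``, ``stars``; CIs
    are estimate +/- t_crit(df = n - p) * SE.
    """

    model_label: str
    outcome: str
    terms: pd.DataFrame
    n: int
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    exog: np.ndarray = field(repr=False)
    endog: np.ndarray = field(repr=False)
    diagnostics: Optional[list[DiagnosticCheck]] = None

    def coef(self, term: str) -> float:
        return float(self.terms.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.terms.loc[term, "se"])

    def to_dict(self) -> dict:
        return {
            "model_label": self.model_label,
            "outcome": self.outcome,
            "n": self.n,
            "r_squared": self.r_squared,
            "terms": {
                name: {
                    "estimate": float(row["estimate"]),
                    "se": float(row["se"]),
                    "ci_low": float(row["ci_low"]),
                    "ci_high": float(row["ci_high"]),
                    "p": float(row["p"]),
                    "p_display": format_p(float(row["p"])),
                    "stars": row["stars"],
                }
                for name, row in self.terms.iterrows()
            },
        }

    def summary(self) -> str:
        lines = [
            f"{self.model_label}: {self.outcome} (n = {self.n}, R^2 = {self.r_squared:.3f})",
            f"  {'term':<14}{'beta':>9}{'SE':>8}  {'95% CI':>18}  {'p':>7}",
        ]
        for name, row in self.terms.iterrows():
            ci = f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}]"
            lines.append(
                f"  {name:<14}{row['estimate']:>9.3f}{row['se']:>8.3f}  {ci:>18}  "
                f"{format_p(row['p']):>7} {row['stars']}"
            )
        return "\n".join(lines)


def compute_derived(
    table: pd.DataFrame, constants: MorganConstants = DEFAULT_CONSTANTS
) -> pd.DataFrame:
    """Populate the Morgan-model derived columns on a cohort copy.

    Adds ``al_morgan_mm``, ``al_emmetropia_mm`` and ``delta_al_mm`` from
    the measured ``cr_mm``, ``ser_d`` and ``al_mm``; domain errors are
    re-raised naming the offending subject.
    """
    out = table.copy()
    if out.empty:
        for col in ("al_morgan_mm", "al_emmetropia_mm", "delta_al_mm"):
            out[col] = pd.Series(dtype=float)
        return out
    cr = out["cr_mm"].to_numpy(dtype=float)
    ser = out["ser_d"].to_numpy(dtype=float)
    al = out["al_mm"].to_numpy(dtype=float)
    try:
        out["al_morgan_mm"] = al_morgan(cr, ser, constants)
        out["al_emmetropia_mm"] = al_emmetropia(cr, constants)
    except ValueError as exc:
        # locate the first offending record for a useful message
        denom = constants.a / np.where(cr > 0, cr, np.nan) + constants.b * ser + constants.c
        bad = np.where(~(np.isfinite(denom)) | (denom <= 0) | (cr <= 0))[0]
        rec = out.iloc[bad[0]] if len(bad) else out.iloc[0]
        raise ValueError(f"record {rec['subject_id']!r} ({rec['eye']}): {exc}") from exc
    out["delta_al_mm"] = al - out["al_emmetropia_mm"]
    return out


def pearson_with_t(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with its exact t statistic.

    t = r * sqrt(n - 2) / sqrt(1 - r^2); two-sided p from the t
    distribution with n - 2 degrees of freedom.
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape:
        raise ValueError(f"length mismatch: {x_arr.shape} vs {y_arr.shape}")
    n = x_arr.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.ptp(x_arr) == 0 or np.ptp(y_arr) == 0:
        raise ValueError("correlation undefined for a constant series")
    r = float(np.corrcoef(x_arr, y_arr)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        t = float(np.sign(r) * np.inf)
        p = 0.0
    else:
        t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
        p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, t=float(t), df=df, p=p)


def bland_altman(
    measured: Sequence[float], estimate: Sequence[float], multiplier: float = 1.96
) -> BlandAltmanResult:
    """Bland-Altman agreement of an estimate against a measurement.

    Differences are measured - estimate; bias is their mean, sd_diff the
    sample SD (ddof = 1), and the limits of agreement bias +/-
    multiplier * sd_diff.
    """
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if m.shape != e.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {e.shape}")
    if m.size < 2:
        raise ValueError(f"need at least 2 observations, got {m.size}")
    d = m - e
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - multiplier * sd,
        loa_high=bias + multiplier * sd,
        multiplier=multiplier,
        n=m.size,
    )


def _design_matrix(table: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    """Build the design frame; 'gender'/'male_gender' become a male = 1 dummy."""
    cols = {}
    for name in predictors:
        if name in ("gender", "male_gender", "male"):
            cols["male_gender"] = (table["gender"] == "male").astype(float)
        else:
            cols[name] = table[name].astype(float)
    X = pd.DataFrame(cols, index=table.index)
    return sm.add_constant(X, has_constant="add")


def fit_linear_model(
    table: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    model_label: Optional[str] = None,
) -> RegressionResult:
    """Ordinary least squares of ``outcome`` on ``predictors`` + intercept.

    Gender enters as a male = 1 dummy.  Raises on rank-deficient designs,
    naming the collinear terms.
    """
    X = _design_matrix(table, predictors)
    y = table[outcome].astype(float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n = {n} too small for {p} terms (outcome {outcome!r})")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # flag columns whose removal restores full column rank
        collinear = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear terms: {collinear}")

    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    terms = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": res.pvalues,
        }
    )
    terms["stars"] = [significance_stars(pv) for pv in terms["p"]]
    terms.index = ["intercept" if ix == "const" else ix for ix in terms.index]
    return RegressionResult(
        model_label=model_label or f"{outcome} ~ {' + '.join(predictors)}",
        outcome=outcome,
        terms=terms,
        n=int(res.nobs),
        r_squared=float(res.rsquared),
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        exog=X.to_numpy(),
        endog=y.to_numpy(),
    )


def run_adjusted_models(
    table: pd.DataFrame,
) -> tuple[RegressionResult, RegressionResult, RegressionResult]:
    """The three covariate-adjusted models sharing one design matrix.

    Model 1: AL ~ SSI + age + gender + CCT
    Model 2: AL_emmetropia ~ same
    Model 3: dAL ~ same

    Because AL = AL_emmetropia + dAL and least squares is linear in the
    outcome, Model 1 coefficients equal Model 2 + Model 3 termwise.
    """
    preds = ["age", "gender", "cct_um", "ssi"]
    m1 = fit_linear_model(table, "al_mm", preds, "Model 1")
    m2 = fit_linear_model(table, "al_emmetropia_mm", preds, "Model 2")
    m3 = fit_linear_model(table, "delta_al_mm", preds, "Model 3")
    return m1, m2, m3


def subgroup_model(table: pd.DataFrame, al_threshold: float = 26.0) -> RegressionResult:
    """Model 3 refitted on the long-eye subgroup AL >= ``al_threshold`` (inclusive)."""
    sub = table[table["al_mm"] >= al_threshold]
    preds = ["age", "gender", "cct_um", "ssi"]
    if len(sub) <= len(preds) + 2:
        raise ValueError(
            f"subgroup AL >= {al_threshold} mm has only {len(sub)} records; too few to fit"
        )
    res = fit_linear_model(sub, "delta_al_mm", preds, f"Model 3 (AL >= {al_threshold} mm)")
    return res


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean emmetropic AL and axial increment in four clinical groups.

    Axial split at 26 mm (>= 26 in the long group); refractive split at
    -6.00 D with SER = -6.00 assigned to the high-myopia group.  Empty
    groups are reported with n = 0 and NaN means, not as errors.
    """
    groups = {
        "AL < 26 mm": table["al_mm"] < 26.0,
        "AL >= 26 mm": table["al_mm"] >= 26.0,
        "SER > -6.00 D": table["ser_d"] > -6.0,
        "SER <= -6.00 D": table["ser_d"] <= -6.0,
    }
    rows = []
    for label, mask in groups.items():
        sub = table[mask]
        rows.append(
            {
                "group": label,
                "n": int(len(sub)),
                "mean_al_emmetropia_mm": float(sub["al_emmetropia_mm"].mean()) if len(sub) else np.nan,
                "mean_delta_al_mm": float(sub["delta_al_mm"].mean()) if len(sub) else np.nan,
                "mean_al_mm": float(sub["al_mm"].mean()) if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def run_diagnostics(fit: RegressionResult, alpha: float = 0.05) -> list[DiagnosticCheck]:
    """Check the OLS assumptions on a fitted model's residuals.

    Four checks, each flagged pass (p >= alpha) / fail:

    * normality of residuals — D'Agostino-Pearson omnibus test;
    * homoscedasticity — Breusch-Pagan of squared residuals on fitted values;
    * independence — Ljung-Box at lag 1 (Durbin-Watson reported in the note);
    * linearity — F-test of a fitted-value-squared augmentation (RESET).

    Checks that cannot run (too few observations, degenerate residuals)
    are reported as not computed rather than raised.
    """
    resid = np.asarray(fit.residuals, dtype=float)
    fitted = np.asarray(fit.fitted, dtype=float)
    n = resid.size
    checks: list[DiagnosticCheck] = []

    degenerate = n < 8 or float(np.std(resid)) < 1e-12

    # normality
    if degenerate or n < 20:
        checks.append(
            DiagnosticCheck("residual_normality", None, None, None, False, "n too small or residuals degenerate")
        )
    else:
        stat, p = sps.normaltest(resid)
        checks.append(
            DiagnosticCheck("residual_normality", float(stat), float(p), bool(p >= alpha))
        )

    # homoscedasticity: Breusch-Pagan against the fitted values
    if degenerate or np.ptp(fitted) < 1e-12:
        checks.append(
            DiagnosticCheck("homoscedasticity", None, None, None, False, "degenerate residuals or constant fit")
        )
    else:
        lm_stat, lm_p, _, _ = het_breuschpagan(resid, sm.add_constant(fitted))
        checks.append(
            DiagnosticCheck("homoscedasticity", float(lm_stat), float(lm_p), bool(lm_p >= alpha))
        )

    # independence: first-order autocorrelation
    if degenerate:
        checks.append(
            DiagnosticCheck("independence", None, None, None, False, "degenerate residuals")
        )
    else:
        lb = acorr_ljungbox(resid, lags=[1])
        lb_stat = float(lb["lb_stat"].iloc[0])
        lb_p = float(lb["lb_pvalue"].iloc[0])
        dw = float(durbin_watson(resid))
        checks.append(
            DiagnosticCheck(
                "independence", lb_stat, lb_p, bool(lb_p >= alpha),
                note=f"Durbin-Watson = {dw:.3f}",
            )
        )

    # linearity: F-test on a fitted^2 augmentation of the design
    p_terms = fit.exog.shape[1]
    if degenerate or n <= p_terms + 2 or np.ptp(fitted) < 1e-12:
        checks.append(
            DiagnosticCheck("linearity", None, None, None, False, "too few observations or degenerate fit")
        )
    else:
        X_aug = np.column_stack([fit.exog, fitted**2])
        if np.linalg.matrix_rank(X_aug) <= np.linalg.matrix_rank(fit.exog):
            checks.append(
                DiagnosticCheck("linearity", None, None, None, False, "augmented design is collinear")
            )
        else:
            beta, _, _, _ = np.linalg.lstsq(X_aug, fit.endog, rcond=None)
            resid_u = fit.endog - X_aug @ beta
            ssr_r = float(resid @ resid)
            ssr_u = float(resid_u @ resid_u)
            df_u = n - X_aug.shape[1]
            f_stat = (ssr_r - ssr_u) / max(ssr_u / df_u, 1e-300)
            f_p = float(sps.f.sf(f_stat, 1, df_u))
            checks.append(
                DiagnosticCheck("linearity", float(f_stat), f_p, bool(f_p >= alpha))
            )

    fit.diagnostics = checks
    return checks


_TWO_DEC = ["ser_d", "ssi", "cr_mm", "al_mm", "al_morgan_mm", "al_emmetropia_mm", "delta_al_mm"]
_ROW_LABELS = {
    "ser_d": "SER ({eye}), diopter",
    "ssi": "SSI ({eye})",
    "cct_um": "CCT ({eye}), um",
    "cr_mm": "CR ({eye}), mm",
    "al_mm": "AL ({eye}), mm",
    "al_morgan_mm": "ALMorgan ({eye}), mm",
    "al_emmetropia_mm": "ALemmetropia ({eye}), mm",
    "delta_al_mm": "dAL ({eye}), mm",
}


def _mean_sd(x: pd.Series, decimals: int) -> tuple[float, float, str]:
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0  # single record: SD = 0 by convention
    fmt = f"{{:.{decimals}f}}" if decimals else "{:.0f}"
    return mean, sd, f"{fmt.format(mean)} ({fmt.format(sd)})"


def descriptive_table(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort descriptive summary: mean (SD) per eye, gender as n (%).

    Age and CCT are rounded to integers, the optical variables to two
    decimals.  For a single record the SD is reported as 0.
    """
    if table.empty:
        raise ValueError("descriptive_table requires a non-empty cohort")
    rows = []
    n_subjects = table["subject_id"].nunique()
    per_subject = table.drop_duplicates("subject_id")

    mean, sd, disp = _mean_sd(per_subject["age"], 0)
    rows.append({"characteristic": "Age, years", "mean": mean, "sd": sd, "n": None, "display": disp})
    for g in ("female", "male"):
        cnt = int((per_subject["gender"] == g).sum())
        pct = 100.0 * cnt / n_subjects
        rows.append(
            {
                "characteristic": g.capitalize(),
                "mean": None,
                "sd": None,
                "n": cnt,
                "display": f"{cnt} ({pct:.0f}%)",
            }
        )
    for eye in ("OD", "OS"):
        sub = table[table["eye"] == eye]
        if sub.empty:
            continue
        for col, label in _ROW_LABELS.items():
            if col not in sub.columns or sub[col].isna().all():
                continue
            decimals = 2 if col in _TWO_DEC else 0
            mean, sd, disp = _mean_sd(sub[col], decimals)
            rows.append(
                {
                    "characteristic": label.format(eye=eye),
                    "mean": mean,
                    "sd": sd,
                    "n": None,
                    "display": disp,
                }
            )
    return pd.DataFrame(rows).set_index("characteristic")
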