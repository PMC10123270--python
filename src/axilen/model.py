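"""Model/Results interface tying the whole analysis together.

:class:`StiffnessElongationModel` is built from a per-eye cohort table
(or simulated from a :class:`~axilen.cohort.GeneratorConfig`); its
:meth:`~StiffnessElongationModel.fit` runs the full pipeline — Morgan
decomposition, agreement and correlation analyses, simple and adjusted
regressions, the long-eye subgroup model and assumption diagnostics —
and returns a :class:`StiffnessElongationResults` holding every estimate
with its uncertainty.

Example
-------
>>> from axilen import GeneratorConfig, StiffnessElongationModel
>>> cfg = GeneratorConfig(n=267, seed=7)
>>> res = StiffnessElongationModel.from_config(cfg).fit()
>>> print(res.summary())        # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import stats as _st
from .cohort import GeneratorConfig, generate_cohort
from .morgan import DEFAULT_CONSTANTS, MorganConstants
from .records import REQUIRED_COLUMNS, read_cohort

__all__ = ["StiffnessElongationModel", "StiffnessElongationResults"]


@dataclass
class StiffnessElongationResults:
    """Results of the full corneal-stiffness / axial-elongation analysis."""

    n: int
    descriptives: pd.DataFrame
    corr_al_morgan: _st.CorrelationResult
    corr_ser_delta: _st.CorrelationResult
    agreement: _st.BlandAltmanResult
    groups: pd.DataFrame
    simple: dict[str, _st.RegressionResult]
    adjusted: tuple[_st.RegressionResult, _st.RegressionResult, _st.RegressionResult]
    subgroup: Optional[_st.RegressionResult]
    subgroup_note: str = ""
    diagnostics: dict[str, list[_st.DiagnosticCheck]] = field(default_factory=dict)

    @property
    def simple_slopes(self) -> dict[str, float]:
        """SSI slopes of the three simple regressions (AL, ALemm, dAL)."""
        return {k: v.coef("ssi") for k, v in self.simple.items()}

    def to_dict(self) -> dict:
        """JSON-serialisable summary of every fitted quantity."""
        out = {
            "n": self.n,
            "correlations": {
                "al_vs_al_morgan": vars(self.corr_al_morgan),
                "ser_vs_delta_al": vars(self.corr_ser_delta),
            },
            "bland_altman": vars(self.agreement),
            "group_means": self.groups.reset_index().to_dict(orient="records"),
            "simple_regressions": {k: v.to_dict() for k, v in self.simple.items()},
            "adjusted_models": {m.model_label: m.to_dict() for m in self.adjusted},
            "subgroup_model": self.subgroup.to_dict() if self.subgroup else None,
            "subgroup_note": self.subgroup_note,
            "diagnostics": {
                label: [
                    {
                        "name": c.name,
                        "statistic": c.statistic,
                        "p_value": c.p_value,
                        "passed": c.passed,
                        "computed": c.computed,
                        "note": c.note,
                    }
                    for c in checks
                ]
                for label, checks in self.diagnostics.items()
            },
            "descriptives": self.descriptives.reset_index().to_dict(orient="records"),
        }
        return out

    def summary(self) -> str:
        """Human-readable report mirroring the clinical-paper layout."""
        ba = self.agreement
        lines = [
            f"Corneal stiffness & axial elongation analysis (n = {self.n} eyes)",
            "=" * 64,
            "",
            "Agreement of measured AL with the Morgan estimate",
            f"  Pearson r = {self.corr_al_morgan.r:.2f}, t = {self.corr_al_morgan.t:.1f}, "
            f"p = {_st.format_p(self.corr_al_morgan.p)}",
            f"  Bland-Altman ({ba.direction}): bias {ba.bias:.2f} mm, SD {ba.sd_diff:.2f} mm, "
            f"95% LoA [{ba.loa_low:.2f}, {ba.loa_high:.2f}] mm",
            "",
            "Correlation of SER with the axial increment dAL",
            f"  Pearson r = {self.corr_ser_delta.r:.2f}, t = {self.corr_ser_delta.t:.1f}, "
            f"p = {_st.format_p(self.corr_ser_delta.p)}",
            "",
            "Simple regressions on SSI",
        ]
        for key, fit in self.simple.items():
            b0 = fit.coef("intercept")
            b1 = fit.coef("ssi")
            sign = "-" if b1 < 0 else "+"
            lines.append(f"  {fit.outcome} = {b0:.3g} {sign} {abs(b1):.3g} x SSI")
        lines += ["", "Adjusted models (age, gender, CCT)"]
        for m in self.adjusted:
            lines.append(m.summary())
        lines.append("")
        if self.subgroup is not None:
            lines.append(self.subgroup.summary())
        else:
            lines.append(f"Subgroup model not fitted: {self.subgroup_note}")
        if self.diagnostics:
            lines += ["", "Assumption checks (pass at p >= 0.05)"]
            for label, checks in self.diagnostics.items():
                status = ", ".join(
                    f"{c.name}={'pass' if c.passed else 'FAIL' if c.passed is not None else 'n/c'}"
                    for c in checks
                )
                lines.append(f"  {label}: {status}")
        return "\n".join(lines)


class StiffnessElongationModel:
    """Morgan-decomposition analysis of one per-eye biometry cohort.

    Parameters
    ----------
    data : pandas.DataFrame
        Cohort table with the required measured columns (see
        :data:`axilen.records.REQUIRED_COLUMNS`).  Derived columns are
        (re)computed on construction, so they are always consistent with
        the measured values.
    constants : MorganConstants
        Coefficients of the Morgan equation.
    """

    def __init__(self, data: pd.DataFrame, constants: MorganConstants = DEFAULT_CONSTANTS):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"cohort table missing required columns {missing}")
        self.constants = constants
        self.data = _st.compute_derived(data, constants)

    @classmethod
    def from_csv(cls, path, constants: MorganConstants = DEFAULT_CONSTANTS
                 ) -> "StiffnessElongationModel":
        """Build the model from a cohort CSV file."""
        return cls(read_cohort(path), constants)

    @classmethod
    def from_config(cls, config: GeneratorConfig,
                    constants: MorganConstants = DEFAULT_CONSTANTS
                    ) -> "StiffnessElongationModel":
        """Simulate a synthetic cohort and build the model from it."""
        return cls(generate_cohort(config, constants), constants)

    def fit(self, al_threshold: float = 26.0, diagnostics: bool = True
            ) -> StiffnessElongationResults:
        """Run the full analysis pipeline and return the results object."""
        df = self.data
        if len(df) < 8:
            raise ValueError(f"cohort of n = {len(df)} is too small to analyse")

        corr_al = _st.pearson_with_t(df["al_mm"], df["al_morgan_mm"])
        corr_ser = _st.pearson_with_t(df["ser_d"], df["delta_al_mm"])
        agreement = _st.bland_altman(df["al_mm"], df["al_morgan_mm"])
        groups = _st.group_summary(df)

        simple = {
            "al": _st.fit_linear_model(df, "al_mm", ["ssi"], "AL ~ SSI"),
            "al_emmetropia": _st.fit_linear_model(
                df, "al_emmetropia_mm", ["ssi"], "ALemmetropia ~ SSI"
            ),
            "delta_al": _st.fit_linear_model(df, "delta_al_mm", ["ssi"], "dAL ~ SSI"),
        }
        adjusted = _st.run_adjusted_models(df)

        subgroup = None
        note = ""
        try:
            subgroup = _st.subgroup_model(df, al_threshold)
        except ValueError as exc:
            note = str(exc)

        diag: dict[str, list[_st.DiagnosticCheck]] = {}
        if diagnostics:
            for m in adjusted:
                diag[m.model_label] = _st.run_diagnostics(m)
            if subgroup is not None:
                diag[subgroup.model_label] = _st.run_diagnostics(subgroup)

        return StiffnessElongationResults(
            n=len(df),
            descriptives=_st.descriptive_table(df),
            corr_al_morgan=corr_al,
            corr_ser_delta=corr_ser,
            agreement=agreement,
            groups=groups,
            simple=simple,
            adjusted=adjusted,
            subgroup=subgroup,
            subgroup_note=note,
            diagnostics=diag,
        )


def plot_bland_altman(results: StiffnessElongationResults, data: pd.DataFrame, ax=None):
    """Bland-Altman scatter with bias and limits of agreement."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mean_vals = (data["al_mm"] + data["al_morgan_mm"]) / 2
    diff_vals = data["al_mm"] - data["al_morgan_mm"]
    ba = results.agreement
    ax.scatter(mean_vals, diff_vals, s=8, alpha=0.5)
    for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("Mean of AL and Morgan estimate (mm)")
    ax.set_ylabel("AL - Morgan estimate (mm)")
    return ax


def plot_forest(results: StiffnessElongationResults, ax=None):
    """Forest plot of the adjusted-model coefficients with 95% CIs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    y = 0
    ticks, labels = [], []
    for m in results.adjusted:
        for name, row in m.terms.iterrows():
            if name == "intercept":
                continue
            ax.errorbar(
                row["estimate"], y,
                xerr=[[row["estimate"] - row["ci_low"]], [row["ci_high"] - row["estimate"]]],
                fmt="o", color="k", markersize=3, capsize=2,
            )
            ticks.append(y)
            labels.append(f"{m.model_label}: {name}")
            y += 1
    ax.axvline(0, color="grey", linewidth=0.8)
    ax.set_yticks(ticks)
    ax.set_yticklabels(labels, fontsize=7)
    ax.set_xlabel("Coefficient (95% CI)")
    return ax
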