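"""Cohort validation and exclusion filtering.

The clinical exclusion criteria (high astigmatism, contact-lens wear,
corneal disease, prior eye surgery, failed measurement quality) were
applied at recruitment in the original study; here they are re-expressed
as data-validation rules so arbitrary input files can be screened.  The
flag columns are optional: records lacking them are retained with a
logged warning.  Physiological-guard violations are always excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .records import guard_mask

__all__ = ["ExclusionReport", "apply_exclusions", "OPTIONAL_FLAG_COLUMNS"]

logger = logging.getLogger(__name__)

#: Optional screening columns and how they are interpreted.
OPTIONAL_FLAG_COLUMNS = {
    "astigmatism_d": "exclude when >= 3.0 D",
    "contact_lens": "exclude when truthy",
    "corneal_disease": "exclude when truthy",
    "prior_surgery": "exclude when truthy",
    "quality_ok": "exclude when falsy",
}

ASTIGMATISM_LIMIT_D = 3.0  # "3 D or more" is excluded (inclusive threshold)


@dataclass
class ExclusionReport:
    """Per-rule exclusion counts and the ids of excluded records."""

    input_count: int
    retained_count: int
    counts: dict[str, int] = field(default_factory=dict)
    excluded_ids: list[str] = field(default_factory=list)
    missing_columns: list[str] = field(default_factory=list)

    @property
    def excluded_count(self) -> int:
        return self.input_count - self.retained_count

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "retained_count": self.retained_count,
            "excluded_count": self.excluded_count,
            "counts_per_rule": dict(self.counts),
            "excluded_ids": list(self.excluded_ids),
            "missing_optional_columns": list(self.missing_columns),
        }


def _truthy(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    return col.astype(str).str.strip().str.lower().isin({"1", "true", "yes", "y"})


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Screen a cohort table against the exclusion rules.

    Returns the retained table and an :class:`ExclusionReport`; a record
    is excluded if it fails *any* rule, and each rule's count tallies
    every record it catches (so counts can sum to more than the number
    excluded).  Idempotent: re-running on the output excludes nothing.
    """
    n = len(table)
    masks: dict[str, pd.Series] = {}
    missing = []

    if "astigmatism_d" in table.columns:
        masks["astigmatism_ge_3d"] = (
            pd.to_numeric(table["astigmatism_d"], errors="coerce") >= ASTIGMATISM_LIMIT_D
        )
    else:
        missing.append("astigmatism_d")
    for col, rule in (
        ("contact_lens", "contact_lens"),
        ("corneal_disease", "corneal_disease"),
        ("prior_surgery", "prior_surgery"),
    ):
        if col in table.columns:
            masks[rule] = _truthy(table[col]).fillna(False)
        else:
            missing.append(col)
    if "quality_ok" in table.columns:
        masks["failed_quality"] = ~_truthy(table["quality_ok"]).fillna(True)
    else:
        missing.append("quality_ok")

    masks["out_of_range"] = ~guard_mask(table)

    if missing:
        logger.warning(
            "optional exclusion columns %s absent; affected rules skipped", missing
        )

    excluded = pd.Series(False, index=table.index)
    counts = {}
    for rule, mask in masks.items():
        counts[rule] = int(mask.sum())
        excluded |= mask

    retained = table[~excluded].copy()
    report = ExclusionReport(
        input_count=n,
        retained_count=len(retained),
        counts=counts,
        excluded_ids=[str(s) for s in table.loc[excluded, "subject_id"]],
        missing_columns=missing,
    )
    return retained, report
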