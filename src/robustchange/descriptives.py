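"""Descriptive layer: inclusion filters, frequency tables, difference scores.

The inclusion filters mirror a typical online-survey screening ledger:
incomplete records, records with ambiguous mental-health information,
under-age respondents, and respondents who participated after the cutoff
date are removed in that fixed order, and a row violating several rules is
counted once, under the first rule that catches it.

Reported percentages are rounded half-up to two decimals, and denominators
are always explicit parameters: published frequency tables routinely switch
denominators (total sample, currently-affected subsample, ...) without
notice, so the caller must state which population a percentage refers to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyTable",
    "ExclusionLog",
    "DescriptivesError",
    "round_half_up",
    "percentage",
    "apply_inclusion_filters",
    "frequency_table",
    "difference_scores",
]

#: Screening rules in application order: (rule name, required column).
FILTER_RULES = (
    ("incomplete", "completed"),
    ("ambiguous_health", "ambiguous_health"),
    ("under_age", "age"),
    ("after_cutoff", "participation_date"),
)


class DescriptivesError(ValueError):
    """Invalid descriptive-layer input."""


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), unlike numpy's half-even."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, denominator: int, decimals: int = 2) -> float:
    if denominator <= 0:
        raise DescriptivesError("denominator must be positive")
    return round_half_up(100.0 * count / denominator, decimals)


@dataclass
class ExclusionLog:
    """Per-rule exclusion counts, in application order."""

    counts: dict[str, int] = field(default_factory=dict)
    n_before: int = 0
    n_after: int = 0

    @property
    def total_excluded(self) -> int:
        return sum(self.counts.values())


@dataclass
class FrequencyTable:
    """Counts and percentages of one categorical stratum."""

    rows: pd.DataFrame  # columns: stratum, count, pct
    denominator: int
    denominator_definition: str

    def __post_init__(self) -> None:
        if self.rows["count"].sum() > self.denominator:
            raise DescriptivesError("counts exceed the stated denominator")


def apply_inclusion_filters(
    raw: pd.DataFrame,
    cutoff_date: str | pd.Timestamp | None = None,
    min_age: float = 18.0,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the screening rules in order; each row is excluded at most once.

    Expected columns (each optional — a rule is skipped when its column is
    absent, except that `cutoff_date` requires `participation_date`):
    ``completed`` (bool), ``ambiguous_health`` (bool), ``age`` (years),
    ``participation_date`` (parseable dates).  Returns the filtered frame and
    a per-rule ledger.  Filtering is idempotent: reapplying it to its own
    output removes nothing.
    """
    log = ExclusionLog(n_before=len(raw))
    keep = pd.Series(True, index=raw.index)

    for rule, column in FILTER_RULES:
        if column not in raw.columns:
            if rule == "after_cutoff" and cutoff_date is not None:
                raise DescriptivesError("cutoff_date given but 'participation_date' column missing")
            continue
        if rule == "incomplete":
            violates = ~raw[column].astype(bool)
        elif rule == "ambiguous_health":
            violates = raw[column].astype(bool)
        elif rule == "under_age":
            violates = raw[column].astype(float) < min_age
        else:  # after_cutoff
            if cutoff_date is None:
                continue
            dates = pd.to_datetime(raw[column])
            violates = dates > pd.to_datetime(cutoff_date)
        newly = violates & keep
        log.counts[rule] = int(newly.sum())
        keep &= ~violates

    out = raw[keep].copy()
    log.n_after = len(out)
    return out, log


def frequency_table(
    table: pd.DataFrame,
    stratum_column: str,
    denominator: int | None = None,
    denominator_definition: str = "all rows of the input table",
) -> FrequencyTable:
    """Counts and half-up-rounded percentages of one categorical column."""
    if stratum_column not in table.columns:
        raise DescriptivesError(f"missing stratum column {stratum_column!r}")
    denom = len(table) if denominator is None else int(denominator)
    if denom <= 0:
        raise DescriptivesError("denominator must be positive")
    counts = table[stratum_column].value_counts(dropna=False)
    rows = pd.DataFrame(
        {
            "stratum": counts.index.astype(str),
            "count": counts.to_numpy(),
            "pct": [percentage(int(c), denom) for c in counts],
        }
    )
    return FrequencyTable(rows, denom, denominator_definition)


def difference_scores(table: pd.DataFrame, variable: str) -> np.ndarray:
    """Elementwise T1 minus T0 change scores in original score units."""
    t0_col, t1_col = f"{variable}_t0", f"{variable}_t1"
    for col in (t0_col, t1_col):
        if col not in table.columns:
            raise DescriptivesError(f"variable {variable!r}: missing column {col!r}")
    missing = table[t0_col].isna() | table[t1_col].isna()
    if missing.any():
        ids = (
            table.loc[missing, "participant_id"].tolist()
            if "participant_id" in table.columns
            else table.index[missing].tolist()
        )
        raise DescriptivesError(
            f"variable {variable!r}: missing timepoint for participant(s) {ids[:5]}"
        )
    return (table[t1_col] - table[t0_col]).to_numpy(dtype=float)
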