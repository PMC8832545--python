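"""Rounding and contingency-table reporting.

All printed percentages in the package go through :func:`round_half_up`
(half-up at the reported precision, via ``decimal``), centralised here so
worked-example outputs are reproducible to the printed digit.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = ["round_half_up", "percent", "ContingencyTable"]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero at ``decimals`` (5 always rounds up)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """100 * numerator / denominator with half-up rounding."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    return round_half_up(100.0 * numerator / denominator, decimals)


@dataclass
class ContingencyTable:
    """Cross-tabulation of group/class labels against called labels."""

    counts: pd.DataFrame  # rows: groups (or true classes); cols: called labels

    @classmethod
    def from_calls(
        cls, calls: pd.DataFrame, group_col: str, label_col: str
    ) -> "ContingencyTable":
        counts = pd.crosstab(calls[group_col], calls[label_col])
        return cls(counts=counts)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def percent(self, row, col, decimals: int = 0) -> float:
        """Within-row percentage of one called label (half-up rounded).

        Returns NaN for an empty row (0/0 is reported as undefined)."""
        denom = int(self.row_totals.loc[row])
        if denom == 0:
            return float("nan")
        return percent(int(self.counts.loc[row, col]), denom, decimals)

    def purity(self, decimals: int = 0) -> dict:
        """Per-row purity: the majority column's share of the row, in %."""
        out = {}
        for row in self.counts.index:
            denom = int(self.row_totals.loc[row])
            if denom == 0:
                out[row] = float("nan")
                continue
            out[row] = percent(int(self.counts.loc[row].max()), denom, decimals)
        return out

    def pooled_percent(self, col, decimals: int = 0) -> float:
        return percent(int(self.col_totals.loc[col]), self.total, decimals)
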