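"""Per-deficiency relative viability and hybrid-incompatibility calls.

For each stock x species x temperature, progeny counts are pooled over
vials and the deficiency class is compared against the balancer class.
Under equal survival, deficiency- and balancer-class daughters segregate
1:1, so the relative viability

    v_hat = n_df / (n_df + n_bal)

is 0.5.  A dearth of deficiency-class daughters is assessed with a
chi-square goodness-of-fit test against the 1:1 expectation (1 degree of
freedom, no continuity correction):

    chi2 = (n_df - n_bal)^2 / (n_df + n_bal)

A stock is called HI (hybrid incompatibility) when the test is significant
AND the deficiency class is the minority AND the pooled total reaches a
minimum size; a significant *excess* of deficiency-class daughters is never
called HI.  Complete lethality (n_df = 0 with an adequate balancer count)
is always called HI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HISet",
    "DEFAULT_ALPHA",
    "DEFAULT_MIN_TOTAL",
    "aggregate_counts",
    "relative_viability",
    "chi2_ratio_test",
    "viability_table",
    "classify_hi",
    "write_viability_table",
]

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_TOTAL = 20


@dataclass
class HISet:
    """HI-flagged stocks for one (species, temperature) condition."""

    species: str
    temperature: str
    members: frozenset[str]
    intervals: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    # stock_id -> (arm, start, end); populated when a panel is supplied

    @property
    def condition(self) -> tuple[str, str]:
        return (self.species, self.temperature)

    def __len__(self) -> int:
        return len(self.members)


def aggregate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Pool vial counts into per stock x species x temperature totals.

    Returns a DataFrame with columns ``stock_id, species, temperature,
    n_df, n_bal, n_vials``; groups whose pooled total is zero are retained
    with a ``no_progeny`` flag so they can be reported separately.
    """
    grouped = (
        counts.groupby(["stock_id", "species", "temperature"], sort=True)
        .agg(n_df=("n_df", "sum"), n_bal=("n_bal", "sum"), n_vials=("vial_id", "size"))
        .reset_index()
    )
    grouped["no_progeny"] = (grouped["n_df"] + grouped["n_bal"]) == 0
    return grouped


def relative_viability(n_df: int, n_bal: int) -> float:
    """Deficiency-class share of scored daughters: n_df / (n_df + n_bal)."""
    total = n_df + n_bal
    if total <= 0:
        raise ValueError("relative viability undefined for zero total progeny")
    return n_df / total


def chi2_ratio_test(n_df: int, n_bal: int) -> tuple[float, float]:
    """Chi-square test of a 1:1 deficiency:balancer ratio.

    Returns ``(statistic, p_value)`` where the statistic is
    ``(n_df - n_bal)^2 / (n_df + n_bal)`` and p is the upper tail of the
    chi-square distribution with 1 degree of freedom.
    """
    total = n_df + n_bal
    if total <= 0:
        raise ValueError("chi-square ratio test undefined for zero total progeny")
    statistic = (n_df - n_bal) ** 2 / total
    p_value = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p_value


def viability_table(
    totals: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> pd.DataFrame:
    """Per-stock viability statistics and HI calls from pooled totals.

    Adds columns ``v_hat, chi2, p, testable, hi_call, complete_lethal`` to
    the aggregated totals.  Stocks with pooled totals below ``min_total``
    are flagged untestable and never called HI.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    out = totals.copy()
    n_df = out["n_df"].to_numpy(dtype=float)
    n_bal = out["n_bal"].to_numpy(dtype=float)
    total = n_df + n_bal
    with np.errstate(invalid="ignore", divide="ignore"):
        v_hat = np.where(total > 0, n_df / np.maximum(total, 1), np.nan)
        chi2 = np.where(total > 0, (n_df - n_bal) ** 2 / np.maximum(total, 1), np.nan)
    p = np.where(total > 0, stats.chi2.sf(chi2, df=1), np.nan)
    testable = total >= min_total
    complete_lethal = (n_df == 0) & (n_bal >= min_total)
    hi_call = (testable & (p < alpha) & (n_df < n_bal)) | complete_lethal
    out["v_hat"] = v_hat
    out["chi2"] = chi2
    out["p"] = p
    out["testable"] = testable
    out["hi_call"] = hi_call
    out["complete_lethal"] = complete_lethal
    return out


def classify_hi(
    table: pd.DataFrame,
    panel=None,
) -> dict[tuple[str, str], HISet]:
    """Split a viability table into per-condition HI sets.

    ``table`` is the output of :func:`viability_table`.  When a
    :class:`~dfscreen.panel.DeficiencyPanel` is supplied, each HI set also
    carries the arm-tagged intervals of its members for locus resolution.
    """
    intervals_by_id: dict[str, tuple[str, int, int]] = {}
    if panel is not None:
        intervals_by_id = {
            d.stock_id: (d.arm, d.start, d.end) for d in panel.deficiencies
        }
        unknown = set(table["stock_id"]) - set(intervals_by_id)
        if unknown:
            raise ValueError(
                f"counts reference stocks absent from the panel: {sorted(unknown)[:5]}"
            )
    sets: dict[tuple[str, str], HISet] = {}
    for (sp, temp), grp in table.groupby(["species", "temperature"], sort=True):
        members = frozenset(grp.loc[grp["hi_call"], "stock_id"])
        intervals = {m: intervals_by_id[m] for m in members if m in intervals_by_id}
        sets[(sp, temp)] = HISet(sp, temp, members, intervals)
    return sets


def write_viability_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = [
        "stock_id", "species", "temperature", "n_df", "n_bal",
        "v_hat", "chi2", "p", "hi_call", "complete_lethal", "testable",
    ]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
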