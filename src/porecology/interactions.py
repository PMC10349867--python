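"""Rule-based classification of pairwise microbial interactions.

Co-culture rule (biofilm yields): with monoculture yields y_a, y_b and
derived Y_min = min, Y_sum = y_a + y_b,

    positive         iff  Y_co > Y_sum
    strong_negative  iff  Y_co < Y_min
    weak_negative    iff  Y_min <= Y_co <= Y_sum

Conditioned-medium rule (growth in conditioned vs unconditioned medium):

    positive         iff  Y_c >= Y_u
    weak_negative    iff  0.5 <= Y_c / Y_u < 1
    strong_negative  iff  Y_c / Y_u < 0.5
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CocultureYields",
    "InteractionCall",
    "classify_coculture",
    "classify_conditioned",
    "classify_coculture_table",
    "frequency_metrics",
    "POSITIVE",
    "WEAK_NEGATIVE",
    "STRONG_NEGATIVE",
]

POSITIVE = "positive"
WEAK_NEGATIVE = "weak_negative"
STRONG_NEGATIVE = "strong_negative"


@dataclass(frozen=True)
class CocultureYields:
    """Monoculture and co-culture biofilm yields (OD units, >= 0)."""

    y_a: float
    y_b: float
    y_co: float

    def __post_init__(self):
        if self.y_a < 0 or self.y_b < 0 or self.y_co < 0:
            raise ValueError("yields must be nonnegative")

    @property
    def y_min(self) -> float:
        return min(self.y_a, self.y_b)

    @property
    def y_max(self) -> float:
        return max(self.y_a, self.y_b)

    @property
    def y_sum(self) -> float:
        return self.y_a + self.y_b

    @property
    def y_ave(self) -> float:
        return self.y_sum / 2.0


@dataclass(frozen=True)
class InteractionCall:
    label: str | None
    margin: float | None
    flag: str | None = None


def classify_coculture(y: CocultureYields) -> InteractionCall:
    """Classify a co-culture outcome by the stated yield inequalities.

    The classification is total and mutually exclusive over nonnegative
    inputs; both boundaries (Y_co = Y_min, Y_co = Y_sum) fall in
    ``weak_negative``.  The margin is the distance of Y_co from the nearest
    class boundary, in yield units.
    """
    if y.y_co > y.y_sum:
        label = POSITIVE
    elif y.y_co < y.y_min:
        label = STRONG_NEGATIVE
    else:
        label = WEAK_NEGATIVE
    margin = min(abs(y.y_co - y.y_min), abs(y.y_co - y.y_sum))
    return InteractionCall(label=label, margin=float(margin))


def classify_conditioned(y_c: float, y_u: float) -> InteractionCall:
    """Classify growth in conditioned medium relative to unconditioned.

    Returns an explicit null call when y_u = 0 (undefined ratio).  The
    margin is the distance of the ratio Y_c/Y_u from the nearest boundary
    {0.5, 1}.
    """
    if y_c < 0 or y_u < 0:
        raise ValueError("yields must be nonnegative")
    if y_u == 0:
        return InteractionCall(label=None, margin=None, flag="undefined-ratio")
    ratio = y_c / y_u
    if ratio >= 1.0:
        label = POSITIVE
    elif ratio >= 0.5:
        label = WEAK_NEGATIVE
    else:
        label = STRONG_NEGATIVE
    margin = min(abs(ratio - 0.5), abs(ratio - 1.0))
    return InteractionCall(label=label, margin=float(margin))


def classify_coculture_table(df: pd.DataFrame) -> pd.DataFrame:
    """Classify each row of a co-culture yield table.

    Expects columns ``y_a``, ``y_b``, ``y_co`` (plus any identifiers, which
    are passed through).  When a ``replicate`` column is present, replicate
    yields are averaged per ``pair_id`` before the aggregate call, and the
    per-replicate calls are returned alongside.
    """
    out = df.copy()
    calls = [classify_coculture(CocultureYields(r.y_a, r.y_b, r.y_co))
             for r in df.itertuples()]
    out["call"] = [c.label for c in calls]
    out["margin"] = [c.margin for c in calls]
    if "replicate" in df.columns and "pair_id" in df.columns:
        mean = df.groupby("pair_id")[["y_a", "y_b", "y_co"]].mean()
        agg = {pid: classify_coculture(CocultureYields(r.y_a, r.y_b, r.y_co))
               for pid, r in mean.iterrows()}
        out["call_mean"] = out["pair_id"].map(lambda p: agg[p].label)
    return out


def frequency_metrics(
    counts: pd.DataFrame,
    focal: str,
    *,
    reference: float = 0.5,
    inoculum_compartment: str = "inoculum",
) -> pd.DataFrame:
    """Per-compartment genotype frequencies with a signed-rank test vs 0.5.

    Parameters
    ----------
    counts : DataFrame
        Long table with columns ``replicate``, ``compartment``, ``genotype``,
        ``count`` (cell numbers, >= 0).
    focal : str
        Genotype whose frequency is reported (count_focal / total per
        replicate and compartment; empty compartments yield a null
        frequency).

    Returns one row per compartment with the replicate frequencies' median,
    the two-sided Wilcoxon signed-rank p-value against `reference` (exact
    null for n <= 25; p = 1 when all differences are zero), and the median
    frequency change versus the inoculum compartment when present.
    """
    required = {"replicate", "compartment", "genotype", "count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    if (counts["count"] < 0).any():
        raise ValueError("counts must be nonnegative")

    freq = (
        counts.pivot_table(index=["compartment", "replicate"],
                           columns="genotype", values="count",
                           aggfunc="sum", fill_value=0.0)
    )
    totals = freq.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = freq.get(focal, pd.Series(0.0, index=freq.index)) / totals
    f[totals == 0] = np.nan  # empty compartment: null frequency

    rows = []
    inoc_median = None
    by_comp = f.groupby(level="compartment")
    medians = by_comp.median()
    if inoculum_compartment in medians.index:
        inoc_median = medians[inoculum_compartment]
    for comp, values in by_comp:
        vals = values.dropna().to_numpy()
        diffs = vals - reference
        if vals.size == 0:
            p = np.nan
            flag = "empty"
        elif np.all(diffs == 0):
            p = 1.0
            flag = "all-zero-differences"
        else:
            method = "exact" if vals.size <= 25 else "auto"
            p = float(stats.wilcoxon(diffs, alternative="two-sided",
                                     method=method).pvalue)
            flag = None
        rows.append({
            "compartment": comp,
            "n": int(vals.size),
            "median_frequency": float(np.median(vals)) if vals.size else np.nan,
            "pvalue_vs_reference": p,
            "flag": flag,
            "delta_vs_inoculum": (
                float(np.median(vals) - inoc_median)
                if vals.size and inoc_median is not None else np.nan
            ),
        })
    return pd.DataFrame(rows)
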