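"""Colloid breakthrough-curve moment analysis.

The mean travel time of colloids through the porous chamber is the first
normalized temporal moment of the effluent particle-density curve,

    tau = integral(t * C(t) dt, 0..T) / integral(C(t) dt, 0..T),

evaluated by trapezoidal quadrature on the sampled time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BreakthroughCurve",
    "TTestSummary",
    "mean_travel_time",
    "compare_mean_travel_times",
    "read_curve_csv",
]


@dataclass
class BreakthroughCurve:
    """Time-stamped effluent particle-density series.

    Parameters
    ----------
    t : array-like
        Sampling times in minutes, strictly increasing, within [0, duration].
    c : array-like
        Particle density (arbitrary nonnegative units), same length as `t`.
    duration : float
        Duration T of the experiment in minutes.
    """

    t: np.ndarray
    c: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.t.ndim != 1 or self.c.ndim != 1 or self.t.size != self.c.size:
            raise ValueError("t and c must be 1-D arrays of equal length")
        if self.t.size < 3:
            raise ValueError("a breakthrough curve needs at least 3 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.t[0] < 0 or self.t[-1] > self.duration + 1e-9:
            raise ValueError("time stamps must lie within [0, duration]")
        if np.any(self.c < 0):
            raise ValueError("particle density must be nonnegative")

    def __len__(self) -> int:
        return self.t.size


def mean_travel_time(curve: BreakthroughCurve) -> float:
    """First normalized temporal moment (mean travel time, minutes).

    Raises
    ------
    ValueError
        If the curve is identically zero (the moment is undefined).
    """
    mass = np.trapezoid(curve.c, curve.t)
    if mass <= 0:
        raise ValueError("curve has zero integral; mean travel time undefined")
    first = np.trapezoid(curve.t * curve.c, curve.t)
    tau = first / mass
    # quadrature cannot move the moment outside the sampling window
    return float(np.clip(tau, 0.0, curve.duration))


@dataclass
class TTestSummary:
    difference: float  # mean(a) - mean(b)
    statistic: float
    pvalue: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    equal_var: bool = field(default=False)


def compare_mean_travel_times(
    group_a, group_b, *, equal_var: bool = False
) -> TTestSummary:
    """Two-sided two-sample t-test between groups of travel times.

    Welch's unequal-variance flavor by default; pass ``equal_var=True`` for
    the classic Student test.  Groups with zero variance and equal means are
    reported with p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    summary = dict(
        difference=float(a.mean() - b.mean()),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        equal_var=equal_var,
    )
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return TTestSummary(statistic=0.0, pvalue=1.0, **summary)
        return TTestSummary(statistic=np.inf * np.sign(summary["difference"]),
                            pvalue=0.0, **summary)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestSummary(statistic=float(res.statistic),
                        pvalue=float(res.pvalue), **summary)


def read_curve_csv(path, duration: float | None = None) -> BreakthroughCurve:
    """Read a curve from CSV with columns ``time_min`` and ``signal``."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"time_min", "signal"} - set(df.columns)
    if missing:
        raise ValueError(f"curve CSV missing columns: {sorted(missing)}")
    t = df["time_min"].to_numpy(dtype=float)
    if duration is None:
        duration = float(t[-1])
    return BreakthroughCurve(t=t, c=df["signal"].to_numpy(dtype=float),
                             duration=duration)
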