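"""qPCR calibration, absolute quantification and compartment partitioning.

A standard curve relates quantification cycle to template amount,
``Cq = intercept + slope * log10(copies)``, with amplification efficiency
``E = 10**(-1/slope) - 1``.  Chamber populations are split into planktonic
and biofilm compartments from the effluent cell density and the total cell
number recovered from the chamber:

    C_planktonic = D_planktonic * V_chip
    C_biofilm    = C_entire - C_planktonic
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "StandardCurve",
    "CompartmentCounts",
    "LogisticFit",
    "DEFAULT_CHAMBER_VOLUME_UL",
    "fit_standard_curve",
    "quantify",
    "partition_cells",
    "fit_logistic",
]

#: Chamber volume of the reference microfluidic design, in microliters.
DEFAULT_CHAMBER_VOLUME_UL = 3.0


@dataclass(frozen=True)
class StandardCurve:
    """Fitted dilution-series calibration line (Cq vs log10 copies)."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    cq_min: float
    cq_max: float

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * self.efficiency


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency (fraction) implied by a standard-curve slope."""
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(copies, cq) -> StandardCurve:
    """Least-squares line of Cq on log10(copies).

    Technical replicates sharing a copy number are averaged on the Cq scale
    before fitting.  Requires at least 3 distinct dilution levels and a
    negative fitted slope.
    """
    copies = np.asarray(copies, dtype=float)
    cq = np.asarray(cq, dtype=float)
    if copies.shape != cq.shape:
        raise ValueError("copies and cq must have the same length")
    if np.any(copies <= 0):
        raise ValueError("copy numbers must be positive")
    levels = np.unique(copies)
    if levels.size < 3:
        raise ValueError("need at least 3 distinct dilution levels")
    # average technical replicates per level
    mean_cq = np.array([cq[copies == lv].mean() for lv in levels])
    x = np.log10(levels)
    res = stats.linregress(x, mean_cq)
    if res.slope >= 0:
        raise ValueError("fitted slope is nonnegative: inverted standard curve")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=float(efficiency_from_slope(res.slope)),
        cq_min=float(mean_cq.min()),
        cq_max=float(mean_cq.max()),
    )


def quantify(cq, curve: StandardCurve):
    """Convert Cq value(s) to absolute copy numbers via the standard curve.

    copies = 10 ** ((cq - intercept) / slope).  Values outside the calibrated
    Cq range are still converted but a warning flags the extrapolation.
    """
    cq_arr = np.asarray(cq, dtype=float)
    outside = (cq_arr < curve.cq_min - 1e-9) | (cq_arr > curve.cq_max + 1e-9)
    if np.any(outside):
        warnings.warn(
            f"{int(np.count_nonzero(outside))} Cq value(s) outside the "
            f"calibrated range [{curve.cq_min:.2f}, {curve.cq_max:.2f}]; "
            "extrapolating",
            stacklevel=2,
        )
    copies = 10.0 ** ((cq_arr - curve.intercept) / curve.slope)
    if np.isscalar(cq) or cq_arr.ndim == 0:
        return float(copies)
    return copies


@dataclass
class CompartmentCounts:
    """Absolute cell numbers per chamber compartment."""

    d_planktonic: float  # cells/uL in effluent
    v_chip: float  # uL
    c_planktonic: float
    c_biofilm: float
    c_entire: float
    clamped: bool = False
    raw_biofilm: float | None = None  # pre-clamp difference when clamped


def partition_cells(
    d_planktonic: float,
    c_entire: float,
    v_chip: float = DEFAULT_CHAMBER_VOLUME_UL,
) -> CompartmentCounts:
    """Split the chamber population into planktonic and biofilm compartments.

    A negative biofilm estimate (total below the planktonic fraction, which
    can happen under measurement noise) is clamped to zero; the raw value is
    retained and a warning emitted.
    """
    if d_planktonic < 0 or c_entire < 0 or v_chip < 0:
        raise ValueError("inputs must be nonnegative")
    c_plank = d_planktonic * v_chip
    raw = c_entire - c_plank
    if raw < 0:
        warnings.warn(
            f"negative biofilm estimate ({raw:.4g}) clamped to 0", stacklevel=2
        )
        return CompartmentCounts(d_planktonic, v_chip, c_plank, 0.0, c_entire,
                                 clamped=True, raw_biofilm=raw)
    return CompartmentCounts(d_planktonic, v_chip, c_plank, raw, c_entire)


@dataclass
class LogisticFit:
    k: float | None  # carrying capacity
    r: float | None  # growth rate (per time unit)
    t_mid: float | None  # inflection time
    fitted: np.ndarray | None
    rmse: float | None
    converged: bool
    flag: str | None = None


def _logistic(t, k, r, t_mid):
    return k / (1.0 + np.exp(-r * (t - t_mid)))


def fit_logistic(t, counts) -> LogisticFit:
    """Least-squares logistic fit K / (1 + exp(-r (t - t_mid))).

    Initialized from the data (K0 = max count, t_mid0 = time of half
    maximum).  Non-convergence is flagged with null parameters; a negative
    fitted rate or a near-flat profile is flagged but returned.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(counts, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    if np.any(y <= 0):
        raise ValueError("counts must be positive")

    k0 = y.max()
    if np.ptp(y) <= 1e-9 * k0:
        # constant profile: logistic parameters are unidentifiable
        return LogisticFit(float(y.mean()), 0.0, float(t.mean()),
                           np.full_like(y, y.mean()), 0.0, converged=True,
                           flag="degenerate-flat")
    half = np.argmin(np.abs(y - k0 / 2.0))
    span = t[-1] - t[0]
    p0 = (k0, 4.0 / max(span, 1e-9), float(t[half]))
    try:
        popt, _ = optimize.curve_fit(
            _logistic, t, y, p0=p0, maxfev=20000,
            bounds=([1e-12, -np.inf, t[0] - 2 * span],
                    [10 * k0 + 1e-12, np.inf, t[-1] + 2 * span]),
        )
    except (RuntimeError, ValueError):
        return LogisticFit(None, None, None, None, None, converged=False,
                           flag="non-convergence")
    fitted = _logistic(t, *popt)
    rmse = float(np.sqrt(np.mean((fitted - y) ** 2)))
    flag = None
    if popt[1] < 0:
        flag = "negative-rate"
    elif abs(popt[1]) * span < 1e-3:
        flag = "degenerate-flat"
    return LogisticFit(float(popt[0]), float(popt[1]), float(popt[2]),
                       fitted, rmse, converged=True, flag=flag)
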