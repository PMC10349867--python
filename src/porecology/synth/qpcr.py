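"""qPCR standard-curve data generator.

Cq values follow the calibration line Cq = intercept + slope * log10(copies)
with slope = -1 / log10(1 + efficiency), plus optional Gaussian Cq noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["make_qpcr", "slope_from_efficiency"]


def slope_from_efficiency(efficiency: float) -> float:
    return -1.0 / np.log10(1.0 + efficiency)


def make_qpcr(
    efficiency: float,
    intercept: float,
    dilution_levels=None,
    *,
    reps: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Generate a dilution-series Cq table plus its ground truth.

    Parameters
    ----------
    efficiency : amplification efficiency as a fraction in (0.5, 1.5]
        (1.0 = perfect doubling).
    intercept : Cq at a single template copy.
    dilution_levels : template copy numbers; defaults to a 10-fold series
        from 1e7 down over 5 levels.  At least 3 levels required.
    """
    if not 0.5 < efficiency <= 1.5:
        raise ValueError("efficiency must be in (0.5, 1.5]")
    if dilution_levels is None:
        dilution_levels = [10.0 ** k for k in range(7, 2, -1)]
    levels = np.asarray(dilution_levels, dtype=float)
    if np.unique(levels).size < 3:
        raise ValueError("need at least 3 distinct dilution levels")
    if (levels <= 0).any():
        raise ValueError("copy numbers must be positive")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    slope = slope_from_efficiency(efficiency)
    rows = []
    for copies in levels:
        clean = intercept + slope * np.log10(copies)
        for r in range(reps):
            cq = clean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"copies": copies, "replicate": r, "cq": cq})
    truth = {"efficiency": float(efficiency), "slope": float(slope),
             "intercept": float(intercept)}
    return pd.DataFrame(rows), truth
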