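"""Metabolite trajectory generator with planted trend classes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from porecology.metabolome import CONSUMED, OTHER, RELEASED

__all__ = ["TrendSpec", "make_metabolite_series"]

SHAPES = ("monotone_up", "monotone_down", "v_shaped", "flat")


def _shape_values(shape: str, n: int) -> np.ndarray:
    if shape == "monotone_up":
        return np.linspace(1.0, 2.0, n)
    if shape == "monotone_down":
        return np.linspace(2.0, 1.0, n)
    if shape == "v_shaped":
        # symmetric V around the middle time point
        mid = (n - 1) / 2.0
        return 1.0 + np.abs(np.arange(n) - mid) / mid
    if shape == "flat":
        return np.full(n, 1.5)
    raise ValueError(f"unknown shape {shape!r}")


def _label_for(values: np.ndarray, times: np.ndarray) -> str:
    """Spearman rule applied to the noiseless values."""
    if np.ptp(values) == 0:
        return OTHER
    rho, _ = stats.spearmanr(times, values)
    if rho > 0.5:
        return RELEASED
    if rho < -0.5:
        return CONSUMED
    return OTHER


@dataclass
class TrendSpec:
    shape: str
    n_timepoints: int = 7
    noise_sd: float = 0.0
    seed: int = 0
    class_label: str | None = None  # derived from shape when omitted

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.n_timepoints < 4:
            raise ValueError("n_timepoints must be >= 4")
        times = np.arange(self.n_timepoints, dtype=float)
        derived = _label_for(_shape_values(self.shape, self.n_timepoints),
                             times)
        if self.class_label is None:
            self.class_label = derived
        elif self.class_label != derived:
            raise ValueError(
                f"class_label {self.class_label!r} inconsistent with the "
                f"Spearman rule for shape {self.shape!r} ({derived!r})"
            )


def make_metabolite_series(
    specs: list[TrendSpec],
    *,
    time_span_h: float = 96.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render metabolite trajectories for a list of trend specs.

    Returns a tidy peak-area table (``metabolite``, ``time_h``, ``value``)
    and a label table (``metabolite``, ``class``, ``shape``); labels are the
    Spearman-rule classes of the noiseless trajectories.
    """
    peaks = []
    labels = []
    for i, spec in enumerate(specs):
        rng = np.random.default_rng(spec.seed)
        times = np.linspace(0.0, time_span_h, spec.n_timepoints)
        clean = _shape_values(spec.shape, spec.n_timepoints)
        noisy = clean + (rng.normal(0.0, spec.noise_sd, clean.shape)
                         if spec.noise_sd > 0 else 0.0)
        name = f"m{i:03d}_{spec.shape}"
        for t, v in zip(times, noisy):
            peaks.append({"metabolite": name, "time_h": t, "value": v})
        labels.append({"metabolite": name, "class": spec.class_label,
                       "shape": spec.shape})
    return pd.DataFrame(peaks), pd.DataFrame(labels)
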