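"""Co-culture yield table generator with planted interaction classes."""

from __future__ import annotations

import numpy as np
import pandas as pd

from porecology.interactions import (
    POSITIVE,
    STRONG_NEGATIVE,
    WEAK_NEGATIVE,
    CocultureYields,
    classify_coculture,
)

__all__ = ["make_coculture_table"]

_CLASSES = (POSITIVE, WEAK_NEGATIVE, STRONG_NEGATIVE)


def make_coculture_table(
    n_pairs: int,
    class_mix: dict[str, float] | None = None,
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate mono-/co-culture yields with known interaction classes.

    Monoculture yields are uniform on [0.2, 1.0]; the co-culture yield is
    placed strictly inside the planted class region (clear of its
    boundaries), and the planted label is the classification of the
    noiseless yields.  Gaussian noise (clipped at zero) is then applied to
    all reported yields.  `class_mix` proportions must sum to 1.
    """
    if class_mix is None:
        class_mix = {c: 1.0 / 3.0 for c in _CLASSES}
    unknown = set(class_mix) - set(_CLASSES)
    if unknown:
        raise ValueError(f"unknown classes in mix: {sorted(unknown)}")
    probs = np.array([class_mix.get(c, 0.0) for c in _CLASSES], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    rng = np.random.default_rng(seed)
    planted = rng.choice(len(_CLASSES), size=n_pairs, p=probs)
    rows = []
    for i in range(n_pairs):
        y_a, y_b = rng.uniform(0.2, 1.0, size=2)
        y_min, y_sum = min(y_a, y_b), y_a + y_b
        cls = _CLASSES[planted[i]]
        if cls == POSITIVE:
            y_co = y_sum * rng.uniform(1.2, 1.8)
        elif cls == STRONG_NEGATIVE:
            y_co = y_min * rng.uniform(0.1, 0.7)
        else:  # weak_negative: strictly between the boundaries
            y_co = y_min + (y_sum - y_min) * rng.uniform(0.15, 0.85)
        assert classify_coculture(
            CocultureYields(y_a, y_b, y_co)).label == cls
        rows.append({
            "pair_id": f"p{i:03d}",
            "strain_a": f"A{i:03d}",
            "strain_b": f"B{i:03d}",
            "y_a": max(0.0, y_a + rng.normal(0, noise_sd)) if noise_sd else y_a,
            "y_b": max(0.0, y_b + rng.normal(0, noise_sd)) if noise_sd else y_b,
            "y_co": (max(0.0, y_co + rng.normal(0, noise_sd))
                     if noise_sd else y_co),
            "planted_class": cls,
        })
    return pd.DataFrame(rows)
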