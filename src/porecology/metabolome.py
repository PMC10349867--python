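"""Exometabolite trend classification, correlation screening and concordance.

Trends are classified from the Spearman rank correlation between each
metabolite's (z-scored) trajectory and incubation time: rho > 0.5 is
"released", rho < -0.5 is "consumed", everything else (including the exactly
symmetric V-shaped profile, rho = 0) is "other".
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import procrustes as _procrustes

__all__ = [
    "TrendCall",
    "ProcrustesResult",
    "zscore",
    "classify_trend",
    "classify_trend_table",
    "feature_correlations",
    "concordance",
    "pcoa",
    "RELEASED",
    "CONSUMED",
    "OTHER",
]

RELEASED = "released"
CONSUMED = "consumed"
OTHER = "other"


def zscore(values) -> tuple[np.ndarray, bool]:
    """Standardize to mean 0, population SD 1.

    Returns ``(z, degenerate)``; a constant series maps to all zeros with
    the degenerate flag set.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = v.std()  # population SD
    if sd == 0:
        return np.zeros_like(v), True
    return (v - v.mean()) / sd, False


@dataclass(frozen=True)
class TrendCall:
    label: str
    rho: float | None
    pvalue: float | None = None
    flag: str | None = None


def classify_trend(values, times, *, threshold: float = 0.5) -> TrendCall:
    """Classify a metabolite trajectory by rank correlation with time.

    Average-rank tie handling; a constant series has undefined rho and is
    classified "other" with a flag.  Requires >= 4 time points.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if v.size != t.size:
        raise ValueError("values and times must have the same length")
    if v.size < 4:
        raise ValueError("need at least 4 time points")
    if np.ptp(v) == 0:
        return TrendCall(label=OTHER, rho=None, flag="constant-series")
    rho, p = stats.spearmanr(t, v)
    rho = float(rho)
    if rho > threshold:
        label = RELEASED
    elif rho < -threshold:
        label = CONSUMED
    else:
        label = OTHER
    return TrendCall(label=label, rho=rho, pvalue=float(p))


def classify_trend_table(
    peaks: pd.DataFrame, *, threshold: float = 0.5
) -> pd.DataFrame:
    """Classify every metabolite in a tidy table.

    `peaks` columns: ``metabolite``, ``time_h``, ``value``.  Values are
    z-scored per metabolite before classification (the rank correlation is
    unaffected, but z-scores are reported for plotting parity).
    """
    rows = []
    for met, grp in peaks.groupby("metabolite", sort=True):
        grp = grp.sort_values("time_h")
        call = classify_trend(grp["value"].to_numpy(), grp["time_h"].to_numpy())
        rows.append({"metabolite": met, "class": call.label, "rho": call.rho,
                     "flag": call.flag})
    return pd.DataFrame(rows)


@lru_cache(maxsize=8)
def _exact_spearman_null(n: int) -> np.ndarray:
    """All n! Spearman rho values for tie-free rankings (small n only)."""
    base = np.arange(n, dtype=float)
    perms = np.array(list(permutations(range(n))), dtype=float)
    num = ((perms - base.mean()) * (base - base.mean())).sum(axis=1)
    den = n * base.var()
    return num / den


def _spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with an exact two-sided p for small tie-free samples."""
    rho, p = stats.spearmanr(x, y)
    n = x.size
    tie_free = (np.unique(x).size == n) and (np.unique(y).size == n)
    if tie_free and n <= 8:
        null = _exact_spearman_null(n)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    return float(rho), float(p)


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def feature_correlations(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    *,
    r_min: float = 0.5,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Screen all cross-table Spearman correlations.

    Both inputs are feature x sample tables; correlations are computed over
    the shared sample columns (>= 5 required).  Rows are retained iff
    |r| >= `r_min` and p <= `alpha`, with significance stars at
    0.05 / 0.01 / 0.001.  Optional Benjamini-Hochberg adjustment of p before
    filtering (off by default).
    """
    shared = [s for s in features_a.columns if s in set(features_b.columns)]
    if len(shared) < 5:
        raise ValueError(
            f"need >= 5 shared samples, got {len(shared)}"
        )
    a = features_a[shared]
    b = features_b[shared]
    rows = []
    for fa, va in a.iterrows():
        xa = va.to_numpy(dtype=float)
        for fb, vb in b.iterrows():
            r, p = _spearman_with_p(xa, vb.to_numpy(dtype=float))
            rows.append({"feature_a": fa, "feature_b": fb, "r": r, "p": p})
    table = pd.DataFrame(rows)
    if fdr and len(table):
        table["p"] = _benjamini_hochberg(table["p"].to_numpy())
    table["stars"] = table["p"].map(_stars)
    keep = (table["r"].abs() >= r_min) & (table["p"] <= alpha)
    return table[keep].reset_index(drop=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


@dataclass(frozen=True)
class ProcrustesResult:
    correlation: float  # sqrt(1 - m2)
    m2: float  # standardized residual sum of squares
    pvalue: float
    n_permutations: int
    flag: str | None = None


def concordance(
    coords_a, coords_b, *, n_perm: int = 999, seed: int = 0
) -> ProcrustesResult:
    """Procrustes concordance between two sample ordinations.

    Least-squares superimposition (translation, uniform scaling, rotation);
    the correlation is sqrt(1 - m2).  Significance is a permutation test on
    sample labels of the second configuration, deterministic given `seed`;
    p = (1 + #{m2_perm <= m2_obs}) / (n_perm + 1).
    """
    xa = np.asarray(coords_a, dtype=float)
    xb = np.asarray(coords_b, dtype=float)
    if xa.ndim == 1:
        xa = xa[:, None]
    if xb.ndim == 1:
        xb = xb[:, None]
    if xa.shape[0] != xb.shape[0]:
        raise ValueError("configurations must share samples")
    if xa.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    flag = None
    for x in (xa, xb):
        if np.linalg.norm(x - x.mean(axis=0)) == 0:
            raise ValueError("degenerate configuration (all points coincide)")
        if np.linalg.matrix_rank(x - x.mean(axis=0)) < min(x.shape[1],
                                                           x.shape[0] - 1):
            flag = "rank-deficient"
    # pad to common dimensionality for the superimposition
    dim = max(xa.shape[1], xb.shape[1])
    xa = np.pad(xa, ((0, 0), (0, dim - xa.shape[1])))
    xb = np.pad(xb, ((0, 0), (0, dim - xb.shape[1])))
    _, _, m2 = _procrustes(xa, xb)
    rng = np.random.default_rng(seed)
    n = xa.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, _, m2p = _procrustes(xa, xb[perm])
        if m2p <= m2 + 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    corr = float(np.sqrt(max(0.0, 1.0 - m2)))
    return ProcrustesResult(correlation=corr, m2=float(m2), pvalue=float(p),
                            n_permutations=n_perm, flag=flag)


def pcoa(dissimilarity: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical metric MDS of a square dissimilarity matrix.

    Used to turn Bray-Curtis matrices into sample coordinates for the
    concordance test; negative eigenvalues are truncated at zero.
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("dissimilarity must be square")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_components]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)
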