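"""Phylogenetic-bin null-model inference of community assembly processes.

Taxa are partitioned into phylogenetic bins (single-linkage agglomeration on
the cophenetic distance with a cutoff, small bins merged into their nearest
neighbor).  For every sample pair and bin, the abundance-weighted between-
community mean pairwise phylogenetic distance (betaMPD) is standardized
against a "taxa shuffle" null (tip labels permuted within the bin):

    betaNRI = (obs - mean_null) / sd_null

Pairs with |betaNRI| <= 1.96 fall through to the modified Raup-Crick metric
(null-standardized Bray-Curtis scaled to [-1, 1]).  The per-bin process
labels — homogeneous selection (HoS), heterogeneous selection (HeS),
homogenizing dispersal (HD), dispersal limitation (DL) and drift (DR) — are
aggregated weighted by bin relative abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, permutations
from math import factorial

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import braycurtis, squareform

__all__ = [
    "CommunitySeries",
    "PhyloBin",
    "PROCESSES",
    "cophenetic_matrix",
    "bin_taxa",
    "beta_mpd",
    "beta_nri",
    "rc_metric",
    "assign_process",
    "score_pairs",
    "aggregate_processes",
    "succession_trend",
]

#: Assembly process labels, in reporting order.
PROCESSES = ("HoS", "HeS", "HD", "DL", "DR")

#: Default analysis parameters (phylogenetic distance cutoff, minimum bin
#: size, randomizations, score thresholds, one-sided confidence level).
DEFAULTS = {
    "d_max": 0.2,
    "min_bin_size": 12,
    "n_null": 1000,
    "bnri_threshold": 1.96,
    "rc_threshold": 0.95,
    "confidence": 0.975,
}


@dataclass
class CommunitySeries:
    """ASV x sample abundance matrix with sample times and a phylogeny."""

    abundance: pd.DataFrame  # taxa (index) x samples (columns), counts
    sample_time: np.ndarray  # hours, aligned with columns
    tree: dendropy.Tree
    replicate: np.ndarray | None = None  # replicate id per sample

    def __post_init__(self):
        self.sample_time = np.asarray(self.sample_time, dtype=float)
        if self.sample_time.size != self.abundance.shape[1]:
            raise ValueError("sample_time must align with abundance columns")
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("abundances must be nonnegative")
        tips = {t.label for t in self.tree.taxon_namespace}
        missing = set(self.abundance.index) - tips
        if missing:
            raise ValueError(
                f"{len(missing)} abundance rows have no tree tip, e.g. "
                f"{sorted(missing)[:3]}"
            )

    @property
    def taxa(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)


@dataclass(frozen=True)
class PhyloBin:
    bin_id: int
    taxa: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.taxa)


def cophenetic_matrix(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Pairwise patristic (cophenetic) distances among the named tips."""
    pdm = tree.phylogenetic_distance_matrix()
    by_label = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.distance(by_label[taxa[i]], by_label[taxa[j]])
    return d


def bin_taxa(
    tree: dendropy.Tree,
    taxa: list[str],
    *,
    d_max: float = DEFAULTS["d_max"],
    min_bin_size: int = DEFAULTS["min_bin_size"],
    dist: np.ndarray | None = None,
) -> list[PhyloBin]:
    """Partition taxa into phylogenetic bins.

    Single-linkage agglomeration on the cophenetic distance at cutoff
    `d_max`, then bins smaller than `min_bin_size` are merged (smallest
    first, ties by smaller bin id) into the bin holding their phylogenetically
    nearest taxon.  Fewer taxa than `min_bin_size` yields a single bin with
    a warning.
    """
    if dist is None:
        dist = cophenetic_matrix(tree, taxa)
    n = len(taxa)
    if n < min_bin_size:
        warnings.warn(
            f"only {n} taxa (< min_bin_size={min_bin_size}): single bin",
            stacklevel=2,
        )
        return [PhyloBin(0, tuple(taxa))]
    if n == 1:
        return [PhyloBin(0, tuple(taxa))]
    link = hierarchy.linkage(squareform(dist, checks=False), method="single")
    labels = hierarchy.fcluster(link, t=d_max, criterion="distance")
    groups: list[list[int]] = [
        [i for i in range(n) if labels[i] == lab]
        for lab in sorted(set(labels), key=lambda c: min(
            i for i in range(n) if labels[i] == c))
    ]

    def inter(a: list[int], b: list[int]) -> float:
        return dist[np.ix_(a, b)].min()

    while len(groups) > 1:
        sizes = [len(g) for g in groups]
        small = [k for k, s in enumerate(sizes) if s < min_bin_size]
        if not small:
            break
        k = min(small, key=lambda k: (sizes[k], k))
        others = [j for j in range(len(groups)) if j != k]
        target = min(others, key=lambda j: (inter(groups[k], groups[j]), j))
        groups[target] = sorted(groups[target] + groups[k])
        del groups[k]
    groups.sort(key=min)
    return [PhyloBin(b, tuple(taxa[i] for i in g))
            for b, g in enumerate(groups)]


def beta_mpd(f: np.ndarray, g: np.ndarray, dist: np.ndarray,
             weighted: bool = True) -> float:
    """Between-community mean pairwise phylogenetic distance.

    Abundance-weighted by default: sum_ij p_i q_j d_ij with p, q the
    within-bin relative abundances of the two samples; the unweighted
    variant averages over taxa present in each sample.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if weighted:
        p = f / f.sum()
        q = g / g.sum()
    else:
        p = (f > 0) / max((f > 0).sum(), 1)
        q = (g > 0) / max((g > 0).sum(), 1)
    return float(p @ dist @ q)


def _null_permutations(n_taxa: int, n_null: int, rng: np.random.Generator,
                       exhaustive: bool) -> np.ndarray:
    if exhaustive:
        if factorial(n_taxa) > 50000:
            raise ValueError("exhaustive mode is limited to small bins")
        return np.array(list(permutations(range(n_taxa))), dtype=np.intp)
    return np.argsort(rng.random((n_null, n_taxa)), axis=1)


def beta_nri(
    f: np.ndarray,
    g: np.ndarray,
    dist: np.ndarray,
    *,
    n_null: int = DEFAULTS["n_null"],
    seed: int | np.random.Generator = 0,
    weighted: bool = True,
    exhaustive: bool = False,
) -> tuple[float, str | None]:
    """Standardized betaMPD against the within-bin taxa-shuffle null.

    The null permutes tip identities within the bin (a single permutation
    applied to both communities, as the shuffle acts on the tree); with
    ``exhaustive=True`` all permutations are enumerated instead of sampled.
    Returns ``(score, flag)``; a zero null SD yields ``(nan, "zero-null-sd")``.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if (f > 0).sum() < 2 or (g > 0).sum() < 2:
        return np.nan, "insufficient-taxa"
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    obs = beta_mpd(f, g, dist, weighted=weighted)
    perms = _null_permutations(f.size, n_null, rng, exhaustive)
    if weighted:
        p = f / f.sum()
        q = g / g.sum()
    else:
        p = (f > 0) / max((f > 0).sum(), 1)
        q = (g > 0) / max((g > 0).sum(), 1)
    # permuting tip labels by pi is equivalent to permuting both abundance
    # vectors by pi^-1; uniform either way
    null = np.einsum("ni,ij,nj->n", p[perms], dist, q[perms])
    sd = null.std()
    if sd == 0:
        return np.nan, "zero-null-sd"
    return float((obs - null.mean()) / sd), None


def _pool_null_community(sample: np.ndarray, pool_p: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw one null community: fixed richness and total, pool-weighted.

    The observed richness is preserved by choosing that many taxa without
    replacement with probability proportional to the pair's pooled
    abundance; each chosen taxon gets one individual and the remaining
    total is assigned multinomially with the same weights.
    """
    richness = int(np.count_nonzero(sample))
    total = int(round(sample.sum()))
    chosen = rng.choice(pool_p.size, size=richness, replace=False, p=pool_p)
    out = np.zeros_like(pool_p)
    p = pool_p[chosen]
    out[chosen] = 1.0 + rng.multinomial(total - richness, p / p.sum())
    return out


def rc_metric(
    f: np.ndarray,
    g: np.ndarray,
    *,
    n_null: int = DEFAULTS["n_null"],
    seed: int | np.random.Generator = 0,
    null: str = "pool",
    exhaustive: bool = False,
) -> tuple[float, str | None]:
    """Modified Raup-Crick metric on within-bin Bray-Curtis dissimilarity.

    RC = 2 [P(null < obs) + 0.5 P(null = obs)] - 1, in [-1, 1].  Two null
    dialects are available:

    ``"pool"`` (default)
        Each null community is re-assembled from the pair's pooled
        abundances with observed richness and total preserved
        (probabilistic abundance assignment); calibrated so that two draws
        from a shared pool score near 0.
    ``"shuffle"``
        Taxon identities are permuted within the bin independently for each
        sample (abundance multisets preserved).  Exhaustive enumeration is
        available for this dialect: because Bray-Curtis is invariant under
        a joint relabeling, it fixes one sample and enumerates permutations
        of the other.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.sum() == 0 or g.sum() == 0:
        return np.nan, "empty-sample"
    if null not in ("pool", "shuffle"):
        raise ValueError(f"unknown null dialect {null!r}")
    if exhaustive and null != "shuffle":
        raise ValueError("exhaustive mode requires the shuffle null")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    obs = braycurtis(f, g)
    denom = f.sum() + g.sum()
    if null == "shuffle":
        if exhaustive:
            perms = _null_permutations(g.size, 0, rng, True)
            null_d = np.abs(f[None, :] - g[perms]).sum(axis=1) / denom
        else:
            pf = _null_permutations(f.size, n_null, rng, False)
            pg = _null_permutations(g.size, n_null, rng, False)
            null_d = np.abs(f[pf] - g[pg]).sum(axis=1) / denom
    else:
        pool = f + g
        pool_p = pool / pool.sum()
        null_d = np.empty(n_null)
        for i in range(n_null):
            a = _pool_null_community(f, pool_p, rng)
            b = _pool_null_community(g, pool_p, rng)
            null_d[i] = braycurtis(a, b)
    return _rc_score(obs, null_d)


def _rc_score(obs: float, null_d: np.ndarray,
              tol: float = 1e-12) -> tuple[float, str | None]:
    """Counting definition: RC = 2 [P(null < obs) + 0.5 P(null = obs)] - 1."""
    below = (null_d < obs - tol).mean()
    equal = (np.abs(null_d - obs) <= tol).mean()
    if equal == 1.0:
        return 0.0, "degenerate-null"
    rc = 2.0 * (below + 0.5 * equal) - 1.0
    return float(np.clip(rc, -1.0, 1.0)), None


def assign_process(
    bnri: float,
    rc: float | None,
    *,
    bnri_threshold: float = DEFAULTS["bnri_threshold"],
    rc_threshold: float = DEFAULTS["rc_threshold"],
) -> tuple[str, str | None]:
    """Map (betaNRI, RC) scores to an assembly process label.

    HoS if betaNRI < -1.96; HeS if betaNRI > 1.96; otherwise HD if
    RC < -0.95, DL if RC > 0.95, DR if |RC| <= 0.95.  An undefined betaNRI
    falls through to the RC rule with a flag.
    """
    flag = None
    if bnri is None or np.isnan(bnri):
        flag = "undefined-bnri"
    elif bnri < -bnri_threshold:
        return "HoS", None
    elif bnri > bnri_threshold:
        return "HeS", None
    if rc is None or np.isnan(rc):
        raise ValueError("RC required when |betaNRI| <= threshold")
    if rc < -rc_threshold:
        return "HD", flag
    if rc > rc_threshold:
        return "DL", flag
    return "DR", flag


def score_pairs(
    series: CommunitySeries,
    *,
    bins: list[PhyloBin] | None = None,
    pairs: list[tuple[str, str]] | None = None,
    n_null: int = DEFAULTS["n_null"],
    seed: int = 0,
    d_max: float = DEFAULTS["d_max"],
    min_bin_size: int = DEFAULTS["min_bin_size"],
    weighted: bool = True,
    rc_null: str = "pool",
) -> pd.DataFrame:
    """betaNRI / RC / process label for every (sample pair, bin).

    RC is only computed when the betaNRI rule does not decide the pair
    (|betaNRI| <= threshold or undefined).  The per-row weight is the mean
    relative abundance of the bin across the two samples.  Deterministic
    given `seed` (one spawned substream per pair and bin).
    """
    taxa = series.taxa
    dist = cophenetic_matrix(series.tree, taxa)
    if bins is None:
        bins = bin_taxa(series.tree, taxa, d_max=d_max,
                        min_bin_size=min_bin_size, dist=dist)
    if pairs is None:
        pairs = list(combinations(series.samples, 2))
    idx = {t: i for i, t in enumerate(taxa)}
    counts = series.abundance.to_numpy(dtype=float)
    col = {s: j for j, s in enumerate(series.samples)}
    totals = counts.sum(axis=0)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(pairs) * len(bins))
    rows = []
    k = 0
    for si, sj in pairs:
        a = counts[:, col[si]]
        b = counts[:, col[sj]]
        for pb in bins:
            rng = np.random.default_rng(children[k])
            k += 1
            members = np.array([idx[t] for t in pb.taxa])
            f = a[members]
            g = b[members]
            dsub = dist[np.ix_(members, members)]
            weight = 0.5 * (f.sum() / totals[col[si]]
                            + g.sum() / totals[col[sj]])
            bnri, flag = beta_nri(f, g, dsub, n_null=n_null, seed=rng,
                                  weighted=weighted)
            rc = np.nan
            if flag == "insufficient-taxa":
                rows.append(dict(sample_i=si, sample_j=sj, bin_id=pb.bin_id,
                                 beta_nri=np.nan, rc=np.nan, process=None,
                                 weight=weight, flag=flag))
                continue
            if np.isnan(bnri) or abs(bnri) <= DEFAULTS["bnri_threshold"]:
                rc, rc_flag = rc_metric(f, g, n_null=n_null, seed=rng,
                                        null=rc_null)
                flag = flag or rc_flag
            process, pflag = assign_process(bnri, rc)
            rows.append(dict(sample_i=si, sample_j=sj, bin_id=pb.bin_id,
                             beta_nri=bnri, rc=rc, process=process,
                             weight=weight, flag=flag or pflag))
    return pd.DataFrame(rows)


def aggregate_processes(scores: pd.DataFrame) -> dict[str, float]:
    """Abundance-weighted relative importance of each assembly process.

    fraction(P) = sum of row weights with label P / total weight over rows
    with a label; fractions sum to 1.
    """
    labeled = scores[scores["process"].notna()]
    total = labeled["weight"].sum()
    if total <= 0:
        raise ValueError("zero total weight: nothing to aggregate")
    return {
        p: float(labeled.loc[labeled["process"] == p, "weight"].sum() / total)
        for p in PROCESSES
    }


def succession_trend(
    abundance: pd.DataFrame,
    sample_time: np.ndarray,
    replicate: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float, float, str | None]:
    """Bray-Curtis dissimilarity between adjacent time points vs time.

    Computed on relative abundances, per replicate when replicate ids are
    given.  Returns ``(interval table, pearson r, p, flag)``; with fewer
    than 3 intervals or a constant dissimilarity series the correlation is
    undefined and flagged.
    """
    t = np.asarray(sample_time, dtype=float)
    rel = abundance.to_numpy(dtype=float)
    sums = rel.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("empty sample in abundance table")
    rel = rel / sums
    rep = (np.zeros(t.size, dtype=int) if replicate is None
           else np.asarray(replicate))
    rows = []
    for r in np.unique(rep):
        sel = np.flatnonzero(rep == r)
        sel = sel[np.argsort(t[sel])]
        for a, b in zip(sel[:-1], sel[1:]):
            rows.append({
                "replicate": r,
                "time_from": t[a],
                "time_to": t[b],
                "bray_curtis": float(braycurtis(rel[:, a], rel[:, b])),
            })
    table = pd.DataFrame(rows)
    if len(table) < 3:
        return table, np.nan, np.nan, "too-few-intervals"
    bc = table["bray_curtis"].to_numpy()
    if np.ptp(bc) == 0 or np.ptp(table["time_to"].to_numpy()) == 0:
        return table, np.nan, np.nan, "constant-series"
    r_val, p_val = stats.pearsonr(table["time_to"], bc)
    return table, float(r_val), float(p_val), None
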