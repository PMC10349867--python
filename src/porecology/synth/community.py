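"""Community time-series generator under controlled assembly regimes.

A pure-birth (Yule) tree is simulated and scaled to a target depth; a
Brownian-motion trait with tunable phylogenetic signal evolves on it.
Samples are multinomial draws from a shared lognormal metacommunity whose
taxon identities are randomly permuted across the tree tips (so the neutral
regime is, by construction, exchangeable with a taxa-shuffle null).
Selection regimes bias the sampling weights by a perfectly conserved trait
— the (negated, standardized) cophenetic distance to an anchor tip — so
favored taxa always form a phylogenetic neighborhood: the same anchor for
every sample (homogeneous selection) or a different anchor per sample
(heterogeneous).  Dispersal limitation confines each sample to a disjoint
slice of the taxon pool.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from porecology.assembly import CommunitySeries

__all__ = ["AssemblyRegime", "make_community_series", "simulate_yule_tree",
           "brownian_trait"]

REGIMES = ("neutral", "homogeneous_selection", "heterogeneous_selection",
           "dispersal_limitation")


@dataclass
class AssemblyRegime:
    kind: str
    n_taxa: int = 50
    n_samples: int = 6
    tree_depth: float = 1.0
    trait_conservatism: float = 1.0  # Pagel-lambda-like in [0, 1]
    selection_strength: float = 0.0
    evenness_sigma: float = 1.0  # lognormal sigma of metacommunity abundances
    n_reads: int = 2000
    time_step: float = 12.0  # hours between samples
    seed: int = 0

    def __post_init__(self):
        if self.kind not in REGIMES:
            raise ValueError(f"unknown regime {self.kind!r}")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.kind == "neutral" and self.selection_strength != 0:
            raise ValueError("neutral regime requires selection_strength=0")
        if self.kind.endswith("selection") and self.selection_strength <= 0:
            raise ValueError(f"{self.kind} requires selection_strength>0")
        if not 0.0 <= self.trait_conservatism <= 1.0:
            raise ValueError("trait_conservatism must be in [0, 1]")


def simulate_yule_tree(n_taxa: int, depth: float, seed: int) -> dendropy.Tree:
    """Pure-birth tree with tips relabeled t0000.. and depth rescaled."""
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        rng=random.Random(seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i:04d}"
    tree.calc_node_root_distances()
    max_depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    if max_depth > 0:
        scale = depth / max_depth
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    return tree


def brownian_trait(tree: dendropy.Tree, conservatism: float,
                   rng: np.random.Generator) -> pd.Series:
    """Standardized tip trait: BM on the tree blended with iid noise.

    conservatism = 1 gives pure Brownian motion (full phylogenetic signal),
    0 gives iid values — a Pagel-lambda-like dial.
    """
    values: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        base = values[id(parent)] if parent is not None else 0.0
        step = np.sqrt(node.edge.length or 0.0)
        values[id(node)] = base + rng.normal(0.0, step) if step > 0 else base
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    bm = np.array([values[id(leaf)] for leaf in tree.leaf_node_iter()])
    iid = rng.normal(size=bm.size)

    def z(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    lam = conservatism
    trait = np.sqrt(lam) * z(bm) + np.sqrt(1.0 - lam) * z(iid)
    return pd.Series(z(trait), index=labels).sort_index()


def make_community_series(
    regime: AssemblyRegime,
) -> tuple[CommunitySeries, str]:
    """Simulate an ASV x sample table + tree under the requested regime."""
    rng = np.random.default_rng(regime.seed)
    tree = simulate_yule_tree(regime.n_taxa, regime.tree_depth,
                              seed=regime.seed)
    taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    n = len(taxa)

    # shared metacommunity, identities decoupled from the phylogeny
    meta = rng.lognormal(mean=0.0, sigma=regime.evenness_sigma, size=n)
    meta = meta[rng.permutation(n)]
    meta /= meta.sum()

    s = regime.selection_strength

    dist = None
    if regime.kind.endswith("selection"):
        from porecology.assembly import cophenetic_matrix

        dist = cophenetic_matrix(tree, taxa)

    def anchor_trait(anchor: int) -> np.ndarray:
        """Conserved trait: closeness to the anchor tip, noise-blended."""
        d = dist[anchor]
        closeness = -(d - d.mean()) / (d.std() or 1.0)
        lam = regime.trait_conservatism
        noise = rng.normal(size=n)
        return np.sqrt(lam) * closeness + np.sqrt(1 - lam) * noise

    counts = np.zeros((n, regime.n_samples), dtype=float)
    if regime.kind == "dispersal_limitation":
        pools = np.array_split(rng.permutation(n), regime.n_samples)
    elif regime.kind == "homogeneous_selection":
        trait = anchor_trait(int(rng.integers(n)))
    elif regime.kind == "heterogeneous_selection":
        anchors = rng.choice(n, size=regime.n_samples, replace=False)
        traits = [anchor_trait(int(a)) for a in anchors]
    for j in range(regime.n_samples):
        if regime.kind == "neutral":
            p = meta
        elif regime.kind == "homogeneous_selection":
            p = meta * np.exp(s * trait)
        elif regime.kind == "heterogeneous_selection":
            p = meta * np.exp(s * traits[j])
        else:  # dispersal_limitation
            p = np.zeros(n)
            p[pools[j]] = meta[pools[j]]
        p = p / p.sum()
        counts[:, j] = rng.multinomial(regime.n_reads, p)

    abundance = pd.DataFrame(
        counts, index=taxa,
        columns=[f"s{j:02d}" for j in range(regime.n_samples)],
    )
    times = np.arange(regime.n_samples) * regime.time_step
    series = CommunitySeries(abundance=abundance, sample_time=times,
                             tree=tree)
    return series, regime.kind
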