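import dendropy
import numpy as np
import pytest

from porecology import synth


@pytest.fixture
def sinusoid_scene():
    """One grain, thickness 10 + 4 sin(theta) um, no noise."""
    spec = synth.SceneSpec(
        image_size=(160, 160),
        grain_centers=[(80, 80)],
        thickness=lambda th: 10.0 + 4.0 * np.sin(th),
        grain_radius=25.0,
        seed=11,
    )
    return synth.make_grain_scene(spec)


@pytest.fixture
def uniform_scene():
    """One grain, uniform 10 um annulus, no noise."""
    spec = synth.SceneSpec(
        image_size=(160, 160),
        grain_centers=[(80, 80)],
        thickness=10.0,
        grain_radius=25.0,
        seed=3,
    )
    return synth.make_grain_scene(spec)


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture
def two_clade_tree():
    """Two 3-tip clades: within-clade distance 0.1, between-clade 0.5."""
    return tree_from_newick(
        "((a:0.05,b:0.05,c:0.05):0.2,(d:0.05,e:0.05,f:0.05):0.2);"
    )


@pytest.fixture
def star_tree():
    """Four tips, all pairwise distances 0.5."""
    return tree_from_newick("(a:0.25,b:0.25,c:0.25,d:0.25);")
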