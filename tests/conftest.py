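import pytest

from plclock import ResolvedConstraint, read_newick
from plclock.simulate import make_benchmark


@pytest.fixture
def basic_tree():
    """The three-taxon workhorse: ((A:1,B:1):1,C:2);"""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def toy():
    """An 8-tip synthetic benchmark with known truth (seed-pinned)."""
    return make_benchmark("toy", seed=11)


@pytest.fixture(scope="session")
def paperlike():
    """The 56-tip study-scale benchmark (seed-pinned)."""
    return make_benchmark("paperlike", seed=11)


def pin_root(tree, age, name="root pin"):
    """A degenerate calibration box fixing the root's age exactly."""
    return [ResolvedConstraint(node=tree.root, min_age=age, max_age=age, provenance=name)]


def strict_clock_phylogram(chronogram, rate):
    """Noiseless phylogram: every branch length set exactly to rate*duration."""
    from plclock import PhyloTree

    new = chronogram.copy()
    for node in new.preorder():
        if node.parent is not None:
            node.length *= rate
    return PhyloTree(new.root)
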