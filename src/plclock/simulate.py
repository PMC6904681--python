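"""Synthetic benchmarks with known divergence times.

The generator emulates the statistical structure the dating analysis
assumes, at the scale of a multi-genus diatom study with a shallow focal
clade of closely related strains:

* a Yule (pure-birth) chronogram rescaled to a chosen root age, with a
  younger focal crown clade grafted in place of one terminal (mimicking a
  densely sampled species inside a genus-level tree);
* branch rates drawn from k discrete categories with Markov inheritance
  along the tree (a child branch keeps its parent branch's category with
  probability 1 - switch_prob), giving the smoothing penalty something real
  to act on;
* Poisson substitution noise: observed branch lengths are
  x ~ Poisson(rate * duration * s) divided by the alignment length s;
* calibration boxes drawn around true node ages (always containing them);
* bootstrap-like perturbation: Poisson redraws of branch lengths plus
  random nearest-neighbour interchanges of internal edges.

No sequences are simulated; noise is injected at the branch-length level
where the dating likelihood operates.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from dendropy.simulate import treesim

from .calibrations import CalibrationPoint, write_calibration_table
from .trees import Node, PhyloTree, TreeSet, read_newick, write_tree_list


class SimulationError(ValueError):
    pass


def _subseed(seed: int, stream: str) -> int:
    """Deterministic 31-bit child seed for a named substream."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stream.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_chronogram(n_tips: int, root_age: float, seed: int) -> PhyloTree:
    """A Yule-process chronogram with the given number of tips and root age.

    Node times are rescaled so the root sits exactly at ``root_age`` and all
    tips at 0.  Deterministic for a fixed seed.
    """
    if n_tips < 2:
        raise SimulationError("n_tips must be >= 2")
    if not root_age > 0:
        raise SimulationError("root_age must be > 0")
    if n_tips == 2:
        return read_newick(f"(t1:{root_age:.10g},t2:{root_age:.10g});")
    rng = random.Random(seed)
    dtree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    tree = read_newick(dtree.as_string(schema="newick", suppress_rooting=True))
    # relabel deterministically and rescale to the requested root age
    for i, leaf in enumerate(tree.leaves(), start=1):
        leaf.label = f"t{i}"
    depths = tree.depths()
    tip_depth = max(depths[leaf] for leaf in tree.leaves())
    scale = root_age / tip_depth
    for node in tree.preorder():
        if node.parent is not None:
            node.length *= scale
    # force exact ultrametricity (birth_death_tree is already ultrametric up
    # to round-off; absorb the residual into terminal branches)
    depths = tree.depths()
    for leaf in tree.leaves():
        leaf.length = max(leaf.length + root_age - depths[leaf], 0.0)
    return PhyloTree(tree.root)


def graft_focal_clade(
    tree: PhyloTree,
    n_focal: int,
    crown_age: float,
    seed: int,
    prefix: str = "dg",
) -> tuple[PhyloTree, frozenset[str]]:
    """Replace one terminal with a shallow ``n_focal``-tip crown clade.

    The grafted clade's crown sits at ``crown_age`` My; its terminals are
    labelled ``<prefix>01..``; returns the new tree and the focal taxon set.
    """
    if crown_age >= tree.node_ages()[tree.root]:
        raise SimulationError("focal crown age must be below the root age")
    new = tree.copy()
    leaves = new.leaves()
    rng = random.Random(_subseed(seed, "graft-choice"))
    # the host terminal's branch must span down past the new crown age
    eligible = [l for l in leaves if l.length > 1.2 * crown_age]
    if eligible:
        host = eligible[rng.randrange(len(eligible))]
    else:
        host = max(leaves, key=lambda l: l.length)
    sub = simulate_chronogram(n_focal, crown_age, _subseed(seed, "graft-topology"))
    for i, leaf in enumerate(sub.leaves(), start=1):
        leaf.label = f"{prefix}{i:02d}"
    # host branch ran (parent age -> 0); now it runs (parent age -> crown_age)
    sub.root.length = host.length - crown_age
    if sub.root.length < 0:
        raise SimulationError(
            "focal crown age exceeds the replaced terminal's branch span"
        )
    parent = host.parent
    idx = parent.children.index(host)
    parent.children[idx] = sub.root
    sub.root.parent = parent
    out = PhyloTree(new.root)
    return out, frozenset(f"{prefix}{i:02d}" for i in range(1, n_focal + 1))


def assign_rates(
    tree: PhyloTree,
    k: int,
    rates,
    switch_prob: float,
    seed: int,
) -> dict[Node, tuple[int, float]]:
    """Markov-inherited discrete rate categories for every branch.

    The root's children draw categories uniformly; every other branch
    inherits its parent branch's category with probability ``1 -
    switch_prob`` and otherwise redraws uniformly over all k categories.
    Returns ``{node below branch: (category, rate)}``.
    """
    rates = [float(r) for r in rates]
    if len(rates) != k:
        raise SimulationError(f"expected {k} rates, got {len(rates)}")
    if any(r <= 0 for r in rates):
        raise SimulationError("rates must be > 0")
    if len(set(rates)) != len(rates):
        raise SimulationError("rates must be distinct")
    if not 0.0 <= switch_prob <= 1.0:
        raise SimulationError("switch_prob must be in [0, 1]")
    rng = np.random.default_rng(_subseed(seed, "rates"))
    out: dict[Node, tuple[int, float]] = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        if node.parent is tree.root:
            c = int(rng.integers(k))
        else:
            c_parent = out[node.parent][0]
            if rng.random() < switch_prob:
                c = int(rng.integers(k))
            else:
                c = c_parent
        out[node] = (c, rates[c])
    return out


def simulate_phylogram(
    tree: PhyloTree,
    branch_rates: dict[Node, tuple[int, float]],
    s: int,
    seed: int,
) -> PhyloTree:
    """Poisson substitution noise on a chronogram.

    For each branch of duration d with rate r, draws x ~ Poisson(r*d*s) and
    sets the phylogram branch length to x/s.  The returned tree is a copy
    (same preorder) of the input with transformed lengths.
    """
    if s < 1:
        raise SimulationError("alignment length s must be >= 1")
    rng = np.random.default_rng(_subseed(seed, "poisson"))
    new = tree.copy()
    for old, fresh in zip(tree.preorder(), new.preorder()):
        if old.parent is None:
            continue
        r = branch_rates[old][1]
        fresh.length = float(rng.poisson(r * old.length * s)) / s
    return PhyloTree(new.root)


def _eligible_nni_edges(tree: PhyloTree) -> list[Node]:
    """Internal non-root nodes whose parent has >= 2 children."""
    out = []
    for node in tree.preorder():
        if node.parent is not None and not node.is_leaf:
            if len(node.parent.children) >= 2 and len(node.children) >= 2:
                out.append(node)
    return out


def perturb_tree(
    tree: PhyloTree,
    n_replicates: int,
    nni_prob: float,
    seed: int,
    s: int = 3754,
    label: str = "perturbed",
) -> TreeSet:
    """Bootstrap-like replicates of a phylogram.

    Each replicate redraws every branch length by the Poisson mechanism
    (x ~ Poisson(b*s), b' = x/s) and applies, to each eligible internal
    edge independently with probability ``nni_prob``, a random
    nearest-neighbour interchange (a child of the edge's lower node swaps
    places with one of its siblings).  Deterministic for a fixed seed.
    """
    if n_replicates < 1:
        raise SimulationError("n_replicates must be >= 1")
    if not 0.0 <= nni_prob <= 1.0:
        raise SimulationError("nni_prob must be in [0, 1]")
    rng = np.random.default_rng(_subseed(seed, "perturb"))
    reps = []
    for _ in range(n_replicates):
        rep = tree.copy()
        for node in rep.preorder():
            if node.parent is not None:
                node.length = float(rng.poisson(node.length * s)) / s
        for node in _eligible_nni_edges(rep):
            if rng.random() < nni_prob:
                parent = node.parent
                siblings = [c for c in parent.children if c is not node]
                sib = siblings[int(rng.integers(len(siblings)))]
                child = node.children[int(rng.integers(len(node.children)))]
                # swap child <-> sib across the edge (lengths travel along)
                node.children[node.children.index(child)] = sib
                parent.children[parent.children.index(sib)] = child
                sib.parent = node
                child.parent = parent
        reps.append(PhyloTree(rep.root))
    return TreeSet(trees=reps, label=label, universe=frozenset(tree.leaf_labels()))


@dataclass
class SyntheticTruth:
    """Everything the generator knows about one benchmark instance."""

    profile: str
    seed: int
    chronogram: PhyloTree  # true node times (My)
    phylogram: PhyloTree  # Poisson-noised observed branch lengths
    branch_rates: dict[Node, tuple[int, float]]  # keyed by chronogram nodes
    k: int
    rate_values: tuple[float, ...]
    s: int
    focal_taxa: frozenset[str]
    calibrations: list[CalibrationPoint]
    bootstrap: TreeSet

    def true_ages_by_clade(self) -> dict[frozenset[str], float]:
        ages = self.chronogram.node_ages()
        return {
            self.chronogram.leafset(n): a
            for n, a in ages.items()
            if not n.is_leaf
        }

    @property
    def true_focal_crown_age(self) -> float:
        node = self.chronogram.mrca(self.focal_taxa)
        return self.chronogram.node_ages()[node]


PROFILES: dict[str, dict] = {
    # 8 tips: 5 background + 3 focal; small s keeps Poisson noise visible
    "toy": dict(
        n_background=6,
        n_focal=3,
        root_age=50.0,
        focal_crown_age=5.0,
        k=2,
        rate_values=(0.002, 0.008),
        switch_prob=0.2,
        s=1000,
        n_calibrations=4,
        n_bootstrap=10,
        nni_prob=0.15,
    ),
    # the study-scale preset: 56 tips incl. an 11-tip focal crown clade,
    # 8 calibrated nodes, alignment length 3754
    "paperlike": dict(
        n_background=46,
        n_focal=11,
        root_age=250.0,
        focal_crown_age=5.0,
        k=2,
        rate_values=(0.001, 0.004),
        switch_prob=0.2,
        s=3754,
        n_calibrations=8,
        n_bootstrap=100,
        nni_prob=0.1,
    ),
}


def _draw_calibrations(
    truth_tree: PhyloTree,
    focal_taxa: frozenset[str],
    n_calibrations: int,
    seed: int,
) -> list[CalibrationPoint]:
    """Calibration boxes around true ages; every box contains its true age.

    The root and the focal crown are always calibrated (two-sided); the
    remaining points are drawn among other internal nodes, one of them
    expressed in the stem convention to exercise both roles.
    """
    ages = truth_tree.node_ages()
    rng = np.random.default_rng(_subseed(seed, "calibrations"))
    focal_crown = truth_tree.mrca(focal_taxa)
    root_age = ages[truth_tree.root]
    internal = [
        n
        for n in truth_tree.preorder()
        if not n.is_leaf and n is not truth_tree.root and n is not focal_crown
        and n.parent is not None and ages[n] > 0.01 * root_age
    ]
    n_extra = max(0, n_calibrations - 2)
    extra_idx = rng.choice(len(internal), size=min(n_extra, len(internal)), replace=False)
    points: list[CalibrationPoint] = []

    def box(age: float) -> tuple[float, float]:
        lo = round(age * (1.0 - rng.uniform(0.15, 0.5)), 6)
        hi = round(age * (1.0 + rng.uniform(0.15, 0.5)), 6)
        return max(lo, 0.0), max(hi, lo + 1e-6)

    lo, hi = box(ages[truth_tree.root])
    points.append(
        CalibrationPoint(
            name="root crown",
            node_role="crown",
            clade_taxa=truth_tree.leafset(truth_tree.root),
            min_age=lo,
            max_age=hi,
            evidence="synthetic",
        )
    )
    lo, hi = box(ages[focal_crown])
    points.append(
        CalibrationPoint(
            name="focal crown",
            node_role="crown",
            clade_taxa=truth_tree.leafset(focal_crown),
            min_age=lo,
            max_age=hi,
            evidence="synthetic",
        )
    )
    for rank, idx in enumerate(sorted(int(i) for i in extra_idx)):
        node = internal[idx]
        lo, hi = box(ages[node])
        if rank == 0:
            # stem convention: constrain this node as the stem of one child clade
            child = node.children[0]
            points.append(
                CalibrationPoint(
                    name=f"stem point {rank + 1}",
                    node_role="stem",
                    clade_taxa=truth_tree.leafset(child),
                    min_age=lo,
                    max_age=hi,
                    evidence="synthetic",
                )
            )
        else:
            points.append(
                CalibrationPoint(
                    name=f"crown point {rank + 1}",
                    node_role="crown",
                    clade_taxa=truth_tree.leafset(node),
                    min_age=lo,
                    max_age=hi,
                    evidence="synthetic",
                )
            )
    # by-construction containment, asserted
    for p in points:
        node = truth_tree.mrca(p.clade_taxa)
        if p.node_role == "stem":
            node = node.parent
        a = ages[node]
        assert p.lo <= a <= p.hi, f"calibration box for {p.name!r} misses truth"
    return points


def make_benchmark(
    profile: str,
    seed: int,
    outdir: str | Path | None = None,
    n_bootstrap: int | None = None,
) -> SyntheticTruth:
    """Generate a named benchmark instance (and optionally write its files).

    Files written to ``outdir``: ``phylogram.nwk``, ``truth_chronogram.nwk``,
    ``calibrations.tsv``, ``focal_taxa.txt``, ``bootstrap.nwk``.
    """
    if profile not in PROFILES:
        raise SimulationError(
            f"unknown profile {profile!r}; available: {sorted(PROFILES)}"
        )
    p = PROFILES[profile]
    backbone = simulate_chronogram(
        p["n_background"], p["root_age"], _subseed(seed, "backbone")
    )
    chrono, focal = graft_focal_clade(
        backbone, p["n_focal"], p["focal_crown_age"], seed
    )
    branch_rates = assign_rates(
        chrono, p["k"], p["rate_values"], p["switch_prob"], seed
    )
    phylo = simulate_phylogram(chrono, branch_rates, p["s"], seed)
    calibrations = _draw_calibrations(chrono, focal, p["n_calibrations"], seed)
    nb = p["n_bootstrap"] if n_bootstrap is None else n_bootstrap
    bootstrap = perturb_tree(
        phylo, nb, p["nni_prob"], seed, s=p["s"], label=f"{profile}-bootstrap"
    )
    truth = SyntheticTruth(
        profile=profile,
        seed=seed,
        chronogram=chrono,
        phylogram=phylo,
        branch_rates=branch_rates,
        k=p["k"],
        rate_values=tuple(p["rate_values"]),
        s=p["s"],
        focal_taxa=focal,
        calibrations=calibrations,
        bootstrap=bootstrap,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "phylogram.nwk").write_text(phylo.to_newick() + "\n")
        (outdir / "truth_chronogram.nwk").write_text(chrono.to_newick() + "\n")
        write_calibration_table(calibrations, outdir / "calibrations.tsv")
        (outdir / "focal_taxa.txt").write_text("\n".join(sorted(focal)) + "\n")
        (outdir / "bootstrap.nwk").write_text(write_tree_list(bootstrap))
    return truth
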