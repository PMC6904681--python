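"""Rooted phylogenetic trees and the Newick plumbing every stage consumes.

Trees here come in two flavours distinguished only by the units of their
branch lengths: *phylograms* (expected substitutions per site, the raw output
of ML or parsimony inference) and *chronograms* (absolute time in My, so all
tips are equidistant from the root).  Both are plain rooted trees; bifurcating
and multifurcating topologies are handled transparently and no polytomy is
ever resolved arbitrarily.

Newick parsing is delegated to :mod:`dendropy`; the classes below are a thin,
mutation-friendly node structure that the dating optimizer can index into
flat arrays.
"""

from __future__ import annotations

import hashlib
import io
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import dendropy


class NewickParseError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicates, ...)."""


class TreeError(ValueError):
    """An operation was asked of a tree that cannot support it."""


# Relative tip-depth spread tolerated before a tree stops counting as
# ultrametric; floating-point age arithmetic never closes exactly.
ULTRAMETRIC_RTOL = 1e-6


class Node:
    """One vertex of a rooted tree.

    ``length`` is the length of the branch subtending this node (undefined on
    the root); ``label`` is the taxon name on terminals and an optional
    support/annotation string on internals.
    """

    __slots__ = ("label", "length", "parent", "children", "support")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} length={self.length:g}>"


class PhyloTree:
    """A rooted tree with named terminals and non-negative branch lengths.

    Invariants enforced on construction: exactly one root, unique non-empty
    terminal labels, and finite branch lengths ``>= 0``.  Zero-length branches
    are legal everywhere (bootstrap trees commonly contain them).
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # ------------------------------------------------------------------
    # construction / validation
    # ------------------------------------------------------------------
    def _validate(self) -> None:
        labels: list[str] = []
        for node in self.preorder():
            if node is not self.root:
                if node.parent is None:
                    raise TreeError("non-root node without a parent")
                if not (node.length >= 0.0) or node.length != node.length:
                    raise TreeError(
                        f"negative or non-finite branch length {node.length!r}"
                    )
                if node.length == float("inf"):
                    raise TreeError("infinite branch length")
            if node.is_leaf:
                if not node.label:
                    raise TreeError("terminal with empty label")
                labels.append(node.label)
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise TreeError(f"duplicate terminal labels: {sorted(dupes)}")

    # ------------------------------------------------------------------
    # traversal / basic queries
    # ------------------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]  # type: ignore[misc]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def leafset(self, node: Node) -> frozenset[str]:
        """Labels of all terminals descending from (or equal to) ``node``."""
        if node.is_leaf:
            return frozenset([node.label])  # type: ignore[list-item]
        out: set[str] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.add(n.label)  # type: ignore[arg-type]
            else:
                stack.extend(n.children)
        return frozenset(out)

    def find_leaf(self, label: str) -> Node:
        for n in self.preorder():
            if n.is_leaf and n.label == label:
                return n
        raise TreeError(f"terminal {label!r} not present in tree")

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.support = node.support
            for c in node.children:
                new.add_child(clone(c))
            return new

        return PhyloTree(clone(self.root))

    # ------------------------------------------------------------------
    # MRCA / monophyly
    # ------------------------------------------------------------------
    def mrca(self, taxa: Sequence[str] | set[str] | frozenset[str]) -> Node:
        """Deepest node ancestral to every taxon in ``taxa``.

        A single taxon maps to its own terminal; the full terminal set maps
        to the root.
        """
        taxa = frozenset(taxa)
        if not taxa:
            raise TreeError("mrca of an empty taxon set is undefined")
        present = frozenset(self.leaf_labels())
        unknown = taxa - present
        if unknown:
            raise TreeError(f"unknown terminal labels: {sorted(unknown)}")
        node = self.root
        while True:
            hits = [c for c in node.children if taxa & self.leafset(c)]
            if len(hits) == 1 and taxa <= self.leafset(hits[0]):
                node = hits[0]
            else:
                return node

    def is_monophyletic(self, taxa: Sequence[str] | set[str]) -> bool:
        """True iff ``taxa`` is exactly the terminal set under its MRCA."""
        taxa = frozenset(taxa)
        return self.leafset(self.mrca(taxa)) == taxa

    # ------------------------------------------------------------------
    # pruning
    # ------------------------------------------------------------------
    def prune_terminal(self, label: str) -> "PhyloTree":
        """Return a new tree without terminal ``label``.

        The degree-2 node left behind is suppressed with its two incident
        branch lengths summed, so all pairwise path lengths among the
        remaining terminals are preserved.  If the suppressed node is the
        root, the surviving child becomes the new root (its subtending length
        is discarded, as root branches carry none).
        """
        if self.n_leaves < 3:
            raise TreeError("pruning would leave fewer than 2 terminals")
        new = self.copy()
        leaf = new.find_leaf(label)
        parent = leaf.parent
        assert parent is not None
        parent.children.remove(leaf)
        if len(parent.children) == 1:
            only = parent.children[0]
            grand = parent.parent
            if grand is None:
                only.parent = None
                only.length = 0.0
                return PhyloTree(only)
            only.length += parent.length
            idx = grand.children.index(parent)
            grand.children[idx] = only
            only.parent = grand
        return PhyloTree(new.root)

    # ------------------------------------------------------------------
    # ages (chronograms)
    # ------------------------------------------------------------------
    def depths(self) -> dict[Node, float]:
        """Root-to-node path lengths."""
        d: dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is not self.root:
                d[node] = d[node.parent] + node.length  # type: ignore[index]
        return d

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        depths = self.depths()
        tip_depths = [depths[n] for n in self.leaves()]
        span = max(tip_depths) - min(tip_depths)
        scale = max(max(tip_depths), 1e-300)
        return span <= rtol * scale

    def node_ages(self, rtol: float = ULTRAMETRIC_RTOL) -> dict[Node, float]:
        """Ages (distance to tips) for an ultrametric tree; tips at 0.

        Raises :class:`TreeError` reporting the worst tip-depth spread when
        the tree is not ultrametric within ``rtol`` of the root age.
        """
        depths = self.depths()
        tip_depths = [depths[n] for n in self.leaves()]
        root_age = max(tip_depths)
        span = root_age - min(tip_depths)
        if span > rtol * max(root_age, 1e-300):
            raise TreeError(
                "tree is not ultrametric: tip-depth spread "
                f"{span:g} exceeds {rtol:g} x root age {root_age:g}"
            )
        ages = {n: (0.0 if n.is_leaf else root_age - depths[n]) for n in self.preorder()}
        return ages

    # ------------------------------------------------------------------
    # Newick I/O
    # ------------------------------------------------------------------
    def to_newick(self, precision: int = 10) -> str:
        def fmt(x: float) -> str:
            return f"{x:.{precision}g}"

        def rec(node: Node) -> str:
            if node.is_leaf:
                return f"{_quote(node.label)}:{fmt(node.length)}"
            inner = ",".join(rec(c) for c in node.children)
            lab = _quote(node.label) if node.label else ""
            if node is self.root:
                return f"({inner}){lab}"
            return f"({inner}){lab}:{fmt(node.length)}"

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_leaves} terminals>"


def _quote(label: str | None) -> str:
    if label is None:
        return ""
    if any(c in label for c in "()[]{}/\\,;:=*'\"`<> \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label)
        else:
            node = Node(dnode.label)
            if dnode.label is not None:
                try:
                    node.support = float(dnode.label)
                except ValueError:
                    pass
        if dnode.edge.length is None:
            node.length = 0.0
        else:
            node.length = float(dnode.edge.length)
        for c in dnode.child_nodes():
            node.add_child(convert(c))
        return node

    missing = sum(
        1
        for e in dtree.preorder_edge_iter()
        if e.length is None and e.head_node is not dtree.seed_node
    )
    if missing:
        warnings.warn(
            f"{missing} branch(es) had no length in Newick input; defaulting to 0",
            stacklevel=3,
        )
    root = convert(dtree.seed_node)
    root.length = 0.0
    return PhyloTree(root)


def read_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick statement into a :class:`PhyloTree`.

    Supports branch lengths, quoted labels and internal-node support labels;
    square-bracket comments are ignored.  Missing branch lengths default to 0
    with a warning.  Malformed input raises :class:`NewickParseError` naming
    the offending position.
    """
    text = text.strip()
    if not text:
        raise NewickParseError("empty Newick input")
    if not text.rstrip().endswith(";"):
        raise NewickParseError("unterminated Newick statement (missing ';')")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"could not parse Newick input: {exc}") from exc
    try:
        return _from_dendropy(dtree)
    except TreeError as exc:
        raise NewickParseError(str(exc)) from exc


def write_newick(tree: PhyloTree, precision: int = 10) -> str:
    return tree.to_newick(precision=precision)


@dataclass
class TreeSet:
    """An ordered collection of trees over a shared taxon universe.

    ``label`` records provenance (e.g. ``"ML-bootstrap"``).  Every member's
    terminal set must be a subset of the declared universe.
    """

    trees: list[PhyloTree]
    label: str = "trees"
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("empty tree set")
        if not self.universe:
            self.universe = frozenset().union(
                *[frozenset(t.leaf_labels()) for t in self.trees]
            )
        for i, t in enumerate(self.trees):
            extra = frozenset(t.leaf_labels()) - self.universe
            if extra:
                raise TreeError(
                    f"tree {i} has terminals outside the declared universe: "
                    f"{sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.trees)

    def __getitem__(self, i: int) -> PhyloTree:
        return self.trees[i]


def read_tree_list(text: str, label: str = "trees") -> TreeSet:
    """Parse a multi-tree Newick document (one statement per record).

    Any malformed record aborts the whole read, reporting its 0-based index.
    """
    records = [s.strip() for s in text.split(";")]
    records = [r + ";" for r in records if r]
    if not records:
        raise NewickParseError("empty tree set")
    trees = []
    for i, rec in enumerate(records):
        try:
            trees.append(read_newick(rec))
        except NewickParseError as exc:
            raise NewickParseError(f"record {i}: {exc}") from exc
    return TreeSet(trees=trees, label=label)


def write_tree_list(treeset: TreeSet, precision: int = 10) -> str:
    return "\n".join(t.to_newick(precision=precision) for t in treeset) + "\n"


def leafset_hash(labels: Sequence[str] | frozenset[str]) -> str:
    """Stable short hash of a clade's terminal set, for node-table exports."""
    joined = "|".join(sorted(labels))
    return hashlib.sha1(joined.encode()).hexdigest()[:12]


def export_node_ages(tree: PhyloTree, path) -> None:
    """Write a TSV of node ages (``node_id, clade_leafset_hash, age_My``)."""
    ages = tree.node_ages()
    buf = io.StringIO()
    buf.write("node_id\tclade_leafset_hash\tage_My\n")
    for i, node in enumerate(tree.preorder()):
        buf.write(f"{i}\t{leafset_hash(tree.leafset(node))}\t{ages[node]:.10g}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
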