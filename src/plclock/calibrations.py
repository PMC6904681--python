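"""Node-age calibration tables and their resolution onto concrete trees.

A calibration point is a clade definition (a set of terminal labels) plus a
[min, max] age box in My, justified by fossil, geological or secondary
evidence.  ``crown`` points constrain the MRCA of the clade's sampled
members; ``stem`` points constrain the node where the clade's subtending
branch attaches (the crown node's parent), the convention used by
fossil-based dating.

Because bootstrap and parsimony topologies need not recover every calibrated
clade, resolution is skip-with-warning: a point whose clade is not
monophyletic in a given tree is dropped from that tree's constraint list and
logged, never fatal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from math import inf
from typing import Iterable, Sequence

import pandas as pd

from .trees import Node, PhyloTree, TreeError

logger = logging.getLogger(__name__)

_ROLES = ("crown", "stem")
_EVIDENCE = ("fossil", "geological", "secondary", "synthetic", "")


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationPoint:
    """A clade-based age constraint: at least one of min/max present (My)."""

    name: str
    node_role: str  # "crown" | "stem"
    clade_taxa: frozenset[str]
    min_age: float | None = None
    max_age: float | None = None
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.node_role not in _ROLES:
            raise CalibrationError(
                f"{self.name!r}: unknown node_role {self.node_role!r} "
                f"(expected one of {_ROLES})"
            )
        if not self.clade_taxa:
            raise CalibrationError(f"{self.name!r}: empty clade definition")
        if self.min_age is None and self.max_age is None:
            raise CalibrationError(f"{self.name!r}: no age bound given")
        if self.min_age is not None and self.min_age < 0:
            raise CalibrationError(f"{self.name!r}: negative min_age")
        if (
            self.min_age is not None
            and self.max_age is not None
            and not self.min_age < self.max_age
        ):
            raise CalibrationError(
                f"{self.name!r}: min_age {self.min_age} >= max_age {self.max_age}"
            )

    @property
    def lo(self) -> float:
        """Min bound with the absent side closed at 0."""
        return 0.0 if self.min_age is None else self.min_age

    @property
    def hi(self) -> float:
        """Max bound with the absent side left open (+inf).

        During fitting an open max inherits whatever upper bound propagates
        down from calibrated ancestors (ultimately the root's box).
        """
        return inf if self.max_age is None else self.max_age


@dataclass(frozen=True)
class ResolvedConstraint:
    """A calibration box attached to a concrete node of a specific tree.

    Unlike :class:`CalibrationPoint`, a degenerate box (min == max) is legal
    here: it pins the node's age exactly, which is how noiseless recovery
    benchmarks fix the root.
    """

    node: Node
    min_age: float
    max_age: float  # may be +inf
    provenance: str

    def __post_init__(self) -> None:
        if not self.min_age <= self.max_age or self.min_age < 0:
            raise CalibrationError(
                f"constraint {self.provenance!r}: invalid box "
                f"[{self.min_age}, {self.max_age}]"
            )


def load_calibration_table(path) -> list[CalibrationPoint]:
    """Read a calibration TSV into :class:`CalibrationPoint` records.

    Columns: ``name, node_role, min_age, max_age, evidence, taxa`` with taxa
    semicolon-separated.  Rows sharing a ``name`` are merged into one point
    carrying both bounds (published tables often list one-sided rows
    separately); evidence strings are joined.  An empty file yields an empty
    list with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"name", "node_role", "min_age", "max_age", "evidence", "taxa"}
    missing = required - set(df.columns)
    if missing:
        raise CalibrationError(f"calibration table missing columns: {sorted(missing)}")
    if df.empty:
        warnings.warn("calibration table is empty", stacklevel=2)
        return []

    merged: dict[str, dict] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        name = row["name"].strip()
        if name not in merged:
            order.append(name)
            merged[name] = {
                "node_role": row["node_role"].strip(),
                "min_age": None,
                "max_age": None,
                "evidence": [],
                "taxa": frozenset(
                    t.strip() for t in row["taxa"].split(";") if t.strip()
                ),
            }
        rec = merged[name]
        if rec["node_role"] != row["node_role"].strip():
            raise CalibrationError(f"{name!r}: conflicting node_role across rows")
        for side in ("min_age", "max_age"):
            raw = row[side].strip()
            if raw:
                val = float(raw)
                if rec[side] is not None and rec[side] != val:
                    raise CalibrationError(f"{name!r}: conflicting {side} across rows")
                rec[side] = val
        ev = row["evidence"].strip()
        if ev and ev != "-" and ev not in rec["evidence"]:
            rec["evidence"].append(ev)

    points = []
    for name in order:
        rec = merged[name]
        points.append(
            CalibrationPoint(
                name=name,
                node_role=rec["node_role"],
                clade_taxa=rec["taxa"],
                min_age=rec["min_age"],
                max_age=rec["max_age"],
                evidence="+".join(rec["evidence"]),
            )
        )
    return points


def write_calibration_table(points: Iterable[CalibrationPoint], path) -> None:
    rows = []
    for p in points:
        rows.append(
            {
                "name": p.name,
                "node_role": p.node_role,
                "min_age": "" if p.min_age is None else f"{p.min_age:.10g}",
                "max_age": "" if p.max_age is None else f"{p.max_age:.10g}",
                "evidence": p.evidence,
                "taxa": ";".join(sorted(p.clade_taxa)),
            }
        )
    pd.DataFrame(
        rows, columns=["name", "node_role", "min_age", "max_age", "evidence", "taxa"]
    ).to_csv(path, sep="\t", index=False)


def resolve_calibrations(
    tree: PhyloTree, points: Sequence[CalibrationPoint]
) -> list[ResolvedConstraint]:
    """Attach calibration boxes to the nodes of ``tree``.

    Crown points map to ``mrca(clade_taxa)``; stem points to that node's
    parent (for a single-terminal clade, the terminal's parent).  Points whose
    clade is not monophyletic in this tree are skipped with a logged warning.
    Taxa absent from the tree altogether raise :class:`TreeError`.

    Resolution is deterministic: the same tree and table always give the same
    constraint list, in table order.
    """
    out: list[ResolvedConstraint] = []
    for p in points:
        crown = tree.mrca(p.clade_taxa)  # raises on unknown taxa
        if not tree.leafset(crown) == p.clade_taxa:
            logger.warning(
                "calibration point %r skipped: clade not monophyletic in tree", p.name
            )
            continue
        if p.node_role == "stem":
            node = crown.parent
            if node is None:
                logger.warning(
                    "calibration point %r skipped: stem of the root is undefined",
                    p.name,
                )
                continue
        else:
            node = crown
        out.append(
            ResolvedConstraint(
                node=node, min_age=p.lo, max_age=p.hi, provenance=p.name
            )
        )
    return out


def feasible_subset(tree: PhyloTree, constraints: Sequence["ResolvedConstraint"]):
    """Drop jointly infeasible constraints until the box system is solvable.

    On rearranged (bootstrap) or pruned topologies a monophyletic clade can
    re-attach so that its box contradicts an ancestor's.  When two
    constraints clash, the subordinate one is dropped with a warning: a
    non-root constraint before one sitting on the root (root boxes anchor
    the timescale), otherwise the one defining the smaller clade (the more
    local statement).  Returns ``(kept constraints, dropped provenances)``.
    """
    from .model import ClockModel, InfeasibleConstraintsError

    kept = list(constraints)
    dropped: list[str] = []
    for _ in range(len(constraints) + 1):
        try:
            ClockModel(tree, kept, s=1)
            return kept, dropped
        except InfeasibleConstraintsError as exc:
            contenders = [
                c
                for c in kept
                if c.provenance in (exc.lo_provenance, exc.hi_provenance)
            ]
            if not contenders:
                raise
            non_root = [c for c in contenders if c.node is not tree.root]
            pool = non_root if non_root else contenders
            victim = min(pool, key=lambda c: len(tree.leafset(c.node)))
            kept = [c for c in kept if c is not victim]
            dropped.append(victim.provenance)
            logger.warning(
                "constraint %r dropped: %s", victim.provenance, exc
            )
    raise InfeasibleConstraintsError("could not reach a feasible constraint set")


def study_calibration_table() -> list[CalibrationPoint]:
    """The packaged diatom calibration set (8 points; bounds in My).

    Mirrors the published fossil/geological/secondary constraints for the
    diatom phylogeny this package was designed around: diatom stem and crown,
    Mediophyceae stem, Bacillariophyceae crown, the core araphid/raphid
    split, the raphid-pennate crown, the Pinnularia stem and the
    Didymosphenia crown.  Clade memberships follow standard diatom taxonomy
    over the study's taxon sample.
    """
    ref = resources.files("plclock.data").joinpath("diatom_calibrations.tsv")
    with resources.as_file(ref) as path:
        return load_calibration_table(path)
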