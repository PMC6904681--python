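"""Terminal-deletion cross-validation for choosing the clock parameters.

For a candidate (k, lambda) the reference tree (RT) is dated in full,
yielding the focal clade's observed crown height (OCH); then each terminal
of the RT is deleted in turn, the pruned tree is re-dated under the same
parameters, and the focal crown height is re-read (the predictor crown
heights, PCH).  The score

    CV = sum_m (OCH - PCH_m)^2 / OCH

(in My, no further normalization) measures how sensitive the focal crown
age is to single-taxon removal; the grid argmin over k and lambda picks the
clock configuration.  Deletions that make the score ill-defined are the
only exclusions: removals leaving fewer than two focal terminals, or
removing the only taxon set that bounds the root's age from above.  Both
are logged so the effective M can be audited.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .calibrations import CalibrationPoint, resolve_calibrations
from .model import ClockConfig, ClockModel
from .trees import PhyloTree

logger = logging.getLogger(__name__)

DEFAULT_K_VALUES = tuple(range(2, 11))
DEFAULT_LAMBDA_VALUES = tuple(j / 9.0 for j in range(10))


class CVError(ValueError):
    pass


def cv_score(och: float, pchs: Sequence[float]) -> float:
    """The terminal-deletion cross-validation score, sum((OCH-PCH)^2)/OCH."""
    if not och > 0:
        raise CVError(f"OCH must be > 0, got {och}")
    pchs = list(pchs)
    if not pchs:
        raise CVError("empty PCH list")
    if any(p < 0 for p in pchs):
        raise CVError("PCH values must be >= 0")
    return float(sum((och - p) ** 2 for p in pchs) / och)


def restrict_points(
    points: Sequence[CalibrationPoint], present: frozenset[str]
) -> list[CalibrationPoint]:
    """Intersect calibration clades with the taxa present in a tree.

    Points whose clade empties, or whose crown clade reduces to a single
    terminal (a tip cannot carry a crown age), are dropped.
    """
    out = []
    for p in points:
        taxa = p.clade_taxa & present
        if not taxa:
            continue
        if p.node_role == "crown" and len(taxa) < 2:
            continue
        if taxa == p.clade_taxa:
            out.append(p)
        else:
            out.append(
                CalibrationPoint(
                    name=p.name,
                    node_role=p.node_role,
                    clade_taxa=taxa,
                    min_age=p.min_age,
                    max_age=p.max_age,
                    evidence=p.evidence,
                )
            )
    return out


def _root_bounded(tree: PhyloTree, constraints) -> bool:
    return any(
        c.node is tree.root and math.isfinite(c.max_age) for c in constraints
    )


def deletion_replicates(
    rt: PhyloTree,
    focal_taxa: frozenset[str] | set[str],
    points: Sequence[CalibrationPoint],
) -> tuple[list[tuple[str, PhyloTree, list]], list[tuple[str, str]]]:
    """One pruned tree per RT terminal, with constraints re-resolved.

    Returns ``(replicates, skipped)`` where each replicate is
    ``(deleted label, pruned tree, resolved constraints)`` and ``skipped``
    records ``(label, reason)`` for deletions excluded because the focal
    crown would degenerate or the root would lose every upper age bound.
    """
    if rt.n_leaves < 3:
        raise CVError("deletion replicates require >= 3 terminals")
    focal_taxa = frozenset(focal_taxa)
    replicates: list[tuple[str, PhyloTree, list]] = []
    skipped: list[tuple[str, str]] = []
    for label in rt.leaf_labels():
        if label in focal_taxa and len(focal_taxa) - 1 < 2:
            skipped.append((label, "focal-crown-degenerate"))
            logger.warning("deletion of %r skipped: focal crown degenerates", label)
            continue
        pruned = rt.prune_terminal(label)
        present = frozenset(pruned.leaf_labels())
        constraints = resolve_calibrations(pruned, restrict_points(points, present))
        if not _root_bounded(pruned, constraints):
            skipped.append((label, "root-upper-bound-lost"))
            logger.warning(
                "deletion of %r skipped: no upper age bound on the root remains",
                label,
            )
            continue
        replicates.append((label, pruned, constraints))
    return replicates, skipped


def _build_replicate_models(reps, skipped, config):
    """Compile deletion replicates into models.

    Pruning (like bootstrap rearrangement) can re-attach a calibrated clade
    so that its box contradicts an ancestor's; clashing subordinate
    constraints are dropped with a warning (see
    :func:`plclock.calibrations.feasible_subset`).  A replicate is skipped
    only if no dateable constraint set remains.
    """
    from .calibrations import feasible_subset

    models = []
    skipped = list(skipped)
    for label, tree, cons in reps:
        try:
            kept, dropped = feasible_subset(tree, cons)
            if not _root_bounded(tree, kept):
                skipped.append((label, "root-upper-bound-lost"))
                continue
            models.append((label, ClockModel(tree, kept, s=config.s)))
        except Exception as exc:
            skipped.append((label, f"infeasible-after-deletion: {exc}"))
            logger.warning("deletion of %r skipped: %s", label, exc)
    return models, skipped


@dataclass
class CVResult:
    """One grid cell: the CV score and its ingredients."""

    k: int
    lam: float
    och: float
    pchs: list[float]
    cv: float
    skipped: list[tuple[str, str]] = field(default_factory=list)
    valid: bool = True

    @property
    def M(self) -> int:
        return len(self.pchs)


@dataclass
class CVSurface:
    """A complete (k, lambda) grid of CV results."""

    k_values: tuple[int, ...]
    lambda_values: tuple[float, ...]
    results: dict[tuple[int, float], CVResult]

    def __post_init__(self) -> None:
        missing = [
            (k, lam)
            for k in self.k_values
            for lam in self.lambda_values
            if (k, lam) not in self.results
        ]
        if missing:
            raise CVError(f"incomplete CV surface; missing cells {missing[:5]}")

    @property
    def n_cells(self) -> int:
        return len(self.k_values) * len(self.lambda_values)

    @property
    def argmin(self) -> CVResult:
        """Lowest-CV cell; ties broken by smaller k, then smaller lambda."""
        best = None
        for k in sorted(self.k_values):
            for lam in sorted(self.lambda_values):
                r = self.results[(k, lam)]
                if not r.valid:
                    continue
                if best is None or r.cv < best.cv:
                    best = r
        if best is None:
            raise CVError("every cell of the CV surface is invalid")
        return best

    def to_frame(self) -> pd.DataFrame:
        rows = []
        best = self.argmin
        for k in self.k_values:
            for lam in self.lambda_values:
                r = self.results[(k, lam)]
                rows.append(
                    {
                        "k": k,
                        "lambda": f"{lam:.2f}",
                        "M": r.M,
                        "OCH": r.och,
                        "CV": r.cv,
                        "n_skipped": len(r.skipped),
                        "is_argmin": int(r is best),
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def plot(self, path=None):
        """Fig.-3-style panels: one per lambda, CV against k."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        nlam = len(self.lambda_values)
        ncol = min(5, nlam)
        nrow = (nlam + ncol - 1) // ncol
        fig, axes = plt.subplots(
            nrow, ncol, figsize=(3 * ncol, 2.5 * nrow), squeeze=False, sharex=True
        )
        for idx, lam in enumerate(self.lambda_values):
            ax = axes[idx // ncol][idx % ncol]
            ks = list(self.k_values)
            cvs = [self.results[(k, lam)].cv for k in ks]
            ax.plot(ks, cvs, "o-", ms=3)
            ax.set_title(f"$\\lambda$ = {lam:.2f}", fontsize=9)
            ax.set_xlabel("k")
            ax.set_ylabel("CV")
        for idx in range(nlam, nrow * ncol):
            axes[idx // ncol][idx % ncol].axis("off")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def evaluate_cell(
    rt: PhyloTree,
    focal_taxa,
    points: Sequence[CalibrationPoint],
    k: int,
    lam: float,
    config: ClockConfig | None = None,
    *,
    _rt_model: ClockModel | None = None,
    _replicates: list | None = None,
    _skipped: list | None = None,
) -> CVResult:
    """Score one (k, lambda) grid cell.

    Fits the reference tree, then every deletion replicate warm-started
    from the RT solution, and applies :func:`cv_score` to the crown
    heights.  The private keyword arguments let :func:`grid_search` reuse
    the compiled models across cells; results are identical either way.
    """
    config = config or ClockConfig()
    focal_taxa = frozenset(focal_taxa)
    if _rt_model is None:
        present = frozenset(rt.leaf_labels())
        constraints = resolve_calibrations(rt, restrict_points(points, present))
        _rt_model = ClockModel(rt, constraints, s=config.s)
    if _replicates is None or _skipped is None:
        reps, _skipped = deletion_replicates(rt, focal_taxa, points)
        _replicates, _skipped = _build_replicate_models(reps, _skipped, config)
    try:
        rt_fit = _rt_model.fit(config, k=k, lam=lam)
    except Exception as exc:
        logger.warning("RT fit failed at k=%d lambda=%.3g: %s", k, lam, exc)
        return CVResult(
            k=k, lam=lam, och=math.nan, pchs=[], cv=math.inf,
            skipped=list(_skipped), valid=False,
        )
    och = rt_fit.crown_height(focal_taxa)
    pchs = []
    skipped = list(_skipped)
    for label, rep_model in _replicates:
        try:
            rep_fit = rep_model.fit(config, k=k, lam=lam, init=rt_fit)
            pchs.append(rep_fit.crown_height(focal_taxa - {label}))
        except Exception as exc:
            skipped.append((label, f"fit-failed: {exc}"))
            logger.warning(
                "replicate %r fit failed at k=%d lambda=%.3g: %s", label, k, lam, exc
            )
    if not pchs:
        return CVResult(
            k=k, lam=lam, och=och, pchs=[], cv=math.inf, skipped=skipped, valid=False
        )
    return CVResult(
        k=k, lam=lam, och=och, pchs=pchs, cv=cv_score(och, pchs), skipped=skipped
    )


def grid_search(
    rt: PhyloTree,
    focal_taxa,
    points: Sequence[CalibrationPoint],
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    lambda_values: Sequence[float] = DEFAULT_LAMBDA_VALUES,
    config: ClockConfig | None = None,
) -> CVSurface:
    """Exhaustively score every (k, lambda) cell of the grid.

    Default axes: k in 2..10, lambda in 0, 1/9, ..., 1 (90 cells).
    """
    if not k_values or not lambda_values:
        raise CVError("empty grid axes")
    config = config or ClockConfig()
    focal_taxa = frozenset(focal_taxa)
    present = frozenset(rt.leaf_labels())
    constraints = resolve_calibrations(rt, restrict_points(points, present))
    rt_model = ClockModel(rt, constraints, s=config.s)
    reps, skipped = deletion_replicates(rt, focal_taxa, points)
    rep_models, skipped = _build_replicate_models(reps, skipped, config)
    results: dict[tuple[int, float], CVResult] = {}
    for k in k_values:
        for lam in lambda_values:
            results[(k, lam)] = evaluate_cell(
                rt,
                focal_taxa,
                points,
                k,
                lam,
                config,
                _rt_model=rt_model,
                _replicates=rep_models,
                _skipped=skipped,
            )
    surface = CVSurface(
        k_values=tuple(k_values),
        lambda_values=tuple(lambda_values),
        results=results,
    )
    surface.argmin  # raises if every cell is invalid
    return surface
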