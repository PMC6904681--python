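"""tMRCA ensembles: dating grids over collections of trees.

Phylogenetic uncertainty is integrated by dating not just the optimal tree
but every bootstrap (or otherwise alternative) topology under every clock
configuration of the (k, lambda) grid, and summarizing the distribution of
the focal clade's crown age (tMRCA) across all resulting chronograms:
quartiles, the central-75% interval, and the fraction of chronograms below
a user threshold (e.g. 1 My, the horizon separating a recent-invader
scenario from an older radiation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibrations import CalibrationPoint, feasible_subset, resolve_calibrations
from .crossval import (
    DEFAULT_K_VALUES,
    DEFAULT_LAMBDA_VALUES,
    _root_bounded,
    restrict_points,
)
from .model import ClockConfig, ClockModel
from .trees import TreeSet

logger = logging.getLogger(__name__)


class EnsembleError(ValueError):
    pass


@dataclass
class TMRCARecord:
    source: str
    tree_index: int
    k: int
    lam: float
    tmrca: float
    converged: bool


@dataclass
class TMRCAEnsemble:
    """tMRCA estimates across trees x grid cells, plus logged failures."""

    records: list[TMRCARecord]
    k_values: tuple[int, ...]
    lambda_values: tuple[float, ...]
    focal_taxa: frozenset[str]
    failures: list[tuple[str, int, str]] = field(default_factory=list)
    n_trees: int = 0

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def grid_size(self) -> int:
        return len(self.k_values) * len(self.lambda_values)

    def check_count_identity(self) -> bool:
        """n must equal (trees x grid cells) minus logged failures."""
        return self.n == self.n_trees * self.grid_size - len(self.failures)

    def tmrcas(self, converged_only: bool = False) -> np.ndarray:
        vals = [
            r.tmrca for r in self.records if r.converged or not converged_only
        ]
        return np.asarray(vals, dtype=float)

    def merge(self, other: "TMRCAEnsemble") -> "TMRCAEnsemble":
        """Pool two ensembles (same grid and focal clade)."""
        if (
            self.k_values != other.k_values
            or self.lambda_values != other.lambda_values
            or self.focal_taxa != other.focal_taxa
        ):
            raise EnsembleError("cannot merge ensembles with different designs")
        return TMRCAEnsemble(
            records=self.records + other.records,
            k_values=self.k_values,
            lambda_values=self.lambda_values,
            focal_taxa=self.focal_taxa,
            failures=self.failures + other.failures,
            n_trees=self.n_trees + other.n_trees,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": r.source,
                    "tree_index": r.tree_index,
                    "k": r.k,
                    "lambda": f"{r.lam:.2f}",
                    "tmrca_My": r.tmrca,
                    "converged": int(r.converged),
                }
                for r in self.records
            ],
            columns=["source", "tree_index", "k", "lambda", "tmrca_My", "converged"],
        )


@dataclass
class EnsembleSummary:
    """Distributional summary of an ensemble's tMRCAs (all in My)."""

    n: int
    min: float
    max: float
    q1: float
    q3: float
    central75_lo: float  # 12.5th percentile
    central75_hi: float  # 87.5th percentile
    threshold: float
    n_below: int
    frac_below: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n": self.n,
                    "min_My": self.min,
                    "Q1_My": self.q1,
                    "Q3_My": self.q3,
                    "max_My": self.max,
                    "central75_lo_My": self.central75_lo,
                    "central75_hi_My": self.central75_hi,
                    "threshold_My": self.threshold,
                    "n_below_threshold": self.n_below,
                    "frac_below_threshold": self.frac_below,
                }
            ]
        )


def run_ensemble(
    tree_sets: Sequence[TreeSet],
    points: Sequence[CalibrationPoint],
    focal_taxa,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    lambda_values: Sequence[float] = DEFAULT_LAMBDA_VALUES,
    config: ClockConfig | None = None,
) -> TMRCAEnsemble:
    """One tMRCA per (tree, grid cell) across all tree sets.

    Trees lacking at least two focal terminals, or every root upper bound,
    are skipped with a warning (all their cells are logged as failures);
    individual fit failures are logged, never silently dropped.
    Deterministic for a fixed config seed.
    """
    if not k_values or not lambda_values:
        raise EnsembleError("empty grid axes")
    if not tree_sets:
        raise EnsembleError("no tree sets given")
    config = config or ClockConfig()
    focal_taxa = frozenset(focal_taxa)
    records: list[TMRCARecord] = []
    failures: list[tuple[str, int, str]] = []
    cells = [(k, lam) for k in k_values for lam in lambda_values]
    n_trees = 0
    for tset in tree_sets:
        for idx, tree in enumerate(tset):
            n_trees += 1
            present = frozenset(tree.leaf_labels())
            focal_here = focal_taxa & present
            if len(focal_here) < 2:
                logger.warning(
                    "tree %d of %r skipped: fewer than 2 focal terminals",
                    idx,
                    tset.label,
                )
                failures.extend(
                    (tset.label, idx, "fewer-than-2-focal-terminals") for _ in cells
                )
                continue
            constraints = resolve_calibrations(tree, restrict_points(points, present))
            constraints, dropped = feasible_subset(tree, constraints)
            if dropped:
                logger.warning(
                    "tree %d of %r: dropped clashing constraints %s",
                    idx, tset.label, dropped,
                )
            if not _root_bounded(tree, constraints):
                logger.warning(
                    "tree %d of %r skipped: root has no upper age bound",
                    idx,
                    tset.label,
                )
                failures.extend(
                    (tset.label, idx, "root-upper-bound-lost") for _ in cells
                )
                continue
            try:
                model = ClockModel(tree, constraints, s=config.s)
            except Exception as exc:
                logger.warning(
                    "tree %d of %r skipped: %s", idx, tset.label, exc
                )
                failures.extend(
                    (tset.label, idx, f"infeasible-constraints: {exc}")
                    for _ in cells
                )
                continue
            for k, lam in cells:
                try:
                    fit = model.fit(config, k=k, lam=lam)
                except Exception as exc:
                    failures.append((tset.label, idx, f"k={k},lam={lam:.2f}: {exc}"))
                    logger.warning(
                        "fit failed on tree %d of %r at k=%d lambda=%.3g: %s",
                        idx, tset.label, k, lam, exc,
                    )
                    continue
                records.append(
                    TMRCARecord(
                        source=tset.label,
                        tree_index=idx,
                        k=k,
                        lam=lam,
                        tmrca=fit.crown_height(focal_here),
                        converged=fit.converged,
                    )
                )
    ensemble = TMRCAEnsemble(
        records=records,
        k_values=tuple(k_values),
        lambda_values=tuple(lambda_values),
        focal_taxa=focal_taxa,
        failures=failures,
        n_trees=n_trees,
    )
    assert ensemble.check_count_identity(), "record-count identity violated"
    return ensemble


def summarize(
    ensemble: TMRCAEnsemble,
    threshold: float = 1.0,
    converged_only: bool = False,
    n_bins: int = 50,
) -> EnsembleSummary:
    """Quantiles, central-75% interval and below-threshold fraction.

    Quantiles use linear interpolation between order statistics (the
    "type 7" convention); the below-threshold count uses strict inequality.
    The histogram uses ``n_bins`` equal-width bins on log10(My) (tMRCAs
    typically span several orders of magnitude); non-positive tMRCAs are
    floored to the smallest positive value for binning only.
    """
    vals = ensemble.tmrcas(converged_only=converged_only)
    if vals.size == 0:
        raise EnsembleError("no records to summarize (after convergence filtering)")
    q1, q3, lo75, hi75 = np.percentile(
        vals, [25.0, 75.0, 12.5, 87.5], method="linear"
    )
    n_below = int((vals < threshold).sum())
    pos = vals[vals > 0]
    floor = pos.min() if pos.size else 1e-6
    logs = np.log10(np.maximum(vals, floor))
    lo, hi = logs.min(), logs.max()
    if hi <= lo:
        hi = lo + 1e-6
    counts, edges = np.histogram(logs, bins=n_bins, range=(lo, hi))
    return EnsembleSummary(
        n=int(vals.size),
        min=float(vals.min()),
        max=float(vals.max()),
        q1=float(q1),
        q3=float(q3),
        central75_lo=float(lo75),
        central75_hi=float(hi75),
        threshold=float(threshold),
        n_below=n_below,
        frac_below=n_below / vals.size,
        hist_edges=10.0**edges,
        hist_counts=counts,
    )


def plot_histogram(ensemble: TMRCAEnsemble, summary: EnsembleSummary, path=None):
    """tMRCA histogram on a log time axis, with quartile markers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    edges = np.log10(summary.hist_edges)
    ax.bar(
        edges[:-1],
        summary.hist_counts,
        width=np.diff(edges),
        align="edge",
        color="#4c72b0",
        edgecolor="white",
    )
    for v, label in [(summary.q1, "Q1"), (summary.q3, "Q3")]:
        ax.axvline(np.log10(max(v, 1e-12)), color="k", ls="--", lw=0.8)
        ax.text(np.log10(max(v, 1e-12)), ax.get_ylim()[1] * 0.95, label, fontsize=8)
    ax.set_xlabel("tMRCA (log10 My)")
    ax.set_ylabel("chronograms")
    ax.set_title(f"tMRCA distribution (n = {summary.n})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def export_ensemble(
    ensemble: TMRCAEnsemble,
    summary: EnsembleSummary,
    outdir,
    prefix: str = "ensemble",
) -> dict[str, Path]:
    """Write records TSV, summary TSV and histogram figure.

    Outputs are byte-identical across reruns with the same seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / f"{prefix}_records.tsv",
        "summary": outdir / f"{prefix}_summary.tsv",
        "histogram": outdir / f"{prefix}_histogram.png",
    }
    ensemble.to_frame().to_csv(
        paths["records"], sep="\t", index=False, float_format="%.10g"
    )
    summary.to_frame().to_csv(
        paths["summary"], sep="\t", index=False, float_format="%.10g"
    )
    plot_histogram(ensemble, summary, paths["histogram"])
    return paths
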