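"""Penalized-likelihood dating under a discrete-rate molecular clock.

The model: a rooted phylogram carries, on each branch ``i``, an observed
substitution load ``x_i = b_i * s`` (branch length ``b_i`` in expected
substitutions per site times alignment length ``s``).  A chronogram assigns
each node an age (My, tips at 0) and each branch one of ``k`` shared rate
categories with rates ``r_1..r_k`` (substitutions/site/My).  Writing
``d_i`` for the branch duration and ``mu_i = r_{c(i)} * d_i * s``, the
fitted objective is

    log L  =  sum_i [ x_i log mu_i - mu_i - lnGamma(x_i + 1) ]
    objective  =  log L  -  lambda * sum_(i,j) (log r_{c(i)} - log r_{c(j)})^2

where the penalty runs over adjacent branch pairs (each non-root branch
against its parent branch; the root's children against each other).  The
log-rate form makes the penalty dimensionless, so rescaling the time unit
rescales ages by ``c`` and rates by ``1/c`` without changing the optimum;
``lambda -> inf`` approaches a strict clock and ``lambda = 0`` leaves rates
unpenalized.  ``k = 1`` is the strict clock exactly.

Calibrations enter as hard [min, max] age boxes on nodes, never as penalty
terms.  Maximization is block-coordinate ascent (see :mod:`plclock._fitter`)
in a proportional-depth feasible region: each node's age moves inside the
interval pinned by its parent's age, its children's ages and its propagated
calibration box, which keeps the parent >= child ordering implicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from . import _fitter
from .calibrations import ResolvedConstraint
from .trees import Node, PhyloTree, TreeError, leafset_hash


class InfeasibleConstraintsError(ValueError):
    """A calibration min exceeds a calibration max somewhere on the tree.

    ``lo_provenance``/``hi_provenance`` name the two clashing constraints
    (the min comes from a descendant-or-self box, the max from an
    ancestor-or-self box).
    """

    def __init__(self, message, lo_provenance=None, hi_provenance=None):
        super().__init__(message)
        self.lo_provenance = lo_provenance
        self.hi_provenance = hi_provenance


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class ClockConfig:
    """Parameters of the penalized discrete-clock fit.

    k: number of discrete rate categories (>= 1).
    lam: penalty weight on rate changes across the phylogeny (>= 0).
    s: alignment length (sites) scaling branch lengths to substitution
       counts; default 3754, typical of a three-locus diatom supermatrix.
    tol: relative objective-change convergence threshold.
    n_starts: restarts of the ascent from jittered initializations.
    seed: seeds the restart jitter (deterministic fits for a fixed value).
    """

    k: int = 2
    lam: float = 1.0 / 3.0
    s: int = 3754
    max_iter: int = 500
    tol: float = 1e-8
    n_starts: int = 1
    seed: int = 0
    rate_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.s < 1:
            raise ValueError("alignment length s must be >= 1")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


class ClockModel:
    """Penalized-likelihood dating model for one phylogram.

    Parameters
    ----------
    tree:
        Rooted phylogram (branch lengths in substitutions/site); >= 2
        terminals.
    constraints:
        Calibration boxes resolved onto nodes of *this* tree.  At least one
        constraint must bound the root's age from above, directly or via a
        constraint on a node ancestral to everything else.
    s:
        Alignment length in sites.

    Use :meth:`fit` to obtain a :class:`ChronogramResults`.
    """

    def __init__(
        self,
        tree: PhyloTree,
        constraints: Sequence[ResolvedConstraint],
        s: int = 3754,
    ):
        if tree.n_leaves < 2:
            raise TreeError("dating requires >= 2 terminals")
        self.tree = tree
        self.constraints = list(constraints)
        self.s = int(s)
        self._compile()

    @classmethod
    def from_calibrations(cls, tree, points, s: int = 3754) -> "ClockModel":
        """Build a model by resolving a calibration table onto ``tree``."""
        from .calibrations import resolve_calibrations

        return cls(tree, resolve_calibrations(tree, points), s=s)

    # ------------------------------------------------------------------
    def _compile(self) -> None:
        nodes = list(self.tree.preorder())
        index = {id(n): i for i, n in enumerate(nodes)}
        for c in self.constraints:
            if id(c.node) not in index:
                raise TreeError(
                    f"constraint {c.provenance!r} references a node "
                    "not in this tree"
                )
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        x = np.zeros(n, dtype=np.float64)
        is_tip = np.zeros(n, dtype=np.bool_)
        for i, node in enumerate(nodes):
            if node.parent is not None:
                parent[i] = index[id(node.parent)]
                x[i] = node.length * self.s
            is_tip[i] = node.is_leaf
        child_lists: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            child_lists[parent[i]].append(i)
        child_ptr = np.zeros(n + 1, dtype=np.int64)
        child_idx = np.zeros(n - 1, dtype=np.int64)
        pos = 0
        for i in range(n):
            child_ptr[i] = pos
            for c in child_lists[i]:
                child_idx[pos] = c
                pos += 1
        child_ptr[n] = pos

        # penalty adjacency: branch vs parent branch; root children pairwise
        pair_list: list[tuple[int, int]] = []
        for i in range(1, n):
            p = parent[i]
            if p != 0:
                pair_list.append((i, p))
        root_children = child_lists[0]
        for a in range(len(root_children)):
            for b in range(a + 1, len(root_children)):
                pair_list.append((root_children[a], root_children[b]))
        pairs = np.array(pair_list, dtype=np.int64).reshape(-1, 2)
        partners: list[list[int]] = [[] for _ in range(n)]
        for a, b in pair_list:
            partners[a].append(b)
            partners[b].append(a)
        part_ptr = np.zeros(n + 1, dtype=np.int64)
        part_idx = np.zeros(2 * len(pair_list), dtype=np.int64)
        pos = 0
        for i in range(n):
            part_ptr[i] = pos
            for j in partners[i]:
                part_idx[pos] = j
                pos += 1
        part_ptr[n] = pos

        self._nodes = nodes
        self._index = index
        self._parent = parent
        self._x = x
        self._is_tip = is_tip
        self._child_ptr = child_ptr
        self._child_idx = child_idx
        self._pairs = pairs
        self._part_ptr = part_ptr
        self._part_idx = part_idx
        self._n_branches = n - 1
        self._build_boxes()

    def _build_boxes(self) -> None:
        n = len(self._nodes)
        lo = np.zeros(n)
        hi = np.full(n, math.inf)
        lo_src = ["tip age 0" if t else "none" for t in self._is_tip]
        hi_src = ["tip age 0" if t else "none" for t in self._is_tip]
        hi[self._is_tip] = 0.0
        for c in self.constraints:
            i = self._index[id(c.node)]
            if c.min_age > lo[i]:
                lo[i] = c.min_age
                lo_src[i] = c.provenance
            if c.max_age < hi[i]:
                hi[i] = c.max_age
                hi_src[i] = c.provenance
        # propagate descendant minima up ...
        for i in range(n - 1, 0, -1):
            p = self._parent[i]
            if lo[i] > lo[p]:
                lo[p] = lo[i]
                lo_src[p] = lo_src[i]
        # ... and ancestor maxima down
        for i in range(1, n):
            p = self._parent[i]
            if hi[p] < hi[i]:
                hi[i] = hi[p]
                hi_src[i] = hi_src[p]
        for i in range(n):
            limit = hi[i] if not self._is_tip[i] else 0.0
            if lo[i] > limit:
                raise InfeasibleConstraintsError(
                    f"infeasible calibration box at node {i}: minimum "
                    f"{lo[i]:g} (from {lo_src[i]!r}) exceeds maximum "
                    f"{limit:g} (from {hi_src[i]!r})",
                    lo_provenance=lo_src[i],
                    hi_provenance=hi_src[i],
                )
        self._lo = lo
        self._hi = hi

    # ------------------------------------------------------------------
    def objective(
        self,
        ages: Mapping[Node, float],
        rates: Sequence[float],
        assignment: Mapping[Node, int],
    ) -> tuple[float, float]:
        """Evaluate (loglik, penalty) at an explicit state.

        ``ages`` maps nodes to ages in My (tips may be omitted, defaulting
        to 0); ``assignment`` maps each non-root node to its branch's
        category index.  Ages must respect parent >= child and rates must be
        positive.  The penalty is returned unweighted; see
        :meth:`pl_objective` for the lambda-weighted objective.
        """
        rates_arr = np.asarray(rates, dtype=np.float64)
        if np.any(rates_arr <= 0):
            raise ValueError("all category rates must be > 0")
        n = len(self._nodes)
        age_arr = np.zeros(n)
        cat_arr = np.zeros(n, dtype=np.int64)
        for i, node in enumerate(self._nodes):
            age_arr[i] = float(ages.get(node, 0.0))
            if node.parent is not None:
                c = int(assignment[node])
                if not 0 <= c < rates_arr.shape[0]:
                    raise ValueError(f"category index {c} out of range")
                cat_arr[i] = c
        for i in range(1, n):
            if age_arr[self._parent[i]] - age_arr[i] < 0:
                raise ValueError("ages violate parent >= child ordering")
        _, ll, pen = _fitter.objective_kernel(
            self._parent, self._x, cat_arr, rates_arr, age_arr,
            float(self.s), 0.0, self._pairs,
        )
        return ll, pen

    def pl_objective(
        self,
        ages: Mapping[Node, float],
        rates: Sequence[float],
        assignment: Mapping[Node, int],
        lam: float,
    ) -> tuple[float, float, float]:
        """(objective, loglik, penalty) with objective = loglik - lam*penalty."""
        ll, pen = self.objective(ages, rates, assignment)
        return ll - lam * pen, ll, pen

    # ------------------------------------------------------------------
    def _initial_state(
        self, config: ClockConfig, rng, jitter: bool, base_ages=None
    ):
        n = len(self._nodes)
        parent = self._parent
        if base_ages is not None:
            ages = base_ages.copy()
            if jitter:
                for i in range(1, n):
                    if not self._is_tip[i]:
                        ages[i] *= 1.0 + rng.uniform(-0.1, 0.1)
                ages[0] *= 1.0 + rng.uniform(-0.1, 0.1)
                ages[0] = min(max(ages[0], self._lo[0]), self._hi[0])
                for i in range(1, n):
                    if not self._is_tip[i]:
                        upper = min(self._hi[i], ages[parent[i]])
                        ages[i] = min(max(ages[i], self._lo[i]), upper)
            return self._rates_from_ages(config, ages)
        # crude-clock depth proxy: mean substitution path length from each
        # node down to its descendant tips (plus a whiff of edge count so
        # zero-length subtrees still order correctly)
        ntips = np.zeros(n)
        subs = np.zeros(n)
        total_b = max(self._x[1:].sum() / self.s, 1e-12)
        eps_edge = 1e-6 * total_b / max(self._n_branches, 1)
        for i in range(n - 1, 0, -1):
            if self._is_tip[i]:
                ntips[i] = 1.0
            p = parent[i]
            ntips[p] += ntips[i]
            subs[p] += subs[i] + (self._x[i] / self.s + eps_edge) * ntips[i]
        mean_depth = np.where(ntips > 0, subs / np.maximum(ntips, 1.0), 0.0)
        ages = np.zeros(n)
        root_lo, root_hi = self._lo[0], self._hi[0]
        a_root = 0.5 * (root_lo + root_hi)
        if jitter:
            a_root *= 1.0 + rng.uniform(-0.1, 0.1)
        ages[0] = min(max(a_root, root_lo), root_hi)
        for i in range(1, n):
            if self._is_tip[i]:
                continue
            a = ages[0] * mean_depth[i] / mean_depth[0]
            if jitter:
                a *= 1.0 + rng.uniform(-0.1, 0.1)
            upper = min(self._hi[i], ages[parent[i]])
            ages[i] = min(max(a, self._lo[i]), upper)
        return self._rates_from_ages(config, ages)

    def _rates_from_ages(self, config: ClockConfig, ages):
        """Seed categories by quantile-splitting crude branch-rate estimates."""
        n = len(self._nodes)
        parent = self._parent
        dur = ages[parent[1:]] - ages[1:]
        b = self._x[1:] / self.s
        total_dur = dur.sum()
        r0 = max(b.sum() / total_dur if total_dur > 0 else 1.0, config.rate_floor)
        crude = np.where(dur > 0, b / np.where(dur > 0, dur, 1.0), r0)
        crude = np.maximum(crude, config.rate_floor)
        order = np.argsort(crude, kind="stable")
        groups = np.array_split(order, config.k)
        rates = np.empty(config.k)
        cat = np.zeros(n, dtype=np.int64)
        for j, g in enumerate(groups):
            if len(g):
                rates[j] = max(float(crude[g].mean()), config.rate_floor)
                cat[g + 1] = j
            else:
                rates[j] = r0 * (1.0 + 1e-6 * (j + 1))
        return ages, cat, rates

    def _warm_state(self, config: ClockConfig, init: "ChronogramResults"):
        """Map a previous fit's solution onto this model's nodes by clade.

        Used by the cross-validation deletion replicates (same k, pruned
        tree) and by k-continuation (same tree, different k).  When the
        source fit's category count differs from ``config.k`` only the ages
        carry over; categories are reseeded from them.
        """
        if init.model is self:
            if init.config.k == config.k:
                return (
                    init._age_arr.copy(),
                    init._cat_arr.copy(),
                    init.rates.copy(),
                )
            return self._rates_from_ages(config, init._age_arr.copy())
        n = len(self._nodes)
        node_map = self._node_map_from(init.model)
        same_k = init.config.k == config.k
        ages = np.zeros(n)
        cat = np.zeros(n, dtype=np.int64)
        for i in range(n):
            j = node_map[i]
            if self._is_tip[i]:
                if i > 0 and same_k and j >= 0:
                    cat[i] = init._cat_arr[j]
                continue
            a = init._age_arr[j] if j >= 0 else 0.5 * (
                self._lo[i] + min(self._hi[i], self._hi[0])
            )
            upper = self._hi[i] if i == 0 else min(self._hi[i], ages[self._parent[i]])
            ages[i] = min(max(a, self._lo[i]), upper)
            if same_k and j >= 0:
                cat[i] = init._cat_arr[j]
        if not same_k:
            return self._rates_from_ages(config, ages)
        return ages, cat, init.rates.copy()

    def _node_map_from(self, src: "ClockModel") -> np.ndarray:
        """own node index -> src node index, matched by clade (cached).

        A clade is matched through the intersection of the source model's
        leafsets with this tree's taxa (the source may carry extra
        terminals, e.g. the one a deletion replicate pruned); where two
        source nodes collapse onto one clade the deeper one wins.
        """
        cache = getattr(self, "_node_map_cache", None)
        if cache is None:
            cache = {}
            self._node_map_cache = cache
        key = id(src)
        if key in cache:
            return cache[key]
        own_leaves = frozenset(self.tree.leaf_labels())
        src_idx: dict[frozenset, int] = {}
        for j, clade in enumerate(src._clades()):
            restricted = clade & own_leaves
            if restricted:
                src_idx[restricted] = j  # preorder: deeper node overwrites
        node_map = np.full(len(self._nodes), -1, dtype=np.int64)
        for i, clade in enumerate(self._clades()):
            node_map[i] = src_idx.get(clade, -1)
        cache[key] = node_map
        return node_map

    def _clades(self) -> list[frozenset]:
        """Leafset key per node (cached; used for warm-start mapping)."""
        cached = getattr(self, "_clade_cache", None)
        if cached is None:
            cached = [self.tree.leafset(n) for n in self._nodes]
            self._clade_cache = cached
        return cached

    def _strict_fit(self, config: ClockConfig) -> "ChronogramResults":
        """Cached strict-clock (k=1) fit used to seed k >= 2 ascents."""
        cached = getattr(self, "_strict_cache", None)
        key = (config.tol, config.max_iter, config.seed)
        if cached is None or cached[0] != key:
            result = self.fit(
                replace(config, k=1, lam=0.0, n_starts=1)
            )
            self._strict_cache = (key, result)
            cached = self._strict_cache
        return cached[1]

    def fit(
        self,
        config: ClockConfig | None = None,
        *,
        init: "ChronogramResults | None" = None,
        **overrides,
    ) -> "ChronogramResults":
        """Maximize the penalized likelihood; return the best restart.

        ``overrides`` replace individual :class:`ClockConfig` fields, e.g.
        ``model.fit(k=2, lam=0.33)``.  ``init`` warm-starts the ascent from
        another fit's solution (clade-matched), used by the cross-validation
        deletion replicates.  Deterministic for a fixed seed.
        """
        config = replace(config or ClockConfig(), **overrides)
        if not math.isfinite(self._hi[0]):
            raise InfeasibleConstraintsError(
                "the root's age is unbounded above; at least one calibration "
                "must impose a maximum age on the root or an "
                "ancestor-of-all clade"
            )
        if config.k > self._n_branches:
            raise FitError(
                f"k={config.k} exceeds the number of branches "
                f"({self._n_branches})"
            )
        rng = np.random.default_rng(config.seed)
        best = None
        starts: list[tuple] = []
        base_ages = None
        if init is not None:
            starts.append(self._warm_state(config, init))
            base_ages = starts[0][0]
        elif config.k > 1:
            # continuation: the strict-clock optimum is a far better basin
            # than any cold interpolation, and is computed once per model
            strict = self._strict_fit(config)
            starts.append(self._warm_state(config, strict))
            base_ages = strict._age_arr
        else:
            starts.append(self._initial_state(config, rng, jitter=False))
        while len(starts) < config.n_starts:
            starts.append(
                self._initial_state(config, rng, jitter=True, base_ages=base_ages)
            )
        for ages0, cat0, rates0 in starts:
            ages = ages0.copy()
            cat = cat0.copy()
            rates = rates0.copy()
            obj, ll, pen, iters, conv = _fitter.fit_kernel(
                self._parent,
                self._child_ptr,
                self._child_idx,
                self._is_tip,
                self._x,
                self._lo,
                self._hi,
                self._pairs,
                self._part_ptr,
                self._part_idx,
                float(self.s),
                float(config.lam),
                ages,
                cat,
                rates,
                float(config.tol),
                int(config.max_iter),
                float(config.rate_floor),
            )
            if best is None or obj > best[0]:
                best = (obj, ll, pen, iters, conv, ages, cat, rates)
        obj, ll, pen, iters, conv, ages, cat, rates = best
        # hard constraint check (numerical dust clipped, real violations fatal)
        slack = 1e-9 * max(ages[0], 1.0)
        if np.any(ages < self._lo - slack) or np.any(ages > self._hi + slack):
            raise FitError("fitted ages violate a calibration box")
        ages = np.minimum(np.maximum(ages, self._lo), self._hi)
        return ChronogramResults(self, config, ages, cat, rates, obj, ll, pen, iters, conv)


class ChronogramResults:
    """Estimates from one penalized-likelihood dating fit.

    Attributes
    ----------
    ages : dict[Node, float]
        Fitted node ages (My; tips at 0), keyed by nodes of the *input*
        phylogram.
    rates : ndarray
        The k category rates (substitutions/site/My).
    categories : dict[Node, int]
        Branch category index (key = the node below the branch).
    objective, loglik, penalty : float
        ``objective = loglik - lam * penalty`` (identity holds to 1e-9).
    converged : bool
    """

    def __init__(self, model, config, age_arr, cat_arr, rates, obj, ll, pen, iters, conv):
        self.model = model
        self.config = config
        self._age_arr = age_arr
        self._cat_arr = cat_arr
        self.rates = rates
        self.objective = float(obj)
        self.loglik = float(ll)
        self.penalty = float(pen)
        self.n_iter = int(iters)
        self.converged = bool(conv)
        nodes = model._nodes
        self.ages = {nodes[i]: float(age_arr[i]) for i in range(len(nodes))}
        self.categories = {
            nodes[i]: int(cat_arr[i]) for i in range(1, len(nodes))
        }

    @property
    def k(self) -> int:
        return self.config.k

    @property
    def lam(self) -> float:
        return self.config.lam

    def branch_rate(self, node: Node) -> float:
        return float(self.rates[self.categories[node]])

    @property
    def root_age(self) -> float:
        return float(self._age_arr[0])

    def crown_height(self, focal_taxa) -> float:
        """Fitted age of the MRCA of ``focal_taxa`` (monophyly not required)."""
        return self.ages[self.model.tree.mrca(focal_taxa)]

    def chronogram(self) -> PhyloTree:
        """The fitted tree with branch lengths in My (ultrametric)."""
        new = self.model.tree.copy()
        src = self.model._nodes
        dst = list(new.preorder())
        idx = {id(s): i for i, s in enumerate(src)}
        assert len(src) == len(dst)
        for s_node, d_node in zip(src, dst):
            if s_node.parent is not None:
                i = idx[id(s_node)]
                p = idx[id(s_node.parent)]
                d_node.length = float(self._age_arr[p] - self._age_arr[i])
        return PhyloTree(new.root)

    def to_branch_table(self):
        """Per-branch DataFrame: clade hash, duration, rate, category, count."""
        import pandas as pd

        rows = []
        tree = self.model.tree
        for node in tree.preorder():
            if node.parent is None:
                continue
            dur = self.ages[node.parent] - self.ages[node]
            rows.append(
                {
                    "clade_leafset_hash": leafset_hash(tree.leafset(node)),
                    "terminal": node.label if node.is_leaf else "",
                    "duration_My": dur,
                    "rate": self.branch_rate(node),
                    "category": self.categories[node],
                    "subst_per_site": node.length,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Penalized-likelihood discrete-clock fit",
            "=" * 47,
            f"terminals:        {self.model.tree.n_leaves}",
            f"alignment sites:  {self.model.s}",
            f"k (categories):   {self.k}",
            f"lambda:           {self.lam:.4g}",
            f"objective:        {self.objective:.6f}",
            f"  log-likelihood: {self.loglik:.6f}",
            f"  penalty:        {self.penalty:.6f}",
            f"converged:        {self.converged} ({self.n_iter} iterations)",
            f"root age (My):    {self.root_age:.4f}",
        ]
        occupancy = np.bincount(self._cat_arr[1:], minlength=self.k)
        for j in range(self.k):
            lines.append(
                f"  rate[{j + 1}] = {self.rates[j]:.6g} subst/site/My"
                f"  ({occupancy[j]} branches)"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ChronogramResults k={self.k} lam={self.lam:.3g} "
            f"objective={self.objective:.3f} converged={self.converged}>"
        )


# ----------------------------------------------------------------------
# functional surface
# ----------------------------------------------------------------------
def pl_objective(tree, ages, rates, assignment, config: ClockConfig, lam=None):
    """(objective, loglik, penalty) at an explicit state; see ClockModel.objective.

    Calibration boxes play no role in objective evaluation, so the model is
    built without constraints.
    """
    model = ClockModel(tree, [], s=config.s)
    return model.pl_objective(
        ages, rates, assignment, config.lam if lam is None else lam
    )


def fit_chronogram(
    tree: PhyloTree,
    constraints: Sequence[ResolvedConstraint],
    config: ClockConfig,
    init: ChronogramResults | None = None,
) -> ChronogramResults:
    """Fit a chronogram to ``tree`` under ``constraints`` (see ClockModel)."""
    return ClockModel(tree, constraints, s=config.s).fit(config, init=init)


def crown_height(result: ChronogramResults, focal_taxa) -> float:
    """Fitted age (My) of the MRCA of ``focal_taxa`` in a dated tree."""
    return result.crown_height(focal_taxa)
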