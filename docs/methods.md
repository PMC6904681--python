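# Methods

## Model

A rooted phylogram with branch lengths *b<sub>i</sub>* (expected
substitutions per site) is treated as carrying, per branch, a continuous
substitution count *x<sub>i</sub>* = *b<sub>i</sub>·s*, where *s* is the
alignment length in sites. A candidate chronogram assigns ages *a<sub>v</sub>*
to nodes (tips at 0, parent ≥ child) and one of *k* rate categories to each
branch; category *j* has rate *r<sub>j</sub>* in substitutions/site/My.
Writing *d<sub>i</sub>* for branch duration and μ<sub>i</sub> =
*r<sub>c(i)</sub>·d<sub>i</sub>·s*, the fitted objective is

    loglik  = Σ_i [ x_i log μ_i − μ_i − lnΓ(x_i + 1) ]          (continuous Poisson)
    penalty = Σ_{(i,j)} ( log r_c(i) − log r_c(j) )²
    objective = loglik − λ · penalty

The penalty runs over adjacent branch pairs: each non-root branch against
its parent branch, and the root's children pairwise against each other.

**Why log-rate differences.** Squared differences of *log* rates make the
penalty dimensionless: rescaling the time unit by *c* maps every optimum
(ages, rates) to (*c*·ages, rates/*c*) exactly, for any λ. A penalty on raw
rate differences would shrink by 1/*c*² under the same rescaling,
silently changing the effective smoothing — an undesirable coupling between
the unit of time and the meaning of λ. The log form preserves the limits
that define λ's role: λ = 0 leaves category rates unpenalized, λ → ∞ forces
all rates equal (the strict clock), and *k* = 1 is the strict clock at any λ.

**Assumptions.** Substitution counts are Poisson given rates and durations
(no among-site rate variation beyond what the input branch lengths already
absorb, no alignment or estimation error in *b<sub>i</sub>*); rate variation
across the tree is piecewise-constant over *k* shared values; calibrations
are hard truncation boxes, not probability densities.

## Calibrations

A calibration point is a clade (set of terminal labels), a role, and a
[min, max] box in My. A `crown` point constrains the MRCA of the clade's
members; a `stem` point constrains that node's parent (the node where the
clade's subtending branch attaches), the convention used by fossil
calibrations. Tables may state one-sided bounds in separate rows; rows
sharing a name are merged. An absent minimum closes at 0; an absent maximum
stays open and inherits, during fitting, whatever bound propagates down
from calibrated ancestors. At least one constraint must bound the root's
age from above or the timescale is undefined (this is checked and reported).

Resolution onto a specific tree is skip-with-warning: a point whose clade
is not monophyletic in that tree is dropped from that tree's constraint
list, never fatal — bootstrap and parsimony topologies routinely lose
calibrated clades. Two further degeneracy rules apply when trees are pruned
or rearranged: (1) a crown clade reduced to a single terminal is dropped
(a tip cannot carry a crown age); (2) if two surviving constraints become
jointly infeasible (a descendant's minimum above an ancestor's maximum,
which can happen when a rearrangement re-attaches a calibrated clade), the
subordinate constraint is dropped with a warning — non-root before root
(root boxes anchor the timescale), then the smaller clade. A tree or
deletion replicate is skipped only when no dateable constraint set remains
or the root loses every upper bound; all skips are logged with
machine-readable reasons so effective sample sizes can be audited.

## Optimization

Maximization is block-coordinate ascent; every block update is an exact
maximization of the objective with the other blocks fixed, so accepted
iterations are monotone:

1. **Category reassignment** — sequential iterated conditional modes over
   branches in preorder; each branch takes the category maximizing its
   local objective given its neighbours' current categories; ties go to the
   lowest index (determinism).
2. **Category rates** — with assignments and ages fixed, each category's
   log-rate solves a strictly concave 1-D problem (Poisson term plus the
   quadratic coupling to neighbouring categories); the stationary equation
   is solved by bisection to machine precision.
3. **Node ages** — coordinate ascent over internal nodes; each node's age
   maximizes a strictly concave 1-D section (derivative bisection) inside
   the interval pinned by its parent's age, its children's ages and its
   propagated calibration box, which keeps the ordering constraint
   implicit (a proportional-depth feasible region). Tip-ward durations are
   kept strictly positive by a margin of 1e-8 × root age wherever the box
   allows, so branches with observed substitutions never collapse to zero
   duration.
4. **Global rescaling** — an exact line search along "stretch all ages by
   *c*": the penalty is invariant and the likelihood is maximized at
   *c* = Σx / Σμ, clipped so every box stays satisfied. Without this move
   the coordinate sweeps crawl along the nearly flat rate–time valley.
5. **Projected extrapolation** — a candidate step along the last iteration's
   displacement (adaptive factor 2–32, ages projected back into the
   feasible region, rates in log space) is kept only when it improves the
   objective, preserving monotonicity while accelerating the geometric
   tail of the ascent.

Convergence is declared when the relative objective change drops below
`tol` (default 1e-8) within `max_iter` (default 500) iterations; otherwise
the result is returned flagged `converged=False`. Rates are floored at
1e-12. Feasibility of the box system is established up front by
propagating descendant minima up and ancestor maxima down; a contradiction
raises an error naming both offending constraints.

**Initialization and restarts.** The strict clock (*k* = 1) is fit first
from a crude-clock start (node ages proportional to mean subtree tip path
length, root at its box midpoint; rate = total length / total time) — its
basin is far better than any topology-based interpolation — and fits with
*k* ≥ 2 continue from the strict optimum, with categories seeded by
quantile-splitting the per-branch rate estimates *b<sub>i</sub>/d<sub>i</sub>*.
Optional restarts (`n_starts`) jitter ages ±10% under a seeded generator;
all randomness flows from the config seed, so fits are reproducible.
Cross-validation deletion replicates warm-start from the reference-tree
solution restricted to surviving clades.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `k` | rate categories | 2 | 1 = strict clock |
| `lam` (λ) | penalty weight | 1/3 | grid default spans 0–1 in ninths |
| `s` | alignment length (sites) | 3754 | converts lengths to counts; typical of a three-locus diatom supermatrix |
| `tol` | relative objective change | 1e-8 | |
| `max_iter` | ascent iterations | 500 | non-convergence flagged, not fatal |
| `n_starts` | jittered restarts | 1 | continuation usually suffices |
| `rate_floor` | lower rate bound | 1e-12 | subst/site/My |

## Cross-validation

For a cell (*k*, λ): the reference tree is dated in full (observed crown
height, OCH, of the focal clade); each terminal is deleted in turn, the
pruned tree re-dated under the same parameters, and the focal crown height
re-read (PCH). The score is CV = Σ<sub>m</sub>(OCH − PCH<sub>m</sub>)²/OCH,
in My, with no further normalization. All terminals are deleted one at a
time; the only exclusions are the degeneracy rules above plus deletions
leaving fewer than two focal terminals, each logged. The grid argmin (ties:
smaller *k*, then smaller λ) selects the clock configuration; λ values are
exact ninths internally and reported to two decimals (grid point 3/9 prints
as 0.33).

**Known degeneracy.** On synthetic data generated exactly under the fitted
model class, this crown-height-stability score *decreases* with *k*: as the
number of categories grows toward saturation, the likelihood constrains the
ages less and less and the focal crown height settles against its
calibration box — stable under deletion, but no longer informed by the
data. The CV score cannot distinguish "stable because well-estimated" from
"stable because pinned". Consequently the regularization property one might
expect (selected *k* ≤ generating *k*) fails on the package's own
benchmarks, and the test suite documents this with an intentionally failing
test; with real data, model misfit appears to supply the instability that
makes small *k* win. Users should treat the CV surface as a sensitivity
map, inspect it whole (the plotting helper mirrors the one-panel-per-λ
layout), and be suspicious of argmin cells at large *k* whose OCH sits on a
calibration bound.

## Ensembles

One tMRCA per (tree, grid cell) over any collection of tree sets.
Summaries use linear interpolation between order statistics (the "type 7"
quantile convention); the "central 75%" interval is [12.5th, 87.5th]
percentile; the below-threshold fraction uses strict inequality
(tMRCA < threshold). Non-converged fits are included but flagged, with a
converged-only switch; failures (trees that cannot be dated) are logged,
and the record-count identity n = Σ trees × cells − failures is asserted on
every run. Histograms use 50 equal-width bins on log10(My), since tMRCA
ensembles typically span several orders of magnitude. Records and summary
export as TSV, byte-identical across reruns with the same seed.

## Synthetic benchmarks

The generator emulates the statistical situation the analysis is designed
for: a genus-and-above backbone (Yule topology rescaled to a chosen root
age) carrying one densely sampled shallow clade (grafted in place of a
terminal, crown age fixed), discrete-category rates inherited along the
tree with switch probability 0.2, Poisson substitution noise at alignment
length *s*, calibration boxes drawn around true ages (always containing
them; one point expressed in the stem convention to exercise both roles),
and bootstrap-like replicates via Poisson length redraws plus random NNI
moves. Two profiles: `toy` (8 tips, 3-tip focal clade, 4 calibrations,
s = 1000) and `paperlike` (56 tips, 11-tip focal clade, 8 calibrations,
s = 3754, root age 250 My, rates 0.001/0.004 subst/site/My).

What the generator does **not** emulate: sequence-level processes (no
alignments; noise enters at branch-length level where the likelihood
operates), alignment or tree-estimation error beyond NNI perturbation,
among-site rate variation, and any model misspecification — rates really
are drawn from *k* categories and counts really are Poisson. Passing
recovery tests therefore demonstrate correctness of the estimator under
its own assumptions, not robustness on real data; the CV degeneracy above
shows the flip side of that fidelity.

## Problem sizes used by the test suite

Chosen to exercise the full design while staying desk-sized: the
chronogram-count identity (1 optimal + 6 alternative + 200 bootstrap trees
× the 90-cell grid = 18,630 chronograms) runs end-to-end on the toy
profile; the study-scale recovery benchmark runs 10 seeds of the
`paperlike` profile with the grid thinned to *k* ∈ {2,3,4,6,8,10} ×
λ ∈ {0, 1/3, 2/3, 1} and `max_iter` 150 (the ascent's tail beyond that
moves ages by under 0.1%); the 40-tip recovery check pools node errors
over 5 seeded instances at s = 10000. `scripts/acceptance.py` reruns the
design at a user seed and writes the measured counts, CV argmin, tMRCA
summaries and recovery errors.

## Limitations

* Calibration boxes are uniform truncations; no soft densities.
* The discrete clock shares *k* rates globally; no per-branch relaxed
  models or correlated-rate penalties.
* The CV selection inherits the crown-height degeneracy described above.
* Block-coordinate ascent is monotone but local; the strict-clock
  continuation removes the worst basins, yet occasional fits remain
  non-converged at `max_iter` and are flagged rather than re-run.
* Trees are used as given: no rerooting, no tree search, no support
  recomputation.
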