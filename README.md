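# plclock

Penalized-likelihood molecular dating with a discrete-rate clock,
cross-validated smoothing, and chronogram ensembles.

## The problem

Given a rooted phylogram (branch lengths in expected substitutions per
site), how old is the most recent common ancestor of a focal set of
terminals? The question arises, for example, when deciding whether the
strains of a nuisance alga sampled in one region descend from a recent
invader (a tMRCA of decades) or from lineages that radiated in deep time (a
tMRCA of millions of years). Absolute ages require a molecular clock, but a
single rate rarely fits a tree spanning many genera, and the raw data never
pin rate and time separately — external calibrations must anchor the
timescale.

`plclock` implements the full workflow:

* **Dating model.** Each branch *i* carries an observed substitution load
  *x*<sub>*i*</sub> = *b*<sub>*i*</sub>·*s* (branch length times alignment
  length). A chronogram assigns every node an age (tips at 0) and every
  branch one of *k* shared rate categories with rates
  *r*<sub>1</sub>…*r*<sub>*k*</sub>. With branch duration *d*<sub>*i*</sub>
  and μ<sub>*i*</sub> = *r*<sub>*c*(*i*)</sub>·*d*<sub>*i*</sub>·*s*, the
  fit maximizes the penalized log-likelihood

  > Σ<sub>*i*</sub> [ *x*<sub>*i*</sub> log μ<sub>*i*</sub> − μ<sub>*i*</sub> − ln Γ(*x*<sub>*i*</sub>+1) ]
  > − λ · Σ<sub>(*i*,*j*) adjacent</sub> (log *r*<sub>*c*(*i*)</sub> − log *r*<sub>*c*(*j*)</sub>)²

  subject to hard [min, max] age boxes from fossil, geological or secondary
  calibrations. λ → ∞ approaches a strict clock; λ = 0 leaves rates
  unpenalized; *k* = 1 is the strict clock exactly.
* **Smoothing selection.** The (*k*, λ) pair is chosen by terminal-deletion
  cross-validation: CV = Σ(OCH − PCH)²/OCH, comparing the focal crown
  height on the full tree (OCH) with the heights refit after deleting one
  terminal at a time (PCH), over the default grid *k* ∈ {2,…,10},
  λ ∈ {0, 1/9, …, 1}.
* **Uncertainty integration.** The grid is applied to every tree in a
  collection (optimal + bootstrap topologies) and the resulting tMRCA
  distribution is summarized (quartiles, central-75% interval, fraction of
  chronograms below a threshold age).
* **Synthetic benchmarks.** A generator produces known-truth instances —
  Yule chronograms with a shallow focal clade, Markov-switching discrete
  rates, Poisson substitution noise, truth-containing calibration boxes and
  bootstrap-like tree perturbations — so the whole pipeline is testable
  without any sequence data.

## Worked example

Generate an 8-taxon benchmark with known node ages, then date it:

```sh
$ plclock simulate --profile toy --seed 7 --outdir bench
wrote toy benchmark (8 terminals, 4 calibrations, 10 bootstrap trees) to bench

$ plclock date --tree bench/phylogram.nwk --calibrations bench/calibrations.tsv \
    --outdir dated --k 2 --lam 0.33 --s 1000
Penalized-likelihood discrete-clock fit
===============================================
terminals:        8
alignment sites:  1000
k (categories):   2
lambda:           0.33
objective:        -32.320881
  log-likelihood: -30.791983
  penalty:        4.633023
converged:        True (4 iterations)
root age (My):    53.5635
  rate[1] = 0.00168042 subst/site/My  (4 branches)
  rate[2] = 0.00769871 subst/site/My  (10 branches)
```

The objective is the Poisson log-likelihood minus λ times the log-rate
roughness penalty; the two fitted category rates differ about 4.6-fold, and
the root lands at 53.6 My inside its calibration box. `dated/` now holds the
chronogram (Newick, branch lengths in My), a per-branch rate table, and a
JSON manifest with checksums.

Integrating over the bootstrap trees and a small (k, λ) grid:

```sh
$ plclock ensemble --trees bench/phylogram.nwk --trees bench/bootstrap.nwk \
    --calibrations bench/calibrations.tsv --focal bench/focal_taxa.txt \
    --outdir ens --grid-k 2,3 --grid-lambda 0,0.5,1 --s 1000 --threshold 1.0
count identity: 66 records = 11 trees x 6 cells - 0 failures (OK; expected 66 before failures)
 n   min_My    Q1_My     Q3_My    max_My  ...  threshold_My  n_below_threshold  frac_below_threshold
66 3.007334 3.937446 43.375038 60.370508 ...           1.0                  0                   0.0
```

Every (tree, grid-cell) pair yields one chronogram and one focal-clade
tMRCA; here none of the 66 estimates falls below 1 My, so a
recent-origin scenario for the focal clade finds no support in this
(synthetic) data. The same objects are available as a library:

```python
from plclock import ClockModel, read_newick, load_calibration_table, resolve_calibrations

tree = read_newick(open("bench/phylogram.nwk").read())
points = load_calibration_table("bench/calibrations.tsv")
model = ClockModel(tree, resolve_calibrations(tree, points), s=1000)
result = model.fit(k=2, lam=1/3)   # ChronogramResults
print(result.summary())
result.chronogram()                # ultrametric PhyloTree, lengths in My
```

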