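"""Penalized-likelihood discrete-clock fitting."""

import math

import numpy as np
import pytest

from plclock import (
    ClockConfig,
    ClockModel,
    FitError,
    InfeasibleConstraintsError,
    ResolvedConstraint,
    crown_height,
    fit_chronogram,
    pl_objective,
    read_newick,
    resolve_calibrations,
)
from plclock.simulate import (
    assign_rates,
    graft_focal_clade,
    simulate_chronogram,
    simulate_phylogram,
    _draw_calibrations,
)

from conftest import pin_root, strict_clock_phylogram


def straight_line_objective(tree, ages, rates, assignment, s, lam):
    """Independent re-summation of the three objective terms (oracle)."""
    ll = 0.0
    for node in tree.preorder():
        if node.parent is None:
            continue
        x = node.length * s
        d = ages.get(node.parent, 0.0) - ages.get(node, 0.0)
        mu = rates[assignment[node]] * d * s
        if x > 0:
            ll += x * math.log(mu) - mu - math.lgamma(x + 1.0)
        else:
            ll += -mu
    pen = 0.0
    for node in tree.preorder():
        if node.parent is None or node.parent.parent is None:
            continue  # root children handled below
        diff = math.log(rates[assignment[node]]) - math.log(
            rates[assignment[node.parent]]
        )
        pen += diff * diff
    kids = tree.root.children
    for i in range(len(kids)):
        for j in range(i + 1, len(kids)):
            diff = math.log(rates[assignment[kids[i]]]) - math.log(
                rates[assignment[kids[j]]]
            )
            pen += diff * diff
    return ll - lam * pen, ll, pen


class TestObjective:
    def test_matches_straight_line_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(10):
            chrono = simulate_chronogram(12, 30.0, seed=100 + trial)
            k = int(rng.integers(1, 4))
            rates = sorted(rng.uniform(0.001, 0.02, size=k))
            br = assign_rates(chrono, k, rates, switch_prob=0.3, seed=trial)
            phylo = simulate_phylogram(chrono, br, s=2000, seed=trial)
            ages_true = chrono.node_ages()
            # map truth onto the phylogram copy (same preorder)
            ages = {}
            assignment = {}
            for old, new in zip(chrono.preorder(), phylo.preorder()):
                ages[new] = ages_true[old]
                if old.parent is not None:
                    assignment[new] = br[old][0]
            lam = float(rng.uniform(0, 2))
            cfg = ClockConfig(k=k, lam=lam, s=2000)
            got = pl_objective(phylo, ages, rates, assignment, cfg)
            want = straight_line_objective(phylo, ages, rates, assignment, 2000, lam)
            assert got[0] == pytest.approx(want[0], rel=1e-12, abs=1e-9)
            assert got[1] == pytest.approx(want[1], rel=1e-12, abs=1e-9)
            assert got[2] == pytest.approx(want[2], rel=1e-12, abs=1e-9)

    def test_single_category_has_zero_penalty(self):
        tree = read_newick("((A:0.1,B:0.2):0.1,C:0.3);")
        ages = {tree.root: 10.0, tree.mrca({"A", "B"}): 5.0}
        assignment = {n: 0 for n in tree.preorder() if n.parent is not None}
        for lam in (0.0, 0.5, 7.0):
            obj, ll, pen = pl_objective(
                tree, ages, [0.01], assignment, ClockConfig(k=1, s=100, lam=lam)
            )
            assert pen == 0.0
            assert obj == ll

    def test_two_tip_closed_form(self):
        # b = 0.1 per tip, s = 100, root age 10, rate 0.01: x = 10, mu = 10
        tree = read_newick("(A:0.1,B:0.1);")
        ages = {tree.root: 10.0}
        assignment = {n: 0 for n in tree.preorder() if n.parent is not None}
        obj, ll, pen = pl_objective(
            tree, ages, [0.01], assignment, ClockConfig(k=1, s=100, lam=0.0)
        )
        per_branch = 10 * math.log(10) - 10 - math.lgamma(11)
        assert ll == pytest.approx(2 * per_branch, rel=1e-12)

    def test_zero_duration_with_substitutions_is_minus_inf(self):
        tree = read_newick("(A:0.1,B:0.1);")
        obj, ll, pen = pl_objective(
            tree,
            {tree.root: 0.0},
            [0.01],
            {n: 0 for n in tree.preorder() if n.parent is not None},
            ClockConfig(k=1, s=100),
        )
        assert obj == -math.inf

    def test_ordering_violation_errors(self, basic_tree):
        ages = {basic_tree.root: 1.0, basic_tree.mrca({"A", "B"}): 2.0}
        assignment = {
            n: 0 for n in basic_tree.preorder() if n.parent is not None
        }
        with pytest.raises(ValueError, match="parent"):
            pl_objective(basic_tree, ages, [0.01], assignment, ClockConfig(k=1))


class TestFit:
    def test_noiseless_strict_clock_recovers_truth(self):
        chrono = simulate_chronogram(15, 40.0, seed=2)
        phylo = strict_clock_phylogram(chrono, rate=0.005)
        result = fit_chronogram(
            phylo, pin_root(phylo, 40.0), ClockConfig(k=1, lam=0.0, s=10000)
        )
        truth = chrono.node_ages()
        fitted = result.ages
        for old, new in zip(chrono.preorder(), phylo.preorder()):
            if old.is_leaf:
                continue
            assert fitted[new] == pytest.approx(truth[old], rel=1e-6, abs=1e-6 * 40)
        assert result.rates[0] == pytest.approx(0.005, rel=1e-6)

    def test_two_tip_rate_is_x_over_T(self):
        tree = read_newick("(A:0.13,B:0.13);")
        result = fit_chronogram(
            tree, pin_root(tree, 13.0), ClockConfig(k=1, lam=0.0, s=200)
        )
        assert result.rates[0] == pytest.approx(0.13 / 13.0, rel=1e-9)

    def test_objective_identity_and_boxes(self, paperlike):
        cons = resolve_calibrations(paperlike.phylogram, paperlike.calibrations)
        model = ClockModel(paperlike.phylogram, cons, s=paperlike.s)
        result = model.fit(k=2, lam=0.5)
        assert result.objective == pytest.approx(
            result.loglik - 0.5 * result.penalty, abs=1e-9 * abs(result.loglik)
        )
        ages = result.ages
        for c in cons:
            assert c.min_age - 1e-6 <= ages[c.node] <= c.max_age + 1e-6
        for node in paperlike.phylogram.preorder():
            if node.parent is not None:
                assert ages[node.parent] >= ages[node] - 1e-9
        assert result.chronogram().is_ultrametric()

    def test_warm_restart_does_not_decrease_objective(self, toy):
        cons = resolve_calibrations(toy.phylogram, toy.calibrations)
        model = ClockModel(toy.phylogram, cons, s=toy.s)
        first = model.fit(k=2, lam=0.5)
        again = model.fit(k=2, lam=0.5, init=first)
        assert again.objective >= first.objective - 1e-9 * abs(first.objective)

    def test_strict_clock_limit_all_rates_equal(self, toy):
        cons = resolve_calibrations(toy.phylogram, toy.calibrations)
        result = ClockModel(toy.phylogram, cons, s=toy.s).fit(k=1, lam=0.0)
        branch_rates = {result.branch_rate(n) for n in result.categories}
        assert len(branch_rates) == 1

    def test_unpenalized_saturated_limit_fits_each_branch(self, toy):
        # lambda = 0 and one category per branch: rate ~ b_i / d_i exactly
        cons = resolve_calibrations(toy.phylogram, toy.calibrations)
        model = ClockModel(toy.phylogram, cons, s=toy.s)
        n_branches = sum(
            1 for n in toy.phylogram.preorder() if n.parent is not None
        )
        result = model.fit(k=n_branches, lam=0.0, max_iter=2000)
        for node in toy.phylogram.preorder():
            if node.parent is None or node.length == 0:
                continue
            d = result.ages[node.parent] - result.ages[node]
            if d > 1e-6:
                assert result.branch_rate(node) == pytest.approx(
                    node.length / d, rel=1e-3
                )

    def test_rate_variance_non_increasing_in_lambda(self, paperlike):
        cons = resolve_calibrations(paperlike.phylogram, paperlike.calibrations)
        model = ClockModel(paperlike.phylogram, cons, s=paperlike.s)
        variances = []
        for lam in (0.0, 0.5, 1.0, 10.0, 1000.0):
            result = model.fit(k=3, lam=lam)
            rates = [result.branch_rate(n) for n in result.categories]
            variances.append(float(np.var(rates)))
        for lo, hi in zip(variances[1:], variances[:-1]):
            assert lo <= hi + 1e-6

    def test_time_unit_equivariance(self, toy):
        factor = 3.7
        cons = resolve_calibrations(toy.phylogram, toy.calibrations)
        model = ClockModel(toy.phylogram, cons, s=toy.s)
        base = model.fit(k=2, lam=0.5)
        scaled_cons = [
            ResolvedConstraint(
                node=c.node,
                min_age=c.min_age * factor,
                max_age=c.max_age * factor,
                provenance=c.provenance,
            )
            for c in cons
        ]
        scaled = ClockModel(toy.phylogram, scaled_cons, s=toy.s).fit(k=2, lam=0.5)
        for node, age in base.ages.items():
            assert scaled.ages[node] == pytest.approx(
                age * factor, rel=1e-4, abs=1e-6
            )
        np.testing.assert_allclose(scaled.rates, base.rates / factor, rtol=1e-4)

    def test_parameter_recovery_40_tip_benchmark(self):
        # k=2 truth, s=10000, 8 calibration boxes containing true ages;
        # node-age errors pooled over 5 seeded instances
        errs = []
        for seed in range(5):
            backbone = simulate_chronogram(36, 120.0, seed=seed)
            chrono, focal = graft_focal_clade(backbone, 5, 8.0, seed=seed)
            br = assign_rates(chrono, 2, (0.002, 0.007), switch_prob=0.2, seed=seed)
            phylo = simulate_phylogram(chrono, br, s=10000, seed=seed)
            points = _draw_calibrations(chrono, focal, 8, seed=seed)
            cons = resolve_calibrations(phylo, points)
            result = ClockModel(phylo, cons, s=10000).fit(k=2, lam=0.5)
            truth = {
                chrono.leafset(n): a
                for n, a in chrono.node_ages().items()
                if not n.is_leaf
            }
            errs += [
                abs(a - truth[phylo.leafset(n)]) / truth[phylo.leafset(n)]
                for n, a in result.ages.items()
                if not n.is_leaf and truth[phylo.leafset(n)] > 1e-6
            ]
        assert float(np.median(errs)) <= 0.15

    def test_deterministic_for_fixed_seed(self, toy):
        cons = resolve_calibrations(toy.phylogram, toy.calibrations)
        model = ClockModel(toy.phylogram, cons, s=toy.s)
        a = model.fit(k=2, lam=0.5, n_starts=3, seed=7)
        b = model.fit(k=2, lam=0.5, n_starts=3, seed=7)
        assert a.objective == b.objective
        assert all(a.ages[n] == b.ages[n] for n in a.ages)


class TestFitErrors:
    def test_infeasible_box_names_both_constraints(self, basic_tree):
        ab = basic_tree.mrca({"A", "B"})
        cons = [
            ResolvedConstraint(node=basic_tree.root, min_age=0, max_age=5, provenance="shallow root"),
            ResolvedConstraint(node=ab, min_age=10, max_age=20, provenance="deep clade"),
        ]
        with pytest.raises(InfeasibleConstraintsError) as err:
            ClockModel(basic_tree, cons, s=100)
        assert "deep clade" in str(err.value)
        assert "shallow root" in str(err.value)

    def test_unbounded_root_errors(self, basic_tree):
        model = ClockModel(basic_tree, [], s=100)
        with pytest.raises(InfeasibleConstraintsError, match="unbounded"):
            model.fit(k=1, lam=0.0)

    def test_k_exceeding_branches_errors(self, basic_tree):
        model = ClockModel(basic_tree, pin_root(basic_tree, 5.0), s=100)
        with pytest.raises(FitError, match="k="):
            model.fit(k=40, lam=0.0)


class TestResultsSurface:
    def test_crown_height_examples(self, toy):
        cons = resolve_calibrations(toy.phylogram, toy.calibrations)
        result = ClockModel(toy.phylogram, cons, s=toy.s).fit(k=2, lam=0.5)
        all_taxa = set(toy.phylogram.leaf_labels())
        assert result.crown_height(all_taxa) == pytest.approx(result.root_age)
        assert crown_height(result, toy.focal_taxa) == pytest.approx(
            result.ages[toy.phylogram.mrca(toy.focal_taxa)]
        )

    def test_summary_and_branch_table(self, toy):
        cons = resolve_calibrations(toy.phylogram, toy.calibrations)
        result = ClockModel(toy.phylogram, cons, s=toy.s).fit(k=2, lam=0.5)
        text = result.summary()
        assert "k (categories):   2" in text
        assert "root age" in text
        table = result.to_branch_table()
        n_branches = sum(1 for n in toy.phylogram.preorder() if n.parent)
        assert len(table) == n_branches
        assert {"duration_My", "rate", "category"} <= set(table.columns)
        assert (table["duration_My"] >= -1e-12).all()
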