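"""Dated DTL parsimony: DP vs oracle, cost structure, amalgamation."""

import numpy as np
import pytest

from paleophos import (
    CostScheme,
    GeneTree,
    build_ccp,
    brute_force_reconcile,
    compute_time_slices,
    cost_sensitivity,
    lca_duplication_loss_cost,
    optimal_cost,
    parse_dated_newick,
    reconcile,
)
from paleophos.simulate import (
    SimParams,
    simulate_dated_tree,
    simulate_gene_family,
    simulate_tree_sample,
)

from conftest import surviving_family


def random_small_instance(rng, max_leaves=4):
    """A surviving simulated family on a <=4-leaf species tree."""
    while True:
        nt = int(rng.integers(2, max_leaves + 1))
        tree = simulate_dated_tree(nt, 4.0, seed=int(rng.integers(2**31 - 1)))
        params = SimParams(
            dup_rate=0.15, transfer_rate=0.15, loss_rate=0.1,
            seed=int(rng.integers(2**31 - 1)), n_tips=nt,
        )
        g, hist = simulate_gene_family(tree, params)
        if g is not None and 2 <= g.n_leaves <= max_leaves:
            return tree, g, hist


class TestCostScheme:
    def test_defaults_are_3210(self):
        cs = CostScheme()
        assert (cs.transfer, cs.duplication, cs.loss, cs.speciation) == (3, 2, 1, 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            CostScheme(loss=-1)


class TestReconcileBasics:
    def test_congruent_two_leaf_costs_zero(self, two_leaf_tree):
        rec = reconcile(GeneTree.from_newick("(a_A,b_B);"), two_leaf_tree)
        assert rec.total_cost == 0
        assert rec.counts() == {"speciation": 1, "duplication": 0, "transfer": 0, "loss": 0}
        rec.validate(two_leaf_tree)

    def test_incongruent_three_leaf_matches_oracle(self, three_leaf_tree):
        g = GeneTree.from_newick("((a_A,c_C),b_B);")
        rec = reconcile(g, three_leaf_tree)
        oracle = brute_force_reconcile(g, three_leaf_tree, max_events=3)
        assert rec.total_cost == pytest.approx(oracle.total_cost) == pytest.approx(3.0)
        rec.validate(three_leaf_tree)

    def test_duplicated_family_costs_one_duplication(self, two_leaf_tree):
        g = GeneTree.from_newick("((a_A,b_B),(c_A,d_B));")
        rec = reconcile(g, two_leaf_tree)
        assert rec.total_cost == pytest.approx(2.0)
        assert rec.counts()["duplication"] == 1

    def test_unknown_genome_rejected(self, two_leaf_tree):
        with pytest.raises(ValueError, match="Z"):
            reconcile(GeneTree.from_newick("(a_A,b_Z);"), two_leaf_tree)

    def test_cost_identity_and_contemporaneity(self):
        tree = simulate_dated_tree(12, 4.0, seed=21)
        g, _ = surviving_family(tree, 0.2, 0.3, 0.2, seed=5)
        rec = reconcile(g, tree)
        rec.validate(tree, compute_time_slices(tree))  # cost identity + slices
        c = rec.counts()
        expect = 3 * c["transfer"] + 2 * c["duplication"] + 1 * c["loss"]
        assert rec.total_cost == pytest.approx(expect)

    def test_scaling_all_costs_scales_optimum(self, three_leaf_tree):
        g = GeneTree.from_newick("((a_A,c_C),b_B);")
        base = optimal_cost(g, three_leaf_tree)
        assert optimal_cost(g, three_leaf_tree, CostScheme().scaled(2.5)) == pytest.approx(2.5 * base)

    def test_root_search_no_worse_than_given_rooting(self, three_leaf_tree):
        g = GeneTree.from_newick("((a_A,c_C),b_B);")
        free = optimal_cost(g, three_leaf_tree, rooted=False)
        assert free <= optimal_cost(g, three_leaf_tree) + 1e-9


class TestAgainstBruteForce:
    def test_dp_equals_oracle_on_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(30):
            tree, g, _ = random_small_instance(rng)
            dp = optimal_cost(g, tree)
            oracle = brute_force_reconcile(g, tree, max_events=4)
            assert dp == pytest.approx(oracle.total_cost), (
                g.to_newick(), tree.newick()
            )

    def test_oracle_refuses_large_instances(self):
        tree = simulate_dated_tree(6, 4.0, seed=0)
        g, _ = surviving_family(tree, 0.0, 0.0, 0.0, seed=0)
        with pytest.raises(ValueError, match="oracle"):
            brute_force_reconcile(g, tree)


class TestDuplicationLossLimit:
    def test_dl_limit_matches_lca_closed_form(self):
        rng = np.random.default_rng(77)
        no_transfer = CostScheme(transfer=1e9)
        checked = 0
        while checked < 25:
            nt = int(rng.integers(3, 7))
            tree = simulate_dated_tree(nt, 4.0, seed=int(rng.integers(2**31 - 1)))
            params = SimParams(
                dup_rate=0.3, transfer_rate=0.0, loss_rate=0.2,
                seed=int(rng.integers(2**31 - 1)), n_tips=nt,
            )
            g, _ = simulate_gene_family(tree, params)
            if g is None or g.n_leaves < 2:
                continue
            dp = optimal_cost(g, tree, no_transfer)
            closed = lca_duplication_loss_cost(g, tree, no_transfer)
            assert dp == pytest.approx(closed)
            checked += 1

    def test_oracle_matches_lca_form_when_transfers_disabled(self, three_leaf_tree):
        g = GeneTree.from_newick("((a_A,c_C),b_B);")
        no_transfer = CostScheme(transfer=np.inf)
        oracle = brute_force_reconcile(g, three_leaf_tree, no_transfer, max_events=4)
        assert oracle.total_cost == pytest.approx(
            lca_duplication_loss_cost(g, three_leaf_tree, no_transfer)
        )


class TestTrueHistoryLowerBound:
    def test_inferred_cost_never_exceeds_true_history_cost(self):
        scheme = CostScheme()
        for seed, rates in enumerate([(0.1, 0.1, 0.1), (0.3, 0.1, 0.0), (0.0, 0.3, 0.3)]):
            tree = simulate_dated_tree(15, 4.0, seed=seed)
            g, hist = surviving_family(tree, *rates, seed=seed * 10)
            assert optimal_cost(g, tree, scheme) <= hist.parsimony_cost(scheme) + 1e-9

    def test_transfer_priced_out_by_duplication(self, two_leaf_tree):
        # duplication-explainable family: huge transfer cost must not
        # introduce transfers into the backtrack
        g = GeneTree.from_newick("((a_A,b_B),(c_A,d_B));")
        rec = reconcile(g, two_leaf_tree, CostScheme(transfer=100))
        assert rec.counts()["transfer"] == 0
        assert rec.counts()["duplication"] == 1


class TestCostSensitivity:
    def test_grid_includes_base_tau(self, three_leaf_tree):
        g = GeneTree.from_newick("((a_A,c_C),b_B);")
        recs = cost_sensitivity(g, three_leaf_tree, hgt_grid=[2, 4, 6])
        assert sorted(recs) == [2.0, 3.0, 4.0, 6.0]

    def test_congruent_input_identical_everywhere(self, two_leaf_tree):
        g = GeneTree.from_newick("(a_A,b_B);")
        recs = cost_sensitivity(g, two_leaf_tree, hgt_grid=[2, 4, 6])
        for rec in recs.values():
            assert rec.total_cost == 0
            assert sum(rec.counts().values()) == 1  # the lone speciation

    def test_optimum_nondecreasing_in_tau(self):
        tree = simulate_dated_tree(10, 4.0, seed=31)
        g, _ = surviving_family(tree, 0.1, 0.3, 0.1, seed=8)
        costs = [optimal_cost(g, tree, CostScheme(transfer=tau)) for tau in (2, 3, 4, 6)]
        assert costs == sorted(costs)

    def test_empty_grid_rejected(self, two_leaf_tree):
        with pytest.raises(ValueError, match="empty"):
            cost_sensitivity(GeneTree.from_newick("(a_A,b_B);"), two_leaf_tree, hgt_grid=[])


class TestMonotonicityInEachCost:
    def test_optimal_cost_nondecreasing_in_every_event_cost(self):
        tree = simulate_dated_tree(8, 4.0, seed=13)
        g, _ = surviving_family(tree, 0.2, 0.2, 0.1, seed=3)
        base = CostScheme()
        for fieldname in ("transfer", "duplication", "loss", "speciation"):
            prev = None
            for v in (0.5, 1.5, 3.0, 6.0):
                cs = CostScheme(**{**base.__dict__, fieldname: v})
                c = optimal_cost(g, tree, cs)
                if prev is not None:
                    assert c >= prev - 1e-9
                prev = c


class TestAmalgamation:
    def test_amalgamated_cost_at_most_min_per_tree(self):
        tree = simulate_dated_tree(8, 4.0, seed=19)
        g, _ = surviving_family(tree, 0.1, 0.2, 0.1, seed=7)
        sample = simulate_tree_sample(g, 2.0, 30, seed=4)
        table = build_ccp(sample)
        amalgamated = optimal_cost(table, tree)
        per_tree = min(optimal_cost(t, tree) for t in sample)
        assert amalgamated <= per_tree + 1e-9

    def test_single_tree_ccp_equals_tree_dp(self, three_leaf_tree):
        g = GeneTree.from_newick("((a_A,c_C),b_B);")
        sample = simulate_tree_sample(g, 0.0, 10, seed=0)
        table = build_ccp(sample)
        assert optimal_cost(table, three_leaf_tree) == pytest.approx(
            optimal_cost(g, three_leaf_tree)
        )
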