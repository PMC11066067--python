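"""Ground-truth simulator: determinism, invariants, counting identities."""

import numpy as np
import pytest

from paleophos import (
    CostScheme,
    build_ccp,
    compute_time_slices,
    date_events,
    discard_burnin,
    first_appearance,
    optimal_cost,
    reconcile,
)
from paleophos.genetree import genome_of_leaf
from paleophos.simulate import (
    SimParams,
    simulate_abundance,
    simulate_dated_tree,
    simulate_gene_family,
    simulate_scored_tree,
    simulate_tree_sample,
    write_fixture_set,
)


class TestSimulateDatedTree:
    def test_two_tips_is_cherry_at_root_age(self):
        t = simulate_dated_tree(2, 3.5, seed=0)
        assert len(t.leaves()) == 2
        assert t.root_age == pytest.approx(3.5)

    def test_deterministic_given_seed(self):
        a = simulate_dated_tree(12, 4.0, seed=99)
        b = simulate_dated_tree(12, 4.0, seed=99)
        assert a == b
        assert a != simulate_dated_tree(12, 4.0, seed=100)

    def test_invariants_and_slices_at_size_twenty(self):
        t = simulate_dated_tree(20, 4.0, seed=6)  # DatedTree validates itself
        si = compute_time_slices(t)
        assert sum(hi - lo for lo, hi, _ in si.slices) == pytest.approx(4.0)
        assert t.is_binary()

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            simulate_dated_tree(1, 4.0)
        with pytest.raises(ValueError):
            simulate_dated_tree(5, -1.0)


class TestSimulateGeneFamily:
    def test_zero_rates_gives_congruent_tree_and_speciations_only(self):
        tree = simulate_dated_tree(10, 4.0, seed=1)
        g, hist = simulate_gene_family(tree, SimParams(dup_rate=0, transfer_rate=0, loss_rate=0, seed=0))
        assert sorted(genome_of_leaf(lb) for lb in g.leaf_labels()) == sorted(tree.leaf_labels())
        assert set(hist.event_counts()) == {"speciation"}
        assert hist.origination_date == pytest.approx(4.0)
        assert optimal_cost(g, tree) == pytest.approx(0.0)

    def test_duplication_counting_identity_without_loss(self):
        # with no loss and root origination, every duplication on branch b
        # contributes one extra copy per species leaf below b
        tree = simulate_dated_tree(6, 4.0, seed=2)
        g, hist = simulate_gene_family(
            tree, SimParams(dup_rate=0.4, transfer_rate=0.0, loss_rate=0.0, seed=5)
        )
        extra = sum(
            len(tree.clade_leaves(e.branch))
            for e in hist.events
            if e.etype == "duplication"
        )
        assert g.n_leaves == len(tree.leaves()) + extra
        assert hist.event_counts().get("duplication", 0) >= 1

    def test_deterministic_given_seed(self):
        tree = simulate_dated_tree(8, 4.0, seed=3)
        p = SimParams(dup_rate=0.2, transfer_rate=0.2, loss_rate=0.1, seed=7)
        g1, h1 = simulate_gene_family(tree, p)
        g2, h2 = simulate_gene_family(tree, p)
        assert g1.to_newick() == g2.to_newick()
        assert h1.events == h2.events

    def test_transfer_endpoints_contemporaneous(self):
        tree = simulate_dated_tree(12, 4.0, seed=4)
        p = SimParams(dup_rate=0.1, transfer_rate=0.5, loss_rate=0.1, seed=9)
        g, hist = simulate_gene_family(tree, p)
        for e in hist.events:
            if e.etype != "transfer":
                continue
            for b in (e.branch, e.recipient):
                lo, hi = tree.branch_interval(b)
                assert lo < e.date < hi

    def test_all_extinct_family_is_valid_empty_outcome(self):
        tree = simulate_dated_tree(4, 4.0, seed=5)
        p = SimParams(dup_rate=0.0, transfer_rate=0.0, loss_rate=20.0, seed=1)
        g, hist = simulate_gene_family(tree, p)
        assert g is None
        assert hist.empty

    def test_true_history_cost_is_feasible_upper_bound(self):
        scheme = CostScheme()
        n_checked = 0
        for seed in range(12):
            tree = simulate_dated_tree(10, 4.0, seed=seed)
            p = SimParams(dup_rate=0.2, transfer_rate=0.2, loss_rate=0.2, seed=seed)
            g, hist = simulate_gene_family(tree, p)
            if g is None or g.n_leaves < 2:
                continue
            assert optimal_cost(g, tree, scheme) <= hist.parsimony_cost(scheme) + 1e-9
            n_checked += 1
        assert n_checked >= 5


class TestSimulateTreeSample:
    def test_strength_zero_identical_trees_and_unit_ccp(self):
        tree = simulate_dated_tree(8, 4.0, seed=6)
        g, _ = simulate_gene_family(tree, SimParams(seed=3, dup_rate=0.1, transfer_rate=0.1, loss_rate=0))
        sample = simulate_tree_sample(g, 0.0, 15, seed=2)
        assert len({t.to_newick() for t in sample}) == 1
        table = build_ccp(sample)
        assert all(f == pytest.approx(1.0) for f in table.clade_freq.values())
        assert table.clades() == g.clades()

    def test_large_strength_creates_novel_clades(self):
        tree = simulate_dated_tree(10, 4.0, seed=7)
        g, _ = simulate_gene_family(tree, SimParams(seed=8, dup_rate=0.2, transfer_rate=0.1, loss_rate=0))
        sample = simulate_tree_sample(g, 5.0, 25, seed=3)
        table = build_ccp(sample)
        assert table.clades() - g.clades()

    def test_burnin_composes_with_sampling(self):
        tree = simulate_dated_tree(6, 4.0, seed=8)
        g, _ = simulate_gene_family(tree, SimParams(seed=2, dup_rate=0.1, transfer_rate=0, loss_rate=0))
        sample = simulate_tree_sample(g, 1.0, 100, seed=4)
        assert len(discard_burnin(sample, 0.25)) == 75


class TestSimulateScoredTree:
    def test_family_is_separable_and_monophyletic(self):
        scored_tree, truth = simulate_scored_tree(seed=0)
        fam_scores = [scored_tree.scores[lf] for lf in truth]
        out_scores = [
            s for lf, s in scored_tree.scores.items() if lf not in truth
        ]
        assert min(fam_scores) > scored_tree.threshold > max(out_scores)
        assert truth in scored_tree.tree.clades()


class TestSimulateAbundance:
    def test_noiseless_points_exactly_on_line(self):
        p = SimParams(abundance_noise_sd=0.0, seed=5)
        t = simulate_abundance(p)
        x = t.data["phosphate_uM"]
        y = t.data["gene1"]
        assert np.allclose(y, p.abundance_intercept + p.abundance_slope * x)

    def test_deterministic_given_seed(self):
        p = SimParams(seed=6)
        assert simulate_abundance(p).data.equals(simulate_abundance(p).data)

    def test_phosphate_within_survey_range(self):
        t = simulate_abundance(SimParams(seed=7))
        x = t.data["phosphate_uM"]
        assert x.min() >= 0 and x.max() <= 3.29
        assert len(t.data) == 139


class TestEndToEndZeroRates:
    def test_pipeline_returns_root_speciation_chronology(self):
        tree = simulate_dated_tree(10, 4.0, seed=10)
        g, hist = simulate_gene_family(
            tree, SimParams(dup_rate=0, transfer_rate=0, loss_rate=0, seed=0)
        )
        sample = simulate_tree_sample(g, 0.0, 40, seed=1)
        table = build_ccp(discard_burnin(sample, 0.25))
        rec = reconcile(table, tree)
        counts = rec.counts()
        assert counts["duplication"] == counts["transfer"] == counts["loss"] == 0
        log = date_events(rec, tree)
        assert {e.etype for e in log} == {"speciation"}
        est = first_appearance(log, "gene")
        assert est.date == pytest.approx(tree.root_age)
        assert est.etype == "speciation"


class TestFixtureWriter:
    def test_written_formats_reload_consistently(self, tmp_path):
        from paleophos import parse_dated_newick
        from paleophos.ccp import read_tree_sample
        from paleophos.regression import AbundanceTable

        params = SimParams(seed=3, n_tips=8, dup_rate=0.1, transfer_rate=0.1, loss_rate=0.05)
        paths = write_fixture_set(tmp_path, params, sample_size=10)
        tree = parse_dated_newick(paths["species"].read_text())
        assert len(tree.leaves()) == 8
        sample = read_tree_sample(paths["sample"].read_text())
        assert len(sample) == 10
        table = AbundanceTable.from_tsv(paths["abundance"])
        assert "gene1" in table.gene_ids
        history = paths["history"].read_text().splitlines()
        assert history[0].startswith("etype\t")
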