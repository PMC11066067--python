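"""Bit-score propagation, clade retention, and presence accounting."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleophos import (
    GeneTree,
    ScoredTree,
    build_presence_matrix,
    count_presence,
    propagate_scores,
    select_retained_clade,
)
from paleophos.screen import read_hmmer_tblout
from paleophos.simulate import simulate_scored_tree


def scored(newick, scores, queries, threshold=None):
    return ScoredTree(
        tree=GeneTree.from_newick(newick),
        scores=scores,
        queries=frozenset(queries),
        threshold=threshold,
    )


class TestPropagateScores:
    def test_cherry_mean(self):
        st_ = scored("(A,B);", {"A": 10, "B": 20}, {"A"})
        out = propagate_scores(st_)
        assert out[frozenset("AB")] == pytest.approx(15.0)

    def test_descendant_leaf_mean_not_children_mean(self):
        st_ = scored("((A,B),C);", {"A": 10, "B": 20, "C": 30}, {"A"})
        out = propagate_scores(st_)
        assert out[frozenset("AB")] == pytest.approx(15.0)
        assert out[frozenset("ABC")] == pytest.approx(20.0)  # (10+20+30)/3

    def test_random_tree_against_brute_force(self):
        rng = np.random.default_rng(0)
        scored_tree, _ = simulate_scored_tree(n_family=30, n_outgroup=20, seed=14)
        out = propagate_scores(scored_tree)
        for clade, value in out.items():
            brute = np.mean([scored_tree.scores[lf] for lf in clade])
            assert value == pytest.approx(brute)

    def test_unscored_leaf_named(self):
        with pytest.raises(ValueError, match="B"):
            ScoredTree(
                tree=GeneTree.from_newick("(A,B);"),
                scores={"A": 1.0},
                queries=frozenset({"A"}),
            )

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10**5))
    def test_invariant_under_child_reordering(self, seed):
        rng = np.random.default_rng(seed)
        st_, _ = simulate_scored_tree(n_family=6, n_outgroup=5, seed=seed)
        out1 = propagate_scores(st_)
        # reverse every child list
        for n in st_.tree.postorder():
            n.children.reverse()
        out2 = propagate_scores(st_)
        assert out1 == out2


class TestSelectRetainedClade:
    def test_all_pass_retains_all(self):
        st_ = scored("((A,B),(C,D));", {k: 50 for k in "ABCD"}, {"A"}, threshold=10)
        assert select_retained_clade(st_) == frozenset("ABCD")

    def test_query_cherry_only(self):
        st_ = scored(
            "((A,B),(C,D));",
            {"A": 90, "B": 80, "C": 5, "D": 5},
            {"A", "B"},
            threshold=50,
        )
        assert select_retained_clade(st_) == frozenset("AB")

    def test_scattered_passers_against_brute_force_mrca(self):
        for seed in range(25):
            st_, _ = simulate_scored_tree(n_family=8, n_outgroup=8, seed=seed)
            got = select_retained_clade(st_)
            thr = st_.effective_threshold
            anchor = set(st_.queries) | {
                lf for lf, s in st_.scores.items() if s >= thr
            }
            # brute-force MRCA: smallest clade containing the anchor set
            clades = sorted(st_.tree.clades(), key=len)
            mrca_clade = next(c for c in clades if anchor <= c)
            assert got == mrca_clade

    def test_threshold_monotonicity(self):
        st_, _ = simulate_scored_tree(n_family=10, n_outgroup=10, seed=3)
        prev = None
        for thr in sorted({round(v) for v in st_.scores.values()} | {0, 250}):
            st_.threshold = thr
            got = select_retained_clade(st_)
            if prev is not None:
                assert got <= prev
            prev = got

    def test_default_threshold_is_min_query_score(self):
        st_ = scored("((A,B),C);", {"A": 70, "B": 40, "C": 90}, {"A", "B"})
        assert st_.effective_threshold == 40


class TestPresence:
    def test_single_leaf_presence(self):
        m = build_presence_matrix({"f1": ["x_G1"]}, ["G1", "G2", "G3"])
        assert list(m["f1"]) == [1, 0, 0]

    def test_presence_not_count(self):
        m = build_presence_matrix({"f1": ["x_G1", "y_G1"]}, ["G1", "G2"])
        assert m.loc["G1", "f1"] == 1

    def test_unknown_genome_rejected(self):
        with pytest.raises(ValueError, match="G9"):
            build_presence_matrix({"f1": ["x_G9"]}, ["G1"])

    def test_count_modes_on_small_matrix(self):
        m = pd.DataFrame([[1, 1], [1, 0], [0, 0]], columns=["f1", "f2"],
                         index=["g1", "g2", "g3"])
        assert count_presence(m, ["f1", "f2"], mode="all") == 1
        assert count_presence(m, ["f1", "f2"], mode="any") == 2
        assert count_presence(m, ["f1"], "all") == count_presence(m, ["f1"], "any") == 2

    def test_counts_against_brute_force_rows(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(
            rng.integers(0, 2, size=(30, 5)),
            columns=[f"f{i}" for i in range(5)],
            index=[f"g{i}" for i in range(30)],
        )
        fams = ["f0", "f2", "f4"]
        brute_all = sum(1 for _, row in m.iterrows() if all(row[f] for f in fams))
        brute_any = sum(1 for _, row in m.iterrows() if any(row[f] for f in fams))
        assert count_presence(m, fams, "all") == brute_all
        assert count_presence(m, fams, "any") == brute_any
        assert count_presence(m, fams, "all") <= count_presence(m, fams, "any")

    def test_unknown_family_rejected(self):
        m = pd.DataFrame([[1]], columns=["f1"], index=["g1"])
        with pytest.raises(ValueError, match="f9"):
            count_presence(m, ["f9"])


class TestTbloutReader:
    def test_simple_four_column(self):
        text = "# comment\nseq1 profA 1e-30 150.2\nseq2 profA 0.05 22.0\n"
        df = read_hmmer_tblout(io.StringIO(text))
        assert list(df["target"]) == ["seq1", "seq2"]
        assert df["bit_score"].tolist() == [150.2, 22.0]

    def test_full_tblout_layout(self):
        line = (
            "seq1 - profA PF0001 1e-30 150.2 0.1 1e-28 140.0 0.1 "
            "1 1 1 1 1 1 1 1 description here"
        )
        df = read_hmmer_tblout(io.StringIO(line))
        assert df.loc[0, "profile"] == "profA"
        assert df.loc[0, "evalue"] == 1e-30
        assert df.loc[0, "bit_score"] == 150.2
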