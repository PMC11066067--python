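"""Homolog screening by bit-score propagation on gene trees.

Profile-HMM searches return candidate homologs with bit scores and
e-values.  After building a tree over the candidates, internal nodes are
scored with the mean bit score of their descendant leaves, and the family
is delimited as the smallest monophyletic clade containing the query
sequences together with every leaf passing the profile's trusted bit-score
cutoff.  Retained leaves feed a genome x family presence matrix.

E-value pre-filtering (the upstream search's 0.1 threshold) is assumed to
have been applied before trees are built; it is not enforced here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

from .genetree import GeneTree, genome_of_leaf

__all__ = [
    "ScoredTree",
    "propagate_scores",
    "select_retained_clade",
    "build_presence_matrix",
    "count_presence",
    "read_hmmer_tblout",
]

EVALUE_THRESHOLD = 0.1  # upstream search-level cutoff (documented default)


@dataclass
class ScoredTree:
    """Gene tree whose leaves carry HMM bit scores (and e-values).

    ``threshold`` is the profile's trusted bit-score cutoff; when absent the
    minimum query bit score is used (conservative).  ``queries`` are the
    seed sequences known to belong to the family.
    """

    tree: GeneTree
    scores: dict  # leaf label -> bit score
    queries: frozenset
    evalues: dict = field(default_factory=dict)
    threshold: float | None = None

    def __post_init__(self):
        self.queries = frozenset(self.queries)
        leaves = frozenset(self.tree.leaf_labels())
        missing = leaves - set(self.scores)
        if missing:
            raise ValueError(f"unscored leaf: {sorted(missing)[0]!r}")
        if not self.queries:
            raise ValueError("query set is empty")
        if not self.queries <= leaves:
            bad = sorted(self.queries - leaves)
            raise ValueError(f"query labels not in tree: {bad}")
        if any(e < 0 for e in self.evalues.values()):
            raise ValueError("negative e-value")

    @property
    def effective_threshold(self) -> float:
        if self.threshold is not None:
            return float(self.threshold)
        return min(self.scores[q] for q in self.queries)


def propagate_scores(scored: ScoredTree) -> dict:
    """Score every clade with the mean bit score of its descendant leaves.

    Returns a map clade (frozenset of leaf labels) -> score; singleton
    clades keep their leaf score unchanged.
    """
    out = {}
    sums = {}
    for n in scored.tree.postorder():
        if n.is_leaf:
            sums[id(n)] = (scored.scores[n.label], 1, frozenset([n.label]))
        else:
            tot, cnt, acc = 0.0, 0, frozenset()
            for c in n.children:
                s, k, cl = sums[id(c)]
                tot, cnt, acc = tot + s, cnt + k, acc | cl
            sums[id(n)] = (tot, cnt, acc)
        tot, cnt, acc = sums[id(n)]
        out[acc] = tot / cnt
    return out


def select_retained_clade(scored: ScoredTree) -> frozenset:
    """Leaves of the MRCA of (queries ∪ leaves passing the bit-score
    threshold): the monophyletic family delimitation.  Everything outside
    that clade is discarded, even high-scoring leaves, because it falls
    outside the family's monophyletic boundary."""
    thr = scored.effective_threshold
    passers = {lf for lf, s in scored.scores.items() if s >= thr}
    anchor = set(scored.queries) | passers
    if not anchor:
        raise ValueError("no query leaves and no leaves pass the threshold")
    mrca = scored.tree.mrca(anchor)
    return scored.tree.leaf_labels_under(mrca)


def build_presence_matrix(
    retained: dict, genomes, genome_of=genome_of_leaf
) -> pd.DataFrame:
    """0/1 genome x family presence matrix from retained leaf sets.

    ``retained`` maps family id -> iterable of retained leaf labels; a
    genome is present in a family iff at least one retained leaf of that
    family comes from it (presence, not copy number).
    """
    genomes = list(genomes)
    if len(set(genomes)) != len(genomes):
        raise ValueError("duplicate genome ids")
    known = set(genomes)
    mat = pd.DataFrame(0, index=genomes, columns=list(retained), dtype=int)
    for fam, leaves in retained.items():
        for lf in leaves:
            g = genome_of(lf)
            if g not in known:
                raise ValueError(
                    f"leaf {lf!r} of family {fam!r} maps to unknown genome {g!r}"
                )
            mat.loc[g, fam] = 1
    return mat


def count_presence(matrix: pd.DataFrame, families, mode: str = "all") -> int:
    """Number of genomes carrying *all* (co-occurrence) or *any* of the
    listed families."""
    families = list(families)
    unknown = [f for f in families if f not in matrix.columns]
    if unknown:
        raise ValueError(f"unknown family id(s): {unknown}")
    sub = matrix[families]
    if mode == "all":
        return int((sub == 1).all(axis=1).sum())
    if mode == "any":
        return int((sub == 1).any(axis=1).sum())
    raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")


def read_hmmer_tblout(source) -> pd.DataFrame:
    """Read a tblout-style whitespace table of homology scores.

    Accepts either the simplified 4-column layout
    ``target_id  profile_id  evalue  bit_score`` or the full 18+-column
    HMMER3 ``--tblout`` layout (columns 1, 3, 5, 6 used).  Returns a
    DataFrame with columns target, profile, evalue, bit_score.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = source
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) >= 18:  # full tblout
            rows.append((parts[0], parts[2], float(parts[4]), float(parts[5])))
        elif len(parts) >= 4:
            rows.append((parts[0], parts[1], float(parts[2]), float(parts[3])))
        else:
            raise ValueError(f"unparseable score line: {line!r}")
    return pd.DataFrame(rows, columns=["target", "profile", "evalue", "bit_score"])
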