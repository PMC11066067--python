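"""Conditional clade summaries of Bayesian gene-tree samples.

A posterior sample of gene trees (e.g. the ``.t`` file of an MCMC run) is
reduced, after burn-in removal, to the frequencies of observed clades and of
the splits inside each clade.  The reconciliation engine amalgamates over
this clade/split set instead of committing to a single topology, so the
most-parsimonious reconciled tree is searched over the whole sampled
topology space.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .genetree import GeneTree

__all__ = [
    "TreeSample",
    "CCPTable",
    "discard_burnin",
    "build_ccp",
    "read_tree_sample",
    "read_nexus_trees",
    "write_ccp_tsv",
    "read_ccp_tsv",
]


@dataclass
class TreeSample:
    """Ordered list of rooted binary gene trees over a common leaf set."""

    trees: list

    def __post_init__(self):
        if not self.trees:
            raise ValueError("empty tree sample")
        ref = frozenset(self.trees[0].leaf_labels())
        for k, t in enumerate(self.trees):
            if frozenset(t.leaf_labels()) != ref:
                raise ValueError(
                    f"tree {k} has a different leaf set from tree 0"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(self.trees[0].leaf_labels())


def discard_burnin(sample: TreeSample, fraction: float) -> TreeSample:
    """Drop the first ``floor(fraction * N)`` trees (MCMC burn-in)."""
    if not 0 <= fraction < 1:
        raise ValueError("burn-in fraction must be in [0, 1)")
    k = math.floor(fraction * len(sample))
    if k >= len(sample):
        raise ValueError("burn-in would discard every tree")
    return TreeSample(trees=list(sample.trees[k:]))


@dataclass
class CCPTable:
    """Clade and split frequencies of a gene-tree sample.

    ``clade_freq`` maps each observed clade (frozenset of leaf labels) to
    its observation frequency; ``split_freq[clade]`` maps each observed
    split (frozenset of the two child clades) to its frequency.  For every
    non-leaf clade the split frequencies sum to the clade frequency, the
    full leaf set and every singleton have frequency 1.
    """

    leaves: tuple  # canonical (sorted) leaf order
    clade_freq: dict
    split_freq: dict
    n_trees: int

    @property
    def root_clade(self) -> frozenset:
        return frozenset(self.leaves)

    def clades(self) -> set:
        return set(self.clade_freq)

    def splits_of(self, clade: frozenset) -> dict:
        return self.split_freq.get(clade, {})

    def validate(self, tol: float = 1e-9) -> None:
        root = self.root_clade
        if abs(self.clade_freq.get(root, 0.0) - 1.0) > tol:
            raise ValueError("root clade frequency must be 1")
        for lf in self.leaves:
            if abs(self.clade_freq.get(frozenset([lf]), 0.0) - 1.0) > tol:
                raise ValueError(f"singleton clade {lf!r} frequency must be 1")
        for clade, f in self.clade_freq.items():
            if len(clade) == 1:
                continue
            s = sum(self.split_freq.get(clade, {}).values())
            if abs(s - f) > tol:
                raise ValueError(
                    f"split frequencies of clade {sorted(clade)} sum to {s}, "
                    f"expected {f}"
                )


def build_ccp(sample: TreeSample) -> CCPTable:
    """Count clade and split frequencies over a (post burn-in) sample."""
    n = len(sample)
    clade_counts: dict = {}
    split_counts: dict = {}
    for k, tree in enumerate(sample):
        if not tree.is_binary():
            raise ValueError(f"tree {k} is not binary")
        splits = tree.splits()
        for clade in tree.clades():
            clade_counts[clade] = clade_counts.get(clade, 0) + 1
        for clade, ss in splits.items():
            d = split_counts.setdefault(clade, {})
            for sp in ss:
                d[sp] = d.get(sp, 0) + 1
    table = CCPTable(
        leaves=tuple(sorted(sample.leaf_labels)),
        clade_freq={c: cnt / n for c, cnt in clade_counts.items()},
        split_freq={
            c: {sp: cnt / n for sp, cnt in d.items()} for c, d in split_counts.items()
        },
        n_trees=n,
    )
    table.validate()
    return table


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_tree_sample(text: str) -> TreeSample:
    """One Newick per non-empty line."""
    trees = [
        GeneTree.from_newick(line.strip())
        for line in text.splitlines()
        if line.strip() and not line.strip().startswith("#")
    ]
    return TreeSample(trees=trees)


_NEXUS_TREE_RE = re.compile(
    r"^\s*tree\s+\S+\s*=\s*(?:\[[^\]]*\]\s*)?(.+;)\s*$", re.IGNORECASE
)


def read_nexus_trees(text: str) -> TreeSample:
    """Minimal Nexus ``trees`` block reader (with ``translate`` support).

    Handles the layout of MCMC ``.t`` files: an optional translate table
    mapping integer tokens to taxon names, then one ``tree NAME = ...;``
    statement per sampled topology.
    """
    translate = {}
    m = re.search(r"translate(.*?);", text, re.IGNORECASE | re.DOTALL)
    if m:
        for entry in m.group(1).split(","):
            parts = entry.split()
            if len(parts) >= 2:
                translate[parts[0]] = parts[1].strip("'\"")
    trees = []
    for line in text.splitlines():
        tm = _NEXUS_TREE_RE.match(line)
        if not tm:
            continue
        nwk = re.sub(r"\[[^\]]*\]", "", tm.group(1))  # strip comments
        tree = GeneTree.from_newick(nwk)
        if translate:
            for leaf in tree.leaves():
                leaf.label = translate.get(leaf.label, leaf.label)
        trees.append(tree)
    return TreeSample(trees=trees)


def _bitmask(clade: frozenset, leaves: tuple) -> str:
    return "".join("1" if lf in clade else "0" for lf in leaves)


def _from_bitmask(mask: str, leaves: tuple) -> frozenset:
    return frozenset(lf for lf, bit in zip(leaves, mask) if bit == "1")


def write_ccp_tsv(table: CCPTable) -> str:
    """Serialise: header line with the leaf order, then one row per
    (clade, split) pair — clade bitmask, clade frequency, the two split-
    partner bitmasks (empty for singletons), split frequency."""
    lines = ["#leaves\t" + "\t".join(table.leaves)]
    lines.append("clade\tclade_freq\tsplit_a\tsplit_b\tsplit_freq")
    for clade in sorted(table.clade_freq, key=lambda c: (len(c), _bitmask(c, table.leaves))):
        cm = _bitmask(clade, table.leaves)
        f = table.clade_freq[clade]
        splits = table.split_freq.get(clade, {})
        if not splits:
            lines.append(f"{cm}\t{f!r}\t\t\t")
            continue
        for sp, sf in sorted(
            splits.items(), key=lambda kv: sorted(_bitmask(c, table.leaves) for c in kv[0])
        ):
            a, b = sorted(sp, key=lambda c: _bitmask(c, table.leaves))
            lines.append(
                f"{cm}\t{f!r}\t{_bitmask(a, table.leaves)}\t"
                f"{_bitmask(b, table.leaves)}\t{sf!r}"
            )
    return "\n".join(lines) + "\n"


def read_ccp_tsv(text: str) -> CCPTable:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#leaves\t"):
        raise ValueError("missing #leaves header")
    leaves = tuple(lines[0].split("\t")[1:])
    clade_freq: dict = {}
    split_freq: dict = {}
    for ln in lines[2:]:
        cm, f, a, b, sf = (ln.split("\t") + [""] * 5)[:5]
        clade = _from_bitmask(cm, leaves)
        clade_freq[clade] = float(f)
        if a and b:
            sp = frozenset([_from_bitmask(a, leaves), _from_bitmask(b, leaves)])
            split_freq.setdefault(clade, {})[sp] = float(sf)
    table = CCPTable(leaves=leaves, clade_freq=clade_freq, split_freq=split_freq, n_trees=0)
    table.validate()
    return table
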