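"""Lightweight rooted gene trees.

Gene trees here are pure topologies over labelled leaves: branch lengths
play no role in parsimony reconciliation, and clade identity (a frozenset
of leaf labels) is the working currency of both the conditional-clade
summary and the reconciliation engine.

Leaf labels encode their source genome; by convention the genome id is the
suffix after the last underscore (``L7_S3`` comes from genome ``S3``), with
bare labels (no underscore) taken as the genome itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = ["GeneNode", "GeneTree", "genome_of_leaf"]


def genome_of_leaf(label: str) -> str:
    """Source genome id of a gene leaf label (suffix after last ``_``)."""
    return label.rsplit("_", 1)[-1]


@dataclass
class GeneNode:
    label: str | None = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class GeneTree:
    """Rooted (binary, for reconciliation) gene tree."""

    def __init__(self, root: GeneNode):
        self.root = root

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "GeneTree":
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )

        def conv(nd) -> GeneNode:
            if not nd.child_nodes():
                if nd.taxon is None:
                    raise ValueError("unlabelled gene-tree leaf")
                return GeneNode(label=nd.taxon.label)
            return GeneNode(children=[conv(c) for c in nd.child_nodes()])

        return cls(conv(dt.seed_node))

    def copy(self) -> "GeneTree":
        def rec(n: GeneNode) -> GeneNode:
            return GeneNode(label=n.label, children=[rec(c) for c in n.children])

        return GeneTree(rec(self.root))

    # -- traversal ---------------------------------------------------------
    def postorder(self):
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def leaves(self) -> list:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels())

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    # -- clades ------------------------------------------------------------
    def clade_of(self) -> dict:
        """Map each node to its clade (frozenset of descendant leaf labels)."""
        clade = {}
        for n in self.postorder():
            if n.is_leaf:
                clade[id(n)] = frozenset([n.label])
            else:
                acc = frozenset()
                for c in n.children:
                    acc |= clade[id(c)]
                clade[id(n)] = acc
        return clade

    def clades(self) -> set:
        return set(self.clade_of().values())

    def splits(self) -> dict:
        """Map clade -> set of observed splits (frozenset of two child clades).

        Only defined for binary trees.
        """
        if not self.is_binary():
            raise ValueError("splits() requires a binary gene tree")
        clade = self.clade_of()
        out = {}
        for n in self.postorder():
            if n.is_leaf:
                continue
            c1, c2 = (clade[id(c)] for c in n.children)
            out.setdefault(clade[id(n)], set()).add(frozenset([c1, c2]))
        return out

    # -- mrca / subsets ----------------------------------------------------
    def mrca(self, labels) -> GeneNode:
        """Most recent common ancestor of a non-empty set of leaf labels."""
        want = frozenset(labels)
        if not want:
            raise ValueError("mrca of empty leaf set")
        if not want <= frozenset(self.leaf_labels()):
            missing = sorted(want - frozenset(self.leaf_labels()))
            raise ValueError(f"labels not in tree: {missing}")
        clade = self.clade_of()
        best, best_size = None, None
        for n in self.postorder():
            cl = clade[id(n)]
            if want <= cl and (best is None or len(cl) < best_size):
                best, best_size = n, len(cl)
        return best

    def leaf_labels_under(self, node: GeneNode) -> frozenset:
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.label)
            else:
                stack.extend(n.children)
        return frozenset(out)

    # -- rerooting ---------------------------------------------------------
    def all_rootings(self):
        """Yield (branch_key, GeneTree) for every rooting of the unrooted
        topology underlying this tree.

        ``branch_key`` is the canonical clade (frozenset, the smaller side
        lexicographically serialised) of the edge the new root subdivides;
        yields are sorted by that key so iteration order is deterministic.
        """
        base = self.copy()
        parent = {}
        for n in base.postorder():
            for c in n.children:
                parent[id(c)] = n
        clade = base.clade_of()
        nodes = {id(n): n for n in base.postorder()}

        candidates = []
        for nid, n in nodes.items():
            if id(n) == id(base.root):
                continue
            candidates.append((tuple(sorted(clade[nid])), n))
        candidates.sort(key=lambda kv: kv[0])

        seen = set()
        allleaves = frozenset(base.leaf_labels())
        for key, n in candidates:
            cl = clade[id(n)]
            canon = min(cl, allleaves - cl, key=lambda s: (len(s), tuple(sorted(s))))
            ck = tuple(sorted(canon))
            if ck in seen:
                continue
            seen.add(ck)
            yield ck, _reroot_at_edge(base, parent, n)

    def to_newick(self) -> str:
        def rec(n: GeneNode) -> str:
            if n.is_leaf:
                return n.label
            return "(" + ",".join(rec(c) for c in n.children) + ")"

        return rec(self.root) + ";"

    def __repr__(self) -> str:
        return f"GeneTree({self.to_newick()!r})"


def _reroot_at_edge(tree: GeneTree, parent: dict, node: GeneNode) -> GeneTree:
    """New rooted tree with the root subdividing the edge above ``node``.

    Works on a fresh copy so the input tree is untouched.
    """
    # path from node's parent up to the old root
    def flip(n: GeneNode, coming_from: GeneNode | None) -> GeneNode:
        """Rebuild n as seen from the new direction: its children become its
        old children minus coming_from, plus its old parent (flipped)."""
        kids = [c for c in n.children if c is not coming_from]
        p = parent.get(id(n))
        if p is not None:
            kids.append(flip(p, n))
        if len(kids) == 1:  # old root had degree 2: suppress it
            return kids[0]
        return GeneNode(children=kids)

    top = flip(parent[id(node)], node)
    fresh = GeneTree(GeneNode(children=[node, top]))
    return fresh.copy()
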