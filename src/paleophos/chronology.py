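"""Dated species trees, contemporaneity slices, and geological periods.

The backbone object of the pipeline is a rooted, binary, time-calibrated
species tree whose nodes carry absolute ages in Ga (giga-annum before
present; larger = older).  Every leaf sits at the present (age 0) and every
branch ``parent -> child`` spans the age interval ``[child.age, parent.age]``.

Two branches can exchange genes horizontally only while both are alive, so
the tree's distinct internal-node ages cut time into *slices* within which
the set of living branches is constant (:class:`SliceIndex`).  Absolute ages
are mapped to named geological periods via :class:`PeriodTable`.
"""

from __future__ import annotations

import importlib.resources
import io
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DatedTree",
    "SliceIndex",
    "PeriodTable",
    "parse_dated_newick",
    "write_dated_newick",
    "compute_time_slices",
    "assign_geological_period",
    "default_period_table",
]

_AGE_TOL = 1e-9


class DatedTreeError(ValueError):
    """Raised when a tree violates the dated-tree contract."""


@dataclass
class DatedTree:
    """Rooted binary ultrametric species tree with node ages in Ga.

    Nodes are indexed ``0 .. n_nodes-1`` in a canonical preorder: children
    are visited in order of their smallest descendant leaf label, so the
    numbering (and hence every branch index used for deterministic
    tie-breaking downstream) depends only on topology, ages, and labels —
    not on the input Newick's child order.

    A *branch* is identified by the index of the node it leads to; the root
    has no parent branch on the sampled tree (the reconciliation engine adds
    a conceptual stem internally).
    """

    parent: list  # parent[i] = parent index, None for root
    children: list  # children[i] = tuple of child indices (empty for leaves)
    labels: list  # labels[i] = leaf label, or internal label / None
    ages: np.ndarray  # ages[i] in Ga

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self._validate()

    # -- derived structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        roots = [i for i, p in enumerate(self.parent) if p is None]
        return roots[0]

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def leaves(self) -> list:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    def leaf_labels(self) -> list:
        return [self.labels[i] for i in self.leaves()]

    def branches(self) -> list:
        """Branch indices = every non-root node (branch = edge above it)."""
        r = self.root
        return [i for i in range(self.n_nodes) if i != r]

    def branch_interval(self, i: int) -> tuple:
        """Age interval [young, old] spanned by the branch above node ``i``."""
        p = self.parent[i]
        if p is None:
            raise DatedTreeError("the root has no parent branch")
        return float(self.ages[i]), float(self.ages[p])

    def branch_label(self, i: int) -> str:
        """Human-readable ``parent->child`` description of a branch."""

        def name(j):
            if self.labels[j]:
                return str(self.labels[j])
            tips = sorted(self.labels[k] for k in self.clade_leaves(j))
            return "(" + "+".join(tips) + ")"

        p = self.parent[i]
        top = "stem" if p is None else name(p)
        return f"{top}->{name(i)}"

    def clade_leaves(self, i: int) -> list:
        """Leaf indices descending from node ``i`` (inclusive if leaf)."""
        out, stack = [], [i]
        while stack:
            j = stack.pop()
            if self.children[j]:
                stack.extend(self.children[j])
            else:
                out.append(j)
        return out

    def leaf_index(self) -> dict:
        """Map leaf label -> node index."""
        return {self.labels[i]: i for i in self.leaves()}

    def postorder(self) -> list:
        order, stack = [], [self.root]
        while stack:
            j = stack.pop()
            order.append(j)
            stack.extend(self.children[j])
        return order[::-1]

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        n = self.n_nodes
        if not (len(self.children) == len(self.labels) == len(self.ages) == n):
            raise DatedTreeError("field length mismatch")
        roots = [i for i, p in enumerate(self.parent) if p is None]
        if len(roots) != 1:
            raise DatedTreeError(f"expected exactly one root, found {len(roots)}")
        for i, p in enumerate(self.parent):
            if p is not None and i not in self.children[p]:
                raise DatedTreeError(f"node {i} missing from its parent's children")
        if np.any(self.ages < -_AGE_TOL):
            raise DatedTreeError("negative node age")
        for i, p in enumerate(self.parent):
            if p is None:
                continue
            if not self.ages[p] > self.ages[i] + _AGE_TOL:
                raise DatedTreeError(
                    f"branch {p}->{i} has non-positive duration "
                    f"({self.ages[p]:g} -> {self.ages[i]:g} Ga)"
                )
        leaves = self.leaves()
        if any(abs(self.ages[i]) > _AGE_TOL for i in leaves):
            bad = [self.labels[i] for i in leaves if abs(self.ages[i]) > _AGE_TOL]
            raise DatedTreeError(f"leaf ages must be 0, offending leaves: {bad}")
        labels = [self.labels[i] for i in leaves]
        if len(set(labels)) != len(labels):
            raise DatedTreeError("duplicate leaf labels")
        if any(lb in (None, "") for lb in labels):
            raise DatedTreeError("unlabelled leaf")

    # -- convenience -------------------------------------------------------
    def newick(self) -> str:
        return write_dated_newick(self)

    def __eq__(self, other) -> bool:  # topology + ages + labels
        if not isinstance(other, DatedTree):
            return NotImplemented
        if set(self.leaf_labels()) != set(other.leaf_labels()):
            return False

        def signature(t: DatedTree):
            return sorted(
                (frozenset(t.labels[k] for k in t.clade_leaves(i)), round(float(t.ages[i]), 9))
                for i in range(t.n_nodes)
            )

        return signature(self) == signature(other)


# ---------------------------------------------------------------------------
# Newick IO
# ---------------------------------------------------------------------------

def _canonical_order(parent, children, labels, ages):
    """Reindex nodes into canonical preorder (children by min leaf label)."""
    n = len(parent)
    minleaf = [None] * n
    root = next(i for i, p in enumerate(parent) if p is None)
    # postorder fill of smallest descendant leaf label
    stack, order = [root], []
    while stack:
        j = stack.pop()
        order.append(j)
        stack.extend(children[j])
    for j in reversed(order):
        if children[j]:
            minleaf[j] = min(minleaf[c] for c in children[j])
        else:
            minleaf[j] = labels[j]
    # canonical preorder
    newindex = {}
    stack = [root]
    while stack:
        j = stack.pop()
        newindex[j] = len(newindex)
        for c in sorted(children[j], key=lambda c: minleaf[c], reverse=True):
            stack.append(c)
    n_parent = [None] * n
    n_children = [()] * n
    n_labels = [None] * n
    n_ages = np.zeros(n)
    for old, new in newindex.items():
        n_parent[new] = None if parent[old] is None else newindex[parent[old]]
        n_children[new] = tuple(
            sorted((newindex[c] for c in children[old]))
        )
        n_labels[new] = labels[old]
        n_ages[new] = ages[old]
    return n_parent, n_children, n_labels, n_ages


def parse_dated_newick(text: str, ultrametric_tol: float = 1e-6) -> DatedTree:
    """Parse a dated species tree from Newick.

    Ages are taken from ``[&age=x]`` node comments when every node carries
    one; otherwise branch lengths must be ultrametric (all root-to-tip path
    lengths equal within ``ultrametric_tol``) and ages are accumulated from
    the leaves upward.  Polytomies and negative ages are rejected.
    """
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
        extract_comment_metadata=True,
    )
    nodes = list(tree.preorder_node_iter())
    idx = {nd: i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = [None] * n
    children = [()] * n
    labels = [None] * n
    for nd, i in idx.items():
        if nd.parent_node is not None:
            parent[i] = idx[nd.parent_node]
        kids = tuple(idx[c] for c in nd.child_nodes())
        if len(kids) not in (0, 2):
            raise DatedTreeError(
                f"polytomy (or unifurcation) of degree {len(kids)} at node {i}; "
                "the reconciliation model requires a binary species tree"
            )
        children[i] = kids
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label

    explicit = {}
    for nd, i in idx.items():
        for ann in nd.annotations:
            if ann.name == "age":
                explicit[i] = float(ann.value)
    if len(explicit) == n:
        ages = np.array([explicit[i] for i in range(n)], float)
    else:
        if explicit:
            missing = n - len(explicit)
            raise DatedTreeError(
                f"partial [&age=] annotation: {missing} node(s) lack an age; "
                "annotate every node or supply ultrametric branch lengths"
            )
        ages = _ages_from_ultrametric(nodes, idx, parent, children, labels, ultrametric_tol)
    if np.any(ages < -_AGE_TOL):
        bad = [labels[i] or f"node{i}" for i in np.nonzero(ages < -_AGE_TOL)[0]]
        raise DatedTreeError(f"negative age(s) at {bad}")
    return DatedTree(*_canonical_order(parent, children, labels, ages))


def _ages_from_ultrametric(nodes, idx, parent, children, labels, tol):
    n = len(nodes)
    depth = np.zeros(n)  # root-to-node path length
    for nd, i in idx.items():
        if nd.parent_node is None:
            continue
        if nd.edge.length is None:
            raise DatedTreeError("missing branch length and no [&age=] annotations")
        depth[i] = depth[idx[nd.parent_node]] + float(nd.edge.length)
    leaves = [i for i in range(n) if not children[i]]
    dmax = depth[leaves].max()
    dmin_leaf = min(leaves, key=lambda i: depth[i])
    dmax_leaf = max(leaves, key=lambda i: depth[i])
    if depth[dmax_leaf] - depth[dmin_leaf] > tol * max(1.0, dmax):
        raise DatedTreeError(
            "branch lengths are not ultrametric and no [&age=] annotations given: "
            f"leaves {labels[dmin_leaf]!r} (depth {depth[dmin_leaf]:g}) and "
            f"{labels[dmax_leaf]!r} (depth {depth[dmax_leaf]:g}) imply different "
            "root-to-tip depths"
        )
    ages = dmax - depth
    ages[leaves] = 0.0
    return ages


def write_dated_newick(tree: DatedTree, precision: int = 17) -> str:
    """Serialise a :class:`DatedTree`, emitting both branch lengths and
    ``[&age=x]`` comments so either convention can re-read it."""

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    def rec(i: int) -> str:
        if tree.children[i]:
            inner = ",".join(rec(c) for c in tree.children[i])
            core = f"({inner})"
        else:
            core = tree.labels[i]
        p = tree.parent[i]
        if p is None:
            return f"{core}[&age={fmt(tree.ages[i])}]"
        bl = tree.ages[p] - tree.ages[i]
        return f"{core}:{fmt(bl)}[&age={fmt(tree.ages[i])}]"

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Time slices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SliceIndex:
    """Partition of [0, root age] at the distinct internal-node ages.

    ``slices[t]`` is ``(young, old, frozenset of branch indices)`` ordered
    young to old; a branch belongs to every slice its interval spans.
    """

    boundaries: tuple  # ascending, boundaries[0] == 0, boundaries[-1] == root age
    slices: tuple

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def slice_of_age(self, age: float) -> int:
        """Index of the slice containing ``age`` (boundary -> older slice)."""
        if age < -_AGE_TOL or age > self.boundaries[-1] + _AGE_TOL:
            raise ValueError(f"age {age} outside [0, {self.boundaries[-1]}]")
        for t, (lo, hi, _) in enumerate(self.slices):
            if lo - _AGE_TOL <= age <= hi + _AGE_TOL:
                return t
        return self.n_slices - 1

    def contemporaneous(self, x: int, y: int) -> bool:
        """True if branches co-occur in at least one slice."""
        return any(x in s and y in s for _, _, s in self.slices)


def compute_time_slices(tree: DatedTree) -> SliceIndex:
    """Cut [0, root age] at every distinct internal-node age and list the
    branches alive throughout each slice."""
    internal_ages = sorted({round(float(tree.ages[i]), 12) for i in range(tree.n_nodes) if tree.children[i]})
    boundaries = [0.0] + [a for a in internal_ages if a > _AGE_TOL]
    slices = []
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        alive = frozenset(
            b
            for b in tree.branches()
            if tree.ages[b] <= lo + _AGE_TOL and tree.ages[tree.parent[b]] >= hi - _AGE_TOL
        )
        slices.append((lo, hi, alive))
    return SliceIndex(boundaries=tuple(boundaries), slices=tuple(slices))


# ---------------------------------------------------------------------------
# Geological periods
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeriodTable:
    """Ordered geological intervals (name, older bound, younger bound), Ga."""

    names: tuple
    older: tuple
    younger: tuple

    def __post_init__(self):
        if not (len(self.names) == len(self.older) == len(self.younger)):
            raise ValueError("period table field length mismatch")
        for name, o, y in zip(self.names, self.older, self.younger):
            if not o > y:
                raise ValueError(f"period {name}: older bound must exceed younger bound")
        order = sorted(range(len(self.names)), key=lambda i: -self.older[i])
        for a, b in zip(order[:-1], order[1:]):
            if abs(self.younger[a] - self.older[b]) > _AGE_TOL:
                raise ValueError(
                    f"periods {self.names[a]} and {self.names[b]} are not contiguous"
                )

    @classmethod
    def from_tsv(cls, source) -> "PeriodTable":
        df = pd.read_csv(source, sep="\t")
        return cls(
            names=tuple(df["name"]),
            older=tuple(float(x) for x in df["older_Ga"]),
            younger=tuple(float(x) for x in df["younger_Ga"]),
        )

    @property
    def oldest_bound(self) -> float:
        return max(self.older)


def default_period_table() -> PeriodTable:
    """Precambrian eras + Phanerozoic eras of the standard geologic timescale."""
    ref = importlib.resources.files("paleophos.data").joinpath("geological_periods.tsv")
    return PeriodTable.from_tsv(io.StringIO(ref.read_text()))


def assign_geological_period(age: float, periods: PeriodTable | None = None) -> str:
    """Name of the period containing ``age`` (Ga).

    Boundary ages belong to the *younger* period (ties broken toward the
    present), so 3.2 Ga is Mesoarchean, not Paleoarchean.
    """
    if periods is None:
        periods = default_period_table()
    if age < -_AGE_TOL or age > periods.oldest_bound + _AGE_TOL:
        raise ValueError(
            f"age {age} Ga outside period table range [0, {periods.oldest_bound}]"
        )
    age = max(age, 0.0)
    for name, o, y in zip(periods.names, periods.older, periods.younger):
        if (y < age <= o + _AGE_TOL) or (age <= _AGE_TOL and y <= _AGE_TOL):
            return name
    raise ValueError(f"no period contains age {age}")
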