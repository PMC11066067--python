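"""Forward simulation of gene-family histories with known ground truth.

The generator is the verification backbone of the package: it evolves a
gene family down a dated species tree under a continuous-time
duplication / transfer / loss process (rates per lineage per Ga), records
the exact event history, and emits the pruned gene tree of surviving
copies.  Transfers land only on sampled branches alive at the moment of
the event, so every true history is itself a feasible dated reconciliation
— which is what makes the parsimony lower-bound property testable.
Companion generators produce perturbed tree samples (a stand-in for an
MCMC posterior), scored trees for the homolog screen, and abundance tables
with a prescribed phosphate regression structure.

All draws flow from one seed, fanned out to per-component generators by
fixed offsets, so each sub-simulation is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chronology import DatedTree, _canonical_order
from .genetree import GeneNode, GeneTree
from .reconcile import CostScheme
from .regression import AbundanceTable
from .screen import ScoredTree

import pandas as pd

__all__ = [
    "SimParams",
    "TrueEvent",
    "TrueHistory",
    "simulate_dated_tree",
    "simulate_gene_family",
    "simulate_tree_sample",
    "simulate_abundance",
    "simulate_scored_tree",
    "write_fixture_set",
]

# fixed seed offsets per component (reproducible in isolation)
_OFFSETS = {"tree": 1, "family": 2, "sample": 3, "abundance": 4, "scores": 5}


def _rng(seed_or_rng, component: str | None = None):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    seed = int(seed_or_rng)
    if component is not None:
        seed = (seed * 8 + _OFFSETS[component]) % (2**31 - 1)
    return np.random.default_rng(seed)


@dataclass
class SimParams:
    """Study conditions for the synthetic pipeline.

    Rates are events per gene lineage per Ga.  The phosphate range default
    matches the span observed in surface-ocean survey data (0-3.29 uM); the
    default regression slope mirrors the strongest reported gene-abundance
    coefficient and is a simulation setting, not a reproduction claim.
    """

    dup_rate: float = 0.1
    transfer_rate: float = 0.1
    loss_rate: float = 0.1
    origination: object = "root"  # "root" or a species branch index
    seed: int = 0
    n_tips: int = 20
    root_age: float = 4.0
    abundance_form: str = "linear"
    abundance_slope: float = -0.79
    abundance_intercept: float = 5.0
    abundance_noise_sd: float = 1.0
    n_samples: int = 139
    phosphate_range: tuple = (0.0, 3.29)

    def __post_init__(self):
        if min(self.dup_rate, self.transfer_rate, self.loss_rate) < 0:
            raise ValueError("rates must be non-negative")
        lo, hi = self.phosphate_range
        if not (0 <= lo < hi):
            raise ValueError("phosphate range must satisfy 0 <= lo < hi")


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------

def simulate_dated_tree(n_tips: int, root_age: float, seed=0) -> DatedTree:
    """Random binary ultrametric species tree with the root at ``root_age``.

    Internal-node ages are uniform order statistics on (0, root age)
    (a birth-process shape rescaled to the fixed root age); the topology
    coalesces random lineage pairs young to old.  Deterministic given seed.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if root_age <= 0:
        raise ValueError("root age must be positive")
    rng = _rng(seed, "tree")
    inner = sorted(rng.uniform(0.0, root_age, size=n_tips - 2)) + [root_age]
    parent, children, labels, ages = [], [], [], []

    def new_node(label, age):
        parent.append(None)
        children.append(())
        labels.append(label)
        ages.append(age)
        return len(parent) - 1

    lineages = [new_node(f"S{i + 1}", 0.0) for i in range(n_tips)]
    for age in inner:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        a, b = lineages[i], lineages[j]
        p = new_node(None, float(age))
        parent[a] = parent[b] = p
        children[p] = (a, b)
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)] + [p]
    assert len(lineages) == 1
    return DatedTree(*_canonical_order(parent, children, labels, np.array(ages)))


# ---------------------------------------------------------------------------
# Gene families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueEvent:
    etype: str  # speciation | duplication | transfer | loss
    branch: object  # species branch index or "stem"
    date: float  # exact event time, Ga
    recipient: object = None  # transfer target branch


class _Lineage:
    """Node of the full (pre-pruning) simulated lineage tree."""

    __slots__ = ("etype", "time", "branch", "children", "recipient", "label")

    def __init__(self, etype, time, branch, children=(), recipient=None, label=None):
        self.etype = etype
        self.time = time
        self.branch = branch
        self.children = list(children)
        self.recipient = recipient
        self.label = label


@dataclass
class TrueHistory:
    """Ground-truth event record of one simulated gene family.

    ``events`` lists the true events that have at least one surviving
    descendant copy (the ones the genomic record can witness), with exact
    dates.  ``parsimony_cost`` prices the reconciliation induced by pruning
    extinct lineages from the full history — a feasible reconciliation of
    the emitted gene tree, hence an upper bound on the parsimony optimum.
    """

    events: list
    origination_date: float
    gene_tree: GeneTree | None
    _root: object = field(default=None, repr=False)

    @property
    def empty(self) -> bool:
        return self.gene_tree is None

    def event_counts(self) -> dict:
        out: dict = {}
        for e in self.events:
            out[e.etype] = out.get(e.etype, 0) + 1
        return out

    def parsimony_cost(self, scheme: CostScheme | None = None) -> float:
        if scheme is None:
            scheme = CostScheme()
        if self.empty:
            raise ValueError("empty family has no reconciliation cost")

        def rec(node) -> tuple:
            if node.etype == "sample":
                return True, 0.0
            if node.etype == "loss":
                return False, 0.0
            res = [rec(c) for c in node.children]
            alive = [c for (s, c_cost), c in zip(res, node.children) if s]
            costs = [c_cost for (s, c_cost) in res if s]
            k = len(costs)
            if k == 0:
                return False, 0.0
            inner = sum(costs)
            if node.etype == "speciation":
                if k == 2:
                    return True, scheme.speciation + inner
                return True, scheme.loss + inner
            if node.etype == "duplication":
                if k == 2:
                    return True, scheme.duplication + inner
                return True, inner
            if node.etype == "transfer":
                stay, moved = node.children
                s_stay = res[0][0]
                s_moved = res[1][0]
                if s_stay and s_moved:
                    return True, scheme.transfer + inner
                if s_moved:  # donor side extinct: a transfer-loss
                    return True, scheme.transfer + scheme.loss + inner
                return True, inner  # transferred copy extinct: invisible
            raise AssertionError(node.etype)

        survives, cost = rec(self._root)
        assert survives
        return cost


def simulate_gene_family(
    tree: DatedTree, params: SimParams, rng=None
) -> tuple:
    """Evolve one gene family forward in time; return (GeneTree|None, TrueHistory).

    Along each living gene lineage, exponential waiting times trigger
    duplication (copy in place), transfer (copy to a uniformly chosen
    contemporaneous sampled branch) or loss; lineages split for free at
    species-tree nodes and surviving copies at the present become gene
    leaves labelled ``g<k>_<genome>``.  An all-extinct family is a valid
    outcome: the gene tree is None.
    """
    if rng is None:
        rng = _rng(params.seed, "family")
    ages = tree.ages
    total_rate = params.dup_rate + params.transfer_rate + params.loss_rate
    branch_list = tree.branches()

    def alive_at(t, exclude):
        return [
            b
            for b in branch_list
            if b != exclude and ages[b] < t < ages[tree.parent[b]]
        ]

    def evolve(branch, t_start) -> _Lineage:
        t = t_start
        bottom = float(ages[branch])
        while True:
            wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
            if t - wait <= bottom:
                if not tree.children[branch]:  # species leaf at time 0
                    return _Lineage("sample", 0.0, branch)
                y1, y2 = tree.children[branch]
                return _Lineage(
                    "speciation",
                    bottom,
                    branch,
                    children=[evolve(y1, bottom), evolve(y2, bottom)],
                )
            t -= wait
            u = rng.uniform(0.0, total_rate)
            if u < params.dup_rate:
                return _Lineage(
                    "duplication", t, branch,
                    children=[evolve(branch, t), evolve(branch, t)],
                )
            if u < params.dup_rate + params.transfer_rate:
                targets = alive_at(t, exclude=branch)
                if targets:
                    y = targets[int(rng.integers(len(targets)))]
                    return _Lineage(
                        "transfer", t, branch, recipient=y,
                        children=[evolve(branch, t), evolve(y, t)],
                    )
                continue  # nobody to receive: no event
            return _Lineage("loss", t, branch)

    if params.origination == "root":
        y1, y2 = tree.children[tree.root]
        root = _Lineage(
            "speciation",
            tree.root_age,
            "stem",
            children=[evolve(y1, tree.root_age), evolve(y2, tree.root_age)],
        )
        origination_date = tree.root_age
    else:
        b = int(params.origination)
        top = float(ages[tree.parent[b]])
        root = evolve(b, top)
        origination_date = top

    # --- prune extinct lineages and collect witnessed events ---------------
    survives: dict = {}

    def mark(node) -> bool:
        if node.etype == "sample":
            survives[id(node)] = True
            return True
        ok = False
        for c in node.children:
            ok = mark(c) or ok
        survives[id(node)] = ok
        return ok

    mark(root)

    events = []
    leaf_counter = [0]

    def collect(node):
        if not survives[id(node)]:
            return
        if node.etype != "sample":
            events.append(
                TrueEvent(
                    etype=node.etype,
                    branch=node.branch,
                    date=float(node.time),
                    recipient=node.recipient,
                )
            )
        for c in node.children:
            collect(c)

    def build(node) -> GeneNode | None:
        if not survives[id(node)]:
            return None
        if node.etype == "sample":
            leaf_counter[0] += 1
            genome = tree.labels[node.branch]
            label = f"g{leaf_counter[0]}_{genome}"
            node.label = label
            return GeneNode(label=label)
        kids = [build(c) for c in node.children]
        kids = [k for k in kids if k is not None]
        if len(kids) == 1:
            return kids[0]
        return GeneNode(children=kids)

    if not survives[id(root)]:
        return None, TrueHistory(events=[], origination_date=origination_date,
                                 gene_tree=None, _root=root)
    collect(root)
    gtree = GeneTree(build(root))
    history = TrueHistory(
        events=events,
        origination_date=origination_date,
        gene_tree=gtree,
        _root=root,
    )
    return gtree, history


# ---------------------------------------------------------------------------
# Perturbed tree samples
# ---------------------------------------------------------------------------

def _random_nni(tree: GeneTree, rng) -> None:
    """One random nearest-neighbour interchange, in place."""
    parent = {}
    for n in tree.postorder():
        for c in n.children:
            parent[id(c)] = n
    nodes = {id(n): n for n in tree.postorder()}
    candidates = [
        n
        for n in nodes.values()
        if not n.is_leaf and id(n) in parent
    ]
    if not candidates:
        return
    v = candidates[int(rng.integers(len(candidates)))]
    p = parent[id(v)]
    sib = next(c for c in p.children if c is not v)
    child = v.children[int(rng.integers(len(v.children)))]
    v.children[v.children.index(child)] = sib
    p.children[p.children.index(sib)] = child


def simulate_tree_sample(gene_tree: GeneTree, strength: float, n: int, seed=0):
    """N trees obtained by ~Poisson(strength) random NNI moves each.

    Strength 0 reproduces the input tree N times (a converged, conflict-free
    posterior); larger strengths emulate topological uncertainty.
    """
    from .ccp import TreeSample

    if n < 1:
        raise ValueError("need at least one tree")
    rng = _rng(seed, "sample")
    trees = []
    for _ in range(n):
        t = gene_tree.copy()
        for _ in range(int(rng.poisson(strength)) if strength > 0 else 0):
            _random_nni(t, rng)
        trees.append(t)
    return TreeSample(trees=trees)


# ---------------------------------------------------------------------------
# Scored trees for the homolog screen
# ---------------------------------------------------------------------------

def simulate_scored_tree(
    n_family: int = 8,
    n_outgroup: int = 6,
    seed=0,
    family_score: float = 150.0,
    outgroup_score: float = 40.0,
    score_sd: float = 10.0,
    threshold: float = 100.0,
):
    """A gene tree whose true family forms a monophyletic, high-scoring
    clade next to low-scoring off-target hits.

    Returns (ScoredTree, true retained leaf set).  Queries are two random
    family members; bit scores are Gaussian around the family / outgroup
    means, clipped so the two classes stay on their side of the threshold.
    """
    rng = _rng(seed, "scores")

    def random_subtree(labels):
        nodes = [GeneNode(label=lb) for lb in labels]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            a, b = nodes[i], nodes[j]
            nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
            nodes.append(GeneNode(children=[a, b]))
        return nodes[0]

    fam = [f"fam{i + 1}_G{i + 1}" for i in range(n_family)]
    out = [f"hit{i + 1}_H{i + 1}" for i in range(n_outgroup)]
    tree = GeneTree(GeneNode(children=[random_subtree(fam), random_subtree(out)]))
    margin = 5.0
    scores = {}
    evalues = {}
    for lb in fam:
        scores[lb] = float(max(rng.normal(family_score, score_sd), threshold + margin))
        evalues[lb] = float(10 ** rng.uniform(-30, -5))
    for lb in out:
        scores[lb] = float(min(rng.normal(outgroup_score, score_sd), threshold - margin))
        evalues[lb] = float(10 ** rng.uniform(-4, -1))
    queries = frozenset(rng.choice(fam, size=min(2, n_family), replace=False))
    scored = ScoredTree(
        tree=tree, scores=scores, queries=queries, evalues=evalues, threshold=threshold
    )
    return scored, frozenset(fam)


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------

def simulate_abundance(params: SimParams, rng=None, gene: str = "gene1") -> AbundanceTable:
    """Abundance table with a prescribed phosphate regression structure.

    Linear form: ``a = intercept + slope * x + N(0, sd)``; log-linear form:
    ``a = exp(intercept + slope * x) * LogNormal(0, sd)``; both floored at
    zero.  Phosphate is uniform on the configured range.
    """
    if params.n_samples < 3:
        raise ValueError("need at least 3 samples")
    if params.abundance_noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    if rng is None:
        rng = _rng(params.seed, "abundance")
    lo, hi = params.phosphate_range
    x = rng.uniform(lo, hi, size=params.n_samples)
    if params.abundance_form == "linear":
        y = params.abundance_intercept + params.abundance_slope * x
        if params.abundance_noise_sd > 0:
            y = y + rng.normal(0.0, params.abundance_noise_sd, size=x.size)
    elif params.abundance_form == "log-linear":
        y = np.exp(params.abundance_intercept + params.abundance_slope * x)
        if params.abundance_noise_sd > 0:
            y = y * np.exp(rng.normal(0.0, params.abundance_noise_sd, size=x.size))
    else:
        raise ValueError(f"unknown abundance form {params.abundance_form!r}")
    y = np.maximum(y, 0.0)
    df = pd.DataFrame(
        {
            "sample": [f"T{i + 1}" for i in range(x.size)],
            "phosphate_uM": x,
            gene: y,
        }
    )
    return AbundanceTable(df)


# ---------------------------------------------------------------------------
# Fixture writer
# ---------------------------------------------------------------------------

def write_fixture_set(directory, params: SimParams, sample_size: int = 50,
                      perturbation: float = 2.0) -> dict:
    """Write one complete, consistent fixture set to ``directory``.

    Emits the exact formats the pipeline consumes: species.nwk (dated),
    gene.nwk, sample.nwk (one Newick per line), true_history.tsv and
    abundance.tsv.  Returns the path map.  Resimulates until the family
    survives (rate-dependent, seed-deterministic).
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tree = simulate_dated_tree(params.n_tips, params.root_age, params.seed)
    gtree, hist = simulate_gene_family(tree, params)
    attempt = 0
    while gtree is None and attempt < 100:
        attempt += 1
        rng = _rng(params.seed + 1000 + attempt, "family")
        gtree, hist = simulate_gene_family(tree, params, rng=rng)
    if gtree is None:
        raise RuntimeError("family went extinct in 100 attempts; lower the loss rate")
    sample = simulate_tree_sample(gtree, perturbation, sample_size, params.seed)
    abundance = simulate_abundance(params)
    paths = {
        "species": directory / "species.nwk",
        "gene": directory / "gene.nwk",
        "sample": directory / "sample.nwk",
        "history": directory / "true_history.tsv",
        "abundance": directory / "abundance.tsv",
    }
    paths["species"].write_text(tree.newick() + "\n")
    paths["gene"].write_text(gtree.to_newick() + "\n")
    paths["sample"].write_text("".join(t.to_newick() + "\n" for t in sample))
    rows = ["etype\tbranch\tdate_Ga\trecipient"]
    for e in hist.events:
        rows.append(f"{e.etype}\t{e.branch}\t{e.date:.10g}\t{e.recipient if e.recipient is not None else ''}")
    paths["history"].write_text("\n".join(rows) + "\n")
    abundance.to_tsv(paths["abundance"])
    return paths
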