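"""Most-parsimonious dated DTL reconciliation.

A gene tree (or an amalgamated clade set summarising a posterior sample) is
embedded into a dated species tree by choosing, for every gene clade, a
species branch and time slice, and an event explaining each gene-tree
split.  Events and their costs:

* speciation (``sigma``, default 0): the gene lineage tracks a species-tree
  node; its two sub-clades continue into the two descendant branches;
* duplication (``delta``, default 2): the clade splits in place on a branch;
* transfer (``tau``, default 3): one sub-clade stays, the other is received
  by a *contemporaneous* branch (alive in the same time slice) or by the
  unsampled "dead" lineage;
* loss (``lam``, default 1): appears in two compounds — speciation-loss
  (the lineage passes a species node but survives in only one descendant)
  and transfer-loss (the lineage jumps to a contemporaneous branch and the
  donor copy dies).

Transfers into unsampled diversity are modelled by a single dead state per
slice: free to persist, one transfer cost to enter, one to leave; no
observed leaf may end there.  The gene root may originate on any branch in
any slice for free; a conceptual stem branch above the species root lets a
gene speciate at the root node (or duplicate above it).

The dynamic program runs over (gene clade, species branch, slice) young to
old; with an amalgamated :class:`~paleophos.ccp.CCPTable` it ranges over
observed clades and observed splits only.  Backtracking is deterministic:
among co-optimal moves the event preference is speciation < speciation-loss
< duplication < transfer < transfer-loss, then lower canonical branch
index, then younger slice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ccp import CCPTable
from .chronology import DatedTree, SliceIndex, compute_time_slices
from .genetree import GeneTree, genome_of_leaf

__all__ = [
    "CostScheme",
    "Event",
    "Reconciliation",
    "reconcile",
    "optimal_cost",
    "brute_force_reconcile",
    "cost_sensitivity",
    "lca_duplication_loss_cost",
]

_TOL = 1e-9


@dataclass(frozen=True)
class CostScheme:
    """Parsimony event costs (transfer, duplication, loss, speciation)."""

    transfer: float = 3.0
    duplication: float = 2.0
    loss: float = 1.0
    speciation: float = 0.0

    def __post_init__(self):
        for name in ("transfer", "duplication", "loss", "speciation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} cost must be non-negative")

    def with_transfer(self, tau: float) -> "CostScheme":
        return replace(self, transfer=tau)

    def scaled(self, k: float) -> "CostScheme":
        return CostScheme(
            transfer=self.transfer * k,
            duplication=self.duplication * k,
            loss=self.loss * k,
            speciation=self.speciation * k,
        )


@dataclass
class Event:
    """One reconciliation event.

    ``branch`` is a canonical species-branch index, or the strings ``"stem"``
    / ``"dead"``.  ``level`` is the DP level: real slices are 1..T (level t
    corresponds to ``SliceIndex.slices[t-1]``), the stem level is T+1.
    Transfers are recorded once, as receptions (``branch`` = receiver), with
    the donor kept for contemporaneity validation.
    """

    etype: str  # origination | speciation | duplication | transfer | loss
    clade: frozenset
    branch: object
    level: int
    donor: object = None


@dataclass
class Reconciliation:
    total_cost: float
    events: list
    scheme: CostScheme
    leaf_map: dict  # gene leaf label -> species leaf branch index
    root_origin: tuple  # (branch, level)

    def counts(self) -> dict:
        c = {"speciation": 0, "duplication": 0, "transfer": 0, "loss": 0}
        for ev in self.events:
            if ev.etype in c:
                c[ev.etype] += 1
        return c

    @property
    def n_dead_events(self) -> int:
        return sum(1 for ev in self.events if ev.branch == "dead")

    def validate(self, tree: DatedTree, slices: SliceIndex | None = None) -> None:
        """Recheck the cost identity, leaf mapping, and that every transfer
        connects branches alive in its slice."""
        if slices is None:
            slices = compute_time_slices(tree)
        c = self.counts()
        total = (
            self.scheme.speciation * c["speciation"]
            + self.scheme.duplication * c["duplication"]
            + self.scheme.transfer * c["transfer"]
            + self.scheme.loss * c["loss"]
        )
        if not math.isclose(total, self.total_cost, rel_tol=0, abs_tol=1e-6):
            raise AssertionError(
                f"cost identity violated: events imply {total}, stored {self.total_cost}"
            )
        leaf_idx = tree.leaf_index()
        for label, b in self.leaf_map.items():
            g = genome_of_leaf(label)
            if leaf_idx.get(g) != b:
                raise AssertionError(f"gene leaf {label!r} mapped to wrong branch {b}")
        T = slices.n_slices
        for ev in self.events:
            if ev.etype != "transfer":
                continue
            for end in (ev.branch, ev.donor):
                if end in ("dead", "stem"):
                    continue
                if ev.level <= T:
                    _, _, alive = slices.slices[ev.level - 1]
                    if end not in alive:
                        raise AssertionError(
                            f"transfer endpoint {end} not alive in slice {ev.level - 1}"
                        )


# ---------------------------------------------------------------------------
# Problem setup
# ---------------------------------------------------------------------------

class _Species:
    """Indexed species-side structure shared by DP and backtracking."""

    def __init__(self, tree: DatedTree, slices: SliceIndex):
        self.tree = tree
        self.slices = slices
        n = tree.n_nodes
        self.STEM = n
        self.DEAD = n + 1
        self.NB = n + 2
        self.T = slices.n_slices  # real levels are 1..T, stem level is T+1
        self.alive = np.zeros((self.T + 2, self.NB), dtype=bool)
        self.ends = [dict() for _ in range(self.T + 2)]  # level -> {branch: (y1,y2) or None}
        for t in range(1, self.T + 1):
            lo, hi, members = slices.slices[t - 1]
            for b in members:
                self.alive[t, b] = True
                if abs(tree.ages[b] - lo) <= _TOL:
                    if tree.children[b]:
                        self.ends[t][b] = tuple(tree.children[b])
                    else:
                        self.ends[t][b] = None  # terminal: leaf at time 0
            self.alive[t, self.DEAD] = True
        self.alive[self.T + 1, self.STEM] = True
        self.alive[self.T + 1, self.DEAD] = True
        self.ends[self.T + 1][self.STEM] = tuple(tree.children[tree.root])

    def branch_name(self, b) -> str:
        if b == self.STEM or b == "stem":
            return "stem"
        if b == self.DEAD or b == "dead":
            return "dead"
        return self.tree.branch_label(b)

    def public_branch(self, b):
        if b == self.STEM:
            return "stem"
        if b == self.DEAD:
            return "dead"
        return b


def _gene_clades(gene, leaf_to_genome):
    """Normalise the gene input into (clades ascending by size, splits map).

    Returns (clade_list, splits) where splits[clade] is a sorted list of
    (child_a, child_b) frozenset pairs.
    """
    if isinstance(gene, GeneTree):
        if not gene.is_binary():
            raise ValueError("gene tree must be binary for reconciliation")
        split_map = gene.splits()
        clades = gene.clades()
    elif isinstance(gene, CCPTable):
        gene.validate()
        split_map = {c: set(d) for c, d in gene.split_freq.items()}
        clades = set(gene.clade_freq)
    else:
        raise TypeError("gene input must be a GeneTree or a CCPTable")

    def key(c):
        return (len(c), tuple(sorted(c)))

    clade_list = sorted(clades, key=key)
    splits = {}
    for c in clade_list:
        if len(c) == 1:
            continue
        if c not in split_map or not split_map[c]:
            raise ValueError(f"non-singleton clade {sorted(c)} has no observed split")
        pairs = []
        for sp in split_map[c]:
            a, b = sorted(sp, key=key)
            pairs.append((a, b))
        splits[c] = sorted(pairs, key=lambda ab: (key(ab[0]), key(ab[1])))
    return clade_list, splits


def _leaf_branches(clade_list, species: _Species, leaf_to_genome):
    """Map each singleton clade to its species leaf branch index."""
    tree = species.tree
    leaf_idx = tree.leaf_index()
    out = {}
    for c in clade_list:
        if len(c) != 1:
            continue
        (label,) = c
        genome = leaf_to_genome(label)
        if genome not in leaf_idx:
            raise ValueError(
                f"gene leaf {label!r} maps to genome {genome!r}, absent from the species tree"
            )
        out[c] = leaf_idx[genome]
    return out


# ---------------------------------------------------------------------------
# Forward dynamic program
# ---------------------------------------------------------------------------

def _excl_min(v: np.ndarray) -> np.ndarray:
    """out[x] = min over y != x of v[y] (vector min-excluding-self)."""
    order = np.argsort(v, kind="stable")
    i1 = order[0]
    m1 = v[i1]
    m2 = v[order[1]] if len(order) > 1 else np.inf
    out = np.full_like(v, m1)
    out[i1] = m2
    return out


class _DP:
    def __init__(self, gene, species_tree, costs, slices=None, leaf_to_genome=genome_of_leaf):
        self.costs = costs
        if slices is None:
            slices = compute_time_slices(species_tree)
        self.sp = _Species(species_tree, slices)
        self.clades, self.splits = _gene_clades(gene, leaf_to_genome)
        self.leaf_branch = _leaf_branches(self.clades, self.sp, leaf_to_genome)
        self.root_clade = self.clades[-1]
        if len(self.root_clade) != max(len(c) for c in self.clades):
            raise ValueError("missing all-leaves clade")
        self.IN: dict = {}
        self.E: dict = {}
        self.BASE: dict = {}

    # -- forward pass ------------------------------------------------------
    def run(self) -> float:
        sp, cs = self.sp, self.costs
        for clade in self.clades:
            IN = np.full((sp.T + 2, sp.NB), np.inf)
            E = np.full((sp.T + 2, sp.NB), np.inf)
            BASE = np.full((sp.T + 2, sp.NB), np.inf)
            for t in range(1, sp.T + 2):
                e = self._e_vector(clade, t, IN)
                base = e.copy()
                if len(clade) > 1:
                    for a, b in self.splits[clade]:
                        ina, inb = self.IN[a][t], self.IN[b][t]
                        dup = cs.duplication + ina + inb
                        np.minimum(base, dup, out=base)
                        tr = cs.transfer + np.minimum(
                            ina + _excl_min(inb), inb + _excl_min(ina)
                        )
                        np.minimum(base, tr, out=base)
                base[~sp.alive[t]] = np.inf
                res = np.minimum(base, cs.transfer + cs.loss + _excl_min(base))
                res[~sp.alive[t]] = np.inf
                E[t], BASE[t], IN[t] = e, base, res
            self.E[clade], self.BASE[clade], self.IN[clade] = E, BASE, IN
        root = self.IN[self.root_clade]
        return float(root[1:].min())

    def _e_vector(self, clade, t, IN_self) -> np.ndarray:
        """Cost of being present at the bottom boundary of level t."""
        sp, cs = self.sp, self.costs
        e = np.full(sp.NB, np.inf)
        if t == 1:
            if len(clade) == 1:
                e[self.leaf_branch[clade]] = 0.0
            return e
        for x in np.nonzero(sp.alive[t])[0]:
            if x == sp.DEAD:
                e[x] = IN_self[t - 1, sp.DEAD]
                continue
            if x in sp.ends[t]:
                kids = sp.ends[t][x]
                y1, y2 = kids
                sl = cs.loss + min(IN_self[t - 1, y1], IN_self[t - 1, y2])
                best = sl
                if len(clade) > 1:
                    for a, b in self.splits[clade]:
                        ina, inb = self.IN[a][t - 1], self.IN[b][t - 1]
                        s = cs.speciation + min(
                            ina[y1] + inb[y2], ina[y2] + inb[y1]
                        )
                        if s < best:
                            best = s
                e[x] = best
            else:
                e[x] = IN_self[t - 1, x]
        return e

    # -- origination choice ------------------------------------------------
    def best_origin(self) -> tuple:
        """(cost, branch, level) of the cheapest origination, tie-broken by
        lower branch index then younger (lower) level."""
        root = self.IN[self.root_clade]
        best = float(root[1:].min())
        cands = []
        for t in range(1, self.sp.T + 2):
            for x in np.nonzero(root[t] <= best + _TOL)[0]:
                cands.append((x, t))
        x, t = min(cands, key=lambda xt: (xt[0], xt[1]))
        return best, int(x), int(t)

    # -- backtracking ------------------------------------------------------
    def backtrack(self) -> "Reconciliation":
        cost, x0, t0 = self.best_origin()
        events = [
            Event("origination", self.root_clade, self.sp.public_branch(x0), t0)
        ]
        leaf_map = {}
        self._trace_in(self.root_clade, t0, x0, events, leaf_map)
        rec = Reconciliation(
            total_cost=cost,
            events=events,
            scheme=self.costs,
            leaf_map=leaf_map,
            root_origin=(self.sp.public_branch(x0), t0),
        )
        return rec

    def _pick(self, options, target):
        """Deterministically choose among options matching the target cost.

        Each option is (cost, rank, branch_key, level_key, action); event
        preference ranks: pass/leaf 0, speciation 1, speciation-loss 2,
        duplication 3, transfer 4, transfer-loss 5.
        """
        viable = [op for op in options if op[0] <= target + 1e-7]
        if not viable:
            raise AssertionError("backtracking found no option matching DP value")
        return min(viable, key=lambda op: (op[1], op[2], op[3]))

    def _trace_in(self, clade, t, x, events, leaf_map):
        sp, cs = self.sp, self.costs
        target = self.IN[clade][t][x]
        options = self._base_options(clade, t, x)
        base = self.BASE[clade][t]
        for y in np.nonzero(sp.alive[t])[0]:
            if y == x:
                continue
            c = cs.transfer + cs.loss + base[y]
            options.append((c, 5, int(y), t, ("TL", int(y))))
        cost, rank, _, _, action = self._pick(options, target)
        self._apply(clade, t, x, action, events, leaf_map)

    def _trace_base(self, clade, t, x, events, leaf_map):
        target = self.BASE[clade][t][x]
        options = self._base_options(clade, t, x)
        options = [op for op in options if op[0] <= target + 1e-7]
        cost, rank, _, _, action = self._pick(options, target)
        self._apply(clade, t, x, action, events, leaf_map)

    def _base_options(self, clade, t, x):
        """Options whose minimum is BASE[clade][t][x] (everything but TL)."""
        sp, cs = self.sp, self.costs
        options = []
        # bottom-boundary / null-passage component (the E term)
        if t == 1:
            if len(clade) == 1 and x == self.leaf_branch[clade]:
                options.append((0.0, 0, -1, t, ("LEAF",)))
        elif x == sp.DEAD:
            options.append((self.IN[clade][t - 1][sp.DEAD], 0, -1, t - 1, ("NULL",)))
        elif x in sp.ends[t]:
            y1, y2 = sp.ends[t][x]
            if len(clade) > 1:
                for a, b in self.splits[clade]:
                    ina, inb = self.IN[a][t - 1], self.IN[b][t - 1]
                    for (ua, ya), (ub, yb) in (
                        ((a, y1), (b, y2)),
                        ((a, y2), (b, y1)),
                    ):
                        c = cs.speciation + self.IN[ua][t - 1][ya] + self.IN[ub][t - 1][yb]
                        options.append(
                            (c, 1, min(y1, y2), t - 1, ("SPEC", ua, ya, ub, yb))
                        )
            for ykeep, ylost in ((y1, y2), (y2, y1)):
                c = cs.loss + self.IN[clade][t - 1][ykeep]
                options.append((c, 2, int(ylost), t - 1, ("SL", int(ykeep), int(ylost))))
        else:
            options.append((self.IN[clade][t - 1][x], 0, -1, t - 1, ("NULL",)))
        # in-slice binary events
        if len(clade) > 1:
            for a, b in self.splits[clade]:
                ina, inb = self.IN[a][t], self.IN[b][t]
                options.append(
                    (cs.duplication + ina[x] + inb[x], 3, int(x), t, ("DUP", a, b))
                )
                for stay, move in ((a, b), (b, a)):
                    mv = self.IN[move][t]
                    for y in np.nonzero(sp.alive[t])[0]:
                        if y == x:
                            continue
                        c = cs.transfer + self.IN[stay][t][x] + mv[y]
                        options.append((c, 4, int(y), t, ("T", stay, move, int(y))))
        return options

    def _apply(self, clade, t, x, action, events, leaf_map):
        sp = self.sp
        kind = action[0]
        if kind == "LEAF":
            (label,) = clade
            leaf_map[label] = int(x)
        elif kind == "NULL":
            self._trace_in(clade, t - 1, x, events, leaf_map)
        elif kind == "SPEC":
            _, ua, ya, ub, yb = action
            events.append(
                Event("speciation", clade, sp.public_branch(x), t)
            )
            self._trace_in(ua, t - 1, ya, events, leaf_map)
            self._trace_in(ub, t - 1, yb, events, leaf_map)
        elif kind == "SL":
            _, ykeep, ylost = action
            events.append(Event("loss", clade, sp.public_branch(ylost), t - 1))
            self._trace_in(clade, t - 1, ykeep, events, leaf_map)
        elif kind == "DUP":
            _, a, b = action
            events.append(Event("duplication", clade, sp.public_branch(x), t))
            self._trace_in(a, t, x, events, leaf_map)
            self._trace_in(b, t, x, events, leaf_map)
        elif kind == "T":
            _, stay, move, y = action
            events.append(
                Event(
                    "transfer",
                    move,
                    sp.public_branch(y),
                    t,
                    donor=sp.public_branch(x),
                )
            )
            self._trace_in(stay, t, x, events, leaf_map)
            self._trace_in(move, t, y, events, leaf_map)
        elif kind == "TL":
            (_, y) = action
            events.append(
                Event(
                    "transfer", clade, sp.public_branch(y), t, donor=sp.public_branch(x)
                )
            )
            events.append(Event("loss", clade, sp.public_branch(x), t))
            self._trace_base(clade, t, y, events, leaf_map)
        else:  # pragma: no cover
            raise AssertionError(f"unknown action {action}")


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def reconcile(
    gene,
    species: DatedTree,
    costs: CostScheme | None = None,
    slices: SliceIndex | None = None,
    leaf_to_genome=genome_of_leaf,
    rooted: bool = True,
) -> Reconciliation:
    """Minimum-cost dated DTL reconciliation.

    ``gene`` is a rooted binary :class:`GeneTree` or an amalgamated
    :class:`CCPTable`; ``rooted=False`` (gene trees only) tries every root
    position and keeps the cheapest, ties broken by canonical branch.
    """
    if costs is None:
        costs = CostScheme()
    if not rooted:
        if not isinstance(gene, GeneTree):
            raise ValueError("root search requires a GeneTree input")
        best = None
        for key, rooting in gene.all_rootings():
            dp = _DP(rooting, species, costs, slices, leaf_to_genome)
            c = dp.run()
            if best is None or c < best[0] - _TOL:
                best = (c, key, dp)
        return best[2].backtrack()
    dp = _DP(gene, species, costs, slices, leaf_to_genome)
    dp.run()
    return dp.backtrack()


def optimal_cost(
    gene,
    species: DatedTree,
    costs: CostScheme | None = None,
    slices: SliceIndex | None = None,
    leaf_to_genome=genome_of_leaf,
    rooted: bool = True,
) -> float:
    """Forward DP only: the minimum reconciliation cost."""
    if costs is None:
        costs = CostScheme()
    if not rooted:
        if not isinstance(gene, GeneTree):
            raise ValueError("root search requires a GeneTree input")
        return min(
            _DP(r, species, costs, slices, leaf_to_genome).run()
            for _, r in gene.all_rootings()
        )
    return _DP(gene, species, costs, slices, leaf_to_genome).run()


def cost_sensitivity(
    gene,
    species: DatedTree,
    base: CostScheme | None = None,
    hgt_grid=(2.0, 4.0, 6.0),
    slices: SliceIndex | None = None,
    leaf_to_genome=genome_of_leaf,
) -> dict:
    """Reconcile under a grid of transfer costs (other costs held fixed).

    The base scheme's own transfer cost is always included, so the default
    grid {2,4,6} plus the default tau=3 yields four reconciliations.
    """
    if base is None:
        base = CostScheme()
    grid = list(hgt_grid)
    if not grid:
        raise ValueError("empty transfer-cost grid")
    if any(g < 0 for g in grid):
        raise ValueError("transfer costs must be non-negative")
    taus = sorted(set(float(g) for g in grid) | {float(base.transfer)})
    return {
        tau: reconcile(gene, species, base.with_transfer(tau), slices, leaf_to_genome)
        for tau in taus
    }


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_reconcile(
    gene: GeneTree,
    species: DatedTree,
    costs: CostScheme | None = None,
    max_events: int = 4,
    leaf_to_genome=genome_of_leaf,
) -> Reconciliation:
    """Exhaustive enumeration of dated event histories (test oracle).

    Enumerates, without memoisation, every valid history with at most
    ``max_events`` non-speciation events (duplications, transfers and
    losses each consume one unit; a transfer-loss consumes two) and returns
    the cheapest.  Refuses instances beyond 4 gene leaves, 4 species
    leaves, or a budget of 4.
    """
    if costs is None:
        costs = CostScheme()
    if gene.n_leaves > 4 or len(species.leaves()) > 4 or max_events > 4:
        raise ValueError("brute-force oracle limited to <=4 leaves and max_events<=4")
    if not gene.is_binary():
        raise ValueError("gene tree must be binary")

    ages = species.ages
    parent = species.parent
    leaf_idx = species.leaf_index()
    root = species.root
    STEM, DEAD = "stem", "dead"
    boundaries = sorted({round(float(ages[i]), 12) for i in range(species.n_nodes) if species.children[i]})
    boundaries = [0.0] + [a for a in boundaries if a > _TOL]
    nlev = len(boundaries)  # real levels 1..nlev-... stem level = nlev+? mirror DP levels

    def alive_at(level):
        """Sampled branches alive in real level t (1-based) + dead."""
        if level == nlev:  # stem level
            return [STEM, DEAD]
        lo, hi = boundaries[level - 1], boundaries[level]
        out = [
            b
            for b in species.branches()
            if ages[b] <= lo + _TOL and ages[parent[b]] >= hi - _TOL
        ]
        return out + [DEAD]

    def ends_at_bottom(level, b):
        """None if b continues below level, else tuple of child branches
        (empty tuple = terminal leaf)."""
        if b == DEAD:
            return None
        if b == STEM:
            return tuple(species.children[root])
        bottom = boundaries[level - 1]
        if abs(ages[b] - bottom) <= _TOL:
            return tuple(species.children[b])
        return None

    split_map = gene.splits()
    clade_root = frozenset(gene.leaf_labels())

    best = {"cost": np.inf, "events": None, "origin": None, "leaves": None}

    def finish(cost, events, origin, leaves):
        if cost < best["cost"] - _TOL:
            best.update(cost=cost, events=list(events), origin=origin, leaves=dict(leaves))

    def explore(clade, level, b, budget, acc_cost, events, leaves, cont):
        """Enumerate continuations for clade present at top of level on b."""
        if acc_cost >= best["cost"] - _TOL:
            return  # prune: cannot improve
        # (1) descend to the bottom boundary of this level with no in-slice event
        descend(clade, level, b, budget, acc_cost, events, leaves, cont)
        # (2) in-slice events
        if budget >= 1 and len(clade) > 1:
            for sp in split_map.get(clade, ()):  # observed split(s) of this clade
                for a, bb in _both_orders(sp):
                    # duplication
                    ev = ("duplication", clade, b, level)
                    explore(
                        a, level, b, budget - 1, acc_cost + costs.duplication,
                        events + [ev], leaves,
                        lambda bud, cost, evs, lvs, _a=bb, _lvl=level, _b=b, _c=cont: explore(
                            _a, _lvl, _b, bud, cost, evs, lvs, _c
                        ),
                    )
                    break  # duplication is symmetric in the two orders
                for a, bb in _both_orders(sp):
                    for y in alive_at(level):
                        if y == b:
                            continue
                        ev = ("transfer", bb, y, level, b)
                        explore(
                            a, level, b, budget - 1, acc_cost + costs.transfer,
                            events + [ev], leaves,
                            lambda bud, cost, evs, lvs, _a=bb, _lvl=level, _y=y, _c=cont: explore(
                                _a, _lvl, _y, bud, cost, evs, lvs, _c
                            ),
                        )
        # (3) transfer-loss jump within the slice
        if budget >= 2:
            for y in alive_at(level):
                if y == b:
                    continue
                evs = [("transfer", clade, y, level, b), ("loss", clade, b, level)]
                explore(
                    clade, level, y, budget - 2,
                    acc_cost + costs.transfer + costs.loss,
                    events + evs, leaves, cont,
                )

    def descend(clade, level, b, budget, acc_cost, events, leaves, cont):
        kids = ends_at_bottom(level, b)
        if kids is None:
            if level == 1:
                return  # only terminal branches reach time 0
            explore(clade, level - 1, b, budget, acc_cost, events, leaves, cont)
            return
        if kids == ():  # species leaf at time 0
            if len(clade) == 1:
                (label,) = clade
                if leaf_idx[leaf_to_genome(label)] == b:
                    leaves2 = dict(leaves)
                    leaves2[label] = b
                    cont(budget, acc_cost, events, leaves2)
            return
        y1, y2 = kids
        # speciation: both sub-clades continue
        if len(clade) > 1:
            for sp in split_map.get(clade, ()):
                for a, bb in _both_orders(sp):
                    ev = ("speciation", clade, b, level)
                    explore(
                        a, level - 1, y1, budget, acc_cost + costs.speciation,
                        events + [ev], leaves,
                        lambda bud, cost, evs, lvs, _a=bb, _y=y2, _c=cont: explore(
                            _a, level - 1, _y, bud, cost, evs, lvs, _c
                        ),
                    )
        # speciation-loss
        if budget >= 1:
            for ykeep, ylost in ((y1, y2), (y2, y1)):
                ev = ("loss", clade, ylost, level - 1)
                explore(
                    clade, level - 1, ykeep, budget - 1, acc_cost + costs.loss,
                    events + [ev], leaves, cont,
                )

    def _both_orders(sp):
        a, b = sorted(sp, key=lambda c: tuple(sorted(c)))
        yield a, b
        yield b, a

    def top_cont(budget, cost, events, leaves):
        finish(cost, events, ("?", 0), leaves)

    for level in range(nlev, 0, -1):
        for b in alive_at(level):
            explore(
                clade_root, level, b, max_events, 0.0,
                [("origination", clade_root, b, level)], {},
                top_cont,
            )

    if best["events"] is None:
        raise RuntimeError("no history found within the event budget")
    events = [
        Event(e[0], e[1], e[2], e[3], donor=e[4] if len(e) > 4 else None)
        for e in best["events"]
    ]
    origin_ev = events[0]
    return Reconciliation(
        total_cost=float(best["cost"]),
        events=events,
        scheme=costs,
        leaf_map=best["leaves"],
        root_origin=(origin_ev.branch, origin_ev.level),
    )


# ---------------------------------------------------------------------------
# Classical duplication-loss closed form (LCA mapping)
# ---------------------------------------------------------------------------

def lca_duplication_loss_cost(
    gene: GeneTree,
    species: DatedTree,
    costs: CostScheme | None = None,
    leaf_to_genome=genome_of_leaf,
) -> float:
    """Duplication-loss parsimony cost via the LCA mapping closed form.

    The unique optimum when transfers are disallowed: map every gene node to
    the LCA of its leaves' genomes; a node is a duplication iff it maps to
    the same species node as one of its children; losses are counted from
    the depth differences along each gene edge.
    """
    if costs is None:
        costs = CostScheme()
    tree = species
    leaf_idx = tree.leaf_index()
    depth = {tree.root: 0}
    for i in tree.postorder()[::-1]:  # preorder
        for c in tree.children[i]:
            depth[c] = depth[i] + 1
    anc = {}  # node -> list of ancestors up to root (inclusive)

    def ancestors(i):
        if i not in anc:
            path = [i]
            while tree.parent[path[-1]] is not None:
                path.append(tree.parent[path[-1]])
            anc[i] = path
        return anc[i]

    def lca(i, j):
        ai = set(ancestors(i))
        for k in ancestors(j):
            if k in ai:
                return k
        raise AssertionError("disconnected species tree")

    M = {}
    n_dup = 0
    n_loss = 0
    n_spec = 0
    for node in gene.postorder():
        if node.is_leaf:
            g = leaf_to_genome(node.label)
            if g not in leaf_idx:
                raise ValueError(f"gene leaf {node.label!r}: unknown genome {g!r}")
            M[id(node)] = leaf_idx[g]
            continue
        c1, c2 = node.children
        m = lca(M[id(c1)], M[id(c2)])
        M[id(node)] = m
        is_dup = m == M[id(c1)] or m == M[id(c2)]
        if is_dup:
            n_dup += 1
        else:
            n_spec += 1
        for c in (c1, c2):
            d = depth[M[id(c)]] - depth[m]
            n_loss += d if is_dup else d - 1
    return (
        costs.duplication * n_dup
        + costs.loss * n_loss
        + costs.speciation * n_spec
    )
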