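"""Dated, classified event records and gene first-appearance estimates.

A reconciliation fixes, for every event, a species branch and time slice
but not an exact date.  Following the convention used when plotting such
histories, speciations are dated at the age of the node where they occur,
while duplications, losses and transfer receptions are dated at the
midpoint of their species branch (optionally at the midpoint of the branch
segment inside the event's slice).  Transfers appear once, as receptions.
The oldest dated event of a family is the first phylogenetic evidence of
that gene's presence — a lower bound on its origin, since events in
lineages that later went extinct leave no trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .chronology import DatedTree, PeriodTable, assign_geological_period, default_period_table
from .reconcile import Reconciliation

__all__ = [
    "DatedEvent",
    "DatedEventLog",
    "OriginEstimate",
    "date_events",
    "first_appearance",
    "bin_events_by_period",
    "events_to_frame",
]

GAIN_EVENT_TYPES = ("speciation", "duplication", "transfer")


@dataclass(frozen=True)
class DatedEvent:
    etype: str
    family: str
    branch: object  # species branch index, or "stem"
    branch_name: str
    date: float  # Ga
    branch_class: str  # internal | terminal
    period: str


@dataclass
class DatedEventLog:
    """Dated events plus the tally of events excluded from dating because
    they took place in the unsampled (dead) lineage."""

    events: list
    dead_event_counts: dict

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)


@dataclass(frozen=True)
class OriginEstimate:
    family: str
    date: float  # oldest event date, Ga
    etype: str
    qualifier: str = "lower bound"


def date_events(
    rec: Reconciliation,
    tree: DatedTree,
    periods: PeriodTable | None = None,
    family: str = "gene",
    slice_midpoint: bool = False,
) -> DatedEventLog:
    """Convert a reconciliation into dated event records.

    Speciations are dated at their node's age; duplications, losses and
    transfer receptions at the midpoint of their species branch (or, with
    ``slice_midpoint=True``, of the branch segment within the event's
    slice).  Origination records and dead-lineage events carry no date on
    the sampled tree; the latter are tallied in the log.
    """
    if periods is None:
        periods = default_period_table()
    boundaries = None
    if slice_midpoint:
        from .chronology import compute_time_slices

        boundaries = compute_time_slices(tree)
    out = []
    dead_counts: dict = {}
    for ev in rec.events:
        if ev.etype == "origination":
            continue
        if ev.branch == "dead":
            dead_counts[ev.etype] = dead_counts.get(ev.etype, 0) + 1
            continue
        if ev.branch == "stem":
            lo = hi = tree.root_age
            branch_name = "stem"
            branch_class = "internal"
        else:
            b = ev.branch
            if not (0 <= b < tree.n_nodes) or b == tree.root:
                raise ValueError(f"event references unknown species branch {b!r}")
            lo, hi = tree.branch_interval(b)
            branch_name = tree.branch_label(b)
            branch_class = "terminal" if not tree.children[b] else "internal"
        if ev.etype == "speciation":
            # the node where the lineage splits = lower end of its branch
            date = lo if ev.branch != "stem" else tree.root_age
        else:
            if slice_midpoint and ev.branch != "stem" and ev.level - 1 < boundaries.n_slices:
                s_lo, s_hi, _ = boundaries.slices[ev.level - 1]
                date = (max(lo, s_lo) + min(hi, s_hi)) / 2.0
            else:
                date = (lo + hi) / 2.0
        out.append(
            DatedEvent(
                etype=ev.etype,
                family=family,
                branch=ev.branch,
                branch_name=branch_name,
                date=float(date),
                branch_class=branch_class,
                period=assign_geological_period(date, periods),
            )
        )
    return DatedEventLog(events=out, dead_event_counts=dead_counts)


def first_appearance(events, family: str, gains_only: bool = False) -> OriginEstimate:
    """Oldest dated event of ``family``: a lower bound on the gene's origin.

    Losses count by default (a loss implies the gene was already present);
    ``gains_only=True`` restricts to speciation/duplication/transfer.
    """
    if isinstance(events, DatedEventLog):
        events = events.events
    pool = [
        e
        for e in events
        if e.family == family and (not gains_only or e.etype in GAIN_EVENT_TYPES)
    ]
    if not pool:
        raise ValueError(f"no dated events for family {family!r}")
    oldest = max(pool, key=lambda e: e.date)
    return OriginEstimate(family=family, date=oldest.date, etype=oldest.etype)


def bin_events_by_period(events, periods: PeriodTable | None = None) -> pd.DataFrame:
    """Contingency table of event counts per (period, event type)."""
    if periods is None:
        periods = default_period_table()
    if isinstance(events, DatedEventLog):
        events = events.events
    etypes = sorted({e.etype for e in events}) or ["speciation"]
    table = pd.DataFrame(0, index=list(periods.names), columns=etypes, dtype=int)
    for e in events:
        if e.date < 0 or e.date > periods.oldest_bound:
            raise ValueError(f"event date {e.date} Ga outside the period table: {e}")
        period = assign_geological_period(e.date, periods)
        table.loc[period, e.etype] += 1
    return table


def events_to_frame(events) -> pd.DataFrame:
    """Events as a tidy DataFrame (TSV-ready)."""
    if isinstance(events, DatedEventLog):
        events = events.events
    return pd.DataFrame(
        [
            {
                "family": e.family,
                "event": e.etype,
                "branch": e.branch_name,
                "date_Ga": e.date,
                "branch_class": e.branch_class,
                "period": e.period,
            }
            for e in events
        ]
    )
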