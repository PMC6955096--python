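"""Virus-host co-speciation mapping by topology comparison.

A virus divergence is taken as a co-speciation event when the host taxa
induced by its child clades exactly reproduce the child clades of some node
of the dated host tree.  Matched events inherit the host node's age as the
calibration time t.  Detection is filtered on clade support (posterior
probability), with explicit include/exclude overrides for events whose
status rests on outside temporal evidence rather than topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .trees import Chronogram, Phylogeny, TipAssociation

__all__ = [
    "CospeciationEvent",
    "ForcedEvent",
    "induced_host_split",
    "host_partition",
    "map_cospeciations",
    "events_to_rows",
]

#: A partition of host taxa: one frozenset per child clade.
HostPartition = frozenset[frozenset[str]]


@dataclass(frozen=True)
class CospeciationEvent:
    """A virus node calibrated by a host node of age ``t`` (myr)."""

    event_id: str
    virus_tips: frozenset[str]
    host_tips: frozenset[str]
    t: float
    support: float | None
    origin: str  # detected | forced | excluded

    def __post_init__(self):
        if self.origin not in {"detected", "forced", "excluded"}:
            raise ValueError(f"invalid event origin {self.origin!r}")
        if self.t <= 0:
            raise ValueError(f"event {self.event_id}: calibration time must be > 0")
        if not self.virus_tips:
            raise ValueError(f"event {self.event_id}: empty virus tip set")


@dataclass(frozen=True)
class ForcedEvent:
    """A manually asserted co-speciation event.

    ``host_tips`` identifies the calibrating host node as the MRCA of the
    given host taxa (a tip pair suffices); ``t_override`` replaces the host
    node age when outside evidence dates the event differently.
    """

    event_id: str
    virus_tips: frozenset[str]
    host_tips: frozenset[str]
    t_override: float | None = None


def induced_host_split(
    virus_node: dendropy.Node, association: TipAssociation
) -> tuple[frozenset[str], ...]:
    """Host taxa induced by each child clade of an internal virus node.

    Duplicate hosts within a child clade are collapsed (one virus per host
    species in typical use).  Returns one host set per child, in child order;
    bifurcations yield a pair.
    """
    children = virus_node.child_nodes()
    if len(children) < 2:
        raise ValueError("induced_host_split requires an internal node with >= 2 children")
    sides = []
    for child in children:
        tips = [leaf.taxon.label for leaf in child.leaf_iter()]
        sides.append(association.hosts_of(tips))
    return tuple(sides)


def host_partition(node: dendropy.Node) -> HostPartition:
    """Partition of tip labels among the child clades of a host internal node."""
    return frozenset(
        frozenset(leaf.taxon.label for leaf in child.leaf_iter())
        for child in node.child_nodes()
    )


def _virus_partition(
    virus_node: dendropy.Node, association: TipAssociation
) -> HostPartition:
    return frozenset(induced_host_split(virus_node, association))


def map_cospeciations(
    virus_tree: Phylogeny,
    host_chronogram: Chronogram,
    association: TipAssociation,
    *,
    min_support: float = 0.75,
    excluded_ids: Iterable[str] = (),
    forced_events: Sequence[ForcedEvent] = (),
    event_labels: Mapping[str, Iterable[str]] | None = None,
    include_excluded: bool = False,
) -> list[CospeciationEvent]:
    """Detect co-speciation events and apply support/override curation.

    A virus internal node is detected iff (a) the partition of host taxa
    induced by its children equals the child-clade partition of some host
    internal node, (b) its support is >= ``min_support`` (missing support
    fails), and (c) its event id is not in ``excluded_ids``.  Forced events
    are appended regardless of (a)-(b), with t taken from the host MRCA of
    their ``host_tips`` (or ``t_override``).

    ``event_labels`` maps stable event ids (e.g. Roman numerals) to virus tip
    sets; detected events matching a labelled tip set take that id, others
    get positional ids N1, N2, ... in preorder.  Excluded events are dropped
    unless ``include_excluded`` (then returned with origin "excluded").
    """
    association.check_covers(virus_tree)
    excluded_ids = set(excluded_ids)
    labels = {
        frozenset(tips): event_id for event_id, tips in (event_labels or {}).items()
    }

    host_index: dict[HostPartition, dendropy.Node] = {}
    for node in host_chronogram.tree.preorder_internal_node_iter():
        host_index[host_partition(node)] = node

    events: list[CospeciationEvent] = []
    used_ids: set[str] = set()
    auto = 0
    for node in virus_tree.tree.preorder_internal_node_iter():
        partition = _virus_partition(node, association)
        host_node = host_index.get(partition)
        if host_node is None:
            continue
        support = node.support
        if support is None or support < min_support:
            continue
        virus_tips = virus_tree.leaf_labels_under(node)
        event_id = labels.get(virus_tips)
        if event_id is None:
            auto += 1
            event_id = f"N{auto}"
        if event_id in used_ids:
            raise ValueError(f"overlapping event id {event_id!r}")
        used_ids.add(event_id)
        origin = "excluded" if event_id in excluded_ids else "detected"
        if origin == "excluded" and not include_excluded:
            continue
        events.append(
            CospeciationEvent(
                event_id=event_id,
                virus_tips=virus_tips,
                host_tips=host_chronogram.leaf_labels_under(host_node),
                t=host_node.age,
                support=support,
                origin=origin,
            )
        )

    for forced in forced_events:
        if forced.event_id in used_ids:
            raise ValueError(f"overlapping event id {forced.event_id!r}")
        used_ids.add(forced.event_id)
        virus_tips = frozenset(forced.virus_tips)
        if not virus_tips:
            raise ValueError(f"forced event {forced.event_id}: empty virus tip set")
        node = virus_tree.mrca(virus_tips)  # raises on unknown tips
        host_node = host_chronogram.mrca(forced.host_tips)
        t = forced.t_override if forced.t_override is not None else host_node.age
        if t <= 0:
            raise ValueError(
                f"forced event {forced.event_id}: calibration time {t} must be > 0 "
                "(host node is a tip?)"
            )
        events.append(
            CospeciationEvent(
                event_id=forced.event_id,
                virus_tips=virus_tips,
                host_tips=host_chronogram.leaf_labels_under(host_node),
                t=t,
                support=node.support,
                origin="forced",
            )
        )
    return events


def events_to_rows(events: Sequence[CospeciationEvent]) -> list[dict]:
    """Flatten events for the TSV report."""
    return [
        {
            "event_id": e.event_id,
            "n_virus_tips": len(e.virus_tips),
            "virus_tips": ";".join(sorted(e.virus_tips)),
            "host_node": ";".join(sorted(e.host_tips)),
            "t": e.t,
            "support": "" if e.support is None else e.support,
            "origin": e.origin,
        }
        for e in events
    ]
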