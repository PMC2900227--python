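"""Ancestral-network estimation by collapsing dated paralogs.

The pre-duplication network is approximated conservatively: paralogous
genes of the selected age class(es) are merged into single ancestral
nodes, and an ancestral link is present whenever *any* interaction exists
between members of the two families.  The copy-level provenance of every
ancestral edge (which present-day edges it stands for) is retained — it is
what the duplication-subgraph classifier reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

from .net_io import AgeClass, ParalogTable, RegulatoryNetwork

log = logging.getLogger("wgdnet")

__all__ = [
    "DuplicateFamily",
    "AncestralNetwork",
    "build_duplicate_families",
    "collapse_network",
    "collapse_sequence",
]

Edge = tuple[str, str]


@dataclass(frozen=True)
class DuplicateFamily:
    """A set of present-day genes sharing one ancestral node.

    Non-trivial families are connected components of the paralogy graph
    restricted to the selected age classes; untouched genes form singleton
    families.  ``family_id`` is deterministic: the lexicographically
    smallest member (optionally prefixed).
    """

    family_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty duplicate family")


@dataclass
class AncestralNetwork:
    """A collapsed network plus the provenance of every ancestral edge.

    ``provenance[(F, G)]`` is the non-empty set of present-day edges the
    ancestral edge (F, G) represents; within-family links (including
    self-loops) map to an ancestral self-loop.  ``family_map`` sends each
    present-day gene to its ancestral node; ``families`` inverts it.
    """

    net: RegulatoryNetwork
    provenance: dict[Edge, frozenset[Edge]]
    family_map: dict[str, str]
    families: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if set(self.provenance) != set(self.net.edges):
            raise ValueError("provenance domain must equal the ancestral edge set")
        if any(not p for p in self.provenance.values()):
            raise ValueError("empty provenance set on an ancestral edge")

    @property
    def edges(self) -> list[Edge]:
        """Ancestral edges in a stable (sorted) order."""
        return sorted(self.net.edges)

    @cached_property
    def presentday_tfs(self) -> frozenset[str]:
        """Present-day genes with outgoing links (sources of provenance edges)."""
        return frozenset(u for prov in self.provenance.values() for u, _ in prov)

    @classmethod
    def trivial(cls, net: RegulatoryNetwork) -> "AncestralNetwork":
        """Skeleton over an existing network: all-singleton families."""
        return cls(
            net=net,
            provenance={e: frozenset([e]) for e in net.edges},
            family_map={n: n for n in net.nodes},
            families={n: frozenset([n]) for n in net.nodes},
        )


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:  # path compression
            p[x], x = root, p[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id wins as root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def build_duplicate_families(
    pairs: ParalogTable | Iterable[tuple[str, str, AgeClass]],
    classes: Iterable[AgeClass],
    nodes: Iterable[str],
    id_prefix: str = "",
) -> list[DuplicateFamily]:
    """Partition ``nodes`` into duplicate families.

    Families are transitive closures (union-find) of paralog pairs whose
    age is in ``classes`` and whose members are both in ``nodes``; all
    remaining nodes become singletons.  Returns families sorted by id.
    """
    classes = frozenset(classes)
    if not classes:
        raise ValueError("empty age-class selection")
    nodes = frozenset(nodes)
    uf = _UnionFind(nodes)
    for a, b, age in pairs:
        if age in classes and a in nodes and b in nodes:
            uf.union(a, b)
    groups: dict[str, set[str]] = {}
    for n in nodes:
        groups.setdefault(uf.find(n), set()).add(n)
    return sorted(
        (
            DuplicateFamily(id_prefix + min(members), frozenset(members))
            for members in groups.values()
        ),
        key=lambda f: f.family_id,
    )


def collapse_network(
    net: RegulatoryNetwork, families: Sequence[DuplicateFamily]
) -> AncestralNetwork:
    """Collapse a network onto its duplicate families.

    An ancestral edge (F, G) exists iff some present-day edge runs from a
    member of F to a member of G; its provenance records all such edges.
    ``families`` must partition ``net.nodes``.
    """
    fam_of: dict[str, str] = {}
    fam_members: dict[str, frozenset[str]] = {}
    for fam in families:
        if fam.family_id in fam_members:
            raise ValueError(f"duplicate family id {fam.family_id!r}")
        fam_members[fam.family_id] = fam.members
        for m in fam.members:
            if m in fam_of:
                raise ValueError(f"gene {m!r} in two families (not a partition)")
            fam_of[m] = fam.family_id
    if set(fam_of) != set(net.nodes):
        raise ValueError("families do not partition the node set")

    prov: dict[Edge, set[Edge]] = {}
    for u, v in net.edges:
        prov.setdefault((fam_of[u], fam_of[v]), set()).add((u, v))
    anc_net = RegulatoryNetwork(
        nodes=frozenset(fam_members), edges=frozenset(prov)
    )
    return AncestralNetwork(
        net=anc_net,
        provenance={e: frozenset(s) for e, s in prov.items()},
        family_map=fam_of,
        families=fam_members,
    )


def collapse_sequence(
    net: RegulatoryNetwork,
    pairs: ParalogTable,
    ordered_classes: Sequence[Iterable[AgeClass]],
    id_prefix: str = "",
) -> list[AncestralNetwork]:
    """Consecutive collapses, youngest age classes first.

    Step ``k`` collapses the output network of step ``k-1``; paralog gene
    identifiers are remapped through the earlier family maps, and pairs
    whose members have already merged are skipped.  Returns every
    intermediate ancestral network (one per step).
    """
    results: list[AncestralNetwork] = []
    current = net
    # composed map original gene -> current node (identity to start)
    composed = {n: n for n in net.nodes}
    for classes in ordered_classes:
        remapped: list[tuple[str, str, AgeClass]] = []
        for a, b, age in pairs:
            ra, rb = composed.get(a), composed.get(b)
            if ra is None or rb is None or ra == rb:
                continue  # outside the network, or already merged
            remapped.append((ra, rb, age))
        # remapped pairs may collide (same family pair via different genes);
        # union-find does not care, so skip ParalogTable re-validation here
        fams = build_duplicate_families(remapped, classes, current.nodes, id_prefix)
        anc = collapse_network(current, fams)
        results.append(anc)
        composed = {g: anc.family_map[n] for g, n in composed.items()}
        current = anc.net
    return results
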