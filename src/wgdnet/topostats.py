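"""Arrangement statistics for duplication subgraphs on the ancestral network.

These are the quantities scored against the one-shot random-coloring null:

* connectedness of the *WGD network* (the subgraph of edges whose DS kept
  two or more links),
* placement of DS classes in the hierarchical decomposition of the
  network (feedback core, upstream / downstream feed-forward parts, and
  the part running beside the core from roots to leaves),
* co-occurrence of DS classes on neighbouring edges (sharing a source,
  sharing a target, or head-to-tail),
* preservation of copy-level regulatory paths through consecutive edges.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .collapse import AncestralNetwork
from .dsubgraph import (
    CLASS_OF_MASK,
    NONTRIVIAL_CLASSES,
    DSClass,
    EdgeColoring,
    pattern_to_mask,
)
from .nullmodels import (
    EnrichmentScore,
    OneShotSpec,
    sample_class_indices,
    sample_pattern_masks,
)

log = logging.getLogger("wgdnet")

__all__ = [
    "HierarchyLabel",
    "ComponentStats",
    "NeighborPairMatrix",
    "wgd_subnetwork_components",
    "connectivity_significance",
    "hierarchy_decompose",
    "hierarchy_enrichment",
    "neighbor_pair_scores",
    "path_preservation_test",
    "pair_indices",
    "path_preserved",
]

Edge = tuple[str, str]

#: class index (into NONTRIVIAL_CLASSES) -> number of links, for fast masks
_N_LINKS = np.array([c.n_links for c in NONTRIVIAL_CLASSES])
_CLASS_INDEX = {c: i for i, c in enumerate(NONTRIVIAL_CLASSES)}


class HierarchyLabel(Enum):
    """Position of an ancestral edge in the hierarchical decomposition."""

    CORE = "core"            # inside a feedback loop (multi-node SCC)
    UPSTREAM = "upstream"    # feeds the core, not fed by it
    DOWNSTREAM = "downstream"  # fed by the core, does not feed it
    SIDE = "side"            # runs beside the core, roots to leaves
    INTERCORE = "intercore"  # both fed by and feeding feedback cores
    SELF = "self"            # self-loop (autoregulator)


@dataclass
class ComponentStats:
    """Connected-component statistics of an edge-induced subgraph.

    Sizes are counted in edges (one nontrivial DS = one edge), matching
    how the WGD network is measured.
    """

    n_components: int
    largest_component_size: int
    component_of_edge: dict[Edge, int]

    @property
    def sizes(self) -> list[int]:
        counts: dict[int, int] = {}
        for cid in self.component_of_edge.values():
            counts[cid] = counts.get(cid, 0) + 1
        return sorted(counts.values(), reverse=True)


def _tf_target_mask(anc: AncestralNetwork) -> np.ndarray:
    """Per-edge flag: the target family contains at least one present-day TF."""
    tfs = anc.presentday_tfs
    is_tf_family = {f: bool(ms & tfs) for f, ms in anc.families.items()}
    return np.array([is_tf_family[g] for _, g in anc.edges], dtype=bool)


def _components_from_mask(
    edges: Sequence[Edge], keep: np.ndarray
) -> tuple[int, int, dict[Edge, int]]:
    """Weakly-connected components of the subgraph induced by kept edges."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for k in np.flatnonzero(keep):
        u, v = edges[k]
        parent.setdefault(u, u)
        parent.setdefault(v, v)
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[rv] = ru
    comp_ids: dict[str, int] = {}
    comp_of_edge: dict[Edge, int] = {}
    sizes: dict[int, int] = {}
    for k in np.flatnonzero(keep):
        u, _ = edges[k]
        root = find(u)
        cid = comp_ids.setdefault(root, len(comp_ids))
        comp_of_edge[edges[k]] = cid
        sizes[cid] = sizes.get(cid, 0) + 1
    largest = max(sizes.values()) if sizes else 0
    return len(sizes), largest, comp_of_edge


def wgd_subnetwork_components(
    coloring: EdgeColoring,
    anc: AncestralNetwork,
    tf_only: bool = False,
    directed: bool = False,
) -> ComponentStats:
    """Component structure of the WGD network (edges with >= 2 links).

    ``tf_only`` keeps only edges whose target family contains a TF — the
    essential part of the WGD network, since only TFs send out links.
    Connectivity is weak (undirected) by default; ``directed=True`` counts
    strong connectivity instead (edges joining distinct SCCs become their
    own components).
    """
    edges = anc.edges
    keep = np.array(
        [coloring.assignment[e].ds.nontrivial for e in edges], dtype=bool
    )
    if tf_only:
        keep &= _tf_target_mask(anc)
    if not directed:
        n, largest, comp = _components_from_mask(edges, keep)
        return ComponentStats(n, largest, comp)
    g = nx.DiGraph()
    g.add_edges_from(edges[k] for k in np.flatnonzero(keep))
    scc_of = {}
    for cid, scc in enumerate(nx.strongly_connected_components(g)):
        for node in scc:
            scc_of[node] = cid
    comp: dict[Edge, int] = {}
    next_id = len(set(scc_of.values()))
    sizes: dict[int, int] = {}
    for k in np.flatnonzero(keep):
        u, v = edges[k]
        if scc_of[u] == scc_of[v]:
            cid = scc_of[u]
        else:
            cid = next_id
            next_id += 1
        comp[edges[k]] = cid
        sizes[cid] = sizes.get(cid, 0) + 1
    return ComponentStats(len(sizes), max(sizes.values(), default=0), comp)


def connectivity_significance(
    coloring: EdgeColoring,
    anc: AncestralNetwork,
    spec: OneShotSpec,
    n_real: int = 4000,
    seed: int | None = None,
    tf_only: bool = False,
) -> tuple[EnrichmentScore, EnrichmentScore]:
    """Is the WGD network more connected than a random coloring allows?

    Returns scores for the number of connected components (lower tail —
    few components means connected) and the size of the largest component
    (upper tail), each against ``n_real`` one-shot realizations.
    """
    edges = anc.edges
    tf_mask = _tf_target_mask(anc) if tf_only else np.ones(len(edges), dtype=bool)
    obs_keep = np.array(
        [coloring.assignment[e].ds.nontrivial for e in edges], dtype=bool
    ) & tf_mask
    obs_n, obs_largest, _ = _components_from_mask(edges, obs_keep)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    null_n = np.empty(n_real)
    null_largest = np.empty(n_real)
    for r in range(n_real):
        cls = sample_class_indices(len(edges), spec, rng)
        keep = (_N_LINKS[cls] >= 2) & tf_mask
        null_n[r], null_largest[r], _ = _components_from_mask(edges, keep)
    return (
        EnrichmentScore.from_null(obs_n, null_n, tail="lower"),
        EnrichmentScore.from_null(obs_largest, null_largest, tail="upper"),
    )


# ---------------------------------------------------------------------------
# hierarchy decomposition
# ---------------------------------------------------------------------------


def hierarchy_decompose(anc: AncestralNetwork) -> dict[Edge, HierarchyLabel]:
    """Label every ancestral edge by its hierarchical position.

    The feedback core is the set of edges inside multi-node strongly
    connected components.  Any other edge u→v is UPSTREAM if v can reach a
    core and u cannot be reached from one, DOWNSTREAM in the mirror case,
    INTERCORE if both hold, and SIDE if neither (in a core-free network
    every non-self edge is SIDE, connecting roots to leaves).  Self-loops
    are labelled SELF regardless of position.
    """
    g = anc.net.to_networkx()
    scc_of: dict[str, int] = {}
    core_nodes: set[str] = set()
    for cid, scc in enumerate(nx.strongly_connected_components(g)):
        for node in scc:
            scc_of[node] = cid
        if len(scc) >= 2:
            core_nodes |= scc
    # nodes reachable from a core / nodes that can reach a core
    fed_by_core: set[str] = set(core_nodes)
    for node in core_nodes:
        fed_by_core |= nx.descendants(g, node)
    reaches_core: set[str] = set(core_nodes)
    g_rev = g.reverse(copy=False)
    for node in core_nodes:
        reaches_core |= nx.descendants(g_rev, node)

    labels: dict[Edge, HierarchyLabel] = {}
    for u, v in anc.edges:
        if u == v:
            labels[(u, v)] = HierarchyLabel.SELF
        elif scc_of[u] == scc_of[v] and u in core_nodes:
            labels[(u, v)] = HierarchyLabel.CORE
        else:
            down = u in fed_by_core
            up = v in reaches_core
            if up and not down:
                labels[(u, v)] = HierarchyLabel.UPSTREAM
            elif down and not up:
                labels[(u, v)] = HierarchyLabel.DOWNSTREAM
            elif down and up:
                labels[(u, v)] = HierarchyLabel.INTERCORE
            else:
                labels[(u, v)] = HierarchyLabel.SIDE
    return labels


def hierarchy_enrichment(
    coloring: EdgeColoring,
    labeling: dict[Edge, HierarchyLabel],
    anc: AncestralNetwork,
    spec: OneShotSpec,
    n_real: int = 1000,
    seed: int | None = None,
) -> dict[tuple[HierarchyLabel, DSClass], EnrichmentScore]:
    """Count each DS class within each hierarchy component vs the one-shot null.

    The labeling stays fixed; only colors are resampled.  A component with
    zero edges yields observed 0 with a degenerate (sd = 0) null.
    """
    edges = anc.edges
    if set(labeling) != set(edges):
        raise ValueError("labeling domain does not match the ancestral edges")
    label_list = list(HierarchyLabel)
    lab_idx = np.array([label_list.index(labeling[e]) for e in edges])
    n_lab, n_cls = len(label_list), len(NONTRIVIAL_CLASSES)

    def cell_counts(cls_idx: np.ndarray) -> np.ndarray:
        return np.bincount(lab_idx * n_cls + cls_idx, minlength=n_lab * n_cls)

    obs_cls = np.array([_CLASS_INDEX[coloring.assignment[e].ds] for e in edges])
    observed = cell_counts(obs_cls)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    nulls = np.empty((n_real, n_lab * n_cls))
    for r in range(n_real):
        nulls[r] = cell_counts(sample_class_indices(len(edges), spec, rng))
    scores: dict[tuple[HierarchyLabel, DSClass], EnrichmentScore] = {}
    for li, lab in enumerate(label_list):
        for ci, cls in enumerate(NONTRIVIAL_CLASSES):
            k = li * n_cls + ci
            scores[(lab, cls)] = EnrichmentScore.from_null(
                observed[k], nulls[:, k], tail="two-sided"
            )
    return scores


# ---------------------------------------------------------------------------
# neighbor pairs
# ---------------------------------------------------------------------------

RELATIONS = ("ADJ_OUT", "ADJ_IN", "CONSECUTIVE")


@dataclass
class NeighborPairMatrix:
    """Raw co-occurrence counts of DS classes on neighbouring edges.

    ``ADJ_OUT`` / ``ADJ_IN`` count unordered pairs (symmetric matrices,
    stored on the upper triangle with ``counts[(c1, c2)]`` for c1 <= c2 in
    class order); ``CONSECUTIVE`` counts ordered (upstream, downstream)
    pairs.
    """

    relation: str
    counts: dict[tuple[DSClass, DSClass], int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def pair_indices(anc: AncestralNetwork) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Index arrays of all neighbouring edge pairs, per relation.

    Edges are indexed by their position in ``anc.edges``.  ADJ_OUT pairs
    share a source, ADJ_IN share a target (both unordered, i < j in edge
    order); CONSECUTIVE pairs are ordered (a's target is b's source), with
    a self-loop never consecutive with itself.
    """
    edges = anc.edges
    by_source: dict[str, list[int]] = {}
    by_target: dict[str, list[int]] = {}
    for k, (u, v) in enumerate(edges):
        by_source.setdefault(u, []).append(k)
        by_target.setdefault(v, []).append(k)

    def combos(groups: dict[str, list[int]]) -> tuple[np.ndarray, np.ndarray]:
        a, b = [], []
        for ks in groups.values():
            for i, j in itertools.combinations(ks, 2):
                a.append(i)
                b.append(j)
        return np.array(a, dtype=np.int64), np.array(b, dtype=np.int64)

    cons_a, cons_b = [], []
    for k, (u, v) in enumerate(edges):
        for k2 in by_source.get(v, ()):
            if k2 != k:
                cons_a.append(k)
                cons_b.append(k2)
    return {
        "ADJ_OUT": combos(by_source),
        "ADJ_IN": combos(by_target),
        "CONSECUTIVE": (np.array(cons_a, dtype=np.int64),
                        np.array(cons_b, dtype=np.int64)),
    }


def _pair_cell_counts(
    cls_idx: np.ndarray, ia: np.ndarray, ib: np.ndarray, ordered: bool
) -> np.ndarray:
    """Flattened 6x6 cell counts for one relation and one coloring."""
    n = len(NONTRIVIAL_CLASSES)
    ca, cb = cls_idx[ia], cls_idx[ib]
    if not ordered:  # canonicalize unordered pairs onto the upper triangle
        lo = np.minimum(ca, cb)
        hi = np.maximum(ca, cb)
        ca, cb = lo, hi
    return np.bincount(ca * n + cb, minlength=n * n)


def neighbor_pair_scores(
    coloring: EdgeColoring,
    anc: AncestralNetwork,
    spec: OneShotSpec,
    n_real: int = 1000,
    seed: int | None = None,
    classes: Sequence[DSClass] | None = (DSClass.ZETA, DSClass.BETA, DSClass.GAMMA),
) -> tuple[
    dict[tuple[str, DSClass, DSClass], EnrichmentScore],
    dict[str, NeighborPairMatrix],
]:
    """Co-occurrence of DS classes on neighbouring edges vs the one-shot null.

    Returns per-cell enrichment scores (restricted by default to the
    ζ/β/γ classes that dominate the network; pass ``classes=None`` for all
    cells) together with the raw observed count matrices.
    """
    edges = anc.edges
    pairs = pair_indices(anc)
    n = len(NONTRIVIAL_CLASSES)
    obs_cls = np.array([_CLASS_INDEX[coloring.assignment[e].ds] for e in edges])

    observed = {
        rel: _pair_cell_counts(obs_cls, *pairs[rel], ordered=(rel == "CONSECUTIVE"))
        for rel in RELATIONS
    }
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    nulls = {rel: np.empty((n_real, n * n)) for rel in RELATIONS}
    for r in range(n_real):
        cls = sample_class_indices(len(edges), spec, rng)
        for rel in RELATIONS:
            nulls[rel][r] = _pair_cell_counts(
                cls, *pairs[rel], ordered=(rel == "CONSECUTIVE")
            )

    wanted = frozenset(NONTRIVIAL_CLASSES if classes is None else classes)
    scores: dict[tuple[str, DSClass, DSClass], EnrichmentScore] = {}
    matrices: dict[str, NeighborPairMatrix] = {}
    for rel in RELATIONS:
        ordered = rel == "CONSECUTIVE"
        counts: dict[tuple[DSClass, DSClass], int] = {}
        for i, c1 in enumerate(NONTRIVIAL_CLASSES):
            for j, c2 in enumerate(NONTRIVIAL_CLASSES):
                if not ordered and j < i:
                    continue
                k = i * n + j
                cnt = int(observed[rel][k])
                counts[(c1, c2)] = cnt
                if c1 in wanted and c2 in wanted:
                    scores[(rel, c1, c2)] = EnrichmentScore.from_null(
                        cnt, nulls[rel][:, k], tail="two-sided"
                    )
        matrices[rel] = NeighborPairMatrix(relation=rel, counts=counts)
    return scores, matrices


# ---------------------------------------------------------------------------
# path preservation
# ---------------------------------------------------------------------------

def _preserved_table() -> np.ndarray:
    """16x16 truth table of the copy-level path-preservation predicate.

    A consecutive pair (A→B, B→C) preserves a pathway iff some copy of B
    both receives a link in the upstream pattern and sends one in the
    downstream pattern.
    """
    table = np.zeros((16, 16), dtype=bool)
    for m1 in range(16):
        b1 = bool(m1 & 0b0101)  # B copy 1 receives: links (1,1) or (2,1)
        b2 = bool(m1 & 0b1010)  # B copy 2 receives: links (1,2) or (2,2)
        for m2 in range(16):
            s1 = bool(m2 & 0b0011)  # B copy 1 sends: links (1,1) or (1,2)
            s2 = bool(m2 & 0b1100)  # B copy 2 sends: links (2,1) or (2,2)
            table[m1, m2] = (b1 and s1) or (b2 and s2)
    return table


PRESERVED_TABLE = _preserved_table()


def path_preserved(upstream_pattern, downstream_pattern) -> bool:
    """Does a copy-level path survive through the shared middle family?"""
    return bool(
        PRESERVED_TABLE[
            pattern_to_mask(upstream_pattern), pattern_to_mask(downstream_pattern)
        ]
    )


def path_preservation_test(
    anc: AncestralNetwork,
    coloring: EdgeColoring,
    spec: OneShotSpec,
    n_real: int = 1000,
    seed: int | None = None,
) -> tuple[EnrichmentScore, list[tuple[Edge, Edge, bool]]]:
    """Fraction of consecutive pairs whose copy-level path is unbroken.

    Scored upper-tail against one-shot colorings with pattern sampling
    (the null needs concrete patterns, drawn by ``spec.pattern_rule``).
    Requires the observed coloring to carry patterns on every edge.
    """
    edges = anc.edges
    for e in edges:
        if not coloring.assignment[e].pattern:
            raise ValueError(f"edge {e} has no link pattern")
    ia, ib = pair_indices(anc)["CONSECUTIVE"]
    if len(ia) == 0:
        raise ValueError("network has no consecutive edge pairs")
    obs_masks = np.array(
        [pattern_to_mask(coloring.assignment[e].pattern) for e in edges]
    )
    obs_flags = PRESERVED_TABLE[obs_masks[ia], obs_masks[ib]]
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    nulls = np.empty(n_real)
    for r in range(n_real):
        cls = sample_class_indices(len(edges), spec, rng)
        masks = sample_pattern_masks(cls, spec, rng)
        nulls[r] = PRESERVED_TABLE[masks[ia], masks[ib]].mean()
    score = EnrichmentScore.from_null(obs_flags.mean(), nulls, tail="upper")
    detail = [
        (edges[ia[k]], edges[ib[k]], bool(obs_flags[k])) for k in range(len(ia))
    ]
    return score, detail
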