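"""Ground-truthed synthetic data: a planted WGD over a generated ancestor.

The generator inverts the analysis pipeline.  It builds a directed
ancestral network (a TF layer wired by a heavy-tailed out-degree law to
TFs and targets, plus back-edges that create feedback cores), plants a
duplication-subgraph coloring on its edges (i.i.d. at prescribed class
frequencies, or as an equilibrium draw of the spin model), and then
*expands* every node into a WGD copy pair, emitting exactly the
copy-level links of each edge's pattern.  The result is a present-day
network plus a matching paralog table whose collapse must recover the
planted ancestor and coloring — the module's round-trip guarantee, which
every pipeline stage is tested against.

Copies left without links are kept as isolated nodes, so the "isolated
copies are eventually lost" assumption is exercised by the classifier
rather than hidden by the generator.  Optional small-scale POST pairs
(splitting random present-day copies) and decoy PRE pairs exercise the
age-class machinery; the round trip then holds after the POST
pre-collapse step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .collapse import AncestralNetwork
from .dsubgraph import (
    MASKS_OF_CLASS,
    NONTRIVIAL_CLASSES,
    ColoredEdge,
    DSClass,
    EdgeColoring,
    mask_to_pattern,
)
from .net_io import AgeClass, ParalogTable, RegulatoryNetwork
from .nullmodels import OneShotSpec, sample_oneshot_coloring
from .spinmodel import SpinParams, metropolis_sample
from .topostats import HierarchyLabel, hierarchy_decompose

log = logging.getLogger("wgdnet")

__all__ = [
    "DEFAULT_CLASS_PROBS",
    "SyntheticSpec",
    "GroundTruth",
    "generate_ancestral_network",
    "plant_coloring",
    "expand_to_presentday",
    "generate_dataset",
]

#: Default planted class frequencies: the empirical WGD duplication-subgraph
#: occurrence in the yeast transcription network (ζ 94.51%, β 1.1%, γ 4.2%,
#: α 0.041%, δ 0.049%, ε 0.066%), renormalized to sum to one.
_raw = {
    DSClass.ZETA: 0.9451,
    DSClass.ALPHA: 0.00041,
    DSClass.BETA: 0.011,
    DSClass.GAMMA: 0.042,
    DSClass.DELTA: 0.00049,
    DSClass.EPSILON: 0.00066,
}
_total = sum(_raw.values())
DEFAULT_CLASS_PROBS: dict[DSClass, float] = {c: p / _total for c, p in _raw.items()}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic world.

    Defaults emulate the yeast dataset at reduced scale: ~120 regulators
    over ~1800 genes, a heavy-tailed out-degree law (p(k) ∝ k^-1.1 capped
    at 300, mean ≈ 50), a small feedback core, planted DS frequencies at
    the empirical yeast WGD values, and a sprinkling of small-scale
    post-WGD duplicates.
    """

    n_tf: int = 120
    n_target: int = 1800
    out_degree_exponent: float = 1.1
    out_degree_max: int = 300
    core_backedges: int = 25
    coloring_mode: str = "iid"                       # "iid" | "spin"
    class_probabilities: Mapping[DSClass, float] | None = None
    spin_params: SpinParams | None = None
    age_mix: Mapping[str, float] = field(
        default_factory=lambda: {"POST": 0.05, "PRE": 0.02}
    )
    post_link_retention: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tf < 1:
            raise ValueError("n_tf must be >= 1")
        if self.coloring_mode not in ("iid", "spin"):
            raise ValueError(f"unknown coloring_mode {self.coloring_mode!r}")
        if self.class_probabilities is None:
            self.class_probabilities = dict(DEFAULT_CLASS_PROBS)
        total = sum(self.class_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities sum to {total}")
        if self.coloring_mode == "spin" and self.spin_params is None:
            self.spin_params = SpinParams(seed=self.seed)
        for g in self.age_mix:
            if g not in ("PRE", "POST"):
                raise ValueError(f"age_mix group must be PRE or POST, got {g!r}")


@dataclass
class GroundTruth:
    """Everything the pipeline should recover from the emitted dataset."""

    ancestral: AncestralNetwork
    coloring: EdgeColoring
    alias: dict[str, str]            # ancestral node -> its post-collapse id
    hierarchy: dict[tuple[str, str], HierarchyLabel]
    wgd_pairs: tuple[tuple[str, str], ...]
    spec: SyntheticSpec

    def expected_edges(self) -> frozenset[tuple[str, str]]:
        """Planted ancestral edges renamed to the ids the collapse produces."""
        return frozenset(
            (self.alias[u], self.alias[v]) for u, v in self.ancestral.net.edges
        )

    def expected_classes(self) -> dict[tuple[str, str], DSClass]:
        return {
            (self.alias[u], self.alias[v]): ce.ds
            for (u, v), ce in self.coloring.assignment.items()
        }


def _sample_out_degrees(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    kmax = min(spec.out_degree_max, spec.n_tf + spec.n_target - 1)
    k = np.arange(1, kmax + 1, dtype=float)
    p = k ** -spec.out_degree_exponent
    p /= p.sum()
    return rng.choice(np.arange(1, kmax + 1), size=spec.n_tf, p=p)


def generate_ancestral_network(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> AncestralNetwork:
    """Build the ancestral (pre-duplication) network skeleton.

    TFs draw out-degrees from the power law and wire uniformly to any
    other node (TF or target, no self-loops); ``core_backedges`` edges are
    then added closing existing directed paths between TFs, which plants
    feedback strongly connected components.  Returned with all-singleton
    provenance so downstream code sees a regular :class:`AncestralNetwork`.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    tfs = [f"tf{i:04d}" for i in range(spec.n_tf)]
    targets = [f"tgt{i:05d}" for i in range(spec.n_target)]
    nodes = np.array(tfs + targets)
    degrees = _sample_out_degrees(spec, rng)
    if degrees.max() > len(nodes) - 1:
        raise ValueError("out-degree demand exceeds available nodes")
    edges: set[tuple[str, str]] = set()
    for i, tf in enumerate(tfs):
        others = np.delete(np.arange(len(nodes)), i)
        chosen = rng.choice(others, size=degrees[i], replace=False)
        edges.update((tf, str(nodes[j])) for j in chosen)

    # back-edges: close a directed TF->...->TF path to create feedback
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(nodes.tolist())
    g.add_edges_from(edges)
    added = 0
    for _ in range(spec.core_backedges * 20):
        if added >= spec.core_backedges:
            break
        a = tfs[rng.integers(0, len(tfs))]
        # sorted: set iteration order is hash-randomized across processes
        reachable_tfs = sorted(t for t in nx.descendants(g, a)
                               if t.startswith("tf")
                               and t != a and (t, a) not in edges)
        if not reachable_tfs:
            continue
        b = reachable_tfs[rng.integers(0, len(reachable_tfs))]
        edges.add((b, a))
        g.add_edge(b, a)
        added += 1
    if added < spec.core_backedges:
        log.warning("generated only %d of %d requested back-edges",
                    added, spec.core_backedges)
    net = RegulatoryNetwork.from_edges(edges, extra_nodes=nodes.tolist())
    return AncestralNetwork.trivial(net)


def plant_coloring(
    anc: AncestralNetwork,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> EdgeColoring:
    """Plant a DS coloring (with concrete link patterns) on the ancestor.

    ``iid`` mode reuses the one-shot sampler at the spec's class
    frequencies; ``spin`` mode takes the final configuration of a
    Metropolis run (ζ/β/γ only) and attaches patterns uniformly within
    each class.  η is never planted: every ancestral edge keeps at least
    one copy-level link.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    if spec.coloring_mode == "iid":
        oneshot = OneShotSpec(
            class_probabilities=dict(spec.class_probabilities),
            mode="multinomial",
            pattern_rule="uniform",
        )
        return sample_oneshot_coloring(anc, oneshot, rng=rng)
    run = metropolis_sample(anc, spec.spin_params, store_configs=False)
    assignment = {}
    for e, ds in run.final_config().items():
        masks = MASKS_OF_CLASS[ds]
        pattern = mask_to_pattern(int(masks[rng.integers(0, len(masks))]))
        assignment[e] = ColoredEdge(ds=ds, pattern=pattern,
                                    self_loop=(e[0] == e[1]))
    return EdgeColoring(assignment)


def expand_to_presentday(
    anc: AncestralNetwork,
    coloring: EdgeColoring,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[RegulatoryNetwork, ParalogTable, GroundTruth]:
    """Duplicate the whole ancestral network under the planted coloring.

    Every ancestral node F becomes the WGD pair (F_1, F_2); every
    ancestral edge emits exactly the copy-level edges of its pattern.
    ``age_mix['POST']`` then splits that fraction of present-day nodes
    into small-scale post-WGD duplicates (the original keeps all its
    links; the copy inherits each with probability
    ``post_link_retention``), and ``age_mix['PRE']`` adds decoy pre-WGD
    pairs between random unrelated nodes.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    copies = {f: (f + "_1", f + "_2") for f in sorted(anc.net.nodes)}
    nodes: list[str] = [c for pair in copies.values() for c in pair]
    edges: set[tuple[str, str]] = set()
    for (f, g), ce in coloring.assignment.items():
        for i, j in ce.pattern:
            edges.add((copies[f][i - 1], copies[g][j - 1]))
    pairs: list[tuple[str, str, AgeClass]] = [
        (c1, c2, AgeClass.WGD) for c1, c2 in copies.values()
    ]

    # small-scale post-WGD duplicates: split random present-day copies
    post_frac = spec.age_mix.get("POST", 0.0)
    n_post = int(round(post_frac * len(nodes)))
    post_classes = [a for a in AgeClass if a.group == "POST"]
    if n_post:
        split = rng.choice(len(nodes), size=n_post, replace=False)
        for k in split:
            u = nodes[k]
            u_new = u + "p"
            for x, y in sorted(e for e in edges if u in e):
                if rng.random() < spec.post_link_retention:
                    edges.add((u_new if x == u else x, u_new if y == u else y))
            nodes.append(u_new)
            pairs.append((u, u_new,
                          post_classes[rng.integers(0, len(post_classes))]))

    # decoy pre-WGD pairs between unrelated nodes (exercise the age classes;
    # they are never collapsed by the POST->WGD pipeline)
    pre_frac = spec.age_mix.get("PRE", 0.0)
    n_pre = int(round(pre_frac * len(nodes)))
    pre_classes = [a for a in AgeClass if a.group == "PRE"]
    paired = {frozenset((a, b)) for a, b, _ in pairs}
    tries = 0
    while n_pre > 0 and tries < 50 * n_pre:
        tries += 1
        a, b = rng.choice(len(nodes), size=2, replace=False)
        key = frozenset((nodes[a], nodes[b]))
        if len(key) < 2 or key in paired:
            continue
        paired.add(key)
        pairs.append((nodes[a], nodes[b],
                      pre_classes[rng.integers(0, len(pre_classes))]))
        n_pre -= 1

    net = RegulatoryNetwork.from_edges(edges, extra_nodes=nodes)
    table = ParalogTable.from_records(pairs)
    truth = GroundTruth(
        ancestral=anc,
        coloring=coloring,
        alias={f: copies[f][0] for f in copies},
        hierarchy=hierarchy_decompose(anc),
        wgd_pairs=tuple((c1, c2) for c1, c2 in copies.values()),
        spec=spec,
    )
    return net, table, truth


def generate_dataset(
    spec: SyntheticSpec | None = None, seed: int | None = None
) -> tuple[RegulatoryNetwork, ParalogTable, GroundTruth]:
    """Convenience: ancestral network → planted coloring → present-day data."""
    if spec is None:
        spec = SyntheticSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    anc = generate_ancestral_network(spec, rng=rng)
    coloring = plant_coloring(anc, spec, rng=rng)
    return expand_to_presentday(anc, coloring, spec, rng=rng)
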