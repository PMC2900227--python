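"""Plain-text I/O for regulatory networks, paralog tables and annotated edges.

On-disk contracts are deliberately simple:

* **edge list** — two whitespace/tab-separated columns per line,
  ``regulator  target``; ``#`` starts a comment; an optional one-column
  nodes file adds isolated genes.
* **paralog table** — three columns, ``gene_a  gene_b  age_label``, where
  the age label resolves through a dialect mapping to one of the nine fine
  duplication age classes (three pre-WGD, the WGD class itself, five
  post-WGD).
* **annotated edges** — TSV serialisation of a colored ancestral network
  (one row per ancestral edge with its duplication-subgraph class, link
  pattern and descendant present-day edges), plus a Graphviz DOT export.

Everything here validates on read; parse errors carry line numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import networkx as nx

log = logging.getLogger("wgdnet")

__all__ = [
    "AgeClass",
    "ParalogPair",
    "ParalogTable",
    "RegulatoryNetwork",
    "read_paralog_table",
    "read_regulatory_network",
    "read_roles",
    "write_network",
    "write_annotated_edges",
    "read_annotated_edges",
    "export_dot",
]


def check_gene_id(token: str) -> str:
    """Validate a gene identifier: non-empty, no whitespace, case preserved."""
    if not token or token.split() != [token]:
        raise ValueError(f"invalid gene identifier: {token!r}")
    return token


class AgeClass(Enum):
    """Fine duplication age class.

    Nine classes: three pre-WGD groups, the whole-genome-duplication class,
    and five post-WGD groups of small-scale duplicates.  ``group`` collapses
    them to the coarse PRE / WGD / POST partition used by most analyses.
    Classes are totally ordered from youngest (``POST_5``) to oldest
    (``PRE_3``); only the coarse ordering is meaningful biologically.
    """

    POST_5 = "POST_5"
    POST_4 = "POST_4"
    POST_3 = "POST_3"
    POST_2 = "POST_2"
    POST_1 = "POST_1"
    WGD = "WGD"
    PRE_1 = "PRE_1"
    PRE_2 = "PRE_2"
    PRE_3 = "PRE_3"

    @property
    def group(self) -> str:
        """Coarse label in {'PRE', 'WGD', 'POST'}."""
        return "WGD" if self is AgeClass.WGD else self.name.split("_")[0]

    @property
    def rank(self) -> int:
        """Position in the youngest-to-oldest total order (0 = youngest)."""
        return _AGE_ORDER.index(self)

    @classmethod
    def of_group(cls, group: str) -> frozenset["AgeClass"]:
        """All fine classes belonging to a coarse group."""
        members = frozenset(a for a in cls if a.group == group)
        if not members:
            raise ValueError(f"unknown age group: {group!r}")
        return members


_AGE_ORDER = list(AgeClass)

#: Default age-label dialect: the enum names themselves, case-insensitively,
#: with or without the underscore (``post1`` == ``POST_1``).
DEFAULT_AGE_DIALECT: dict[str, AgeClass] = {}
for _a in AgeClass:
    DEFAULT_AGE_DIALECT[_a.name] = _a
    DEFAULT_AGE_DIALECT[_a.name.replace("_", "")] = _a


class ParalogPair(NamedTuple):
    gene_a: str
    gene_b: str
    age: AgeClass


@dataclass(frozen=True)
class RegulatoryNetwork:
    """A directed transcription network: regulator → target edges.

    Self-loops (autoregulators) are permitted.  ``tf_set`` is derived:
    a node is a transcription factor iff it sends out at least one link.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge endpoint not in node set: ({u}, {v})")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "RegulatoryNetwork":
        edges = frozenset((check_gene_id(u), check_gene_id(v)) for u, v in edges)
        nodes = {u for e in edges for u in e} | {check_gene_id(n) for n in extra_nodes}
        return cls(nodes=frozenset(nodes), edges=edges)

    @cached_property
    def tf_set(self) -> frozenset[str]:
        return frozenset(u for u, _ in self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class ParalogTable:
    """Dated duplicate pairs.

    Each record is an unordered gene pair with a fine age class; pairs are
    stored with members in lexicographic order so equality and deduplication
    are orientation-free.  Genes absent from a network are tolerated here
    and dropped (with a logged count) by :meth:`restrict_to`.
    """

    records: tuple[ParalogPair, ...] = field(default=())

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, AgeClass]]
    ) -> "ParalogTable":
        seen: dict[tuple[str, str], AgeClass] = {}
        for a, b, age in records:
            a, b = check_gene_id(a), check_gene_id(b)
            if a == b:
                raise ValueError(f"self-pair in paralog table: {a}")
            key = (a, b) if a < b else (b, a)
            if key in seen:
                if seen[key] is not age:
                    raise ValueError(
                        f"conflicting ages for pair {key}: {seen[key].name} vs {age.name}"
                    )
                continue  # identical duplicate: dedup silently
            seen[key] = age
        recs = tuple(
            ParalogPair(a, b, age) for (a, b), age in sorted(seen.items(),
                                                            key=lambda kv: kv[0])
        )
        return cls(records=recs)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for r in self.records for g in (r.gene_a, r.gene_b))

    def select(self, classes: Iterable[AgeClass]) -> "ParalogTable":
        classes = frozenset(classes)
        return ParalogTable(tuple(r for r in self.records if r.age in classes))

    def select_group(self, group: str) -> "ParalogTable":
        return self.select(AgeClass.of_group(group))

    def restrict_to(self, nodes: Iterable[str]) -> "ParalogTable":
        """Drop pairs with a member outside ``nodes`` (logged, not an error)."""
        nodes = frozenset(nodes)
        kept = tuple(
            r for r in self.records if r.gene_a in nodes and r.gene_b in nodes
        )
        dropped = len(self.records) - len(kept)
        if dropped:
            log.warning("paralog table: dropped %d pair(s) outside the network", dropped)
        return ParalogTable(kept)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _data_lines(path: Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if line:
                yield lineno, line


def read_regulatory_network(
    path: str | Path, nodes_path: str | Path | None = None
) -> RegulatoryNetwork:
    """Read a two-column directed edge list.

    Duplicated lines are deduplicated with a logged count; an optional
    one-column ``nodes_path`` file declares isolated genes.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        cols = line.split()
        if len(cols) < 2:
            raise ValueError(f"{path}:{lineno}: expected >= 2 columns, got {line!r}")
        edges.append((check_gene_id(cols[0]), check_gene_id(cols[1])))
    if not edges:
        raise ValueError(f"{path}: empty edge list")
    n_dup = len(edges) - len(set(edges))
    if n_dup:
        log.warning("%s: %d duplicated edge line(s) removed", path, n_dup)
    extra: list[str] = []
    if nodes_path is not None:
        for lineno, line in _data_lines(Path(nodes_path)):
            extra.append(line.split()[0])
    return RegulatoryNetwork.from_edges(edges, extra_nodes=extra)


def write_network(net: RegulatoryNetwork, path: str | Path,
                  nodes_path: str | Path | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")
    isolated = sorted(net.nodes - {n for e in net.edges for n in e})
    if nodes_path is not None:
        with open(nodes_path, "w") as fh:
            for n in isolated:
                fh.write(n + "\n")
    elif isolated:
        log.warning("write_network: %d isolated node(s) not serialized "
                    "(no nodes_path given)", len(isolated))


def read_paralog_table(
    path: str | Path, age_dialect: Mapping[str, AgeClass] | None = None
) -> ParalogTable:
    """Read a three-column paralog table (gene, gene, age label)."""
    dialect = dict(DEFAULT_AGE_DIALECT if age_dialect is None else age_dialect)
    path = Path(path)
    records: list[tuple[str, str, AgeClass]] = []
    for lineno, line in _data_lines(path):
        cols = line.split()
        if len(cols) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {line!r}")
        label = cols[2]
        age = dialect.get(label, dialect.get(label.upper()))
        if age is None:
            accepted = ", ".join(sorted(dialect))
            raise ValueError(
                f"{path}:{lineno}: unknown age label {label!r}; accepted: {accepted}"
            )
        records.append((cols[0], cols[1], age))
    return ParalogTable.from_records(records)


def write_paralog_table(pairs: ParalogTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, age in pairs:
            fh.write(f"{a}\t{b}\t{age.name}\n")


def read_roles(path: str | Path) -> frozenset[str]:
    """Read an optional roles file; returns the set of genes declared 'TF'."""
    tfs = set()
    for lineno, line in _data_lines(Path(path)):
        cols = line.split()
        if len(cols) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns (gene, role)")
        if cols[1].upper() == "TF":
            tfs.add(check_gene_id(cols[0]))
    return frozenset(tfs)


# -- annotated ancestral edges ----------------------------------------------

_ANNOT_HEADER = "ancestral_source\tancestral_target\tds_class\tn_links\tpattern\tdescendant_edges"


def write_annotated_edges(coloring, anc, path: str | Path) -> None:
    """Serialize a colored ancestral network to TSV.

    One row per ancestral edge: endpoints, duplication-subgraph class, link
    count, the concrete 2x2 link pattern (``i:j`` tokens joined by ``,``)
    and the descendant present-day edges (``u->v`` joined by ``|``).
    """
    if set(coloring.assignment) != set(anc.provenance):
        raise ValueError("coloring domain does not match the ancestral edge set")
    with open(path, "w") as fh:
        fh.write(_ANNOT_HEADER + "\n")
        for (f, g) in sorted(anc.provenance):
            ce = coloring.assignment[(f, g)]
            pat = ",".join(f"{i}:{j}" for i, j in sorted(ce.pattern))
            desc = "|".join(f"{u}->{v}" for u, v in sorted(anc.provenance[(f, g)]))
            fh.write(f"{f}\t{g}\t{ce.ds.name}\t{len(ce.pattern)}\t{pat}\t{desc}\n")


def read_annotated_edges(path: str | Path):
    """Read back :func:`write_annotated_edges` output.

    Returns ``(coloring, provenance)`` where ``coloring`` is an
    :class:`~wgdnet.dsubgraph.EdgeColoring` and ``provenance`` maps each
    ancestral edge to its descendant present-day edges.
    """
    from .dsubgraph import ColoredEdge, DSClass, EdgeColoring

    assignment: dict[tuple[str, str], ColoredEdge] = {}
    provenance: dict[tuple[str, str], frozenset[tuple[str, str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _ANNOT_HEADER:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            f, g, ds_name, n_links, pat, desc = cols
            pattern = frozenset(
                (int(t.split(":")[0]), int(t.split(":")[1]))
                for t in pat.split(",") if t
            )
            if len(pattern) != int(n_links):
                raise ValueError(f"{path}:{lineno}: n_links does not match pattern")
            assignment[(f, g)] = ColoredEdge(DSClass[ds_name], pattern, f == g)
            provenance[(f, g)] = frozenset(
                tuple(t.split("->")) for t in desc.split("|") if t
            )
    return EdgeColoring(assignment), provenance


#: DOT color per duplication-subgraph class (stable across exports).
DS_DOT_COLORS = {
    "ETA": "gray80",
    "ZETA": "gray40",
    "ALPHA": "darkgreen",
    "BETA": "red",
    "GAMMA": "blue",
    "DELTA": "orange",
    "EPSILON": "purple",
}


def export_dot(coloring, anc, path: str | Path, nontrivial_only: bool = False) -> None:
    """Write a Graphviz DOT file with one color per DS class."""
    lines = ["digraph ancestral {"]
    for (f, g) in sorted(anc.provenance):
        ce = coloring.assignment[(f, g)]
        if nontrivial_only and len(ce.pattern) < 2:
            continue
        color = DS_DOT_COLORS[ce.ds.name]
        lines.append(f'  "{f}" -> "{g}" [color={color}, label="{ce.ds.name}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
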