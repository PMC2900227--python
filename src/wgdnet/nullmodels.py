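"""Null models for duplication-subgraph statistics.

Two very different randomizations are used:

* **homology-class shuffling** — re-draws which genes are paralogs
  (within TF / non-TF strata, keeping the network fixed), the standard
  null for asking whether a local structure stems from duplication at all.
  It backs the per-age-class DS abundance Z-scores.
* **one-shot coloring** — re-colors the ancestral network's edges with
  random duplication subgraphs at their empirical frequencies, modelling
  the WGD as a single collective duplication whose per-edge fates are
  independent.  It is the reference for every *arrangement* statistic
  (connectedness, hierarchy placement, neighbor correlation, path
  preservation): the DS content is conserved, only its spatial
  organization is randomized.

Observed-vs-null comparisons are returned as :class:`EnrichmentScore`
(Z-score plus Laplace-corrected empirical p-value, never exactly 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .collapse import AncestralNetwork, build_duplicate_families, collapse_network
from .dsubgraph import (
    MASKS_OF_CLASS,
    NONTRIVIAL_CLASSES,
    CLASS_OF_MASK,
    ColoredEdge,
    DSClass,
    EdgeColoring,
    color_ancestral_network,
    mask_to_pattern,
    pattern_to_mask,
)
from .net_io import AgeClass, ParalogPair, ParalogTable, RegulatoryNetwork

log = logging.getLogger("wgdnet")

__all__ = [
    "EnrichmentScore",
    "OneShotSpec",
    "shuffle_homology_classes",
    "ds_abundance_zscores",
    "sample_oneshot_coloring",
    "sample_class_indices",
    "sample_pattern_masks",
    "score_against_oneshot",
]


@dataclass
class EnrichmentScore:
    """Observed value scored against a null ensemble.

    ``z`` is ``(observed - null_mean) / null_sd`` (``None`` when the null
    is degenerate, never a silent NaN); ``p_emp = (r + 1) / (n_real + 1)``
    with ``r`` the number of null values at least as extreme as the
    observation under the chosen tail — the Laplace correction keeps the
    p-value strictly positive.
    """

    observed: float
    null_mean: float
    null_sd: float
    z: float | None
    p_emp: float
    n_real: int
    tail: str

    @classmethod
    def from_null(
        cls, observed: float, nulls: Sequence[float] | np.ndarray, tail: str = "two-sided"
    ) -> "EnrichmentScore":
        nulls = np.asarray(nulls, dtype=float)
        n = len(nulls)
        mean = float(nulls.mean())
        sd = float(nulls.std(ddof=1)) if n > 1 else 0.0
        if tail == "upper":
            r = int(np.sum(nulls >= observed))
        elif tail == "lower":
            r = int(np.sum(nulls <= observed))
        elif tail == "two-sided":
            r = int(np.sum(np.abs(nulls - mean) >= abs(observed - mean)))
        else:
            raise ValueError(f"unknown tail {tail!r}")
        z = (observed - mean) / sd if sd > 0 else None
        return cls(
            observed=float(observed),
            null_mean=mean,
            null_sd=sd,
            z=z,
            p_emp=(r + 1) / (n + 1),
            n_real=n,
            tail=tail,
        )


# ---------------------------------------------------------------------------
# homology-class shuffling
# ---------------------------------------------------------------------------


def _random_matching(genes: list[str], rng: np.random.Generator,
                     forbidden: set[frozenset] | None = None,
                     max_tries: int = 200) -> list[tuple[str, str]] | None:
    """Uniform random perfect matching of ``genes`` into pairs.

    Rejects matchings with self-pairs (a gene occurring twice in the
    pool), repeated unordered pairs, or pairs in ``forbidden`` (pairs
    already emitted for other strata — the table invariant allows each
    unordered pair once).  Returns None if none found.
    """
    forbidden = forbidden or set()
    idx = np.arange(len(genes))
    for _ in range(max_tries):
        rng.shuffle(idx)
        pairs = []
        ok = True
        seen: set[frozenset] = set()
        for k in range(0, len(idx), 2):
            a, b = genes[idx[k]], genes[idx[k + 1]]
            key = frozenset((a, b))
            if a == b or key in seen or key in forbidden:
                ok = False
                break
            seen.add(key)
            pairs.append((a, b))
        if ok:
            return pairs
    return None


def shuffle_homology_classes(
    net: RegulatoryNetwork,
    pairs: ParalogTable,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    tf_set: frozenset[str] | None = None,
) -> ParalogTable:
    """Randomize duplicate partnerships without mixing TFs and targets.

    Pair memberships are permuted within strata defined by (fine age
    class, role composition): TF genes are re-paired only with TF genes,
    non-TF genes only with non-TF genes, and mixed pairs keep one TF side.
    The number of pairs per age class per stratum is conserved.  A stratum
    with fewer than two pairs (or where no valid re-matching exists) is
    returned unshuffled with a warning.

    The TF stratum is out-degree >= 1 on the present-day network;
    bifunctional genes (regulated regulators) count as TFs.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tfs = net.tf_set if tf_set is None else tf_set

    def role(g: str) -> str:
        return "TF" if g in tfs else "NT"

    strata: dict[tuple[AgeClass, tuple[str, str]], list[ParalogPair]] = {}
    for rec in pairs:
        key = (rec.age, tuple(sorted((role(rec.gene_a), role(rec.gene_b)))))
        strata.setdefault(key, []).append(rec)

    out: list[tuple[str, str, AgeClass]] = []
    used: set[frozenset] = set()

    def fallback(recs_, age, roles) -> None:
        # keep a stratum unshuffled; pairs colliding with already-emitted
        # ones (possible only in tiny fixtures) are dropped with a warning
        for r in recs_:
            key = frozenset((r.gene_a, r.gene_b))
            if key in used:
                log.warning("shuffle: dropped colliding pair %s/%s in "
                            "unshuffled stratum %s/%s",
                            r.gene_a, r.gene_b, age.name, roles)
                continue
            used.add(key)
            out.append((r.gene_a, r.gene_b, r.age))

    for (age, roles) in sorted(strata, key=lambda k: (k[0].name, k[1])):
        recs = strata[(age, roles)]
        if len(recs) < 2:
            log.warning("shuffle: stratum %s/%s too small to permute "
                        "(%d pair(s)); left unshuffled", age.name, roles, len(recs))
            fallback(recs, age, roles)
            continue
        if roles[0] == roles[1]:
            pool = [g for r in recs for g in (r.gene_a, r.gene_b)]
            matching = _random_matching(pool, rng, forbidden=used)
            if matching is None:
                log.warning("shuffle: no valid re-matching for stratum %s/%s; "
                            "left unshuffled", age.name, roles)
                fallback(recs, age, roles)
                continue
            for a, b in matching:
                used.add(frozenset((a, b)))
                out.append((a, b, age))
        else:
            # mixed pairs: permute the TF side against the non-TF side
            tf_side = [r.gene_a if role(r.gene_a) == "TF" else r.gene_b for r in recs]
            nt_side = [r.gene_b if role(r.gene_a) == "TF" else r.gene_a for r in recs]
            chosen = None
            for _ in range(200):
                perm = rng.permutation(len(recs))
                cand = [frozenset((tf_side[k], nt_side[perm[k]]))
                        for k in range(len(recs))]
                if len(set(cand)) == len(cand) and not (set(cand) & used):
                    chosen = perm
                    break
            if chosen is None:
                log.warning("shuffle: no valid re-matching for stratum %s/%s; "
                            "left unshuffled", age.name, roles)
                fallback(recs, age, roles)
                continue
            for k in range(len(recs)):
                used.add(frozenset((tf_side[k], nt_side[chosen[k]])))
                out.append((tf_side[k], nt_side[chosen[k]], age))
    return ParalogTable.from_records(out)


def _grouped_class_counts(
    net: RegulatoryNetwork,
    pairs: ParalogTable,
    groups: Sequence[str],
) -> dict[tuple[str, DSClass], int]:
    """Collapse + classify each coarse age group independently; count classes."""
    counts: dict[tuple[str, DSClass], int] = {}
    for group in groups:
        sel = pairs.select_group(group).restrict_to(net.nodes)
        fams = build_duplicate_families(sel, AgeClass.of_group(group), net.nodes)
        anc = collapse_network(net, fams)
        coloring = color_ancestral_network(anc, reduce_multicopy=True)
        cc = coloring.class_counts()
        for c in NONTRIVIAL_CLASSES:
            counts[(group, c)] = cc[c]
    return counts


def ds_abundance_zscores(
    net: RegulatoryNetwork,
    pairs: ParalogTable,
    n_real: int = 200,
    seed: int | None = None,
    groups: Sequence[str] = ("PRE", "WGD", "POST"),
    tail: str = "two-sided",
) -> dict[tuple[str, DSClass], EnrichmentScore]:
    """DS abundance per coarse age group scored against homology shuffling.

    For every null replicate the paralog table is re-shuffled and the full
    collapse → classify → count pipeline re-run; the observed count of each
    DS class in each group is then scored against the replicate ensemble.
    """
    if n_real < 2:
        raise ValueError("n_real must be >= 2")
    rng = np.random.default_rng(seed)
    groups = [g for g in groups if len(pairs.select_group(g)) > 0]
    observed = _grouped_class_counts(net, pairs, groups)
    nulls: dict[tuple[str, DSClass], list[int]] = {k: [] for k in observed}
    for _ in range(n_real):
        shuffled = shuffle_homology_classes(net, pairs, rng=rng)
        rep = _grouped_class_counts(net, shuffled, groups)
        for k, v in rep.items():
            nulls[k].append(v)
    return {
        k: EnrichmentScore.from_null(observed[k], nulls[k], tail=tail)
        for k in observed
    }


# ---------------------------------------------------------------------------
# one-shot duplication-divergence model
# ---------------------------------------------------------------------------


@dataclass
class OneShotSpec:
    """Specification of the one-shot random-coloring model.

    ``multinomial`` mode draws each edge's class i.i.d. from
    ``class_probabilities``; ``permutation`` mode permutes the empirical
    multiset of colors over the edges, conserving every class count
    exactly.  ``pattern_rule`` decides how a concrete link pattern is
    attached to each colored edge: uniformly over the class's members, or
    resampled from the empirical pattern multiset of that class.
    """

    class_probabilities: dict[DSClass, float] | None = None
    mode: str = "multinomial"
    pattern_rule: str = "uniform"
    class_counts: dict[DSClass, int] | None = None
    empirical_patterns: dict[DSClass, tuple[int, ...]] | None = None  # masks
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("multinomial", "permutation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.pattern_rule not in ("uniform", "empirical"):
            raise ValueError(f"unknown pattern_rule {self.pattern_rule!r}")
        if self.class_probabilities is not None:
            total = sum(self.class_probabilities.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"class probabilities sum to {total}, not 1")
            if DSClass.ETA in self.class_probabilities and \
                    self.class_probabilities[DSClass.ETA] > 0:
                raise ValueError("eta cannot be assigned to a real edge")
        if self.mode == "multinomial" and self.class_probabilities is None:
            raise ValueError("multinomial mode needs class_probabilities")
        if self.mode == "permutation" and self.class_counts is None:
            raise ValueError("permutation mode needs class_counts")

    @classmethod
    def from_coloring(
        cls,
        coloring: EdgeColoring,
        mode: str = "multinomial",
        pattern_rule: str = "uniform",
        seed: int | None = None,
    ) -> "OneShotSpec":
        """Empirical spec: class probabilities/counts read off a coloring."""
        counts = coloring.class_counts()
        total = sum(counts.values())
        pats: dict[DSClass, list[int]] = {c: [] for c in NONTRIVIAL_CLASSES}
        for ce in coloring.assignment.values():
            pats[ce.ds].append(pattern_to_mask(ce.pattern))
        return cls(
            class_probabilities={c: n / total for c, n in counts.items()},
            mode=mode,
            pattern_rule=pattern_rule,
            class_counts=dict(counts),
            empirical_patterns={c: tuple(v) for c, v in pats.items()},
            seed=seed,
        )

    def prob_vector(self) -> np.ndarray:
        if self.class_probabilities is not None:
            return np.array(
                [self.class_probabilities.get(c, 0.0) for c in NONTRIVIAL_CLASSES]
            )
        total = sum(self.class_counts.values())
        return np.array(
            [self.class_counts.get(c, 0) / total for c in NONTRIVIAL_CLASSES]
        )


def sample_class_indices(
    n_edges: int, spec: OneShotSpec, rng: np.random.Generator
) -> np.ndarray:
    """One realization of per-edge class indices (into NONTRIVIAL_CLASSES)."""
    if spec.mode == "multinomial":
        return rng.choice(len(NONTRIVIAL_CLASSES), size=n_edges,
                          p=spec.prob_vector())
    multiset = np.repeat(
        np.arange(len(NONTRIVIAL_CLASSES)),
        [spec.class_counts.get(c, 0) for c in NONTRIVIAL_CLASSES],
    )
    if len(multiset) != n_edges:
        raise ValueError(
            f"permutation mode: {len(multiset)} colors for {n_edges} edges"
        )
    return rng.permutation(multiset)


def sample_pattern_masks(
    class_idx: np.ndarray, spec: OneShotSpec, rng: np.random.Generator
) -> np.ndarray:
    """Attach a concrete link-pattern mask to each colored edge."""
    masks = np.empty(len(class_idx), dtype=np.int64)
    for ci, cls in enumerate(NONTRIVIAL_CLASSES):
        sel = np.flatnonzero(class_idx == ci)
        if len(sel) == 0:
            continue
        if spec.pattern_rule == "uniform" or not spec.empirical_patterns or \
                not spec.empirical_patterns.get(cls):
            pool = np.array(MASKS_OF_CLASS[cls])
        else:
            pool = np.array(spec.empirical_patterns[cls])
        masks[sel] = pool[rng.integers(0, len(pool), size=len(sel))]
    return masks


def sample_oneshot_coloring(
    anc: AncestralNetwork,
    spec: OneShotSpec,
    rng: np.random.Generator | None = None,
) -> EdgeColoring:
    """Draw one random coloring of the ancestral network's edges."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    edges = anc.edges
    cls_idx = sample_class_indices(len(edges), spec, rng)
    masks = sample_pattern_masks(cls_idx, spec, rng)
    assignment = {
        e: ColoredEdge(
            ds=NONTRIVIAL_CLASSES[cls_idx[k]],
            pattern=mask_to_pattern(int(masks[k])),
            self_loop=(e[0] == e[1]),
        )
        for k, e in enumerate(edges)
    }
    return EdgeColoring(assignment)


def score_against_oneshot(
    statistic: Callable[[EdgeColoring], float],
    observed: EdgeColoring,
    anc: AncestralNetwork,
    spec: OneShotSpec,
    n_real: int = 1000,
    seed: int | None = None,
    tail: str = "two-sided",
) -> EnrichmentScore:
    """Score an arbitrary coloring statistic against one-shot realizations."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    obs_val = float(statistic(observed))
    nulls = np.empty(n_real)
    for r in range(n_real):
        coloring = sample_oneshot_coloring(anc, spec, rng=rng)
        try:
            nulls[r] = float(statistic(coloring))
        except Exception as exc:  # pragma: no cover - context for debugging
            raise RuntimeError(f"statistic failed on realization {r}") from exc
    return EnrichmentScore.from_null(obs_val, nulls, tail=tail)
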