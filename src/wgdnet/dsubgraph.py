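"""Duplication subgraphs: taxonomy, edge coloring, abundance, independence test.

After a whole-genome duplication every ancestral TF→target interaction can
leave behind up to four copy-level links, one per (TF copy, target copy)
combination.  The subset of retained links is the edge's *duplication
subgraph* (DS).  Because the two copies of a WGD duplicate cannot be told
apart ('old' vs 'new' is meaningless for a simultaneous duplication),
patterns that differ only by swapping TF copies and/or target copies are
the same DS.  Brute-force orbit enumeration of the 16 link subsets under
this Klein four-group yields exactly seven classes:

========  =======  =========================================================
class     n_links  description
========  =======  =========================================================
η (eta)       0    nothing retained (never seen on a real ancestral edge)
ζ (zeta)      1    a single link — the trivial DS
α (alpha)     2    two parallel, copy-disjoint links (no crosstalk)
β (beta)      2    fan-out: one TF copy regulates both target copies
γ (gamma)     2    fan-in: both TF copies regulate one target copy
δ (delta)     3    three links
ε (epsilon)   4    the full bi-fan — maximal crosstalk
========  =======  =========================================================

Coloring the ancestral network's edges by DS class is the basic data
structure of the whole analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .collapse import AncestralNetwork

log = logging.getLogger("wgdnet")

__all__ = [
    "LINK_POSITIONS",
    "DSClass",
    "NONTRIVIAL_CLASSES",
    "ColoredEdge",
    "EdgeColoring",
    "build_ds_catalog",
    "classify_link_pattern",
    "classify_mask",
    "pattern_to_mask",
    "mask_to_pattern",
    "color_ancestral_network",
    "ds_abundance_table",
    "IndependentModelFit",
    "fit_independent_model",
]

#: The four copy-level link positions (TF copy i -> target copy j), in bit order.
LINK_POSITIONS: tuple[tuple[int, int], ...] = ((1, 1), (1, 2), (2, 1), (2, 2))

Pattern = frozenset  # frozenset of (i, j) pairs


def pattern_to_mask(pattern: Iterable[tuple[int, int]]) -> int:
    mask = 0
    for link in pattern:
        mask |= 1 << LINK_POSITIONS.index(tuple(link))
    return mask


def mask_to_pattern(mask: int) -> Pattern:
    return frozenset(LINK_POSITIONS[b] for b in range(4) if mask >> b & 1)


def _swap_tf(mask: int) -> int:
    """Exchange TF copies 1 and 2: bits (1,1)<->(2,1), (1,2)<->(2,2)."""
    return (mask & 0b0001) << 2 | (mask & 0b0100) >> 2 | \
           (mask & 0b0010) << 2 | (mask & 0b1000) >> 2


def _swap_target(mask: int) -> int:
    """Exchange target copies 1 and 2: bits (1,1)<->(1,2), (2,1)<->(2,2)."""
    return (mask & 0b0001) << 1 | (mask & 0b0010) >> 1 | \
           (mask & 0b0100) << 1 | (mask & 0b1000) >> 1


class DSClass(Enum):
    """The seven duplication-subgraph symmetry classes."""

    ETA = "η"
    ZETA = "ζ"
    ALPHA = "α"
    BETA = "β"
    GAMMA = "γ"
    DELTA = "δ"
    EPSILON = "ε"

    @property
    def n_links(self) -> int:
        return _CLASS_N_LINKS[self]

    @property
    def greek(self) -> str:
        return self.value

    @property
    def nontrivial(self) -> bool:
        """A DS is nontrivial when at least one extra link was inherited."""
        return self.n_links >= 2


_CLASS_N_LINKS = {
    DSClass.ETA: 0,
    DSClass.ZETA: 1,
    DSClass.ALPHA: 2,
    DSClass.BETA: 2,
    DSClass.GAMMA: 2,
    DSClass.DELTA: 3,
    DSClass.EPSILON: 4,
}

#: The six classes a real (non-empty) ancestral edge can take, fixed order.
NONTRIVIAL_CLASSES: tuple[DSClass, ...] = (
    DSClass.ZETA,
    DSClass.ALPHA,
    DSClass.BETA,
    DSClass.GAMMA,
    DSClass.DELTA,
    DSClass.EPSILON,
)


def _orbit(mask: int) -> frozenset[int]:
    return frozenset(
        {mask, _swap_tf(mask), _swap_target(mask), _swap_tf(_swap_target(mask))}
    )


def _label_orbit(orbit: frozenset[int]) -> DSClass:
    rep = min(orbit)
    n = bin(rep).count("1")
    if n == 0:
        return DSClass.ETA
    if n == 1:
        return DSClass.ZETA
    if n == 3:
        return DSClass.DELTA
    if n == 4:
        return DSClass.EPSILON
    # two links: distinguish by degree signature
    links = mask_to_pattern(rep)
    tf_out = {i: 0 for i in (1, 2)}
    tgt_in = {j: 0 for j in (1, 2)}
    for i, j in links:
        tf_out[i] += 1
        tgt_in[j] += 1
    if max(tf_out.values()) == 2:
        return DSClass.BETA  # fan-out: one TF copy sends both links
    if max(tgt_in.values()) == 2:
        return DSClass.GAMMA  # fan-in: one target copy receives both
    return DSClass.ALPHA  # copy-disjoint parallel links


def build_ds_catalog() -> dict[DSClass, frozenset[Pattern]]:
    """Enumerate all 16 link patterns and group them into symmetry orbits.

    Deterministic; the orbits of the copy-swap group partition the pattern
    space into the seven DS classes with member multiplicities
    η:1, ζ:4, α:2, β:2, γ:2, δ:4, ε:1.
    """
    catalog: dict[DSClass, set[Pattern]] = {c: set() for c in DSClass}
    seen: set[int] = set()
    for mask in range(16):
        if mask in seen:
            continue
        orbit = _orbit(mask)
        seen |= orbit
        cls = _label_orbit(orbit)
        catalog[cls] |= {mask_to_pattern(m) for m in orbit}
    return {c: frozenset(ms) for c, ms in catalog.items()}


#: mask -> DSClass lookup, built once at import.
CLASS_OF_MASK: tuple[DSClass, ...] = tuple(
    _label_orbit(_orbit(m)) for m in range(16)
)

#: class -> tuple of member masks (sorted), for samplers.
MASKS_OF_CLASS: dict[DSClass, tuple[int, ...]] = {
    c: tuple(m for m in range(16) if CLASS_OF_MASK[m] is c) for c in DSClass
}


def classify_mask(mask: int) -> DSClass:
    return CLASS_OF_MASK[mask]


def classify_link_pattern(pattern: Iterable[tuple[int, int]]) -> DSClass:
    """Classify a concrete 2x2 link pattern into its DS class."""
    return CLASS_OF_MASK[pattern_to_mask(pattern)]


class ColoredEdge(NamedTuple):
    ds: DSClass
    pattern: Pattern
    self_loop: bool = False


@dataclass
class EdgeColoring:
    """DS class (and concrete link pattern) per ancestral edge."""

    assignment: dict[tuple[str, str], ColoredEdge]

    def __len__(self) -> int:
        return len(self.assignment)

    def classes(self) -> dict[tuple[str, str], DSClass]:
        return {e: ce.ds for e, ce in self.assignment.items()}

    def class_counts(self) -> dict[DSClass, int]:
        counts = {c: 0 for c in NONTRIVIAL_CLASSES}
        for ce in self.assignment.values():
            counts[ce.ds] += 1
        return counts

    def restrict(self, classes: Iterable[DSClass]) -> "EdgeColoring":
        classes = frozenset(classes)
        return EdgeColoring(
            {e: ce for e, ce in self.assignment.items() if ce.ds in classes}
        )


def _top_two(members: list[str], weight: Mapping[str, int]) -> list[str]:
    """Two members carrying the most links; ties broken lexicographically."""
    return sorted(members, key=lambda m: (-weight.get(m, 0), m))[:2]


def color_ancestral_network(
    anc: AncestralNetwork, reduce_multicopy: bool = False
) -> EdgeColoring:
    """Annotate every ancestral edge with its duplication subgraph.

    Copy indices are assigned by lexicographic member order within each
    family (an analysis artifact — WGD copies carry no old/new identity);
    a singleton family occupies copy index 1 only, leaving the other copy
    link-less, which matches the assumption that isolated copies are lost.

    Families larger than two are outside the 2x2 taxonomy; with
    ``reduce_multicopy`` the two members carrying the most links of the
    edge at hand are kept (per-edge reduction, so the pattern is never
    empty), otherwise they raise.
    """
    members_sorted = {f: sorted(ms) for f, ms in anc.families.items()}
    oversize = [f for f, ms in members_sorted.items() if len(ms) > 2]
    if oversize:
        if not reduce_multicopy:
            raise ValueError(
                f"{len(oversize)} famil(ies) with >2 members "
                f"(e.g. {oversize[0]!r}); pass reduce_multicopy=True"
            )
        log.warning(
            "multi-copy reduction applied to %d famil(ies) with >2 members",
            len(oversize),
        )

    assignment: dict[tuple[str, str], ColoredEdge] = {}
    for (f, g), prov in anc.provenance.items():
        src_members = members_sorted[f]
        tgt_members = members_sorted[g]
        if len(src_members) > 2 or len(tgt_members) > 2:
            weight_src: dict[str, int] = {}
            weight_tgt: dict[str, int] = {}
            for u, v in prov:
                weight_src[u] = weight_src.get(u, 0) + 1
                weight_tgt[v] = weight_tgt.get(v, 0) + 1
            src_members = sorted(_top_two(src_members, weight_src))
            tgt_members = sorted(_top_two(tgt_members, weight_tgt))
        src_idx = {m: i + 1 for i, m in enumerate(src_members)}
        tgt_idx = {m: j + 1 for j, m in enumerate(tgt_members)}
        pattern = frozenset(
            (src_idx[u], tgt_idx[v])
            for u, v in prov
            if u in src_idx and v in tgt_idx
        )
        if not pattern:
            # only reachable through multi-copy reduction on pathological
            # provenance; keep the taxonomy total by falling back to zeta
            log.warning("edge (%s, %s): provenance lost in reduction; "
                        "classified as single-link", f, g)
            pattern = frozenset({(1, 1)})
        assignment[(f, g)] = ColoredEdge(
            ds=CLASS_OF_MASK[pattern_to_mask(pattern)],
            pattern=pattern,
            self_loop=(f == g),
        )
    return EdgeColoring(assignment)


def ds_abundance_table(
    colorings: Mapping[str, EdgeColoring] | EdgeColoring,
    normalization: str = "nontrivial",
) -> pd.DataFrame:
    """Tabulate DS counts and frequencies, optionally stratified by age group.

    ``normalization`` selects the denominator: ``"edges"`` divides by all
    ancestral edges (every real edge is a non-η DS), ``"nontrivial"`` by
    the number of duplicated edges, i.e. DSs with two or more links.  A
    zero denominator yields NaN frequencies with a logged warning (never
    silently).
    """
    if normalization not in ("edges", "nontrivial"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if isinstance(colorings, EdgeColoring):
        colorings = {"all": colorings}
    if not colorings:
        raise ValueError("no colorings given")
    rows = []
    for group, coloring in colorings.items():
        counts = coloring.class_counts()
        if normalization == "edges":
            denom = sum(counts.values())
        else:
            denom = sum(n for c, n in counts.items() if c.nontrivial)
        if denom == 0:
            log.warning("abundance table: zero denominator for group %r "
                        "(frequencies undefined)", group)
        for c in NONTRIVIAL_CLASSES:
            rows.append(
                {
                    "group": group,
                    "ds": c.name,
                    "count": counts[c],
                    "freq": counts[c] / denom if denom else float("nan"),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# independent link-conservation model
# ---------------------------------------------------------------------------


@dataclass
class IndependentModelFit:
    """Maximum-likelihood fit of independent per-link conservation.

    The model: each of the four copy-level links of an ancestral edge is
    retained independently with its own probability; a real edge is
    conditioned on at least one link surviving.  Class probabilities are
    sums of Bernoulli products over class members.  With at most four free
    probabilities against six observed categories, a likelihood-ratio
    (G-squared) test against the saturated multinomial measures whether
    link conservation really factorizes.
    """

    probs: tuple[float, ...]          # conservation prob per link position
    n_params: int
    predicted: dict[DSClass, float]   # conditional on >= 1 link retained
    loglik: float
    g2: float
    df: int
    pvalue: float
    converged: bool

    def summary(self) -> str:
        p = ", ".join(f"p{ij[0]}{ij[1]}={q:.3f}"
                      for ij, q in zip(LINK_POSITIONS, self.probs))
        return (f"independent-link fit ({self.n_params} param): {p}; "
                f"G2={self.g2:.2f} (df={self.df}), p={self.pvalue:.3g}")


def _expand_params(theta: np.ndarray, n_params: int) -> np.ndarray:
    """Map free parameters to the four link positions.

    4: one probability per position; 2: one for the diagonal links
    (1,1),(2,2) and one for the crossed links (1,2),(2,1); 1: a single
    shared probability.  (The 2-parameter split is a symmetric convention;
    copy labels themselves carry no meaning.)
    """
    if n_params == 4:
        return theta
    if n_params == 2:
        return np.array([theta[0], theta[1], theta[1], theta[0]])
    if n_params == 1:
        return np.repeat(theta[0], 4)
    raise ValueError("n_params must be 1, 2 or 4")


def _class_logprobs(p: np.ndarray) -> dict[DSClass, float]:
    """Conditional class probabilities given >= 1 retained link."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    mask_probs = np.empty(16)
    for mask in range(16):
        bits = np.array([(mask >> b) & 1 for b in range(4)], dtype=float)
        mask_probs[mask] = np.prod(np.where(bits > 0, p, 1 - p))
    cond = 1.0 - mask_probs[0]
    out = {c: 0.0 for c in NONTRIVIAL_CLASSES}
    for mask in range(1, 16):
        out[CLASS_OF_MASK[mask]] += mask_probs[mask] / cond
    return out


def fit_independent_model(
    counts: Mapping[DSClass, int] | EdgeColoring, n_params: int = 4
) -> IndependentModelFit:
    """Fit the independent-link model to observed DS class counts.

    Needs raw counts (a frequency vector has no likelihood).  Degenerate
    data (all mass in one class) drives probabilities to the boundary; a
    warning is logged and the boundary estimate returned.
    """
    if isinstance(counts, EdgeColoring):
        counts = counts.class_counts()
    n_obs = np.array([counts.get(c, 0) for c in NONTRIVIAL_CLASSES], dtype=float)
    n_total = n_obs.sum()
    if n_total <= 0:
        raise ValueError("no observations")
    if np.count_nonzero(n_obs) == 1:
        log.warning("independent-model fit: all mass in a single class "
                    "(boundary estimate)")

    def nll(theta_logit: np.ndarray) -> float:
        p = _expand_params(special.expit(theta_logit), n_params)
        q = _class_logprobs(p)
        qv = np.array([q[c] for c in NONTRIVIAL_CLASSES])
        return -float(np.sum(n_obs * np.log(np.clip(qv, 1e-300, None))))

    best = None
    for start in ([0.0] * n_params, [1.0] * n_params, [-1.0] * n_params):
        res = optimize.minimize(nll, np.array(start), method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-10,
                                         "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    p_hat = _expand_params(special.expit(best.x), n_params)
    predicted = _class_logprobs(p_hat)
    loglik = -best.fun

    # saturated multinomial log-likelihood and G2
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.sum(n_obs[n_obs > 0] * np.log(n_obs[n_obs > 0] / n_total))
    g2 = float(2.0 * (sat - loglik))
    g2 = max(g2, 0.0)
    df = len(NONTRIVIAL_CLASSES) - 1 - n_params
    if df <= 0:
        log.warning("independent-model fit: non-positive degrees of freedom")
        pvalue = float("nan")
    else:
        pvalue = float(stats.chi2.sf(g2, df))
    return IndependentModelFit(
        probs=tuple(float(x) for x in p_hat),
        n_params=n_params,
        predicted=predicted,
        loglik=float(loglik),
        g2=g2,
        df=df,
        pvalue=pvalue,
        converged=bool(best.success),
    )
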