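# Methods

This note documents the models and procedures implemented in `wgdnet`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish.

## Ancestral-network reconstruction

The pre-duplication network is estimated conservatively: for a chosen set of
duplication age classes, paralogous genes are merged (union–find transitive
closure of the pair relation — pairs alone do not define a partition) and an
ancestral link F→G is present whenever *any* present-day link runs from a
member of F to a member of G. Within-family links, including autoregulation,
become ancestral self-loops. Every ancestral edge keeps its **provenance**
(the exact set of present-day edges it stands for); the sum of provenance
sizes always equals the present-day edge count, which the tests assert.

Collapses compose: by default the five post-WGD small-scale classes are
collapsed first (youngest first) and the WGD pairs second, so the WGD
annotation reads copy-level links off the post-collapsed network. Whether the
focal annotation should be done on the raw or the pre-collapsed network is
ambiguous in principle; both modes exist (`pre_collapse_groups=()` disables
the pre-collapse). Family identifiers are the lexicographically smallest
member, which keeps node names stable across consecutive collapses.

## The duplication-subgraph taxonomy

An ancestral edge's fate is the subset of the four copy-level links
{(1,1),(1,2),(2,1),(2,2)} present in its provenance. WGD copies carry no
old/new identity, so patterns are classified up to the Klein four-group of
copy swaps; the orbits are enumerated by brute force at import time (never
hard-coded) and yield the seven classes η, ζ, α, β, γ, δ, ε with member
multiplicities 1, 4, 2, 2, 2, 4, 1. Conventions:

* **β is fan-out** (one TF copy → both target copies) and **γ is fan-in**.
  This orientation is deduced from the observation that two fan-outs on links
  converging onto a shared target pair form a four-node, four-link
  feed-forward pattern; it is isolated in one place (`_label_orbit`) should
  the opposite convention ever be preferred.
* Copy indices are assigned by lexicographic member order — an analysis
  artifact, not a biological label. A singleton (non-duplicated) endpoint
  occupies copy 1 only; its missing copy simply carries no links, consistent
  with the assumption that link-less copies are lost.
* Families larger than two (paralog pairs chaining into bigger components)
  fall outside the 2×2 taxonomy. With `reduce_multicopy=True` the two source
  members and two target members carrying the most links *of the edge at
  hand* are kept (ties lexicographic). The reduction is per-edge so the
  resulting pattern is never empty; a per-family choice could assign a real
  edge the impossible empty fate.

## Independent link-conservation test

The simplest retention model gives each of the four copy-level links its own
independent survival probability (at most 4 parameters; 2- and 1-parameter
symmetric variants are provided). Class probabilities are Bernoulli-product
sums over class members, conditioned on at least one link surviving. The fit
is by maximum likelihood (Nelder–Mead on logits, three starts) and tested
against the saturated multinomial with a likelihood-ratio G² on
5 − n_params degrees of freedom. Calibration is verified by simulation from
the model itself; data with abundant β and γ but near-absent α and ε — the
empirically relevant configuration — are firmly rejected, which is the point:
fates do not factorize over links.

## Null models

**Homology-class shuffling** randomizes *which genes are paralogs* while
keeping the network fixed: pair memberships are re-drawn as uniform random
matchings within strata defined by fine age class × role composition (TF
genes re-pair only with TF genes; TF = out-degree ≥ 1 on the present-day
network, bifunctional genes count as TFs; mixed pairs keep their TF side).
Pair counts per stratum are conserved, and no unordered pair may repeat
anywhere in the table. Strata too small to permute (or where no valid
re-matching exists) are returned unshuffled with a warning. Shuffling is
done within each fine class; whether the original analysis permuted within
or across classes is unknowable, and within-class is the more conservative
choice (it preserves the age-class size spectrum exactly).

**One-shot coloring** randomizes *where the fates sit*: each ancestral edge
receives a random DS class, either i.i.d. at the empirical frequencies
(multinomial mode, the default — matching a model in which each edge's fate
has a fixed probability) or by permuting the empirical color multiset
(permutation mode, conserving every count exactly). Pattern-level statistics
additionally need a concrete 2×2 pattern per colored edge: uniform within
the class by default, or resampled from the empirical pattern multiset.

All comparisons report a Z-score and a Laplace-corrected empirical p-value,
p = (r+1)/(n+1), which is never exactly zero; degenerate nulls (sd = 0)
yield an explicit undefined Z rather than a NaN. Calibration — uniformity of
empirical p-values when the data are drawn from the null itself — is
asserted for all three null samplers with a KS test over 500 replicates.
Because count statistics on small fixtures are discrete, the calibration
tests score an injective weighted combination of the count vector
(irrational weights); with the raw counts the p-value lattice produced by
ties would fail a literal uniformity test for reasons unrelated to the
samplers.

## Arrangement statistics

* **WGD network components.** Edges whose DS retains ≥ 2 links, optionally
  restricted to edges whose target family contains a TF (only TFs propagate
  regulation). Connectivity is weak/undirected — "connected" in the visual
  sense — with a directed variant available; component sizes are counted in
  edges (one DS = one edge). Significance: component count (lower tail) and
  largest size (upper tail) against one-shot realizations.
* **Hierarchy decomposition.** The feedback core is the set of edges inside
  multi-node strongly connected components. Other edges are labelled by
  core reachability: UPSTREAM (feeds a core, not fed by one), DOWNSTREAM
  (the mirror), SIDE (neither — root-to-leaf paths beside the core), and
  INTERCORE (both; the four-way scheme is silent on edges between two
  cores, so they get their own label). Self-loops are SELF. Removing CORE
  and SELF edges provably leaves a DAG. Per-(label, class) counts are
  scored against re-colorings with the labeling fixed.
* **Neighbor pairs.** Unordered pairs sharing a source (ADJ_OUT) or a target
  (ADJ_IN) and ordered head-to-tail pairs (CONSECUTIVE; a self-loop is never
  consecutive with itself). Cell counts over class pairs are scored per
  cell, by default restricted to the dominant ζ/β/γ classes. The raw
  matrices are always reported in full so no orientation question is
  prejudged.
* **Path preservation.** A consecutive pair (A→B, B→C) with concrete
  patterns preserves a pathway iff some copy of B both receives an upstream
  link and sends a downstream one. The predicate is a precomputed 16×16
  table verified exhaustively against literal path search on the
  instantiated six-node copy graph; the network-level statistic is the
  preserved fraction, scored upper-tail against pattern-sampled one-shot
  colorings.

## The spin model

The positive model promotes the observed neighbor correlations to
interactions: spins s ∈ {ζ, β, γ} on ancestral edges with

H = − J_adj Σ_adjacent A[s,s′] − J_cons Σ_consecutive C[s_up,s_down] − h_β N_β − h_γ N_γ

at temperature 1 (couplings absorb it; ζ is the field reference). The exact
interaction tables used originally are not recoverable, so they are
configuration data; the defaults are the minimal choice reproducing the
observed enrichments — a Potts δ (same-color reward) on adjacent pairs and an
ordered β-upstream-of-γ reward on consecutive pairs. Sampling is single-flip
Metropolis (uniform proposal among the other two states, min(1, e^(−ΔH))
acceptance, one sweep = |edges| updates, local ΔH bookkeeping whose
accumulated value must match a full energy recomputation to 1e-8). The
kernel is numba-compiled with a pure-python fallback. `exact_boltzmann`
enumerates graphs up to 3^10 configurations as the independent oracle; the
sampler must match its marginals within total-variation 0.02 at 10^6
samples, and detailed balance is asserted numerically.

The two fields are *constraints on the magnetizations*, not fitted
structure: `fit_fields_to_magnetizations` matches them to target color
counts by damped stochastic approximation (iterative proportional fitting
with a decaying, clipped log-ratio step). Couplings are never inferred from
data — the model is a proof of principle. Model-vs-data comparison reports
L1 distances on magnetizations and neighbor co-occurrence matrices, against
the uncoupled (J = 0, matched-fields) baseline whose pair expectation is the
analytic independence product. Note that the comparison is only meaningful
with matched fields on both sides: the symmetric coupled ensemble averages
over symmetry-broken branches and cannot track a single polarized draw.
Two caveats: at yeast-like densities (hub out-degrees in the hundreds)
J_adj = 1 is a very strong coupling — adjacent-pair cliques condense — so
couplings should be read as graph-scale-dependent; and rare α/δ/ε edges are
projected onto ζ before comparison, as the model knows three colors.

## Synthetic data

The generator states a world and inverts the pipeline. An ancestral network
is built from `n_tf` regulators wiring to anything (no self-loops) under a
truncated power-law out-degree, plus `core_backedges` edges that each close
an existing directed TF path, planting feedback cores. A DS coloring is
planted either i.i.d. (the one-shot sampler) or as the final configuration
of a Metropolis run; η is never planted. Expansion makes every ancestral
node a WGD copy pair and emits exactly the copy-level edges of each pattern;
copies left without links are kept as isolated nodes so the classifier, not
the generator, handles the "lost copy" assumption. Optionally a fraction of
present-day nodes get small-scale post-WGD duplicates (the original keeps
all links; the copy inherits each with probability 0.5, so the post-collapse
restores the WGD-era network exactly), and decoy pre-WGD pairs between
unrelated nodes exercise the age machinery.

Defaults emulate the yeast dataset at reduced scale: 120 TFs over 1920
genes (≈ 4600 ancestral edges, present-day ≈ 4000 genes / 5300 links versus
4441/12899 in the real compilation; scaled down to keep the full null-model
suite in CPU-minutes), out-degree law p(k) ∝ k^(−1.1) capped at 300 (hubs
with hundreds of targets, as observed), a 25-back-edge feedback core, and
planted fates at the published WGD frequencies (ζ 94.51 %, γ 4.2 %,
β 1.1 %, α 0.041 %, δ 0.049 %, ε 0.066 %, renormalized). The round trip —
collapse + classify recovers the planted edge set and DS class of every edge
exactly, after the POST pre-collapse when age mixing is on — is the
generator's core guarantee and is asserted over randomized specifications.
Recovery is asserted at class level by design: copy *labels* are not
identifiable after expansion, classes are.

What the generator does **not** emulate: biased copy loss (real WGD
retention is ~10 %, here both copies always exist as nodes), rewiring and
link gain after duplication, degree-degree correlations, and any quantitative
fit of the yeast degree distribution. A green round trip therefore
establishes the correctness of the collapse/classification machinery, not
the realism of the evolutionary process; the statistical tests (calibration,
detection of planted structure) establish that the nulls are unbiased and
the scores have power at the stated effect sizes.

## Numerical and edge-case conventions

* Seeded determinism everywhere: identical seeds give bit-identical null
  ensembles, spin trajectories and reports; pipeline stages draw from named
  streams spawned from one master seed.
* Frequencies with a zero denominator are NaN with a logged warning, never
  silent; degenerate enrichment nulls give `z=None`, `p_emp` still defined.
* Empirical p-values use (r+1)/(n+1) with "at least as extreme" tie
  handling; two-sided extremeness is measured as distance from the null
  mean.
* Duplicate input edges are deduplicated with a logged count; conflicting
  duplicate paralog ages are an error, identical ones deduplicate.
* The detection benchmark for planted couplings scores the aggregate
  equal-color adjacent count per relation plus the ordered β→γ consecutive
  cell: with a symmetric Hamiltonian the identity of the dominant color is a
  spontaneously broken symmetry, so per-color diagonal cells are not a
  stable detection target while the aggregates are exactly the statistics
  the couplings drive.

## Known limitations

* The β/γ orientation and the spin Hamiltonian tables are documented
  reconstructions behind single extension points, not recoverable ground
  truth.
* Families larger than two are handled by a reduction heuristic; datasets
  where such families dominate deserve a taxonomy over k×k patterns instead.
* The homology shuffle conditions on validity by rejection; in pathological
  tiny strata it can fall back to the unshuffled stratum (always logged).
* No inference of spin couplings, no rewiring/loss-rate estimation, no
  degree-preserving edge-rewiring null — all out of scope by design.
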