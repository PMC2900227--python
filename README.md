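# wgdnet

**Duplication-subgraph analysis of transcription regulatory networks after a
whole-genome duplication (WGD).**

When a genome duplicates wholesale — as happened ~100–150 Mya in the lineage
of *Saccharomyces cerevisiae* — every transcription-factor→target interaction
suddenly exists in up to four copy-level variants (TF copy *i* → target copy
*j*). Which of those links are retained decides how the duplicated regulatory
pathways are wired into the network. `wgdnet` is a toolkit for asking, for
every ancestral interaction, *which fate it followed*, and for testing whether
those fates are arranged randomly across the network or in an ordered,
correlated configuration.

It is aimed at computational/systems biologists working with directed
regulatory networks and dated paralog tables (e.g. a network compilation plus
orthogroup-derived duplication age classes).

## The objects and the statistics

**Duplication subgraphs (DS).** The retained subset of the four copy-level
links of an ancestral edge, taken up to exchange of the indistinguishable WGD
copies. Brute-force orbit enumeration of the 16 subsets under the copy-swap
group gives exactly seven classes:

| class | links | structure |
|-------|-------|-----------|
| η | 0 | nothing retained (impossible for a real ancestral edge) |
| ζ | 1 | single link (trivial) |
| α | 2 | two copy-disjoint parallel links — no crosstalk |
| β | 2 | fan-out: one TF copy → both target copies |
| γ | 2 | fan-in: both TF copies → one target copy |
| δ | 3 | three links |
| ε | 4 | full bi-fan — maximal crosstalk |

**Pipeline.** (1) collapse dated paralogs (younger small-scale duplicates
first, then the WGD pairs) into an ancestral network, keeping the provenance
of every ancestral edge; (2) classify each edge's provenance into a DS — a
*coloring* of the ancestral network; (3) quantify:

* **abundance** per duplication age, scored against a null that reshuffles
  which genes are paralogs (within TF/non-TF strata, network fixed), plus a
  maximum-likelihood test of whether the four links are retained
  *independently* (they generally are not);
* **arrangement**, scored against the *one-shot* model — a random re-coloring
  of the ancestral edges at the empirical DS frequencies: connectedness of
  the "WGD network" (edges with ≥ 2 retained links), DS placement across the
  feedback core / upstream / downstream / side hierarchy components,
  co-occurrence of DSs on neighbouring edges (shared source, shared target,
  head-to-tail), and preservation of copy-level regulatory paths;
* a **positive model**: a 3-state (ζ/β/γ) spin model on the ancestral edges
  with a same-color reward on adjacent pairs, an ordered β→γ reward on
  consecutive pairs and two fields matched to the magnetizations, sampled by
  Metropolis Monte Carlo with an exact-enumeration oracle for small graphs.

A first-class synthetic generator inverts the pipeline — it *plants* a DS
coloring on a generated ancestor and expands every node into a WGD copy pair —
so every stage is testable against ground truth with zero external data.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate_dataset.py --seed 7    # two synthetic worlds
python analysis/02_collapse_and_classify.py        # ancestral net + coloring
python analysis/03_abundance_vs_shuffle.py         # age-resolved Z-scores
python analysis/04_oneshot_topology.py             # arrangement statistics
python analysis/05_spin_model.py                   # positive model
```

Step 01 writes an *iid world* (4032 genes, 5274 links; every ancestral edge
drawn independently at the yeast WGD fate frequencies ζ 94.5%, γ 4.2%,
β 1.1%, …) and a *spin world* (441 ancestral edges whose fates are an
equilibrium draw of the spin model at J_cons = J_adj = 1). Step 02 collapses
the iid world back:

```
collapse: 4032 -> 3840 -> 1920 nodes; ancestral edges: 4586
DS abundance (normalization=edges):
  ZETA 4309 0.9396   BETA 58 0.0126   GAMMA 209 0.0456  ...
```

— the planted frequencies are recovered. Step 03 shows the WGD age group
standing out against homology shuffling (γ: observed 209 vs null 16.4,
Z = 35; ζ depleted, Z = −19) while the decoy pre-WGD pairs stay null. Step 04
contrasts the two worlds: in the iid world every arrangement statistic is
correctly non-significant (it *is* a one-shot draw), while the spin world
reproduces the ordered phenomenology —

```
ADJ_OUT  β-β  observed 311  null 160.9  Z =  7.59
ADJ_OUT  γ-γ  observed 369  null 207.2  Z =  7.39
CONSECUTIVE β-γ observed 435 null 196.1  Z = 15.21
UPSTREAM β enriched (Z = 4.3), DOWNSTREAM γ enriched (Z = 5.4)
```

— same-color patches, β strictly upstream of γ, and a hierarchical
distribution of fates. Step 05 matches the spin model's fields to the
empirical magnetizations and shows the coupled model sits far closer to the
empirical coloring than the uncoupled one (total L1 236 vs 1329).

Everything is also available in one call (`wgdnet.run_wgd_analysis`, or
`wgdnet run --config analysis.yaml` from the shell), which emits a single
machine-readable `report.json`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic world from the seed and recomputes the full
collapse → classify → null-model → topology → spin pipeline from scratch,
writing the target JSON to `--out` and the complete pipeline report next to
it (`acceptance_report.json`). Runtime is a few minutes on one CPU.
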