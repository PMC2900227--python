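"""One-command orchestration of the full WGD duplication-subgraph analysis.

``run_wgd_analysis`` chains every stage — collapse of the focal age
class (optionally preceded by younger small-scale classes), DS
classification, abundance with homology-shuffle Z-scores, and the
one-shot arrangement suite (connectedness, hierarchy enrichment,
neighbor correlations, path preservation), plus the optional spin-model
comparison — into a single machine-readable report.  Every stochastic
stage draws its seed from an independent named stream spawned from one
master seed, so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import __version__
from .collapse import AncestralNetwork, collapse_sequence
from .dsubgraph import (
    DSClass,
    EdgeColoring,
    color_ancestral_network,
    ds_abundance_table,
    fit_independent_model,
)
from .net_io import (
    AgeClass,
    ParalogTable,
    RegulatoryNetwork,
    read_paralog_table,
    read_regulatory_network,
    write_annotated_edges,
)
from .nullmodels import OneShotSpec, ds_abundance_zscores
from .spinmodel import SpinParams, compare_to_empirical, metropolis_sample
from .topostats import (
    connectivity_significance,
    hierarchy_decompose,
    hierarchy_enrichment,
    neighbor_pair_scores,
    path_preservation_test,
    wgd_subnetwork_components,
)

log = logging.getLogger("wgdnet")

__all__ = ["AnalysisConfig", "run_wgd_analysis"]

REPORT_SCHEMA_VERSION = 1

#: Stage order for the named seed streams (stable across releases).
_SEED_STREAMS = ("shuffle", "components", "hierarchy", "neighbors", "paths", "spin")


@dataclass
class AnalysisConfig:
    """Inputs and knobs for a full analysis run.

    Either file paths or in-memory objects may be given for the network
    and the paralog table.  ``pre_collapse_groups`` are collapsed
    (youngest first) before the focal group, so the focal annotation
    reads copy-level links off the pre-collapsed network; pass an empty
    tuple to annotate the raw network instead.
    """

    network: RegulatoryNetwork | str | Path
    paralogs: ParalogTable | str | Path
    focal_group: str = "WGD"
    pre_collapse_groups: tuple[str, ...] = ("POST",)
    shuffle_reps: int = 200
    oneshot_reps: int = 1000
    oneshot_mode: str = "multinomial"
    pattern_rule: str = "uniform"
    tf_only: bool = True
    run_spin: bool = False
    spin_params: SpinParams | None = None
    seed: int = 7
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.shuffle_reps < 2 or self.oneshot_reps < 2:
            raise ValueError("replicate counts must be >= 2")


def _jsonify(obj: Any) -> Any:
    """Make report structures JSON-serializable (enums, arrays, dataclasses)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, Enum):
        return obj.name
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {_key(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonify(x) for x in obj]
    return obj


def _key(k: Any) -> str:
    if isinstance(k, tuple):
        return "|".join(_key(x) for x in k)
    if isinstance(k, Enum):
        return k.name
    return str(k)


def run_wgd_analysis(config: AnalysisConfig) -> dict:
    """Execute the full analysis; returns (and optionally writes) the report."""
    t0 = time.time()
    net = (
        config.network
        if isinstance(config.network, RegulatoryNetwork)
        else read_regulatory_network(config.network)
    )
    pairs = (
        config.paralogs
        if isinstance(config.paralogs, ParalogTable)
        else read_paralog_table(config.paralogs)
    )
    pairs = pairs.restrict_to(net.nodes)

    seeds = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(
            _SEED_STREAMS, np.random.SeedSequence(config.seed).spawn(len(_SEED_STREAMS))
        )
    }

    def stage(name):
        log.info("stage %-12s starting", name)
        return time.time()

    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "wgdnet_version": __version__,
        "generated_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seeds": seeds,
        "input": {"n_nodes": net.n_nodes, "n_edges": net.n_edges,
                  "n_pairs": len(pairs), "n_tfs": len(net.tf_set)},
    }

    # ---- collapse ---------------------------------------------------------
    t = stage("collapse")
    ordered = [AgeClass.of_group(g) for g in config.pre_collapse_groups]
    ordered.append(AgeClass.of_group(config.focal_group))
    ancestors = collapse_sequence(net, pairs, ordered)
    anc = ancestors[-1]
    report["collapse"] = {
        "steps": [{"n_nodes": a.net.n_nodes, "n_edges": a.net.n_edges}
                  for a in ancestors],
        "focal_group": config.focal_group,
    }

    # ---- classification & abundance ---------------------------------------
    stage("classify")
    coloring = color_ancestral_network(anc, reduce_multicopy=True)
    abundance = {
        norm: ds_abundance_table(coloring, normalization=norm).to_dict("records")
        for norm in ("edges", "nontrivial")
    }
    fit = fit_independent_model(coloring)
    report["classification"] = {
        "class_counts": {c.name: n for c, n in coloring.class_counts().items()},
        "abundance": abundance,
        "independent_model": {
            "probs": fit.probs, "g2": fit.g2, "df": fit.df, "pvalue": fit.pvalue,
        },
    }

    # ---- shuffle null: abundance Z-scores ---------------------------------
    stage("shuffle")
    zscores = ds_abundance_zscores(
        net, pairs, n_real=config.shuffle_reps, seed=seeds["shuffle"]
    )
    report["abundance_zscores"] = _jsonify(zscores)

    # ---- one-shot arrangement suite ---------------------------------------
    spec = OneShotSpec.from_coloring(
        coloring, mode=config.oneshot_mode, pattern_rule=config.pattern_rule
    )

    stage("components")
    comp = wgd_subnetwork_components(coloring, anc, tf_only=config.tf_only)
    comp_n, comp_size = connectivity_significance(
        coloring, anc, spec, n_real=config.oneshot_reps,
        seed=seeds["components"], tf_only=config.tf_only,
    )
    report["wgd_network"] = {
        "tf_only": config.tf_only,
        "n_components": comp.n_components,
        "largest_component_size": comp.largest_component_size,
        "component_sizes": comp.sizes,
        "n_components_score": _jsonify(comp_n),
        "largest_size_score": _jsonify(comp_size),
    }

    stage("hierarchy")
    labeling = hierarchy_decompose(anc)
    hier = hierarchy_enrichment(
        coloring, labeling, anc, spec, n_real=config.oneshot_reps,
        seed=seeds["hierarchy"],
    )
    label_counts: dict[str, int] = {}
    for lab in labeling.values():
        label_counts[lab.name] = label_counts.get(lab.name, 0) + 1
    report["hierarchy"] = {
        "label_counts": label_counts,
        "enrichment": _jsonify(hier),
    }

    stage("neighbors")
    scores, matrices = neighbor_pair_scores(
        coloring, anc, spec, n_real=config.oneshot_reps, seed=seeds["neighbors"]
    )
    report["neighbor_pairs"] = {
        "scores": _jsonify(scores),
        "matrices": _jsonify(matrices),
    }

    stage("paths")
    try:
        path_score, _detail = path_preservation_test(
            anc, coloring, spec, n_real=config.oneshot_reps, seed=seeds["paths"]
        )
        report["path_preservation"] = _jsonify(path_score)
    except ValueError as exc:
        report["path_preservation"] = {"skipped": str(exc)}

    # ---- optional spin model ----------------------------------------------
    if config.run_spin:
        stage("spin")
        import numpy as _np

        from .dsubgraph import ColoredEdge, MASKS_OF_CLASS, mask_to_pattern
        from .spinmodel import SPIN_STATES, fit_fields_to_magnetizations

        # the model knows only zeta/beta/gamma; rare other classes are
        # projected onto zeta for the comparison
        spin_states = set(SPIN_STATES)
        empirical = EdgeColoring({
            e: (ce if ce.ds in spin_states else ColoredEdge(
                DSClass.ZETA,
                mask_to_pattern(MASKS_OF_CLASS[DSClass.ZETA][0]),
                ce.self_loop))
            for e, ce in coloring.assignment.items()
        })
        emp_counts = _np.array(
            [empirical.class_counts()[c] for c in SPIN_STATES], dtype=float
        )
        base = config.spin_params or SpinParams(seed=seeds["spin"])
        params = fit_fields_to_magnetizations(anc, base, emp_counts)
        run = metropolis_sample(anc, params)
        cmp = compare_to_empirical(run, empirical, anc)
        report["spin"] = {
            "params": {
                "j_cons": params.j_cons, "j_adj": params.j_adj,
                "h_beta": params.h_beta, "h_gamma": params.h_gamma,
                "sweeps": params.sweeps, "burn_in": params.burn_in,
            },
            "empirical_magnetizations": _jsonify(emp_counts),
            "mean_magnetizations": _jsonify(run.mean_magnetizations()),
            "acceptance_rate": run.acceptance_rate,
            "comparison": _jsonify(cmp),
        }

    cfg_echo = {
        k: str(v) for k, v in dataclasses.asdict(config).items()
        if k not in ("network", "paralogs")
    }
    report["config"] = cfg_echo
    report["config_hash"] = hashlib.sha256(
        json.dumps(cfg_echo, sort_keys=True).encode()
    ).hexdigest()[:16]
    report["runtime_s"] = round(time.time() - t0, 2)

    _validate_report(report)
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        write_annotated_edges(coloring, anc, outdir / "annotated_edges.tsv")
    return report


_REQUIRED_SECTIONS = (
    "schema_version", "seeds", "input", "collapse", "classification",
    "abundance_zscores", "wgd_network", "hierarchy", "neighbor_pairs",
    "path_preservation",
)


def _validate_report(report: dict) -> None:
    missing = [k for k in _REQUIRED_SECTIONS if k not in report]
    if missing:
        raise RuntimeError(f"report is missing sections: {missing}")
    json.dumps(report)  # must be serializable before any write
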