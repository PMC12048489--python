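"""End-to-end orchestration: partners -> similarity -> branches -> impact ->
saturation, with a deterministic run report.

The pipeline is a pure function of (input tables, config): given the same
files and seed it writes byte-identical outputs, including the JSON report
(config echo, input checksums, per-stage counts, warnings, output manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as io_tables
from .branches import branch_preference, cluster_synapse_locations
from .core import AnalysisConfig, EdgeList, FECO_SUBTYPES, ValidationError, build_edge_list, feco_seeds
from .impact import MotorImpactScorer, module_preference, subtype_preference
from .partners import class_composition, composition_by_group, extract_partners
from .saturation import fit_log_extrapolate, novel_partner_curve
from .similarity import ConnectivityClustering, weight_vectors

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunReport:
    config: dict
    inputs: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def to_json(self, path: Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(record.getMessage())


def run_all(
    neurons_path,
    synapses_path,
    config: AnalysisConfig,
    out_dir,
) -> RunReport:
    """Run every analysis stage on one input table pair.

    Inputs are validated before any output is written; a stage failure raises
    :class:`StageError` naming the stage.
    """
    neurons_path, synapses_path = Path(neurons_path), Path(synapses_path)
    for p in (neurons_path, synapses_path):
        if not p.is_file():
            raise ValidationError(f"input file not found: {p}")
    neurons = io_tables.read_neuron_table(neurons_path)
    synapses = io_tables.read_synapse_table(synapses_path)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        config=dataclasses.asdict(config),
        inputs={
            neurons_path.name: _sha256(neurons_path),
            synapses_path.name: _sha256(synapses_path),
        },
    )
    collector = _WarningCollector()
    root = logging.getLogger("fecomap")
    root.addHandler(collector)
    try:
        _run_stages(neurons, synapses, config, out, report)
    finally:
        root.removeHandler(collector)
        report.warnings = sorted(set(collector.messages))
    for path in sorted(out.iterdir()):
        if path.name != "report.json" and path.is_file():
            report.manifest[path.name] = _sha256(path)
    report.to_json(out / "report.json")
    return report


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ValidationError:
            raise
        except Exception as err:  # noqa: BLE001 - annotate with stage name
            raise StageError(name, err) from err

    return wrap


def _run_stages(neurons, synapses, config, out, report):
    edges = build_edge_list(synapses, neurons)
    io_tables.write_frame(edges.edges, out / "edge_list.csv")
    io_tables.write_frame(edges.input_total.reset_index(), out / "input_totals.csv")
    seeds = list(feco_seeds(neurons)["neuron_id"])
    report.stages["edges"] = {
        "n_neurons": int(len(neurons)),
        "n_synapse_rows": int(len(synapses)),
        "n_edges": int(len(edges.edges)),
        "n_autapses": int(edges.n_autapses),
        "n_seeds": len(seeds),
    }
    if not seeds:
        raise ValidationError("no FeCO sensory seeds in the neuron table")

    _stage("partners")(_partners_stage, neurons, edges, seeds, config, out, report)
    _stage("similarity")(_similarity_stage, edges, seeds, config, out, report)
    _stage("branches")(_branches_stage, neurons, synapses, config, out, report)
    _stage("impact")(_impact_stage, neurons, edges, seeds, config, out, report)
    _stage("saturation")(_saturation_stage, edges, seeds, config, out, report)


def _partners_stage(neurons, edges, seeds, config, out, report):
    pset = extract_partners(
        edges, seeds, "downstream", config.out_threshold, pooled=config.pooled_inclusion
    )
    io_tables.write_frame(pset.members.reset_index(), out / "partners_downstream.csv")
    per_seed = []
    for seed in seeds:
        for partner, count in sorted(edges.out_counts(seed).items()):
            if count >= config.out_threshold:
                per_seed.append((seed, partner, count))
    io_tables.write_frame(
        pd.DataFrame(per_seed, columns=["seed_id", "partner_id", "count"]),
        out / "partners_per_seed.csv",
    )
    comp_class = class_composition(edges, seeds, neurons, by="neuron_class")
    comp_hemi = class_composition(edges, seeds, neurons, by="hemilineage")
    io_tables.write_frame(comp_class.reset_index(), out / "composition_class.csv")
    io_tables.write_frame(comp_hemi.reset_index(), out / "composition_hemilineage.csv")
    info = neurons.set_index("neuron_id")
    groups = {
        s: [n for n in seeds if info.loc[n, "subtype"] == s]
        for s in FECO_SUBTYPES
        if any(info.loc[n, "subtype"] == s for n in seeds)
    }
    io_tables.write_frame(
        composition_by_group(edges, groups, neurons).reset_index(),
        out / "composition_by_subtype.csv",
    )
    report.stages["partners"] = {
        "n_partners": int(len(pset)),
        "n_seed_partner_pairs": len(per_seed),
    }


def _similarity_stage(edges, seeds, config, out, report):
    W = weight_vectors(edges, seeds, "downstream", config.out_threshold)
    model = ConnectivityClustering(
        n_clusters=config.n_clusters,
        distance_threshold=config.distance_threshold,
        linkage=config.linkage,
    ).fit(W)
    io_tables.write_matrix(
        model.similarity_matrix_, W.seeds, W.seeds, out / "similarity_matrix.csv",
        index_name="seed_id",
    )
    leaf_pos = {int(i): rank for rank, i in enumerate(model.leaf_order_)}
    clusters = pd.DataFrame(
        {
            "seed_id": W.seeds,
            "cluster": model.labels_,
            "leaf_position": [leaf_pos.get(i, -1) for i in range(len(W.seeds))],
        }
    )
    io_tables.write_frame(clusters, out / "similarity_clusters.csv")
    report.stages["similarity"] = {
        "n_seeds_clustered": int((model.labels_ >= 0).sum()),
        "n_clusters": int(model.n_clusters_),
    }


def _branches_stage(neurons, synapses, config, out, report):
    info = neurons.set_index("neuron_id")
    subtype_of = info["subtype"].to_dict()
    counts = {}
    for subtype in FECO_SUBTYPES:
        mask = synapses["pre_id"].map(subtype_of).eq(subtype)
        rows = synapses[mask]
        if len(rows) < config.n_branches:
            continue
        assignment = cluster_synapse_locations(
            rows, config.n_branches, config.rng_seed
        )
        assigned = pd.DataFrame(
            {"post_id": rows["post_id"].to_numpy(), "branch": assignment.labels.to_numpy()}
        )
        io_tables.write_frame(assigned, out / f"branches_{subtype}_assignment.csv")
        prefs = branch_preference(assignment, rows)
        io_tables.write_frame(
            prefs.reset_index(), out / f"branches_{subtype}_preference.csv"
        )
        counts[subtype] = int(len(rows))
    report.stages["branches"] = {"n_synapses_per_subtype": counts}


def _impact_stage(neurons, edges, seeds, config, out, report):
    scorer = MotorImpactScorer(threshold=config.out_threshold).fit(edges, neurons)
    if not scorer.modules_:
        raise ValidationError("no motor modules in the neuron table")
    table = scorer.transform(seeds)
    io_tables.write_frame(table, out / "impact.csv")
    info = neurons.set_index("neuron_id")
    table = table.assign(subtype=table["seed_id"].map(info["subtype"]))
    agg = (
        table.groupby(["subtype", "module"])["impact_total"].mean().unstack()
    )
    io_tables.write_frame(agg.reset_index(), out / "impact_by_subtype_module.csv")
    io_tables.write_frame(
        module_preference(edges, neurons).reset_index(), out / "module_preference.csv"
    )
    io_tables.write_frame(
        subtype_preference(edges, neurons).reset_index(), out / "subtype_preference.csv"
    )
    report.stages["impact"] = {
        "n_pairs": int(len(table)),
        "n_modules": len(scorer.modules_),
    }


def _saturation_stage(edges, seeds, config, out, report):
    partner_sets = {
        seed: extract_partners(edges, [seed], "downstream", config.out_threshold).ids()
        for seed in seeds
    }
    curve = novel_partner_curve(partner_sets, config.n_resamples, config.rng_seed)
    io_tables.write_frame(
        pd.DataFrame({"t": curve.t, "mean": curve.mean, "sd": curve.sd}),
        out / "saturation_curve.csv",
    )
    fit = fit_log_extrapolate(curve, config.saturation_target_n, config.log_fit_form)
    io_tables.write_frame(
        pd.DataFrame(
            [
                {
                    "form": fit.form,
                    "a": fit.a,
                    "b": fit.b,
                    "target_n": fit.target_n,
                    "prediction": fit.prediction,
                    "degenerate": fit.degenerate,
                }
            ]
        ),
        out / "saturation_fit.csv",
    )
    report.stages["saturation"] = {
        "terminal_mean_partners": float(curve.mean[-1]),
        "extrapolated_partners": float(fit.prediction),
    }
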