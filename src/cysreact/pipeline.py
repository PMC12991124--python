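"""End-to-end orchestration: simulate -> normalize -> rollup -> call -> score.

A :class:`RunConfig` drives one deterministic run into an output directory;
every artifact is a TSV (or JSON) with stable ordering, and a run manifest
records parameters and content digests so that reruns are bit-for-bit
reproducible. :func:`score_against_truth` compares call sets against the
simulator's planted ground truth: a planted effect counts as recovered when
it is called in the planted condition with the planted direction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io as cio
from .calling import CallParams, call_reactivity, summarize_calls
from .ligand import call_ligand_sensitivity, cross_state_sensitivity
from .quant import condition_ratios, normalize_channels, rollup_proteins, rollup_sites
from .simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_atp_addback,
    simulate_experiment,
    simulate_proteome,
)
from .stats import class_enrichment

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed or a required input is missing."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    sim: SimulationConfig
    out_dir: Path
    call_params: CallParams = field(default_factory=CallParams)
    ligand_threshold: float = 2.0
    cross_states: tuple = ("D8C", "D2")
    normalization: str = "median"
    run_addback: bool = True
    stages: tuple = ("simulate", "quantify", "call", "score")


@dataclass
class RecoveryReport:
    """Sensitivity / false-discovery summary per planted effect type."""

    per_effect: Dict[str, Dict[str, float]]

    def to_dict(self) -> Dict[str, Dict[str, float]]:
        return self.per_effect


def call_expression(
    proteins: pd.DataFrame, fc_threshold: float = 2.0, reference: str = "D2"
) -> pd.DataFrame:
    """Threshold protein abundance fold changes (cross-donor median)."""
    threshold = math.log2(fc_threshold)
    agg = (
        proteins[proteins["condition"] != reference]
        .groupby(["accession", "condition"], sort=False)["log2_ratio"]
        .median()
        .rename("log2fc")
        .reset_index()
    )
    agg["called"] = np.abs(agg["log2fc"]) >= threshold
    agg["direction"] = np.where(agg["log2fc"] > 0, "higher", "lower")
    agg.loc[agg["log2fc"] == 0, "direction"] = ""
    return agg.sort_values(["accession", "condition"], kind="mergesort").reset_index(drop=True)


def _rate(numerator: int, denominator: int) -> float:
    return float(numerator) / denominator if denominator else 0.0


def score_against_truth(
    reactivity_calls: Optional[pd.DataFrame],
    expression_calls: Optional[pd.DataFrame],
    ligand_cross: Optional[pd.DataFrame],
    truth: GroundTruth,
) -> RecoveryReport:
    """Score call sets against planted ground truth.

    Sensitivity is over planted effects; the false discovery proportion is
    over emitted calls (a call on a planted site with the wrong direction
    counts as false). An empty call set gives sensitivity 0 and FDP 0 with
    ``fdp_defined = False``.
    """
    report: Dict[str, Dict[str, float]] = {}

    if reactivity_calls is not None:
        planted = {
            (row.site_id, row.condition): ("higher" if row.log2_offset > 0 else "lower")
            for row in truth.site_effects.itertuples()
        }
        calls = reactivity_calls[reactivity_calls["verdict"] == "reactivity_change"]
        known_sites = set(reactivity_calls["site_id"])
        unknown = set(calls["site_id"]) - known_sites
        if unknown:
            raise PipelineError(f"calls reference unknown sites: {sorted(unknown)[:5]}")
        called = {
            (row.site_id, row.condition): row.direction for row in calls.itertuples()
        }
        n_true = len(planted)
        recovered = sum(
            1 for key, direction in planted.items() if called.get(key) == direction
        )
        false = sum(
            1 for key, direction in called.items() if planted.get(key) != direction
        )
        report["reactivity"] = {
            "sensitivity": _rate(recovered, n_true),
            "fdp": _rate(false, len(called)),
            "fdp_defined": bool(called),
            "n_true": n_true,
            "n_called": len(called),
        }

    if expression_calls is not None:
        planted = {
            (row.accession, row.condition): ("higher" if row.log2_offset > 0 else "lower")
            for row in truth.protein_effects.itertuples()
        }
        calls = expression_calls[expression_calls["called"]]
        called = {
            (row.accession, row.condition): row.direction for row in calls.itertuples()
        }
        n_true = len(planted)
        recovered = sum(
            1 for key, direction in planted.items() if called.get(key) == direction
        )
        false = sum(
            1 for key, direction in called.items() if planted.get(key) != direction
        )
        report["expression"] = {
            "sensitivity": _rate(recovered, n_true),
            "fdp": _rate(false, len(called)),
            "fdp_defined": bool(called),
            "n_true": n_true,
            "n_called": len(called),
        }

    if ligand_cross is not None:
        occluded = set(truth.atp_effects["site_id"])
        flagged = ligand_cross[ligand_cross["flagged"]]
        # direction: occlusion is a labeling decrease in the occluded state
        good = set(
            flagged.loc[flagged["cross_state_delta"] < 0, "site_id"]
        ) & occluded
        n_true_seen = len(occluded & set(ligand_cross["site_id"]))
        n_false = len(set(flagged["site_id"]) - occluded)
        n_null_seen = len(set(ligand_cross["site_id"]) - occluded)
        report["atp"] = {
            "sensitivity": _rate(len(good), n_true_seen),
            "fdp": _rate(n_false, len(set(flagged["site_id"]))),
            "fpr": _rate(n_false, n_null_seen),
            "fdp_defined": bool(len(flagged)),
            "n_true": n_true_seen,
            "n_called": len(set(flagged["site_id"])),
        }

    return RecoveryReport(per_effect=report)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run the configured stages, writing all artifacts under ``out_dir``.

    Returns a dict with artifact paths, the recovery report (when scored)
    and the manifest. Deterministic given the seed and configuration.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}
    result: Dict[str, object] = {}

    def stage_on(name: str) -> bool:
        return name in config.stages

    def require(path: Path, producer: str) -> Path:
        if not path.exists():
            raise PipelineError(
                f"missing input {path.name!r}: run the {producer!r} stage first"
            )
        return path

    current_stage = "setup"
    try:
        if stage_on("simulate"):
            current_stage = "simulate"
            proteome, truth = simulate_proteome(config.sim)
            enriched, unenriched, layouts = simulate_experiment(
                config.sim, proteome, truth
            )
            cio.write_fasta(proteome.database, out / "proteome.fasta")
            cio.write_annotations(proteome.annotations, out / "annotations.tsv")
            cio.write_layout(layouts, out / "main.layout")
            cio.write_quant_table(enriched, layouts, out / "enriched_quant.tsv")
            cio.write_quant_table(unenriched, layouts, out / "unenriched_quant.tsv")
            cio.write_table(truth.to_table(), out / "ground_truth.tsv")
            if config.run_addback:
                ab_records, ab_layouts = simulate_atp_addback(config.sim, proteome, truth)
                cio.write_layout(ab_layouts, out / "addback.layout")
                cio.write_quant_table(ab_records, ab_layouts, out / "addback_quant.tsv")
            for name in [
                "proteome.fasta", "annotations.tsv", "main.layout",
                "enriched_quant.tsv", "unenriched_quant.tsv", "ground_truth.tsv",
            ] + (["addback.layout", "addback_quant.tsv"] if config.run_addback else []):
                artifacts[name] = out / name

        if stage_on("quantify"):
            current_stage = "quantify"
            database = cio.read_fasta(require(out / "proteome.fasta", "simulate"))
            layouts = cio.read_layout(require(out / "main.layout", "simulate"))
            enriched = cio.read_quant_table(
                require(out / "enriched_quant.tsv", "simulate"), layouts, enriched=True
            )
            unenriched = cio.read_quant_table(
                require(out / "unenriched_quant.tsv", "simulate"), layouts, enriched=False
            )
            enriched, _ = normalize_channels(enriched, layouts, method=config.normalization)
            unenriched, _ = normalize_channels(unenriched, layouts, method=config.normalization)
            site_quant = rollup_sites(condition_ratios(enriched, layouts), database)
            protein_quant = rollup_proteins(condition_ratios(unenriched, layouts))
            cio.write_table(site_quant, out / "site_quant.tsv")
            cio.write_table(protein_quant, out / "protein_quant.tsv")
            artifacts["site_quant.tsv"] = out / "site_quant.tsv"
            artifacts["protein_quant.tsv"] = out / "protein_quant.tsv"

        if stage_on("call"):
            current_stage = "call"
            site_quant = cio.read_table(require(out / "site_quant.tsv", "quantify"))
            protein_quant = cio.read_table(require(out / "protein_quant.tsv", "quantify"))
            annotations = cio.read_annotations(require(out / "annotations.tsv", "simulate"))
            calls = call_reactivity(site_quant, protein_quant, config.call_params)
            cio.write_table(calls, out / "reactivity_calls.tsv")
            cio.write_table(
                summarize_calls(calls, annotations), out / "call_summary.tsv"
            )
            expr = call_expression(
                protein_quant,
                config.call_params.fc_threshold,
                config.call_params.reference_condition,
            )
            cio.write_table(expr, out / "expression_calls.tsv")
            hits = sorted(
                set(calls.loc[calls["verdict"] == "reactivity_change", "accession"])
            )
            background = sorted(set(calls["accession"]))
            enrich = class_enrichment(hits, background, annotations)
            cio.write_table(enrich, out / "enrichment.tsv")
            for name in [
                "reactivity_calls.tsv", "call_summary.tsv",
                "expression_calls.tsv", "enrichment.tsv",
            ]:
                artifacts[name] = out / name

            if config.run_addback and (out / "addback_quant.tsv").exists():
                database = cio.read_fasta(require(out / "proteome.fasta", "simulate"))
                ab_layouts = cio.read_layout(out / "addback.layout")
                ab_records = cio.read_quant_table(
                    out / "addback_quant.tsv", ab_layouts, enriched=True
                )
                ligand = call_ligand_sensitivity(
                    ab_records, ab_layouts, database, config.ligand_threshold
                )
                cross = cross_state_sensitivity(
                    ligand, *config.cross_states, threshold=config.ligand_threshold
                )
                cio.write_table(ligand, out / "ligand_calls.tsv")
                cio.write_table(cross, out / "ligand_cross_state.tsv")
                artifacts["ligand_calls.tsv"] = out / "ligand_calls.tsv"
                artifacts["ligand_cross_state.tsv"] = out / "ligand_cross_state.tsv"

        if stage_on("score"):
            current_stage = "score"
            truth = GroundTruth.from_table(
                cio.read_table(require(out / "ground_truth.tsv", "simulate"))
            )
            calls = cio.read_table(require(out / "reactivity_calls.tsv", "call"))
            expr = cio.read_table(require(out / "expression_calls.tsv", "call"))
            cross_path = out / "ligand_cross_state.tsv"
            cross = cio.read_table(cross_path) if cross_path.exists() else None
            report = score_against_truth(calls, expr, cross, truth)
            (out / "recovery.json").write_text(
                json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
            )
            artifacts["recovery.json"] = out / "recovery.json"
            result["recovery"] = report
    except (PipelineError, ValueError) as exc:
        raise PipelineError(f"stage {current_stage!r} failed: {exc}") from exc

    manifest = {
        "parameters": {
            "sim": dataclasses.asdict(config.sim),
            "call_params": dataclasses.asdict(config.call_params),
            "ligand_threshold": config.ligand_threshold,
            "cross_states": list(config.cross_states),
            "normalization": config.normalization,
            "stages": list(config.stages),
        },
        "artifacts": {
            name: _digest(path) for name, path in sorted(artifacts.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    result["artifacts"] = artifacts
    result["manifest"] = manifest
    return result
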