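"""End-to-end pipeline: simulate -> QC -> gate/frequencies -> pseudobulk DGE
-> signature -> enrichment -> spatial, driven by one strictly validated
YAML config. Every run writes a manifest recording the config hash and
seed next to the stage outputs, plus a ``run.log`` of exclusions and
warnings, so runs are diffable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import yaml

from . import io as htio
from .aucscore import (
    CompareConfig,
    compare_enrichment,
    pseudobulk_enrichment,
    random_control_signature,
    score_profiles,
)
from .containers import CellDataset
from .gating import GateDefinition, frequency_table, gate_double_positive, paired_frequency_shift
from .pseudobulk import PseudobulkConfig, build_signature, nb_wald_dge, resample_pseudobulk
from .qc import QCThresholds, clr_adt, filter_cells, filter_genes, normalize_rna
from .simdata import CohortSimConfig, make_section_profiles, simulate_cohort, simulate_spots
from .spatial import SpatialConfig, control_percentile_cutoff, score_spots, spatial_map, threshold_spots

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("homingtrack")

_SECTIONS = {"seed", "sim", "qc", "gate", "dge", "score", "spatial"}


def _build(cls, section: dict, **overrides):
    try:
        return cls(**{**section, **overrides})
    except TypeError as e:
        raise ValueError(f"invalid keys for {cls.__name__}: {e}") from None


class PipelineConfig:
    """Validated bundle of all stage configs plus the global seed.

    Unknown top-level sections or unknown keys within a section are
    rejected before any computation runs.
    """

    def __init__(self, raw: dict):
        unknown = set(raw) - _SECTIONS
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        self.seed = int(raw.get("seed", 0))
        sim_raw = dict(raw.get("sim", {}))
        if "cells_per_sample_range" in sim_raw:
            sim_raw["cells_per_sample_range"] = tuple(sim_raw["cells_per_sample_range"])
        self.sim = _build(CohortSimConfig, sim_raw, seed=sim_raw.pop("seed", self.seed))
        self.qc = _build(QCThresholds, dict(raw.get("qc", {})))
        self.gate = _build(GateDefinition, dict(raw.get("gate", {})))
        dge_raw = dict(raw.get("dge", {}))
        dge_raw.setdefault("cluster", self.sim.homing_cluster_id)
        dge_raw.setdefault("seed", self.seed)
        self.dge = _build(PseudobulkConfig, dge_raw)
        score_raw = dict(raw.get("score", {}))
        self.top_frac = float(score_raw.pop("top_frac", 0.05))
        score_raw.setdefault("seed", self.seed)
        self.score = _build(CompareConfig, score_raw)
        spatial_raw = dict(raw.get("spatial", {}))
        self.spatial_sim = {
            k: spatial_raw.pop(k)
            for k in ("n_spots", "n_infiltrate", "infiltrate_fraction")
            if k in spatial_raw
        }
        self.spatial = _build(SpatialConfig, spatial_raw)
        self.raw = raw

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("pipeline config must be a YAML mapping")
        return cls(raw)

    def hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns a dict of the main artifacts.

    Any stage failure is re-raised annotated with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artifacts: dict = {}
    stage = "setup"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            stage = "simulate"
            cells, adt, truth = simulate_cohort(config.sim)
            log.info("simulated %d cells x %d genes", cells.n_cells, cells.n_genes)

            stage = "qc"
            cells_f, adt_f, report = filter_cells(cells, adt, config.qc)
            cells_f = filter_genes(cells_f, config.qc)
            report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
            log.info("QC retained %d/%d cells, %d genes",
                     cells_f.n_cells, cells.n_cells, cells_f.n_genes)
            norm = normalize_rna(cells_f)
            adt_clr = clr_adt(adt_f)

            stage = "gate-freq"
            flags = gate_double_positive(adt_clr, config.gate)
            freq = frequency_table(cells_f, flags, paired=config.sim.paired)
            freq.to_csv(outdir / "frequency_table.tsv", sep="\t", index=False)
            if config.sim.paired:
                shift = paired_frequency_shift(freq)
                shift.to_csv(outdir / "frequency_shift.tsv", sep="\t", index=False)
                artifacts["frequency_shift"] = shift
            artifacts["frequency_table"] = freq

            stage = "dge"
            tab = resample_pseudobulk(cells_f, config.dge)
            dge = nb_wald_dge(tab)
            dge.reset_index(names="gene").to_csv(outdir / "dge.tsv", sep="\t", index=False)
            artifacts["dge"] = dge

            stage = "signature"
            sig = build_signature(dge, name="homing_signature")
            htio.write_signature(sig, outdir / "signature.json")
            artifacts["signature"] = sig

            stage = "score"
            homing = cells_f.subset_cells(
                (cells_f.obs["cluster"] == config.dge.cluster).to_numpy()
            )
            scores = score_profiles(
                homing.counts, cells_f.genes, sig,
                top_frac=config.top_frac, seed=config.seed, ids=homing.cell_ids,
            )
            per_sample, result = compare_enrichment(scores, cells_f, config.dge.cluster, config.score)
            ctrl_sig = random_control_signature(sig, cells_f.genes, seed=config.seed)
            ctrl_scores = score_profiles(
                homing.counts, cells_f.genes, ctrl_sig,
                top_frac=config.top_frac, seed=config.seed, ids=homing.cell_ids,
            )
            _, ctrl_result = compare_enrichment(ctrl_scores, cells_f, config.dge.cluster, config.score)
            per_sample.to_csv(outdir / "enrichment_per_sample.tsv", sep="\t", index=False)
            (outdir / "enrichment_test.json").write_text(
                json.dumps({"signature": result, "random_control": ctrl_result}, indent=1)
            )
            pb = pseudobulk_enrichment(cells_f, sig, top_frac=config.top_frac, seed=config.seed)
            pb.to_csv(outdir / "pseudobulk_enrichment.tsv", sep="\t", index=False)
            artifacts["enrichment"] = result
            artifacts["enrichment_control"] = ctrl_result

            stage = "spatial"
            background, t09, marker_sig = make_section_profiles(cells_f.genes, seed=config.seed)
            n_spots = int(config.spatial_sim.get("n_spots", 400))
            n_inf = int(config.spatial_sim.get("n_infiltrate", 20))
            f_inf = float(config.spatial_sim.get("infiltrate_fraction", 0.5))
            ctrl_spots, _ = simulate_spots(
                n_spots, 0, 0.0, t09, background, seed=config.seed,
                section="control", condition="control",
            )
            dis_spots, spot_truth = simulate_spots(
                n_spots, n_inf, f_inf, t09, background, seed=config.seed + 1,
                section="disease", condition="disease",
            )
            sc_ctrl = score_spots(ctrl_spots, marker_sig, config.spatial, seed=config.seed)
            sc_dis = score_spots(dis_spots, marker_sig, config.spatial, seed=config.seed)
            import pandas as pd

            all_scores = pd.concat([sc_ctrl, sc_dis])
            cutoff = control_percentile_cutoff(all_scores, ["control"])
            cfg_cut = dataclasses.replace(config.spatial, cutoff=cutoff)
            enriched, summary = threshold_spots(all_scores, cfg_cut)
            summary.to_csv(outdir / "spatial_summary.tsv", sep="\t", index=False)
            spatial_map(all_scores, cfg_cut).to_csv(outdir / "spatial_map.tsv", sep="\t", index=False)
            artifacts["spatial_summary"] = summary
            artifacts["spatial_cutoff"] = cutoff

            for w in caught:
                log.warning("%s", w.message)
    except Exception as e:
        log.error("stage %s failed: %s", stage, e)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    finally:
        log.removeHandler(handler)
        handler.close()

    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    artifacts["manifest"] = manifest
    return artifacts
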