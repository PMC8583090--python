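"""End-to-end pipeline: signatures -> reversal screen -> candidates ->
enrichment consensus -> model lines -> sensitivity -> biomarker correlation
-> copy-number summaries.

In synthetic mode every input is generated by :mod:`sigrev.simulate` from
the single configured seed; reruns with the same config produce
byte-identical output tables.  A run manifest records the config hash, the
seed and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from . import models, reversal, simulate
from .enrichment import build_consensus_list, enrich
from .signatures import build_signature, intersect_signatures, moderated_ttest

logger = logging.getLogger("sigrev")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """All pipeline cutoffs, stage toggles and paths in one place."""

    seed: int = 0
    synthetic: bool = True
    n_datasets: int = 3
    scale: str = "log_intensity"
    # signature cutoffs
    lfc_cut: float = 1.0
    alpha_de: float = 0.001
    # reversal cutoffs
    srges_cut: float = -0.25
    n_strong_min: int = 3
    top_n: int = 100
    # enrichment cutoffs
    consensus_k: int = 5
    consensus_k_lines: int = 20
    alpha_enrich: float = 0.05
    n_null: int = 200
    # models cutoffs
    model_k: int = 10
    n_low: int = 3
    probes_loss: int = 25
    probes_gain: int = 50
    cnloh_mb: float = 5.0
    # stage toggles
    run_signatures: bool = True
    run_reversal: bool = True
    run_enrichment: bool = True
    run_lines: bool = True
    run_sensitivity: bool = True
    run_cnv: bool = True
    # user-data paths (non-synthetic mode)
    expression_paths: tuple = ()
    perturbation_path: str = ""
    gmt_path: str = ""
    segments_path: str = ""
    # simulation overrides (field name -> value)
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("lfc_cut", "alpha_de", "top_n", "consensus_k", "alpha_enrich",
                     "probes_loss", "probes_gain", "cnloh_mb", "n_strong_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "expression_paths" in data:
            data = {**data, "expression_paths": tuple(data["expression_paths"])}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def simulation_config(self) -> simulate.SimulationConfig:
        return simulate.SimulationConfig(seed=self.seed, **self.sim_overrides)


def _write(df: pd.DataFrame, path: Path, **kwargs) -> int:
    df.to_csv(path, sep="\t", float_format="%.8g", **kwargs)
    return len(df)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the configured stages and write TSV outputs plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    counts = manifest["stages"]

    # ---- inputs ------------------------------------------------------
    stage = "inputs"
    try:
        if config.synthetic:
            sim = config.simulation_config()
            cohorts, _truth = simulate.generate_signature_cohorts(
                sim, config.n_datasets, scale=config.scale
            )
            # truth is generated here but deliberately not passed onward:
            # analysis stages see only the data channel
            library = simulate.generate_perturbation_library(
                sim, simulate.make_ground_truth(sim)[1]
            )
            screen = simulate.generate_viability_screen(sim, simulate.make_ground_truth(sim)[1])
            segments = simulate.generate_cn_segments(sim)
            geneset_lib = simulate.generate_geneset_library(sim, simulate.make_ground_truth(sim)[1])
            dataset_ids = [f"synthetic_{i + 1}" for i in range(config.n_datasets)]
        else:
            if not config.expression_paths:
                raise ValueError("non-synthetic mode requires expression_paths")
            cohorts = [sio.read_expression(p) for p in config.expression_paths]
            dataset_ids = [Path(p).stem for p in config.expression_paths]
            library = (
                sio.read_perturbation_library(config.perturbation_path)
                if config.perturbation_path
                else None
            )
            geneset_lib = sio.read_gmt(config.gmt_path) if config.gmt_path else None
            segments = sio.read_segments(config.segments_path) if config.segments_path else None
            screen = None
        counts[stage] = {"n_datasets": len(cohorts)}
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- signatures --------------------------------------------------
    signatures = []
    if config.run_signatures:
        stage = "signatures"
        for ds_id, cohort in zip(dataset_ids, cohorts):
            de = moderated_ttest(cohort)
            sig = build_signature(de, ds_id, lfc_cut=config.lfc_cut, alpha=config.alpha_de)
            signatures.append(sig)
            _write(de, outdir / f"de_{ds_id}.tsv", index_label="gene")
            logger.info(
                "stage=signatures dataset=%s n_genes=%d n_up=%d n_down=%d "
                "cutoffs=|log2FC|>%g,padj<%g",
                ds_id, len(de), len(sig.up), len(sig.down), config.lfc_cut, config.alpha_de,
            )
        counts[stage] = {
            "n_signatures": len(signatures),
            "up_down_sizes": {s.dataset_id: [len(s.up), len(s.down)] for s in signatures},
        }
        if len(signatures) >= 2:
            overlap = intersect_signatures(signatures)
            _write(overlap.pairwise_counts, outdir / "overlap_pairwise.tsv", index_label="dataset")
            _write(overlap.top_ranking, outdir / "overlap_top_deg.tsv", index=False)
            counts[stage]["shared_by_all"] = len(overlap.shared_by_all)

    # ---- reversal screen ---------------------------------------------
    candidates = None
    if config.run_reversal and signatures and library is not None:
        stage = "reversal"
        srges_tables = []
        for sig in signatures:
            records = reversal.score_library(sig, library)
            offsets = reversal.estimate_dose_time_offsets(records)
            srges = reversal.summarize_srges(records, offsets=offsets,
                                             strong_cutoff=config.srges_cut)
            srges["signature"] = sig.dataset_id
            srges_tables.append(srges)
        all_srges = pd.concat(srges_tables, ignore_index=True)
        _write(all_srges, outdir / "srges.tsv", index=False)
        candidates = reversal.select_candidates(
            all_srges,
            top_n=config.top_n,
            srges_cut=config.srges_cut,
            min_strong=config.n_strong_min,
        )
        _write(candidates, outdir / "candidates.tsv", index=False)
        logger.info(
            "stage=reversal n_profiles=%d n_candidates=%d cutoffs=srges<%g,n_strong>=%d",
            len(library), len(candidates), config.srges_cut, config.n_strong_min,
        )
        counts[stage] = {"n_profiles": len(library), "n_candidates": len(candidates)}

    # ---- enrichment consensus ----------------------------------------
    if config.run_enrichment and signatures and geneset_lib is not None:
        stage = "enrichment"
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(10,)))
        per_sig = {}
        for sig in signatures:
            res = enrich(set(sig.genes), geneset_lib, n_null=config.n_null, rng=rng)
            per_sig[sig.dataset_id] = res
            _write(res, outdir / f"ora_{sig.dataset_id}.tsv", index=False)
        consensus = build_consensus_list(
            per_sig, k=config.consensus_k, alpha=config.alpha_enrich,
            library_name=geneset_lib.name,
        )
        _write(consensus.rows, outdir / "consensus.tsv", index_label="term")
        logger.info(
            "stage=enrichment n_terms=%d n_included=%d cutoffs=top%d,padj<%g",
            len(consensus.rows), len(consensus.included_terms),
            config.consensus_k, config.alpha_enrich,
        )
        counts[stage] = {"n_included_terms": len(consensus.included_terms)}

    # ---- model lines --------------------------------------------------
    model_lines = None
    if config.run_lines and signatures and screen is not None:
        stage = "model_lines"
        similarity = models.cellline_similarity(signatures[0], screen.profiles)
        model_lines = models.select_model_lines(
            similarity, list(similarity.index), k=config.model_k
        )
        _write(similarity.to_frame(), outdir / "line_similarity.tsv", index_label="cell_line")
        (outdir / "model_lines.txt").write_text("\n".join(model_lines) + "\n")
        counts[stage] = {"n_lines_scored": len(similarity), "n_selected": len(model_lines)}

    # ---- sensitivity + biomarker correlation --------------------------
    if config.run_sensitivity and config.run_reversal and screen is not None:
        stage = "sensitivity"
        metrics = models.sensitivity_table(screen.curves, n_low=config.n_low)
        _write(metrics, outdir / "sensitivity.tsv", index=False)
        corr = models.biomarker_correlation(
            metrics, screen.profiles, genes=[simulate.BIOMARKER_LABEL]
        )
        _write(corr, outdir / "biomarker_correlation.tsv", index=False)
        counts[stage] = {"n_curves": len(metrics), "n_correlations": len(corr)}

    # ---- copy-number summaries ----------------------------------------
    if config.run_cnv and segments is not None:
        stage = "cnv"
        retained = models.filter_cn_segments(
            segments,
            min_probes_loss=config.probes_loss,
            min_probes_gain=config.probes_gain,
            min_cnloh_bp=int(config.cnloh_mb * 1_000_000),
        )
        _write(retained, outdir / "segments_retained.tsv", index=False)
        gene_coords = {simulate.BIOMARKER_LABEL: simulate.TOP2A_COORDS}
        samples = sorted(segments["sample"].unique()) if "sample" in segments else []
        if samples:
            calls, freq = models.gene_level_cn_summary(retained, gene_coords, samples)
            _write(calls, outdir / "gene_cn_calls.tsv", index=False)
            _write(freq, outdir / "gene_cn_frequency.tsv", index=False)
        logger.info(
            "stage=cnv n_in=%d n_retained=%d cutoffs=loss>=%d,gain>=%d,cnLOH>=%gMb",
            len(segments), len(retained), config.probes_loss, config.probes_gain,
            config.cnloh_mb,
        )
        counts[stage] = {"n_segments_in": len(segments), "n_retained": len(retained)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
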