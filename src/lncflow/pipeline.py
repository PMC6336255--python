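"""End-to-end orchestration: simulate -> discover -> classify -> quantify
-> de -> cis -> enrich -> cerna, with a single flat config and a run
manifest.

Every stage reads and writes plain text files inside the run directory,
so any stage can also be run standalone on externally produced inputs.
The manifest records the config hash, seed, package version and
per-stage row counts (including per-filter drop counts), and contains no
timestamps: identical configs and seeds produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cerna import build_cerna_network, build_trends, export_network
from .cis_enrich import enrich, predict_cis_targets
from .classify import assignments_to_frame, classify_all
from .diffexpr import de_all_contrasts
from .discovery import (
    deduplicate_transcripts,
    outcomes_to_frame,
    read_evidence,
    run_filter_cascade,
)
from .expression import compute_rpkm, expressed_sets, venn_counts
from .genome_io import read_annotation
from .simulate import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)

STAGES = ("simulate", "discover", "classify", "quantify", "de", "cis", "enrich", "cerna")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; thresholds default to the standard
    printed screen (length 200 bp, coverage 3, identity 90%, CPC 0,
    RPKM 1, fold change 2, Q 0.01, 100-kb cis window at alpha 0.01)."""

    outdir: str = "lncflow_run"
    seed: int = 0
    min_length: int = 200
    min_coverage: float = 3.0
    max_known_identity: float = 90.0
    cpc_cutoff: float = 0.0
    rpkm_cutoff: float = 1.0
    fc_cutoff: float = 2.0
    q_cutoff: float = 0.01
    cis_window: int = 100_000
    cis_alpha: float = 0.01
    de_method: str = "pooled_z"
    stages: tuple[str, ...] = STAGES
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name in ("min_length", "min_coverage", "rpkm_cutoff", "fc_cutoff",
                     "q_cutoff", "cis_window", "cis_alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (the output location is not
        part of a run's identity)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        runner = _STAGE_RUNNERS[stage]
        try:
            counts = runner(config, outdir, state)
        except Exception as exc:
            _write_manifest(manifest, outdir)
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = counts
        logger.info("stage %s: %s", stage, counts)

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")


# ---------------------------------------------------------------------------
# stage runners: each returns its row-count summary for the manifest
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    sim_cfg = SimulationConfig(**{"seed": cfg.seed, **cfg.simulation})
    study = simulate_study(sim_cfg)
    study.write(outdir)
    state["study"] = study
    return {
        "transcripts": len(study.transcripts),
        "expression_features": len(study.counts),
        "mirnas": len(study.mirna_counts),
    }


def _load_annotation(cfg: PipelineConfig, outdir: Path, state: dict):
    if "transcripts" not in state:
        state["transcripts"] = read_annotation(outdir / "annotation.gtf")
    return state["transcripts"]


def _stage_discover(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    transcripts = _load_annotation(cfg, outdir, state)
    assembled = [t for t in transcripts if t.category == "assembled"]
    unique = deduplicate_transcripts(assembled)
    evidence = read_evidence(outdir / "evidence.tsv")
    outcomes = run_filter_cascade(
        unique,
        evidence,
        min_length=cfg.min_length,
        min_coverage=cfg.min_coverage,
        max_known_identity=cfg.max_known_identity,
        cpc_cutoff=cfg.cpc_cutoff,
    )
    frame = outcomes_to_frame(outcomes)
    frame.to_csv(outdir / "discovery.tsv", sep="\t", index=False)
    state["novel_ids"] = set(frame.loc[frame["passed"] == 1, "transcript_id"])
    drops = frame.loc[frame["passed"] == 0, "failed_step"].value_counts().to_dict()
    return {
        "assembled": len(assembled),
        "after_dedup": len(unique),
        "novel_lncRNA": len(state["novel_ids"]),
        "dropped": {k: int(v) for k, v in sorted(drops.items())},
    }


def _lnc_and_gene_sets(state: dict) -> tuple[list, list]:
    transcripts = state["transcripts"]
    novel = state.get("novel_ids", set())
    lncs = [
        t
        for t in transcripts
        if t.category == "known_lncRNA" or t.transcript_id in novel
    ]
    genes = [t for t in transcripts if t.category == "known_coding"]
    return lncs, genes


def _stage_classify(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    _load_annotation(cfg, outdir, state)
    lncs, genes = _lnc_and_gene_sets(state)
    assignments = classify_all(lncs, genes, max_gap=cfg.cis_window)
    frame = assignments_to_frame(assignments)
    frame.to_csv(outdir / "classification.tsv", sep="\t", index=False)
    state["classification"] = frame
    return {
        "lncRNAs": len(frame),
        "classified": int((frame["class"] != "unclassified").sum()),
    }


def _stage_quantify(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    transcripts = _load_annotation(cfg, outdir, state)
    counts = pd.read_csv(outdir / "counts.tsv", sep="\t", index_col="feature_id")
    lengths = pd.Series(
        {t.transcript_id: t.length for t in transcripts}, name="length"
    )
    rpkm = compute_rpkm(counts, lengths)
    rpkm.rename_axis("feature_id").to_csv(outdir / "rpkm.tsv", sep="\t")
    sets = expressed_sets(rpkm, threshold=cfg.rpkm_cutoff)
    lnc_ids = {
        t.transcript_id
        for t in transcripts
        if t.category == "known_lncRNA" or t.transcript_id in state.get("novel_ids", set())
    }
    lnc_sets = {t: s & lnc_ids for t, s in sets.items()}
    venn_counts(lnc_sets).to_csv(outdir / "venn_lncRNA.tsv", sep="\t", index=False)
    state.update(counts=counts, rpkm=rpkm, expressed=sets, lnc_ids=lnc_ids)
    return {
        "features": len(rpkm),
        "expressed_per_tissue": {t: len(s) for t, s in sorted(sets.items())},
        "expressed_lncRNA": len(set().union(*lnc_sets.values()) if lnc_sets else set()),
    }


def _stage_de(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    counts = state.get("counts")
    if counts is None:
        counts = pd.read_csv(outdir / "counts.tsv", sep="\t", index_col="feature_id")
    expressed = state.get("expressed")
    if expressed is not None:
        keep = sorted(set().union(*expressed.values()))
        counts_kept = counts.loc[counts.index.intersection(keep)]
    else:
        counts_kept = counts
    tissues = sorted({c.rsplit("_", 1)[0] for c in counts.columns})
    de = de_all_contrasts(
        counts_kept,
        tissues,
        method=cfg.de_method,
        min_fold_change=cfg.fc_cutoff,
        q_cutoff=cfg.q_cutoff,
    )
    de.to_csv(outdir / "de.tsv", sep="\t", index=False)
    state["de"] = de

    mirna_path = outdir / "mirna_counts.tsv"
    summary = {
        "tested": counts_kept.shape[0],
        "significant": int(de["significant"].sum()),
    }
    if mirna_path.exists():
        mirna = pd.read_csv(mirna_path, sep="\t", index_col="feature_id")
        de_mir = de_all_contrasts(
            mirna,
            tissues,
            method=cfg.de_method,
            min_fold_change=cfg.fc_cutoff,
            q_cutoff=cfg.q_cutoff,
        )
        de_mir.to_csv(outdir / "de_mirna.tsv", sep="\t", index=False)
        state["de_mirna"] = de_mir
        summary["mirna_significant"] = int(de_mir["significant"].sum())
    return summary


def _de_feature_sets(state: dict) -> tuple[set, set]:
    de = state["de"]
    de_ids = set(de.loc[de["significant"], "feature_id"])
    lnc_ids = state.get("lnc_ids", set())
    gene_ids = {
        t.transcript_id for t in state["transcripts"] if t.category == "known_coding"
    }
    return de_ids & lnc_ids, de_ids & gene_ids


def _stage_cis(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    _load_annotation(cfg, outdir, state)
    de_lnc, de_genes = _de_feature_sets(state)
    candidates = predict_cis_targets(
        de_lnc,
        de_genes,
        state["rpkm"],
        state["transcripts"],
        window=cfg.cis_window,
        alpha=cfg.cis_alpha,
    )
    candidates.to_csv(outdir / "cis_targets.tsv", sep="\t", index=False)
    state["cis"] = candidates
    return {"de_lncRNA": len(de_lnc), "de_genes": len(de_genes),
            "cis_pairs": len(candidates)}


def _stage_enrich(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    term_map = pd.read_csv(outdir / "terms.tsv", sep="\t")
    background = {
        t.transcript_id for t in state["transcripts"] if t.category == "known_coding"
    }
    targets = set(state["cis"]["gene_id"]) & background
    result = enrich(term_map, targets, background)
    result.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    return {"terms": len(result), "target_genes": len(targets)}


def _stage_cerna(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    lnc_targets = pd.read_csv(outdir / "lnc_targets.tsv", sep="\t")
    mrna_targets = pd.read_csv(outdir / "mrna_targets.tsv", sep="\t")
    de_all = pd.concat([state["de"], state["de_mirna"]], ignore_index=True)
    trends = build_trends(de_all)
    triplets = build_cerna_network(lnc_targets, mrna_targets, trends)
    triplets.to_csv(outdir / "cerna_triplets.tsv", sep="\t", index=False)
    export_network(triplets, outdir / "network.sif", outdir / "network_nodes.tsv")
    accepted = triplets[triplets["accepted"]] if len(triplets) else triplets
    state["triplets"] = triplets
    return {
        "candidate_triplets": len(triplets),
        "accepted_triplets": int(len(accepted)),
        "mirnas": accepted["mirna_id"].nunique() if len(accepted) else 0,
        "lncRNAs": accepted["lnc_id"].nunique() if len(accepted) else 0,
        "mRNAs": accepted["mrna_id"].nunique() if len(accepted) else 0,
    }


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "discover": _stage_discover,
    "classify": _stage_classify,
    "quantify": _stage_quantify,
    "de": _stage_de,
    "cis": _stage_cis,
    "enrich": _stage_enrich,
    "cerna": _stage_cerna,
}
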