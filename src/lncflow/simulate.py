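"""Self-contained synthetic multi-tissue lncRNA study with planted truth.

The generator emulates the shape of a three-tissue (flower / leaf / root),
three-replicate plant RNA-seq study: a toy genome annotated with coding
genes, known lncRNAs and newly assembled transcripts; transcript
sequences; a negative-binomial count matrix; a coding-evidence table;
miRNA-target tables and a miRNA count matrix.  Every downstream stage
has planted, recoverable structure:

* six positional lncRNA classes placed constructively next to a partner
  gene, each in an isolated genomic slot so the planted partner is
  unambiguous;
* decoy assembled transcripts violating exactly one discovery-cascade
  step each, so failure attribution is testable;
* differentially expressed features with a configurable log2 effect;
* cis pairs (lncRNA and gene within the 100-kb window sharing a tissue
  profile, hence correlated);
* ceRNA triplets whose miRNA shows the opposite tissue trend, plus
  decoy triplets with a concordant miRNA trend (to be rejected).

Counts are negative binomial with variance mu + dispersion * mu^2;
dispersion 0 degenerates to Poisson and ``exact_counts`` replaces
sampling with rounded means (the zero-noise limit in which all planted
structure is exactly recoverable).  A single integer seed determines
every output byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .classify import ALL_CLASSES
from .discovery import CASCADE_STEPS, CodingEvidence, write_evidence
from .genome_io import GenomicInterval, TranscriptModel, write_fasta, write_gtf

TISSUES = ("flower", "leaf", "root")


class ConfigurationError(ValueError):
    """The requested study cannot be realized (e.g. genome too small)."""


@dataclass
class SimulationConfig:
    """Study design knobs; defaults define the standard synthetic study."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 15_000_000
    slot_bp: int = 250_000  # isolation slot per planted unit (> cis window)
    n_coding_genes: int = 30  # standalone background coding genes
    n_lnc_per_class: int = 10
    n_known_lnc: int = 20
    n_tissue_specific: int = 6  # known lncRNAs expressed in one tissue only
    n_silent: int = 4  # known lncRNAs below the RPKM threshold everywhere
    n_cis_pairs: int = 8
    n_cerna_triplets: int = 6
    n_cerna_decoys: int = 6
    n_background_mirnas: int = 4
    frac_fail_per_filter: float = 0.05  # decoys per cascade step, as a
    # fraction of planted novel lncRNAs (overridden by n_decoys_per_step)
    n_decoys_per_step: int | None = None
    n_de_standalone: int = 20  # planted DE among standalone coding genes
    n_reps: int = 3
    library_size: int = 2_000_000
    nb_dispersion: float = 0.1
    de_log2fc: float = 2.0
    exact_counts: bool = False
    n_terms: int = 12
    tissues: tuple[str, ...] = TISSUES

    def __post_init__(self) -> None:
        for name in (
            "n_chroms",
            "chrom_length",
            "n_coding_genes",
            "n_lnc_per_class",
            "n_known_lnc",
            "n_cis_pairs",
            "n_cerna_triplets",
            "n_cerna_decoys",
            "n_reps",
            "library_size",
        ):
            if getattr(self, name) < 0 or (
                name in ("n_chroms", "chrom_length", "n_reps", "library_size")
                and getattr(self, name) <= 0
            ):
                raise ConfigurationError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.n_de_standalone > self.n_coding_genes:
            raise ConfigurationError("n_de_standalone exceeds n_coding_genes")
        if self.n_tissue_specific + self.n_silent > self.n_known_lnc:
            raise ConfigurationError(
                "n_tissue_specific + n_silent exceeds n_known_lnc"
            )

    @property
    def n_novel(self) -> int:
        return (
            6 * self.n_lnc_per_class
            + self.n_cis_pairs
            + self.n_cerna_triplets
            + self.n_cerna_decoys
        )

    @property
    def decoys_per_step(self) -> int:
        if self.n_decoys_per_step is not None:
            return self.n_decoys_per_step
        return max(1, round(self.frac_fail_per_filter * self.n_novel))

    @property
    def contrasts(self) -> list[tuple[str, str]]:
        t = self.tissues
        return [(t[i], t[j]) for i in range(len(t)) for j in range(i + 1, len(t))]


@dataclass
class TruthTable:
    """Planted ground truth: per-feature records plus pair/triplet lists."""

    features: pd.DataFrame
    cis_pairs: pd.DataFrame
    triplets: pd.DataFrame


@dataclass
class StudyData:
    """Everything a pipeline run consumes, plus the planted truth."""

    config: SimulationConfig
    transcripts: list[TranscriptModel]
    sequences: dict[str, str]
    counts: pd.DataFrame
    evidence: list[CodingEvidence]
    lnc_targets: pd.DataFrame
    mrna_targets: pd.DataFrame
    mirna_counts: pd.DataFrame
    term_map: pd.DataFrame
    truth: TruthTable
    mean_profiles: pd.DataFrame = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(self.transcripts, outdir / "annotation.gtf")
        write_fasta(self.sequences, outdir / "transcripts.fa")
        self.counts.rename_axis("feature_id").to_csv(
            outdir / "counts.tsv", sep="\t"
        )
        write_evidence(self.evidence, outdir / "evidence.tsv")
        self.lnc_targets.to_csv(outdir / "lnc_targets.tsv", sep="\t", index=False)
        self.mrna_targets.to_csv(outdir / "mrna_targets.tsv", sep="\t", index=False)
        self.mirna_counts.rename_axis("feature_id").to_csv(
            outdir / "mirna_counts.tsv", sep="\t"
        )
        self.term_map.to_csv(outdir / "terms.tsv", sep="\t", index=False)
        self.truth.features.to_csv(outdir / "truth_features.tsv", sep="\t", index=False)
        self.truth.cis_pairs.to_csv(
            outdir / "truth_cis_pairs.tsv", sep="\t", index=False
        )
        self.truth.triplets.to_csv(outdir / "truth_triplets.tsv", sep="\t", index=False)
        with open(outdir / "sim_config.yaml", "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self.config), handle, sort_keys=True)


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------

_MIN_EXON, _MIN_INTRON = 30, 20


def _make_transcript(
    tid: str,
    gid: str,
    chrom: str,
    start: int,
    span: int,
    strand: str,
    n_exons: int,
    category: str,
) -> TranscriptModel:
    """Place a transcript of the given span with roughly 70% exonic bases."""
    if n_exons == 1 or span < n_exons * _MIN_EXON + (n_exons - 1) * _MIN_INTRON + 10:
        exons = [GenomicInterval(chrom, start, start + span, strand)]
    else:
        exon_total = max(n_exons * _MIN_EXON, round(span * 0.7))
        exon_total = min(exon_total, span - (n_exons - 1) * _MIN_INTRON)
        base_e, extra_e = divmod(exon_total, n_exons)
        exon_lens = [base_e + (1 if i < extra_e else 0) for i in range(n_exons)]
        intron_total = span - exon_total
        base_i, extra_i = divmod(intron_total, n_exons - 1)
        intron_lens = [base_i + (1 if i < extra_i else 0) for i in range(n_exons - 1)]
        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append(GenomicInterval(chrom, pos, pos + el, strand))
            pos += el
            if i < len(intron_lens):
                pos += intron_lens[i]
    return TranscriptModel(tid, gid, tuple(exons), category)


class _SlotAllocator:
    def __init__(self, cfg: SimulationConfig, n_slots: int):
        per_chrom = cfg.chrom_length // cfg.slot_bp
        if per_chrom * cfg.n_chroms < n_slots:
            raise ConfigurationError(
                f"genome too small: need {n_slots} slots of {cfg.slot_bp} bp, "
                f"have {per_chrom * cfg.n_chroms}"
            )
        self.cfg = cfg
        self.per_chrom = per_chrom
        self.next_slot = 0

    def take(self) -> tuple[str, int]:
        """Return (chrom, usable start) of the next isolation slot."""
        chrom_idx, slot_idx = divmod(self.next_slot, self.per_chrom)
        self.next_slot += 1
        origin = slot_idx * self.cfg.slot_bp
        return f"chr{chrom_idx + 1}", origin + 10_000


_CLASS_GEOMETRY_SPAN = {
    # (lnc offset, lnc span, partner offset, partner span)
    "containing": (0, 4000, 1000, 2000),
    "nested": (1000, 1000, 0, 4000),
    "overlapping": (0, 2500, 1500, 4000),
    "same_strand": (0, 1200, 5000, 3000),
    "convergent": (0, 1200, 5000, 3000),
    "divergent": (0, 1200, 5000, 3000),
}


def _class_strands(cls: str, rng: np.random.Generator) -> tuple[str, str, bool]:
    """(lnc_strand, partner_strand, lnc_on_left) realizing a class."""
    if cls in ("containing", "nested", "overlapping"):
        return rng.choice(["+", "-"]), rng.choice(["+", "-"]), True
    if cls == "same_strand":
        s = rng.choice(["+", "-"])
        return s, s, bool(rng.integers(2))
    left_of_pair = bool(rng.integers(2))  # lncRNA on the left?
    if cls == "convergent":  # left '+', right '-'
        return ("+", "-", True) if left_of_pair else ("-", "+", False)
    # divergent: left '-', right '+'
    return ("-", "+", True) if left_of_pair else ("+", "-", False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig | None = None) -> StudyData:
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    r = 2.0**cfg.de_log2fc

    transcripts: list[TranscriptModel] = []
    feature_rows: list[dict] = []
    profiles: dict[str, np.ndarray] = {}  # feature -> per-tissue mean
    evidence: list[CodingEvidence] = []
    n_tissues = len(cfg.tissues)

    n_slots = (
        cfg.n_coding_genes
        + 6 * cfg.n_lnc_per_class
        + cfg.n_known_lnc
        + cfg.n_cis_pairs
        + 2 * (cfg.n_cerna_triplets + cfg.n_cerna_decoys)
        + len(CASCADE_STEPS) * cfg.decoys_per_step
    )
    slots = _SlotAllocator(cfg, n_slots)

    counters = {"mrna": 0, "lncK": 0, "asm": 0}

    def next_id(prefix: str) -> str:
        counters[prefix] += 1
        return f"{prefix}_{counters[prefix]:04d}"

    n_expr_features = (
        cfg.n_coding_genes
        + 7 * cfg.n_lnc_per_class  # class lncs + partners
        + cfg.n_known_lnc
        + 2 * cfg.n_cis_pairs
        + 2 * (cfg.n_cerna_triplets + cfg.n_cerna_decoys)
        + len(CASCADE_STEPS) * cfg.decoys_per_step
    )
    base_mean = cfg.library_size / max(n_expr_features, 1)

    def baseline() -> float:
        return float(rng.lognormal(mean=np.log(base_mean), sigma=0.6))

    def add_feature(
        tx: TranscriptModel,
        kind: str,
        role: str,
        profile: np.ndarray,
        planted_class: str = "",
        partner_id: str = "",
        is_novel: bool = False,
        failed_step: str = "none",
    ) -> None:
        transcripts.append(tx)
        profiles[tx.transcript_id] = profile
        feature_rows.append(
            {
                "feature_id": tx.transcript_id,
                "gene_id": tx.gene_id,
                "kind": kind,
                "role": role,
                "chrom": tx.chrom,
                "planted_class": planted_class,
                "partner_id": partner_id,
                "is_novel": is_novel,
                "failed_step": failed_step,
            }
        )

    def passing_evidence(tid: str) -> CodingEvidence:
        ident = None if rng.random() < 0.5 else float(rng.uniform(0, 50))
        return CodingEvidence(
            transcript_id=tid,
            cpc_score=float(rng.uniform(-3.0, -0.5)),
            pfam_hit=False,
            read_coverage=float(rng.uniform(3.0, 60.0)),
            known_lnc_identity=ident,
            overlaps_known_coding=False,
        )

    flat = lambda b: np.full(n_tissues, b)  # noqa: E731

    # --- standalone coding genes (first n_de_standalone are planted DE) ----
    for i in range(cfg.n_coding_genes):
        chrom, start = slots.take()
        tid = next_id("mrna")
        tx = _make_transcript(
            tid,
            f"gene_{tid}",
            chrom,
            start + int(rng.integers(0, 2000)),
            int(rng.integers(3000, 8000)),
            str(rng.choice(["+", "-"])),
            int(rng.integers(2, 6)),
            "known_coding",
        )
        if i < cfg.n_de_standalone:
            b = baseline()
            profile = flat(b)
            t = int(rng.integers(n_tissues))
            profile[t] = b * r if rng.random() < 0.5 else b / r
            add_feature(tx, "coding", "de_standalone", profile)
        else:
            add_feature(tx, "coding", "standalone", flat(baseline()))

    # --- six-class planted lncRNAs, one isolated slot per (lnc, partner) --
    for cls in ALL_CLASSES:
        lnc_off, lnc_span, par_off, par_span = _CLASS_GEOMETRY_SPAN[cls]
        for _ in range(cfg.n_lnc_per_class):
            chrom, start = slots.take()
            base = start + int(rng.integers(0, 2000))
            lnc_strand, par_strand, lnc_left = _class_strands(cls, rng)
            if cls in ("containing", "nested", "overlapping") or lnc_left:
                lo, po = lnc_off, par_off
            else:  # mirrored intergenic layout: partner left, lncRNA right
                lo, po = par_off, lnc_off
            lnc_id = next_id("asm")
            par_id = next_id("mrna")
            lnc = _make_transcript(
                lnc_id,
                f"gene_{lnc_id}",
                chrom,
                base + lo,
                lnc_span,
                lnc_strand,
                int(rng.integers(1, 4)),
                "assembled",
            )
            par = _make_transcript(
                par_id,
                f"gene_{par_id}",
                chrom,
                base + po,
                par_span,
                par_strand,
                int(rng.integers(1, 4)),
                "known_coding",
            )
            add_feature(
                lnc,
                "lncRNA",
                "class_lnc",
                flat(baseline()),
                planted_class=cls,
                partner_id=f"gene_{par_id}",
                is_novel=True,
            )
            add_feature(par, "coding", "class_partner", flat(baseline()))
            evidence.append(passing_evidence(lnc_id))

    # --- known lncRNAs: tissue-specific, silent, and flat ------------------
    for i in range(cfg.n_known_lnc):
        chrom, start = slots.take()
        tid = next_id("lncK")
        tx = _make_transcript(
            tid,
            f"gene_{tid}",
            chrom,
            start + int(rng.integers(0, 2000)),
            int(rng.integers(600, 2000)),
            str(rng.choice(["+", "-"])),
            int(rng.integers(1, 4)),
            "known_lncRNA",
        )
        if i < cfg.n_tissue_specific:
            profile = np.zeros(n_tissues)
            profile[i % n_tissues] = baseline()
            role = "tissue_specific_lnc"
        elif i < cfg.n_tissue_specific + cfg.n_silent:
            profile = flat(0.3)  # well below the RPKM >= 1 expression filter
            role = "silent_lnc"
        else:
            profile = flat(baseline())
            role = "known_lnc"
        add_feature(tx, "lncRNA", role, profile)

    # --- planted cis pairs: lncRNA and gene < 100 kb apart, shared profile -
    cis_rows = []
    for _ in range(cfg.n_cis_pairs):
        chrom, start = slots.take()
        base = start + int(rng.integers(0, 2000))
        lnc_id = next_id("asm")
        gene_tid = next_id("mrna")
        lnc = _make_transcript(
            lnc_id,
            f"gene_{lnc_id}",
            chrom,
            base,
            int(rng.integers(600, 1500)),
            str(rng.choice(["+", "-"])),
            int(rng.integers(1, 3)),
            "assembled",
        )
        gene = _make_transcript(
            gene_tid,
            f"gene_{gene_tid}",
            chrom,
            base + 40_000,
            int(rng.integers(3000, 6000)),
            str(rng.choice(["+", "-"])),
            int(rng.integers(2, 5)),
            "known_coding",
        )
        weights = rng.permutation([1.0, r, r * r])
        add_feature(
            lnc,
            "lncRNA",
            "cis_lnc",
            baseline() * weights,
            partner_id=gene_tid,
            is_novel=True,
        )
        add_feature(gene, "coding", "cis_gene", baseline() * weights)
        evidence.append(passing_evidence(lnc_id))
        cis_rows.append({"lnc_id": lnc_id, "gene_id": gene_tid})

    # --- ceRNA triplets (and concordant-trend decoy triplets) --------------
    mir_profiles: dict[str, np.ndarray] = {}
    mir_rows: list[dict] = []
    lnc_target_rows: list[dict] = []
    mrna_target_rows: list[dict] = []
    triplet_rows: list[dict] = []
    n_mirs = cfg.n_cerna_triplets + cfg.n_cerna_decoys + cfg.n_background_mirnas
    mir_base = (cfg.library_size / 10) / max(n_mirs, 1)

    def add_trio(index: int, planted: bool) -> None:
        t = int(rng.integers(n_tissues))
        chrom, start = slots.take()
        lnc_id = next_id("asm")
        lnc = _make_transcript(
            lnc_id,
            f"gene_{lnc_id}",
            chrom,
            start + int(rng.integers(0, 2000)),
            int(rng.integers(600, 1500)),
            str(rng.choice(["+", "-"])),
            int(rng.integers(1, 3)),
            "assembled",
        )
        chrom, start = slots.take()
        mrna_id = next_id("mrna")
        mrna = _make_transcript(
            mrna_id,
            f"gene_{mrna_id}",
            chrom,
            start + int(rng.integers(0, 2000)),
            int(rng.integers(3000, 6000)),
            str(rng.choice(["+", "-"])),
            int(rng.integers(2, 5)),
            "known_coding",
        )
        up_lnc = flat(baseline())
        up_lnc[t] *= r
        up_mrna = flat(baseline())
        up_mrna[t] *= r
        role = "cerna_lnc" if planted else "cerna_decoy_lnc"
        add_feature(lnc, "lncRNA", role, up_lnc, is_novel=True)
        add_feature(
            mrna, "coding", "cerna_mrna" if planted else "cerna_decoy_mrna", up_mrna
        )
        evidence.append(passing_evidence(lnc_id))

        mir_id = f"mir_{index:04d}"
        mp = flat(float(rng.lognormal(np.log(mir_base), 0.4)))
        # sponge-consistent miRNA moves opposite to its targets; a decoy
        # miRNA moves with them and must be rejected by the trend rule
        mp[t] = mp[t] / r if planted else mp[t] * r
        mir_profiles[mir_id] = mp
        mir_rows.append(
            {"feature_id": mir_id, "role": "mir_planted" if planted else "mir_decoy"}
        )
        score = float(rng.uniform(120, 200))
        lnc_target_rows.append(
            {
                "mirna_id": mir_id,
                "target_id": lnc_id,
                "target_type": "lncRNA",
                "source": "psRNATarget",
                "score": score,
            }
        )
        mrna_target_rows.append(
            {
                "mirna_id": mir_id,
                "target_id": mrna_id,
                "target_type": "mRNA",
                "source": "miRanda",
                "score": float(rng.uniform(120, 200)),
            }
        )
        triplet_rows.append(
            {
                "lnc_id": lnc_id,
                "mirna_id": mir_id,
                "mrna_id": mrna_id,
                "planted": planted,
            }
        )

    for i in range(cfg.n_cerna_triplets):
        add_trio(i, planted=True)
    for i in range(cfg.n_cerna_decoys):
        add_trio(cfg.n_cerna_triplets + i, planted=False)
    for i in range(cfg.n_background_mirnas):
        mir_id = f"mir_{cfg.n_cerna_triplets + cfg.n_cerna_decoys + i:04d}"
        mir_profiles[mir_id] = flat(float(rng.lognormal(np.log(mir_base), 0.4)))
        mir_rows.append({"feature_id": mir_id, "role": "mir_background"})

    # --- discovery-cascade decoys: exactly one violated step each ----------
    for step in CASCADE_STEPS:
        for _ in range(cfg.decoys_per_step):
            chrom, start = slots.take()
            tid = next_id("asm")
            span = (
                int(rng.integers(120, 180))
                if step == "length"
                else int(rng.integers(500, 1500))
            )
            tx = _make_transcript(
                tid,
                f"gene_{tid}",
                chrom,
                start + int(rng.integers(0, 2000)),
                span,
                str(rng.choice(["+", "-"])),
                1 if step == "length" else int(rng.integers(1, 3)),
                "assembled",
            )
            ev = passing_evidence(tid)
            if step == "coverage":
                ev = dataclasses.replace(ev, read_coverage=float(rng.uniform(0, 2.9)))
            elif step == "known_overlap":
                ev = dataclasses.replace(ev, overlaps_known_coding=True)
            elif step == "known_lnc_similarity":
                ev = dataclasses.replace(
                    ev, known_lnc_identity=float(rng.uniform(91, 100))
                )
            elif step == "coding_potential":
                if rng.random() < 0.5:
                    ev = dataclasses.replace(ev, cpc_score=float(rng.uniform(0.0, 3.0)))
                else:
                    ev = dataclasses.replace(ev, pfam_hit=True)
            evidence.append(ev)
            add_feature(
                tx, "lncRNA", "decoy", flat(baseline()), failed_step=step
            )

    # --- counts -------------------------------------------------------------
    samples = [f"{t}_{i + 1}" for t in cfg.tissues for i in range(cfg.n_reps)]
    feature_ids = [tx.transcript_id for tx in transcripts]
    mu = np.array([profiles[fid] for fid in feature_ids])  # features x tissues
    mu_samples = np.repeat(mu, cfg.n_reps, axis=1)

    def draw(mu_mat: np.ndarray) -> np.ndarray:
        if cfg.exact_counts:
            return np.rint(mu_mat).astype(np.int64)
        if cfg.nb_dispersion == 0:
            return rng.poisson(mu_mat).astype(np.int64)
        size = 1.0 / cfg.nb_dispersion
        p = size / (size + mu_mat)
        return rng.negative_binomial(size, p).astype(np.int64)

    counts = pd.DataFrame(draw(mu_samples), index=feature_ids, columns=samples)

    mir_ids = list(mir_profiles)
    mir_mu = np.repeat(
        np.array([mir_profiles[m] for m in mir_ids]), cfg.n_reps, axis=1
    )
    mirna_counts = pd.DataFrame(draw(mir_mu), index=mir_ids, columns=samples)

    # --- sequences ----------------------------------------------------------
    sequences = {tx.transcript_id: _random_seq(rng, tx.length) for tx in transcripts}

    # --- annotation terms: background terms plus one planted enriched term --
    coding_ids = [tx.transcript_id for tx in transcripts if tx.category == "known_coding"]
    term_rows = []
    for t_idx in range(cfg.n_terms):
        term_id = f"TERM:{t_idx:04d}"
        members = rng.choice(
            coding_ids, size=min(len(coding_ids), int(rng.integers(3, 9))), replace=False
        )
        for gid in members:
            term_rows.append(
                {
                    "gene_id": gid,
                    "term_id": term_id,
                    "term_name": f"synthetic process {t_idx}",
                    "namespace": "biological_process",
                }
            )
    # planted term concentrated on the cis-pair genes (DE by construction)
    for row in cis_rows:
        term_rows.append(
            {
                "gene_id": row["gene_id"],
                "term_id": "TERM:CIS",
                "term_name": "planted cis-target process",
                "namespace": "biological_process",
            }
        )
    term_map = pd.DataFrame(
        term_rows, columns=["gene_id", "term_id", "term_name", "namespace"]
    ).drop_duplicates(["gene_id", "term_id"])

    # --- truth: expected per-contrast trends from the mean profiles --------
    features = pd.DataFrame(feature_rows)
    mir_truth = pd.DataFrame(
        [
            {
                "feature_id": row["feature_id"],
                "gene_id": row["feature_id"],
                "kind": "miRNA",
                "role": row["role"],
                "chrom": "",
                "planted_class": "",
                "partner_id": "",
                "is_novel": False,
                "failed_step": "none",
            }
            for row in mir_rows
        ]
    )
    features = pd.concat([features, mir_truth], ignore_index=True)
    all_profiles = {**profiles, **mir_profiles}
    tissue_idx = {t: i for i, t in enumerate(cfg.tissues)}
    eps = 1e-9
    for a, b in cfg.contrasts:
        col = f"trend_{a}-vs-{b}"
        signs = []
        for fid in features["feature_id"]:
            pa = all_profiles[fid][tissue_idx[a]] + eps
            pb = all_profiles[fid][tissue_idx[b]] + eps
            l2 = np.log2(pa / pb)
            signs.append(int(np.sign(l2)) if abs(l2) >= 1.0 else 0)
        features[col] = signs
    for t in cfg.tissues:
        features[f"mean_{t}"] = [
            all_profiles[fid][tissue_idx[t]] for fid in features["feature_id"]
        ]

    truth = TruthTable(
        features=features,
        cis_pairs=pd.DataFrame(cis_rows, columns=["lnc_id", "gene_id"]),
        triplets=pd.DataFrame(
            triplet_rows, columns=["lnc_id", "mirna_id", "mrna_id", "planted"]
        ),
    )
    return StudyData(
        config=cfg,
        transcripts=transcripts,
        sequences=sequences,
        counts=counts,
        evidence=evidence,
        lnc_targets=pd.DataFrame(lnc_target_rows, columns=list(TARGET_COLS)),
        mrna_targets=pd.DataFrame(mrna_target_rows, columns=list(TARGET_COLS)),
        mirna_counts=mirna_counts,
        term_map=term_map,
        truth=truth,
        mean_profiles=pd.DataFrame(
            {fid: all_profiles[fid] for fid in all_profiles},
            index=list(cfg.tissues),
        ).T,
    )


TARGET_COLS = ("mirna_id", "target_id", "target_type", "source", "score")


def config_from_yaml(path: str | Path) -> SimulationConfig:
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    if "tissues" in data:
        data["tissues"] = tuple(data["tissues"])
    return SimulationConfig(**data)
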