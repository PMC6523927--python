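"""End-to-end pipeline driver: simulate -> clean -> annotate -> novel -> DE -> enrich -> report.

All randomness flows from the single config seed and every emitted table is a
deterministic function of the inputs, so a rerun with the same config
reproduces byte-identical files.  The run manifest records the package
version, seed, thresholds and SHA-256 hashes of the inputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    AnnotatedTag,
    map_tags,
    category_summary,
    read_annotation_gff3,
    read_reference_fasta,
)
from .de import DifferentialResult, differential_expression
from .enrich import enrich, predict_targets
from .hairpin import call_novel_mirnas, call_sirna_pairs, locate_tags
from .preprocess import SmallRNATag, clean_reads, length_distribution, read_fastq, summarize_library
from .simulate import SyntheticConfig, generate_reference, generate_target_universe, simulate_to_dir

__all__ = ["PipelineConfig", "PipelineError", "tally_regulation", "run_pipeline"]

STAGES = ("simulate", "clean", "annotate", "novel", "de", "enrich", "report")


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int = 0
    synthetic: SyntheticConfig | None = None  # when set, inputs are simulated
    # thresholds, stage by stage
    quality_floor: float = 20.0
    min_len: int = 18
    max_len: int = 28
    max_mismatch: int = 2
    window_flank: int = 80
    novel_min_count: int = 5
    zero_floor: float = 0.001
    fdr_threshold: float = 0.001
    lfc_threshold: float = 1.0
    target_cutoff: float = 4.0
    enrichment_alpha: float = 0.05

    def __post_init__(self):
        if self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)
        if not (0 < self.fdr_threshold <= 1 and 0 < self.enrichment_alpha <= 1):
            raise ValueError("significance thresholds must lie in (0, 1]")
        if self.max_mismatch not in (0, 1, 2):
            raise ValueError("max_mismatch must be 0, 1 or 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            if "insert_length_weights" in syn:
                syn["insert_length_weights"] = {
                    int(k): float(v) for k, v in syn["insert_length_weights"].items()
                }
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def tally_regulation(results: list[DifferentialResult]) -> tuple[int, int, int]:
    """Counts of up, down and total differentially expressed sRNAs (ns excluded)."""
    n_up = sum(1 for r in results if r.regulation == "up")
    n_down = sum(1 for r in results if r.regulation == "down")
    return n_up, n_down, n_up + n_down


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(stage: str, t0: float) -> None:
    print(f"[saltmir] {stage}: {time.perf_counter() - t0:.2f}s", file=sys.stderr)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order and return the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: v for k, v in asdict(config).items() if k not in ("synthetic",)
        },
        "stages": {},
        "input_hashes": {},
    }

    # --- simulate ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        syn = config.synthetic
        paths = simulate_to_dir(syn, outdir / "sim")
        sim_ref = generate_reference(syn)
        universe = generate_target_universe(syn, sim_ref)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc
    manifest["stages"]["simulate"] = sorted(str(p.name) for p in paths.values())
    for key, p in paths.items():
        manifest["input_hashes"][key] = _sha256(p)
    _log("simulate", t0)

    # --- clean ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        raw_counts = {}
        cleaned = {}
        for lib, fastq in (("control", paths["control_fastq"]), ("stress", paths["stress_fastq"])):
            reads = list(read_fastq(fastq))
            raw_counts[lib] = len(reads)
            cleaned[lib] = clean_reads(
                reads,
                adapter=syn.adapter,
                quality_floor=config.quality_floor,
                min_len=config.min_len,
                max_len=config.max_len,
                primer5=syn.primer5,
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("clean", str(exc)) from exc
    lengths_rows = []
    for lib, res in cleaned.items():
        total, unique = length_distribution(res.tags)
        for L in sorted(k for k in total if k != -1):
            lengths_rows.append({"library": lib, "length": L, "reads": total[L], "unique_tags": unique[L]})
        lengths_rows.append({"library": lib, "length": "overflow", "reads": total[-1], "unique_tags": unique[-1]})
    pd.DataFrame(lengths_rows).to_csv(outdir / "lengths.tsv", sep="\t", index=False)
    rej_rows = [
        {"library": lib, "rule": rule, "reads": n}
        for lib, res in cleaned.items()
        for rule, n in res.rejections.items()
    ]
    pd.DataFrame(rej_rows).to_csv(outdir / "rejections.tsv", sep="\t", index=False)
    manifest["stages"]["clean"] = ["lengths.tsv", "rejections.tsv"]
    _log("clean", t0)

    # --- annotate ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        reference = read_reference_fasta(paths["reference"])
        annotations = read_annotation_gff3(paths["annotation"], reference)
        # union of unique sequences with per-library counts
        seq_counts: dict[str, dict[str, int]] = {}
        for lib, res in cleaned.items():
            for tag in res.tags:
                seq_counts.setdefault(tag.sequence, {"control": 0, "stress": 0})[lib] = tag.count
        union_tags = [
            SmallRNATag(seq, c["control"] + c["stress"]) for seq, c in sorted(seq_counts.items())
        ]
        annotated, _ = map_tags(union_tags, reference, annotations, config.max_mismatch)
        by_seq = {at.tag.sequence: at for at in annotated}
        summary_rows = []
        for lib, res in cleaned.items():
            lib_tags = res.tags
            mapped_n = sum(t.count for t in lib_tags if by_seq[t.sequence].genome_mapped)
            s = summarize_library(raw_counts[lib], res.clean_read_total, mapped_n)
            summary_rows.append({"library": lib, **s.__dict__})
            cat_rows = category_summary(
                [
                    AnnotatedTag(t, by_seq[t.sequence].hits, by_seq[t.sequence].resolved_category)
                    for t in lib_tags
                ],
                res.clean_read_total,
            )
            pd.DataFrame(cat_rows).to_csv(outdir / f"categories_{lib}.tsv", sep="\t", index=False)
        pd.DataFrame(summary_rows).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("annotate", str(exc)) from exc
    manifest["stages"]["annotate"] = ["summary.tsv", "categories_control.tsv", "categories_stress.tsv"]
    _log("annotate", t0)

    # --- novel ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        unannotated = [
            at.tag for at in annotated if at.resolved_category == "unannotated" and at.genome_mapped
        ]
        locations = locate_tags(unannotated, reference)
        candidates = call_novel_mirnas(
            locations,
            reference,
            window_flank=config.window_flank,
            min_count=config.novel_min_count,
        )
        sirnas = call_sirna_pairs(locations)
        cand_rows = [
            {
                "candidate_id": f"novel@{c.contig}:{c.window_start}-{c.window_end}",
                "mature_sequence": c.mature_tag.sequence,
                "count": c.mature_tag.count,
                "strand": c.strand,
                "paired_fraction": round(c.paired_fraction, 4),
                "score_density": round(c.score_density, 4),
                "mature_arm": c.mature_arm,
                "star_support": c.star_support,
                "verdict": c.verdict,
            }
            for c in candidates
        ]
        pd.DataFrame(
            cand_rows,
            columns=[
                "candidate_id", "mature_sequence", "count", "strand", "paired_fraction",
                "score_density", "mature_arm", "star_support", "verdict",
            ],
        ).to_csv(outdir / "novel_candidates.tsv", sep="\t", index=False)
        with open(outdir / "novel_precursors.fa", "w") as fh:
            for c in candidates:
                if c.verdict:
                    cid = f"novel@{c.contig}:{c.window_start}-{c.window_end}"
                    fh.write(f">{cid}\n{c.sequence}\n;{c.fold}\n")
        sirna_rows = [
            {
                "contig": s.tag_a.contig,
                "plus_start": s.tag_a.start,
                "plus_end": s.tag_a.end,
                "minus_start": s.tag_b.start,
                "minus_end": s.tag_b.end,
            }
            for s in sirnas
        ]
        pd.DataFrame(
            sirna_rows, columns=["contig", "plus_start", "plus_end", "minus_start", "minus_end"]
        ).to_csv(outdir / "sirna_candidates.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("novel", str(exc)) from exc
    manifest["stages"]["novel"] = ["novel_candidates.tsv", "novel_precursors.fa", "sirna_candidates.tsv"]
    _log("novel", t0)

    # --- differential expression --------------------------------------
    t0 = time.perf_counter()
    try:
        # aggregate per-library counts per sRNA id: annotated miRNA loci plus
        # verdict-positive novel candidates (identified by mature sequence)
        novel_by_seq = {
            c.mature_tag.sequence: f"novel@{c.contig}:{c.window_start}-{c.window_end}"
            for c in candidates
            if c.verdict
        }
        id_counts: dict[str, dict[str, int]] = {}
        id_seq: dict[str, str] = {}
        for seq, counts in seq_counts.items():
            at = by_seq[seq]
            if at.resolved_category == "miRNA" and at.best_locus:
                sid = at.best_locus
            elif seq in novel_by_seq:
                sid = novel_by_seq[seq]
            else:
                continue
            slot = id_counts.setdefault(sid, {"control": 0, "stress": 0})
            slot["control"] += counts["control"]
            slot["stress"] += counts["stress"]
            id_seq.setdefault(sid, seq)
        ids = sorted(id_counts)
        results = differential_expression(
            ids,
            [id_counts[i]["control"] for i in ids],
            [id_counts[i]["stress"] for i in ids],
            cleaned["control"].clean_read_total,
            cleaned["stress"].clean_read_total,
            zero_floor=config.zero_floor,
            fdr_threshold=config.fdr_threshold,
            lfc_threshold=config.lfc_threshold,
        )
        de_df = pd.DataFrame(
            [
                {
                    "srna_id": r.srna_id,
                    "count_control": r.count_a,
                    "count_stress": r.count_b,
                    "tpm_control": round(r.tpm_a, 6),
                    "tpm_stress": round(r.tpm_b, 6),
                    "log2_ratio": round(r.log2_ratio, 6),
                    "regulation": r.regulation,
                    "p_value": f"{r.p_value:.6g}",
                    "fdr": f"{r.fdr:.6g}",
                }
                for r in results
            ]
        )
        de_df.to_csv(outdir / "de.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("de", str(exc)) from exc
    manifest["stages"]["de"] = ["de.tsv"]
    _log("de", t0)

    # --- enrichment ----------------------------------------------------
    t0 = time.perf_counter()
    try:
        des_ids = [r.srna_id for r in results if r.regulation != "ns"]
        mirna_seqs = {sid: id_seq[sid] for sid in des_ids}
        if mirna_seqs:
            assignments = predict_targets(mirna_seqs, universe.transcripts, config.target_cutoff)
            target_genes = sorted({a.gene_id for a in assignments})
        else:
            assignments, target_genes = [], []
        pd.DataFrame(
            [a.__dict__ for a in assignments],
            columns=["mirna_id", "gene_id", "penalty_score", "site_start"],
        ).to_csv(outdir / "targets.tsv", sep="\t", index=False)
        for mode, gene_terms in (("go", universe.gene_go), ("kegg", universe.gene_kegg)):
            background = sorted(gene_terms)
            in_bg = [g for g in target_genes if g in gene_terms]
            rows = enrich(gene_terms, background, in_bg, alpha=config.enrichment_alpha)
            pd.DataFrame(
                [
                    {
                        "term_id": r.term_id,
                        "term_name": r.term_name,
                        "namespace": r.namespace,
                        "m": r.m,
                        "M": r.M,
                        "p_value": f"{r.p_value:.6g}",
                        "p_corrected": f"{r.p_corrected:.6g}",
                        "significant": r.significant,
                    }
                    for r in rows
                ],
                columns=[
                    "term_id", "term_name", "namespace", "m", "M",
                    "p_value", "p_corrected", "significant",
                ],
            ).to_csv(outdir / f"enrichment_{mode}.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("enrich", str(exc)) from exc
    manifest["stages"]["enrich"] = ["targets.tsv", "enrichment_go.tsv", "enrichment_kegg.tsv"]
    _log("enrich", t0)

    # --- report --------------------------------------------------------
    t0 = time.perf_counter()
    n_up, n_down, n_des = tally_regulation(results)
    manifest["regulation_tally"] = {"up": n_up, "down": n_down, "total_des": n_des}
    manifest["stages"]["report"] = ["manifest.json"]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _log("report", t0)
    return manifest
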