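"""Synthetic two-condition small-RNA-seq libraries with known ground truth.

The generator emulates the statistical structure of a pooled control/stress
SE50 sRNA experiment at desk scale: a reference contig carrying known-miRNA,
decoy (Rfam/snoRNA/other) and novel-miRNA loci; single-end 50 nt reads made
of an insert plus a fixed 3' adapter; insert lengths dominated by the 21 and
24 nt species; a configurable junk fraction (adapter-free, poly-A, short or
low-quality reads) to exercise the cleaning filters; and per-locus Poisson
read counts whose stress-library mean is the control mean times a per-locus
fold change.

Novel-miRNA loci are embedded as stem-loops — the mature arm is followed by
a short loop and its reverse complement — so that hairpin folding recovers
them, and a low-abundance star-arm read (the classic 2-nt-offset Dicer
partner) is emitted alongside the mature.  Everything is a deterministic
function of the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from .preprocess import RawRead

__all__ = [
    "SyntheticConfig",
    "SimLocus",
    "SimReference",
    "SimLibraries",
    "generate_reference",
    "generate_libraries",
    "simulate_to_dir",
    "write_fasta",
    "write_gff3",
    "write_fastq",
]

# truth category -> class tag written to the GFF3 annotation
GFF_CLASS = {
    "known_mirna": "miRNA",
    "rfam": "Rfam",
    "snoRNA": "snoRNA",
    "piRNA": "piRNA",
    "other": "other_sRNA",
    "novel_mirna": "novel-truth",
}

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"
DEFAULT_PRIMER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
READ_LENGTH = 50
STAR_FRACTION = 0.10  # star-arm read abundance relative to the mature
JUNK_KINDS = ("no_adapter", "poly_a", "short_insert", "low_quality", "unmapped_insert")


def _default_length_weights() -> dict[int, float]:
    w = {
        17: 0.01, 18: 0.02, 19: 0.03, 20: 0.07, 21: 0.30, 22: 0.10,
        23: 0.08, 24: 0.25, 25: 0.05, 26: 0.03, 27: 0.02, 28: 0.01,
    }
    for length in range(29, 35):
        w[length] = 0.005
    return w


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_known_mirnas: int = 30
    n_novel_mirnas: int = 10
    n_other_loci: int = 20
    reads_per_library: int = 50_000
    adapter: str = DEFAULT_ADAPTER
    primer5: str = DEFAULT_PRIMER5
    insert_length_weights: dict[int, float] = field(default_factory=_default_length_weights)
    base_expression: dict[str, float] | None = None  # per-locus control mean
    fold_changes: dict[str, float] | None = None  # per-locus stress/control factor
    de_fraction: float = 0.3  # loci given a non-unit fold when fold_changes is None
    junk_fraction: float = 0.10
    noise: str = "poisson"
    contig_length: int | None = None  # optional cap; error if loci do not fit

    def __post_init__(self):
        total = sum(self.insert_length_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"insert length weights sum to {total}, expected 1")
        if self.fold_changes is not None and any(f <= 0 for f in self.fold_changes.values()):
            raise ValueError("fold changes must be strictly positive")
        if self.noise != "poisson":
            raise ValueError("only poisson noise is supported")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "insert_length_weights" in raw:
            raw["insert_length_weights"] = {int(k): float(v) for k, v in raw["insert_length_weights"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class SimLocus:
    locus_id: str
    category: str  # truth category (known_mirna | novel_mirna | rfam | snoRNA | piRNA | other)
    contig: str
    start: int  # mature span, 1-based inclusive
    end: int
    strand: str
    sequence: str  # mature sequence
    star_start: int | None = None  # star arm span for novel loci
    star_end: int | None = None

    @property
    def gff_class(self) -> str:
        return GFF_CLASS[self.category]


@dataclass
class SimReference:
    reference: dict[str, str]
    loci: list[SimLocus]


@dataclass
class SimLibraries:
    control_reads: list[RawRead]
    stress_reads: list[RawRead]
    truth: pd.DataFrame  # locus_id, category, true_counts_control, true_counts_stress, true_log2_fc


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))

def _draw_length(rng: np.random.Generator, weights: dict[int, float], lo: int | None = None, hi: int | None = None) -> int:
    items = [(L, w) for L, w in sorted(weights.items()) if (lo is None or L >= lo) and (hi is None or L <= hi)]
    lengths = np.array([L for L, _ in items])
    probs = np.array([w for _, w in items], dtype=float)
    probs /= probs.sum()
    return int(rng.choice(lengths, p=probs))


def generate_reference(config: SyntheticConfig) -> SimReference:
    """Build the contig, its locus cassettes and the category annotation.

    Known and decoy loci are random sequences dropped into spacer context;
    novel-miRNA cassettes are mature + 11 nt loop + reverse-complement arm,
    which folds back into a stem-loop.
    """
    rng = np.random.default_rng(config.seed)
    contig = "chr1"
    parts: list[str] = []
    loci: list[SimLocus] = []
    pos = 1  # 1-based cursor

    def emit(seq: str) -> int:
        nonlocal pos
        parts.append(seq)
        start = pos
        pos += len(seq)
        return start

    decoy_cats = ["rfam", "snoRNA", "other"]
    plan: list[tuple[str, str]] = []
    for i in range(config.n_known_mirnas):
        plan.append((f"known_mir{i + 1}", "known_mirna"))
    for i in range(config.n_other_loci):
        plan.append((f"decoy{i + 1}", decoy_cats[i % len(decoy_cats)]))
    for i in range(config.n_novel_mirnas):
        plan.append((f"novel{i + 1}", "novel_mirna"))

    for locus_id, category in plan:
        emit(_random_seq(rng, int(rng.integers(30, 50))))  # spacer
        if category == "novel_mirna":
            mature = _random_seq(rng, _draw_length(rng, config.insert_length_weights, 19, 25))
            loop = _random_seq(rng, 11)
            star_arm = str(Seq(mature).reverse_complement())
            m_start = emit(mature)
            emit(loop)
            s_start = emit(star_arm)
            loci.append(
                SimLocus(
                    locus_id=locus_id,
                    category=category,
                    contig=contig,
                    start=m_start,
                    end=m_start + len(mature) - 1,
                    strand="+",
                    sequence=mature,
                    star_start=s_start,
                    star_end=s_start + len(star_arm) - 1,
                )
            )
        else:
            lo, hi = (19, 25) if category == "known_mirna" else (None, None)
            seq = _random_seq(rng, _draw_length(rng, config.insert_length_weights, lo, hi))
            start = emit(seq)
            loci.append(
                SimLocus(
                    locus_id=locus_id,
                    category=category,
                    contig=contig,
                    start=start,
                    end=start + len(seq) - 1,
                    strand="+",
                    sequence=seq,
                )
            )
    emit(_random_seq(rng, 40))  # trailing spacer

    sequence = "".join(parts)
    if config.contig_length is not None:
        if len(sequence) > config.contig_length:
            raise ValueError(
                f"loci require {len(sequence)} nt but contig_length is {config.contig_length}"
            )
        sequence += _random_seq(rng, config.contig_length - len(sequence))
    return SimReference(reference={contig: sequence}, loci=loci)


def _expression_plan(config: SyntheticConfig, loci: list[SimLocus], rng: np.random.Generator):
    ids = [loc.locus_id for loc in loci]
    id_set = set(ids)
    if config.base_expression is not None:
        for key in config.base_expression:
            if key not in id_set:
                raise KeyError(f"base_expression refers to unknown locus {key!r}")
        means = {i: float(config.base_expression.get(i, 0.0)) for i in ids}
    else:
        raw = rng.lognormal(mean=0.0, sigma=1.2, size=len(ids))
        signal_budget = config.reads_per_library * (1.0 - config.junk_fraction)
        scale = signal_budget / raw.sum()
        means = {i: float(v * scale) for i, v in zip(ids, raw)}
    if config.fold_changes is not None:
        for key in config.fold_changes:
            if key not in id_set:
                raise KeyError(f"fold_changes refers to unknown locus {key!r}")
        folds = {i: float(config.fold_changes.get(i, 1.0)) for i in ids}
    else:
        folds = {}
        choices = np.array([0.125, 0.25, 4.0, 8.0])
        for i in ids:
            if rng.random() < config.de_fraction:
                folds[i] = float(rng.choice(choices))
            else:
                folds[i] = 1.0
    return means, folds


def _make_read(insert: str, adapter: str, read_id: str, quality_char: str = "I") -> RawRead:
    seq = (insert + adapter + "A" * READ_LENGTH)[:READ_LENGTH]
    return RawRead(id=read_id, sequence=seq, quality=quality_char * len(seq))


def _junk_read(rng: np.random.Generator, config: SyntheticConfig, read_id: str) -> RawRead:
    kind = JUNK_KINDS[int(rng.integers(0, len(JUNK_KINDS)))]
    if kind == "no_adapter":
        return RawRead(id=read_id, sequence=_random_seq(rng, READ_LENGTH), quality="I" * READ_LENGTH)
    if kind == "poly_a":
        return _make_read("A" * 25, config.adapter, read_id)
    if kind == "short_insert":
        return _make_read(_random_seq(rng, int(rng.integers(5, 18))), config.adapter, read_id)
    if kind == "unmapped_insert":
        # survives every cleaning filter but matches nothing in the reference
        return _make_read(_random_seq(rng, int(rng.integers(20, 25))), config.adapter, read_id)
    read = _make_read(_random_seq(rng, 21), config.adapter, read_id)
    read.quality = "#" * len(read.sequence)  # Phred 2: fails the quality floor
    return read


def _library_reads(
    loci: list[SimLocus],
    counts: dict[str, int],
    config: SyntheticConfig,
    rng: np.random.Generator,
    prefix: str,
) -> list[RawRead]:
    reads: list[RawRead] = []
    idx = 0
    for loc in loci:
        n = counts[loc.locus_id]
        for _ in range(n):
            idx += 1
            reads.append(_make_read(loc.sequence, config.adapter, f"{prefix}_{loc.locus_id}_{idx}"))
        if loc.category == "novel_mirna" and loc.star_start is not None:
            # star-arm reads: the Dicer partner, at low abundance
            n_star = int(rng.poisson(STAR_FRACTION * max(counts[loc.locus_id], 0)))
            for _ in range(n_star):
                idx += 1
                star = str(Seq(loc.sequence).reverse_complement())
                reads.append(_make_read(star, config.adapter, f"{prefix}_{loc.locus_id}_star_{idx}"))
    n_junk = int(rng.binomial(config.reads_per_library, config.junk_fraction))
    for _ in range(n_junk):
        idx += 1
        reads.append(_junk_read(rng, config, f"{prefix}_junk_{idx}"))
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def generate_libraries(config: SyntheticConfig, sim_ref: SimReference) -> SimLibraries:
    """Draw Poisson read counts per locus and materialise both libraries."""
    rng = np.random.default_rng(config.seed + 1)
    means, folds = _expression_plan(config, sim_ref.loci, rng)
    counts_c = {i: int(rng.poisson(means[i])) for i in means}
    counts_s = {i: int(rng.poisson(means[i] * folds[i])) for i in means}
    control = _library_reads(sim_ref.loci, counts_c, config, rng, "ctl")
    stress = _library_reads(sim_ref.loci, counts_s, config, rng, "str")
    truth = pd.DataFrame(
        {
            "locus_id": [loc.locus_id for loc in sim_ref.loci],
            "category": [loc.category for loc in sim_ref.loci],
            "true_counts_control": [counts_c[loc.locus_id] for loc in sim_ref.loci],
            "true_counts_stress": [counts_s[loc.locus_id] for loc in sim_ref.loci],
            "true_log2_fc": [math.log2(folds[loc.locus_id]) for loc in sim_ref.loci],
        }
    )
    return SimLibraries(control_reads=control, stress_reads=stress, truth=truth)


@dataclass
class TargetUniverse:
    """Synthetic transcriptome plus flat GO/KEGG annotation maps.

    One transcript per miRNA locus embeds the exact reverse complement of the
    mature sequence (a perfect plant-style target site); background genes
    carry no site.  Annotation terms are assigned at random so that null
    enrichment behaves like a flat background.
    """

    transcripts: dict[str, str]
    gene_go: dict[str, list[tuple[str, str, str]]]
    gene_kegg: dict[str, list[tuple[str, str, str]]]


def generate_target_universe(
    config: SyntheticConfig,
    sim_ref: SimReference,
    n_background_genes: int = 60,
    n_go_terms: int = 15,
    n_kegg_pathways: int = 8,
) -> TargetUniverse:
    rng = np.random.default_rng(config.seed + 2)
    transcripts: dict[str, str] = {}
    mirna_loci = [l for l in sim_ref.loci if l.category in ("known_mirna", "novel_mirna")]
    for loc in mirna_loci:
        site = str(Seq(loc.sequence).reverse_complement())
        left = _random_seq(rng, int(rng.integers(40, 120)))
        right = _random_seq(rng, int(rng.integers(40, 120)))
        transcripts[f"gene_{loc.locus_id}"] = left + site + right
    for i in range(n_background_genes):
        transcripts[f"gene_bg{i + 1}"] = _random_seq(rng, int(rng.integers(120, 260)))

    namespaces = ["biological_process", "molecular_function", "cellular_component"]
    go_terms = [
        (f"GO:{7000000 + i}", f"synthetic process {i}", namespaces[i % 3])
        for i in range(n_go_terms)
    ]
    kegg_terms = [
        (f"ko{10 + i:05d}", f"synthetic pathway {i}", "Metabolism")
        for i in range(n_kegg_pathways)
    ]
    gene_go: dict[str, list[tuple[str, str, str]]] = {}
    gene_kegg: dict[str, list[tuple[str, str, str]]] = {}
    for gene in transcripts:
        k = int(rng.integers(1, 4))
        picks = rng.choice(len(go_terms), size=k, replace=False)
        gene_go[gene] = [go_terms[j] for j in picks]
        picks = rng.choice(len(kegg_terms), size=int(rng.integers(1, 3)), replace=False)
        gene_kegg[gene] = [kegg_terms[j] for j in picks]
    return TargetUniverse(transcripts=transcripts, gene_go=gene_go, gene_kegg=gene_kegg)


def write_fasta(reference: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(loci: Iterable[SimLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            fh.write(
                f"{loc.contig}\tsaltmir-sim\tncRNA\t{loc.start}\t{loc.end}\t.\t{loc.strand}\t.\t"
                f"ID={loc.locus_id};sRNA_class={loc.gff_class}\n"
            )


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{read.quality}\n")


def simulate_to_dir(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full simulation and write reference, annotation, FASTQs, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_ref = generate_reference(config)
    libs = generate_libraries(config, sim_ref)
    paths = {
        "reference": outdir / "reference.fa",
        "annotation": outdir / "annotation.gff3",
        "control_fastq": outdir / "control.fastq",
        "stress_fastq": outdir / "stress.fastq",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(sim_ref.reference, paths["reference"])
    write_gff3(sim_ref.loci, paths["annotation"])
    write_fastq(libs.control_reads, paths["control_fastq"])
    write_fastq(libs.stress_reads, paths["stress_fastq"])
    libs.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
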