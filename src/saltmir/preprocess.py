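"""Raw-read cleaning, tag collapsing and library-level summaries.

Single-end 50 nt small-RNA reads carry the insert followed by a 3' adapter.
Cleaning applies, in order: a mean-quality floor, a 3' adapter requirement
(the insert is everything before the first match of the adapter's leading
bases), a 5'-contaminant check, removal of empty and poly-A inserts, and a
length window.  Survivors are collapsed to unique insert sequences ("tags")
with per-library counts, the pipeline's atomic unit.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "RawRead",
    "SmallRNATag",
    "CleanResult",
    "LibrarySummary",
    "read_fastq",
    "clean_reads",
    "length_distribution",
    "summarize_library",
    "write_tag_fasta",
    "write_tag_tsv",
]

ADAPTER_SEED_LEN = 8
DEFAULT_QUALITY_FLOOR = 20.0
POLY_A_FRACTION = 0.80

REJECTION_RULES = (
    "low_quality",
    "no_3p_adapter",
    "5p_contaminant",
    "empty_insert",
    "poly_a",
    "length_out_of_range",
)


@dataclass
class RawRead:
    id: str
    sequence: str
    quality: str

    def mean_phred(self) -> float:
        return sum(ord(c) - 33 for c in self.quality) / len(self.quality)


@dataclass(frozen=True)
class SmallRNATag:
    """A unique clean insert sequence with its per-library count."""

    sequence: str
    count: int


@dataclass
class CleanResult:
    tags: list[SmallRNATag]
    rejections: dict[str, int]
    # insert lengths observed before the length filter, for the
    # length-distribution figure (wider axis than the analysis window)
    pre_filter_lengths: Counter = field(default_factory=Counter)

    @property
    def clean_read_total(self) -> int:
        return sum(t.count for t in self.tags)


@dataclass
class LibrarySummary:
    raw_tag_count: int
    clean_tag_count: int
    clean_percent: float
    mapped_tag_count: int
    mapped_percent: float


def _round2(x: float) -> float:
    """Round half away from zero to 2 decimals, as printed summary tables do."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream reads from a FASTQ file (optionally gzip-compressed)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield RawRead(id=rec.id, sequence=str(rec.seq).upper(), quality=qual)


def clean_reads(
    reads: Iterable[RawRead],
    adapter: str,
    quality_floor: float = DEFAULT_QUALITY_FLOOR,
    min_len: int = 18,
    max_len: int = 28,
    poly_a_fraction: float = POLY_A_FRACTION,
    primer5: str | None = None,
) -> CleanResult:
    """Filter raw reads and collapse surviving inserts into counted tags.

    Adapter detection is an exact substring match of the 3' adapter's first
    ``ADAPTER_SEED_LEN`` bases; the insert is everything before the first
    match; no mismatches are tolerated.  When a 5' primer sequence is given,
    inserts beginning with its leading bases are rejected as 5' contaminants.
    The per-rule rejection tallies plus the clean read total always sum to
    the input size.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    seed = adapter[: ADAPTER_SEED_LEN]
    p5_seed = primer5[: ADAPTER_SEED_LEN] if primer5 else None
    rejections = {rule: 0 for rule in REJECTION_RULES}
    survivors: Counter = Counter()
    pre_filter_lengths: Counter = Counter()

    for read in reads:
        if read.mean_phred() < quality_floor:
            rejections["low_quality"] += 1
            continue
        pos = read.sequence.find(seed)
        if pos == -1:
            rejections["no_3p_adapter"] += 1
            continue
        insert = read.sequence[:pos]
        if p5_seed and insert.startswith(p5_seed):
            rejections["5p_contaminant"] += 1
            continue
        if not insert:
            rejections["empty_insert"] += 1
            continue
        if insert.count("A") / len(insert) >= poly_a_fraction:
            rejections["poly_a"] += 1
            continue
        pre_filter_lengths[len(insert)] += 1
        if not (min_len <= len(insert) <= max_len):
            rejections["length_out_of_range"] += 1
            continue
        survivors[insert] += 1

    tags = [SmallRNATag(seq, n) for seq, n in sorted(survivors.items())]
    return CleanResult(tags=tags, rejections=rejections, pre_filter_lengths=pre_filter_lengths)


def length_distribution(
    tags: Iterable[SmallRNATag], lo: int = 16, hi: int = 36
) -> tuple[dict[int, int], dict[int, int]]:
    """Per-length totals and unique-tag counts over [lo, hi].

    Lengths outside the window are accumulated under the key -1 (overflow bin)
    so that the returned counts always partition the input.
    """
    total = {length: 0 for length in range(lo, hi + 1)}
    unique = {length: 0 for length in range(lo, hi + 1)}
    total[-1] = 0
    unique[-1] = 0
    for tag in tags:
        key = len(tag.sequence) if lo <= len(tag.sequence) <= hi else -1
        total[key] += tag.count
        unique[key] += 1
    return total, unique


def summarize_library(raw_n: int, clean_n: int, mapped_n: int) -> LibrarySummary:
    """Library-level sequencing summary with percentages at 2 decimals."""
    if raw_n <= 0:
        raise ValueError("raw read count must be positive")
    if not (0 <= mapped_n <= clean_n <= raw_n):
        raise ValueError("expected 0 <= mapped <= clean <= raw")
    return LibrarySummary(
        raw_tag_count=raw_n,
        clean_tag_count=clean_n,
        clean_percent=_round2(100.0 * clean_n / raw_n),
        mapped_tag_count=mapped_n,
        mapped_percent=_round2(100.0 * mapped_n / clean_n),
    )


def write_tag_fasta(tags: Iterable[SmallRNATag], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            fh.write(f">tag{i}_x{tag.count}\n{tag.sequence}\n")


def write_tag_tsv(tags: Iterable[SmallRNATag], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for tag in tags:
            fh.write(f"{tag.sequence}\t{tag.count}\n")
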