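"""Mapping clean tags to the reference and resolving sRNA categories.

A tag hits an annotated locus when it aligns inside the locus span, on either
strand, with at most ``max_mismatch`` substitutions (no indels).  Tags hitting
several categories are resolved to a single one by the fixed priority

    miRNA > piRNA > snoRNA > Rfam > other_sRNA

so that every unique sRNA is counted in exactly one category; tags with no
hits are "unannotated".  The mapped-tag total counts reads (tag counts) whose
sequence matches the reference exactly anywhere, on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .preprocess import SmallRNATag

__all__ = [
    "CATEGORY_PRIORITY",
    "UNANNOTATED",
    "AnnotationRecord",
    "AnnotatedTag",
    "read_reference_fasta",
    "read_annotation_gff3",
    "write_annotation_gff3",
    "map_tags",
    "resolve_category",
    "category_summary",
]

# Priority rank: lower rank wins when a tag hits multiple categories.
CATEGORY_PRIORITY = {"miRNA": 0, "piRNA": 1, "snoRNA": 2, "Rfam": 3, "other_sRNA": 4}
UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class AnnotationRecord:
    locus_id: str
    category: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    sequence: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"locus {self.locus_id}: start > end")
        if self.category not in CATEGORY_PRIORITY:
            raise ValueError(f"locus {self.locus_id}: unknown category {self.category!r}")


@dataclass
class AnnotatedTag:
    tag: SmallRNATag
    hits: list[tuple[str, str, int]]  # (locus_id, category, mismatches)
    resolved_category: str
    genome_mapped: bool = False
    best_locus: str | None = None

    @property
    def best_hit(self) -> tuple[str, str, int] | None:
        if not self.hits:
            return None
        return min(self.hits, key=lambda h: (h[2], CATEGORY_PRIORITY[h[1]], h[0]))


def read_reference_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _parse_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for part in attr_field.strip().split(";"):
        if part and "=" in part:
            key, val = part.split("=", 1)
            out[key] = val
    return out


def read_annotation_gff3(path: str | Path, reference: dict[str, str]) -> list[AnnotationRecord]:
    """Load locus annotations from GFF3; category comes from ``sRNA_class=``.

    Records whose class is not one of the five mapping categories (e.g. the
    simulator's ground-truth novel loci) are skipped here; they are not part
    of the known-annotation set.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _source, _type, start, end, _score, strand, _phase, attrs = cols
            attributes = _parse_attributes(attrs)
            category = attributes.get("sRNA_class", "")
            if category not in CATEGORY_PRIORITY:
                continue
            start_i, end_i = int(start), int(end)
            seq = reference[contig][start_i - 1 : end_i]
            if strand == "-":
                seq = str(Seq(seq).reverse_complement())
            records.append(
                AnnotationRecord(
                    locus_id=attributes.get("ID", f"{contig}:{start}-{end}"),
                    category=category,
                    contig=contig,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    sequence=seq,
                )
            )
    return records


def write_annotation_gff3(records: Iterable, path: str | Path) -> None:
    """Write locus records (any object with the AnnotationRecord fields)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write(
                f"{rec.contig}\tsaltmir\tncRNA\t{rec.start}\t{rec.end}\t.\t{rec.strand}\t.\t"
                f"ID={rec.locus_id};sRNA_class={rec.category}\n"
            )


def resolve_category(hits: Sequence[tuple[str, str, int]] | Sequence[str]) -> str:
    """Highest-priority category among the hits; empty input -> unannotated."""
    categories = [h[1] if isinstance(h, tuple) else h for h in hits]
    for cat in categories:
        if cat not in CATEGORY_PRIORITY:
            raise ValueError(f"unknown category label: {cat!r}")
    if not categories:
        return UNANNOTATED
    return min(categories, key=lambda c: CATEGORY_PRIORITY[c])


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _genome_index(reference: dict[str, str], lengths: set[int]) -> set[str]:
    """All substrings of the reference (both strands) at the given lengths."""
    windows: set[str] = set()
    for contig_seq in reference.values():
        rc = str(Seq(contig_seq).reverse_complement())
        for strand_seq in (contig_seq, rc):
            for length in lengths:
                for i in range(len(strand_seq) - length + 1):
                    windows.add(strand_seq[i : i + length])
    return windows


def map_tags(
    tags: Sequence[SmallRNATag],
    reference: dict[str, str],
    annotations: Sequence[AnnotationRecord],
    max_mismatch: int = 0,
) -> tuple[list[AnnotatedTag], int]:
    """Assign tags to annotated loci and count genome-mapped reads.

    Locus hits allow up to ``max_mismatch`` substitutions against the locus
    sequence (either orientation, any offset inside the span); genome mapping
    for the Table-1-style mapped total is exact-match only.  Returns the
    annotated tags and the mapped read total (weighted by tag count).
    """
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")

    lengths = {len(t.sequence) for t in tags}
    index = _genome_index(reference, lengths) if lengths else set()

    # group tags by length for vectorised mismatch counting against each locus
    by_length: dict[int, list[int]] = {}
    for i, t in enumerate(tags):
        by_length.setdefault(len(t.sequence), []).append(i)
    encoded = {
        L: np.vstack([_encode(tags[i].sequence) for i in idx])
        for L, idx in by_length.items()
    }

    hits_per_tag: list[list[tuple[str, str, int]]] = [[] for _ in tags]
    for ann in annotations:
        fwd = ann.sequence
        rc = str(Seq(fwd).reverse_complement())
        locus_len = len(fwd)
        for L, idx in by_length.items():
            if L > locus_len:
                continue
            arr = encoded[L]
            best = np.full(len(idx), np.iinfo(np.int32).max, dtype=np.int32)
            for oriented in (fwd, rc):
                ref_arr = _encode(oriented)
                for off in range(locus_len - L + 1):
                    mm = (arr != ref_arr[off : off + L]).sum(axis=1)
                    np.minimum(best, mm.astype(np.int32), out=best)
            for j, tag_i in enumerate(idx):
                if best[j] <= max_mismatch:
                    hits_per_tag[tag_i].append((ann.locus_id, ann.category, int(best[j])))

    annotated = []
    mapped_total = 0
    for i, tag in enumerate(tags):
        hits = hits_per_tag[i]
        mapped = tag.sequence in index
        if mapped:
            mapped_total += tag.count
        at = AnnotatedTag(
            tag=tag,
            hits=hits,
            resolved_category=resolve_category(hits),
            genome_mapped=mapped,
        )
        bh = at.best_hit
        at.best_locus = bh[0] if bh else None
        annotated.append(at)
    return annotated, mapped_total


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def category_summary(
    annotated: Sequence[AnnotatedTag], clean_total: int
) -> list[dict[str, object]]:
    """Per-category read counts and percentages of the clean-read total."""
    counts: dict[str, int] = {cat: 0 for cat in CATEGORY_PRIORITY}
    counts[UNANNOTATED] = 0
    for at in annotated:
        counts[at.resolved_category] += at.tag.count
    total_assigned = sum(counts.values())
    if clean_total < total_assigned:
        raise ValueError("clean_total smaller than the sum of tag counts")
    return [
        {"category": cat, "count": n, "percent": _round2(100.0 * n / clean_total)}
        for cat, n in counts.items()
    ]
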