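"""Novel miRNA calling by precursor excision and hairpin folding.

A genuine miRNA precursor folds back on itself: the mature sequence sits on
one arm of a stem-loop and pairs with the opposite arm.  For each abundant
unannotated tag with a genomic position, a window of the tag plus flanking
sequence is excised and folded with a weighted base-pair-maximisation dynamic
program (G-C = 3, A-T = 2, G-U wobble = 1, no pseudoknots, hairpin loops of
at least ``min_loop`` bases).  The fold stands in for a thermodynamic model:
the weighted score per base is an energy proxy, and the structural criteria
(well-paired window, mature almost fully paired, mature confined to one arm)
mirror what a precursor-prediction tool checks.

siRNA duplex candidates are found from the Dicer signature instead: two
22-24 nt tags on opposite strands whose alignment leaves a 2-nt 3' overhang
on each strand.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from Bio.Seq import Seq

from .preprocess import SmallRNATag

__all__ = [
    "FoldResult",
    "HairpinCandidate",
    "SiRNACandidate",
    "TagLocation",
    "fold_max_pairing",
    "brute_force_fold",
    "locate_tags",
    "call_novel_mirnas",
    "call_sirna_pairs",
    "dinucleotide_shuffle",
]

# pair weights indexed by base codes A=0, C=1, G=2, T=3
_WEIGHTS = np.zeros((4, 4), dtype=np.int32)
_WEIGHTS[2, 1] = _WEIGHTS[1, 2] = 3  # G-C
_WEIGHTS[0, 3] = _WEIGHTS[3, 0] = 2  # A-T
_WEIGHTS[2, 3] = _WEIGHTS[3, 2] = 1  # G-U wobble
_WEIGHTS_WC = _WEIGHTS.copy()
_WEIGHTS_WC[2, 3] = _WEIGHTS_WC[3, 2] = 0
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

DEFAULT_MIN_LOOP = 3
DEFAULT_WINDOW_FLANK = 80
DEFAULT_MIN_COUNT = 5
DEFAULT_PAIRED_FRACTION = 0.55
DEFAULT_MIN_MATURE_PAIRED = 16
DEFAULT_MAX_MATURE_SELF_BASES = 2
DEFAULT_MIN_SCORE_DENSITY = 0.85
HELIX_SPAN_TOLERANCE = 6  # bulge allowance when clustering mature partners


@dataclass
class FoldResult:
    sequence: str
    dot_bracket: str
    pairs: list[tuple[int, int]]
    score: int

    @property
    def pair_count(self) -> int:
        return len(self.pairs)

    @property
    def paired_fraction(self) -> float:
        return 2 * len(self.pairs) / len(self.sequence) if self.sequence else 0.0

    def partner_map(self) -> dict[int, int]:
        out = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


@dataclass
class TagLocation:
    tag: SmallRNATag
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str


@dataclass
class HairpinCandidate:
    contig: str
    window_start: int
    window_end: int
    strand: str
    sequence: str
    fold: str
    paired_fraction: float
    score_density: float
    mature_tag: SmallRNATag
    mature_arm: str  # "5p" or "3p"
    mature_paired_bases: int
    mature_self_paired_bases: int
    star_support: bool
    verdict: bool


@dataclass
class SiRNACandidate:
    tag_a: TagLocation  # plus strand
    tag_b: TagLocation  # minus strand
    overhang_check: bool = True


@njit(cache=True)
def _fill(codes, weights, min_loop):  # pragma: no cover - exercised via wrapper
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            best = 0
            w = weights[codes[i], codes[j]]
            if w > 0 and j - i - 1 >= min_loop:
                inner = dp[i + 1, j - 1] if i + 1 <= j - 1 else 0
                best = w + inner
            for k in range(i, j):
                right = dp[k + 1, j] if k + 1 <= j else 0
                cand = dp[i, k] + right
                if cand > best:
                    best = cand
            dp[i, j] = best
    return dp


def _traceback(dp, codes, min_loop, pairs, weights):
    """Deterministic traceback: pairing (i,j) wins ties, then smallest split."""
    stack = [(0, codes.shape[0] - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or dp[i, j] == 0:
            continue
        w = weights[codes[i], codes[j]]
        inner = dp[i + 1, j - 1] if i + 1 <= j - 1 else 0
        if w > 0 and j - i - 1 >= min_loop and dp[i, j] == w + inner:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            right = dp[k + 1, j] if k + 1 <= j else 0
            if dp[i, k] + right == dp[i, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break


def fold_max_pairing(seq: str, min_loop: int = DEFAULT_MIN_LOOP, wobble: bool = True) -> FoldResult:
    """Fold by weighted base-pair maximisation (Nussinov-style DP).

    Maximises the total pair weight over all non-crossing pairings whose
    hairpin loops span at least ``min_loop`` unpaired bases.  ``wobble=False``
    restricts pairing to Watson-Crick (G-C, A-T) only.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    if min_loop < 3:
        raise ValueError("min_loop must be at least 3")
    try:
        codes = np.array([_CODE[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character in sequence: {exc}") from None
    weights = _WEIGHTS if wobble else _WEIGHTS_WC
    dp = _fill(codes, weights, min_loop)
    pairs: list[tuple[int, int]] = []
    _traceback(dp, codes, min_loop, pairs, weights)
    pairs.sort()
    structure = ["."] * len(seq)
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    return FoldResult(
        sequence=seq.upper(),
        dot_bracket="".join(structure),
        pairs=pairs,
        score=int(dp[0, len(seq) - 1]) if len(seq) > 1 else 0,
    )


def brute_force_fold(seq: str, min_loop: int = DEFAULT_MIN_LOOP, wobble: bool = True) -> int:
    """Exhaustive maximum over all non-crossing pairings (oracle, len <= ~14)."""
    seq = seq.upper()
    n = len(seq)
    weights = _WEIGHTS if wobble else _WEIGHTS_WC

    def best(i: int, j: int) -> int:
        if i >= j:
            return 0
        # enumerate the fate of base i: unpaired, or paired with some j'
        score = best(i + 1, j)
        for jp in range(i + min_loop + 1, j + 1):
            w = weights[_CODE[seq[i]], _CODE[seq[jp]]]
            if w > 0:
                score = max(score, w + best(i + 1, jp - 1) + best(jp + 1, j))
        return score

    return best(0, n - 1)


def locate_tags(tags: Sequence[SmallRNATag], reference: dict[str, str]) -> list[TagLocation]:
    """First exact genomic occurrence of each tag (plus strand preferred)."""
    out = []
    for tag in tags:
        placed = False
        for contig, seq in reference.items():
            pos = seq.find(tag.sequence)
            if pos != -1:
                out.append(TagLocation(tag, contig, pos + 1, pos + len(tag.sequence), "+"))
                placed = True
                break
            rc = str(Seq(tag.sequence).reverse_complement())
            pos = seq.find(rc)
            if pos != -1:
                out.append(TagLocation(tag, contig, pos + 1, pos + len(tag.sequence), "-"))
                placed = True
                break
        if not placed:
            continue
    return out


def _evaluate_window(
    window_seq: str,
    mature_offset: int,
    mature_len: int,
    min_loop: int,
    paired_fraction_min: float,
    min_mature_paired: int,
    max_mature_self_bases: int,
    min_score_density: float,
) -> tuple[FoldResult, bool, str, int, int, float]:
    """Fold the window and test the mature against the hairpin criteria.

    The "one arm" condition is enforced as helix compactness: the mature must
    pair into partners lying within a single interval of width
    mature_len + HELIX_SPAN_TOLERANCE outside the mature (one contiguous
    opposite-arm helix, allowing small bulges).  The required duplex extent
    scales with mature length — at least max(min_mature_paired,
    ceil(0.85 * mature_len)) bases in the helix — and at most
    max(max_mature_self_bases, 0.15 * mature_len) mature bases may pair
    anywhere else (within the mature itself or to stray positions).
    """
    fold = fold_max_pairing(window_seq, min_loop=min_loop)
    partners = fold.partner_map()
    m_lo, m_hi = mature_offset, mature_offset + mature_len - 1
    outside: list[int] = []
    self_paired = 0
    for i in range(m_lo, m_hi + 1):
        j = partners.get(i)
        if j is None:
            continue
        if m_lo <= j <= m_hi:
            self_paired += 1
        else:
            outside.append(j)
    outside.sort()
    helix_paired = 0
    helix_lo = 0
    width = mature_len + HELIX_SPAN_TOLERANCE
    for a in range(len(outside)):
        b = a
        while b < len(outside) and outside[b] - outside[a] < width:
            b += 1
        if b - a > helix_paired:
            helix_paired = b - a
            helix_lo = a
    stray = len(outside) + self_paired - helix_paired
    mature_paired = len(outside) + self_paired
    density = fold.score / len(window_seq)
    if helix_paired:
        helix_mid = outside[helix_lo + helix_paired // 2]
        arm = "5p" if helix_mid > m_hi else "3p"
    else:
        arm = "5p"
    need_paired = max(min_mature_paired, math.ceil(0.85 * mature_len))
    stray_allowance = max(max_mature_self_bases, int(0.15 * mature_len))
    verdict = (
        fold.paired_fraction >= paired_fraction_min
        and helix_paired >= need_paired
        and stray <= stray_allowance
        and density >= min_score_density
    )
    return fold, verdict, arm, mature_paired, self_paired, density


def call_novel_mirnas(
    tag_locations: Sequence[TagLocation],
    reference: dict[str, str],
    window_flank: int = DEFAULT_WINDOW_FLANK,
    min_count: int = DEFAULT_MIN_COUNT,
    min_loop: int = DEFAULT_MIN_LOOP,
    paired_fraction_min: float = DEFAULT_PAIRED_FRACTION,
    min_mature_paired: int = DEFAULT_MIN_MATURE_PAIRED,
    max_mature_self_bases: int = DEFAULT_MAX_MATURE_SELF_BASES,
    min_score_density: float = DEFAULT_MIN_SCORE_DENSITY,
) -> list[HairpinCandidate]:
    """Fold a flanked window around each abundant unannotated tag.

    The verdict is positive when the window is well paired overall, at least
    ``min_mature_paired`` mature bases are paired, the mature pairs with the
    opposite arm rather than itself (at most ``max_mature_self_bases`` bases
    of self-pairing), and the weighted score per base clears the
    energy-proxy threshold.  Windows are clipped at contig ends.
    """
    candidates = []
    for loc in tag_locations:
        if loc.tag.count < min_count:
            continue
        contig_seq = reference[loc.contig]
        w_start = max(1, loc.start - window_flank)
        w_end = min(len(contig_seq), loc.end + window_flank)
        window = contig_seq[w_start - 1 : w_end]
        offset = loc.start - w_start
        if loc.strand == "-":
            window = str(Seq(window).reverse_complement())
            offset = w_end - loc.end
        fold, verdict, arm, mature_paired, self_paired, density = _evaluate_window(
            window,
            offset,
            len(loc.tag.sequence),
            min_loop,
            paired_fraction_min,
            min_mature_paired,
            max_mature_self_bases,
            min_score_density,
        )
        star = _star_support(loc, fold, offset, tag_locations, w_start, w_end)
        candidates.append(
            HairpinCandidate(
                contig=loc.contig,
                window_start=w_start,
                window_end=w_end,
                strand=loc.strand,
                sequence=window,
                fold=fold.dot_bracket,
                paired_fraction=fold.paired_fraction,
                score_density=density,
                mature_tag=loc.tag,
                mature_arm=arm,
                mature_paired_bases=mature_paired,
                mature_self_paired_bases=self_paired,
                star_support=star,
                verdict=verdict,
            )
        )
    return candidates


def _star_support(
    loc: TagLocation,
    fold: FoldResult,
    mature_offset: int,
    all_locations: Sequence[TagLocation],
    w_start: int,
    w_end: int,
) -> bool:
    """Another tag covering the mature's pairing partners (simplified star check)."""
    m_len = len(loc.tag.sequence)
    partners = fold.partner_map()
    partner_idx = {
        partners[i]
        for i in range(mature_offset, mature_offset + m_len)
        if i in partners and not (mature_offset <= partners[i] < mature_offset + m_len)
    }
    if not partner_idx:
        return False
    for other in all_locations:
        if other is loc or other.contig != loc.contig:
            continue
        if other.start < w_start or other.end > w_end:
            continue
        if other.start == loc.start and other.end == loc.end:
            continue
        if loc.strand == "+":
            span = set(range(other.start - w_start, other.end - w_start + 1))
        else:
            span = set(range(w_end - other.end, w_end - other.start + 1))
        if len(span & partner_idx) >= max(1, len(partner_idx) - 4):
            return True
    return False


def call_sirna_pairs(tag_locations: Sequence[TagLocation]) -> list[SiRNACandidate]:
    """Dicer-signature duplexes: opposite-strand 22-24 nt tags with 2-nt 3' overhangs.

    For a plus-strand tag spanning [s1, e1] and a minus-strand tag spanning
    [s2, e2] the overhang condition is s1 - s2 = 2 and e1 - e2 = 2.
    """
    plus = [t for t in tag_locations if t.strand == "+" and 22 <= len(t.tag.sequence) <= 24]
    minus = [t for t in tag_locations if t.strand == "-" and 22 <= len(t.tag.sequence) <= 24]
    by_contig: dict[str, list[TagLocation]] = {}
    for m in minus:
        by_contig.setdefault(m.contig, []).append(m)
    out = []
    for p in plus:
        for m in by_contig.get(p.contig, []):
            if p.start - m.start == 2 and p.end - m.end == 2:
                out.append(SiRNACandidate(tag_a=p, tag_b=m))
    return out


def dinucleotide_shuffle(seq: str, rng: random.Random) -> str:
    """Shuffle preserving dinucleotide counts (Altschul-Erickson Euler walk)."""
    seq = seq.upper()
    if len(seq) <= 2:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    for _ in range(200):
        trial = {a: lst[:] for a, lst in edges.items()}
        # pick a random terminal edge for each non-final vertex, check the
        # terminal edges form a tree into the final vertex (Euler condition)
        terminal: dict[str, str] = {}
        ok = True
        for a in trial:
            if a == last:
                continue
            terminal[a] = rng.choice(trial[a])
        for a in terminal:
            seen = {a}
            cur = a
            while cur != last:
                cur = terminal.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if not ok:
            continue
        for a, b in terminal.items():
            trial[a].remove(b)
        for a in trial:
            rng.shuffle(trial[a])
        for a, b in terminal.items():
            trial[a].append(b)
        out = [seq[0]]
        cur = seq[0]
        while trial.get(cur):
            nxt = trial[cur].pop(0)
            out.append(nxt)
            cur = nxt
        if len(out) == len(seq):
            return "".join(out)
    return "".join(rng.sample(seq, len(seq)))  # fallback: plain shuffle
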