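"""miRNA target prediction and GO/KEGG over-representation analysis.

Plant miRNAs recognise targets by near-perfect complementarity, so target
prediction here is a penalty-scored reverse-complement scan: each candidate
site is compared position-by-position against the miRNA, mismatches cost 1,
G:U wobbles 0.5, and costs double inside the functionally critical positions
2-13 from the miRNA 5' end; sites at or below the cutoff are reported.

Enrichment asks whether the target genes of the differentially expressed
sRNAs over-represent an annotation term.  With N annotated genes, n of them
targets, M genes carrying the term and m targets among those, the p-value is
the upper hypergeometric tail P(X >= m), Bonferroni-corrected over the tested
terms.  GO terms and KEGG pathways run through the identical machinery; only
the gene->term map differs.  Term maps are taken as flat annotations (no
ontology-graph propagation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.special import gammaln

__all__ = [
    "TargetAssignment",
    "EnrichmentInput",
    "EnrichmentResult",
    "predict_targets",
    "hypergeom_p",
    "enrich",
]

SEED_REGION = range(2, 14)  # miRNA positions 2..13, 1-based from the 5' end
DEFAULT_TARGET_CUTOFF = 4.0
DEFAULT_ALPHA = 0.05

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class TargetAssignment:
    mirna_id: str
    gene_id: str
    penalty_score: float
    site_start: int  # 0-based offset of the site in the transcript


@dataclass(frozen=True)
class EnrichmentInput:
    N: int  # genes with annotation
    n: int  # target genes among N
    M: int  # genes carrying the term
    m: int  # target genes carrying the term

    def __post_init__(self):
        if not (0 <= self.m <= min(self.n, self.M) and self.n <= self.N and self.M <= self.N):
            raise ValueError(f"inconsistent enrichment counts: {self}")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    namespace: str
    m: int
    M: int
    p_value: float
    p_corrected: float
    significant: bool


def _site_penalty(mirna: str, site: str) -> float:
    """Penalty of a candidate site (same length as the miRNA).

    ``site`` is read 5'->3' on the transcript; its 3' end pairs the miRNA's
    5' end, so transcript position i faces miRNA position L - i (1-based).
    """
    L = len(mirna)
    penalty = 0.0
    for i in range(L):
        p = L - i  # miRNA position, 1-based from 5' end
        m_base = mirna[p - 1]
        t_base = site[i]
        if t_base == _COMPLEMENT[m_base]:
            cost = 0.0
        elif {m_base, t_base} == {"G", "T"}:
            cost = 0.5
        else:
            cost = 1.0
        if p in SEED_REGION:
            cost *= 2.0
        penalty += cost
    return penalty


def predict_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    cutoff: float = DEFAULT_TARGET_CUTOFF,
) -> list[TargetAssignment]:
    """Scan every transcript for complementary sites of every miRNA.

    Emits the best (lowest-penalty) site per miRNA/transcript pair when its
    penalty is at or below ``cutoff``.  No indels are considered.
    """
    if not mirnas or not transcripts:
        raise ValueError("mirnas and transcripts must be non-empty")
    out = []
    for mid, mseq in mirnas.items():
        mseq = mseq.upper()
        L = len(mseq)
        for gid, tseq in transcripts.items():
            tseq = tseq.upper()
            best: tuple[float, int] | None = None
            for w in range(len(tseq) - L + 1):
                pen = _site_penalty(mseq, tseq[w : w + L])
                if best is None or pen < best[0]:
                    best = (pen, w)
            if best is not None and best[0] <= cutoff:
                out.append(TargetAssignment(mid, gid, best[0], best[1]))
    return out


def _log_binom(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_p(inp: EnrichmentInput) -> float:
    """Upper-tail hypergeometric p-value P(X >= m), exact in log space.

    Equals 1 - sum_{i=0}^{m-1} C(M,i) C(N-M,n-i) / C(N,n); computed by
    summing the upper tail directly for numerical stability.
    """
    N, n, M, m = inp.N, inp.n, inp.M, inp.m
    if m == 0:
        return 1.0
    log_denom = _log_binom(N, n)
    hi = min(n, M)
    total = 0.0
    for i in range(m, hi + 1):
        if n - i > N - M:
            continue
        total += math.exp(_log_binom(M, i) + _log_binom(N - M, n - i) - log_denom)
    return min(total, 1.0)


def enrich(
    gene_terms: Mapping[str, Iterable[tuple[str, str, str]]],
    background: Iterable[str],
    targets: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    full_report: bool = False,
) -> list[EnrichmentResult]:
    """Term over-representation among target genes.

    ``gene_terms`` maps gene -> iterable of (term_id, term_name, namespace).
    Terms with no target gene enter the output only when ``full_report`` is
    set (with p = 1) and never count toward the Bonferroni denominator.
    """
    background = set(background)
    if not background:
        raise ValueError("background gene set is empty")
    targets = set(targets)
    if not targets <= background:
        raise ValueError("target set must be a subset of the background")

    term_genes: dict[str, set[str]] = {}
    term_meta: dict[str, tuple[str, str]] = {}
    for gene, terms in gene_terms.items():
        if gene not in background:
            continue
        for term_id, term_name, namespace in terms:
            term_genes.setdefault(term_id, set()).add(gene)
            term_meta[term_id] = (term_name, namespace)

    N = len(background)
    n = len(targets)
    tested = {t for t, genes in term_genes.items() if genes & targets}
    n_tested = len(tested)

    results = []
    for term_id in sorted(term_genes):
        genes = term_genes[term_id]
        M = len(genes)
        m = len(genes & targets)
        if m == 0 and not full_report:
            continue
        if m == 0:
            p = 1.0
            p_corr = 1.0
        else:
            p = hypergeom_p(EnrichmentInput(N=N, n=n, M=M, m=m))
            p_corr = min(1.0, p * n_tested)
        name, ns = term_meta[term_id]
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=name,
                namespace=ns,
                m=m,
                M=M,
                p_value=p,
                p_corrected=p_corr,
                significant=(m > 0 and p_corr <= alpha),
            )
        )
    results.sort(key=lambda r: (r.p_corrected, r.term_id))
    return results
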