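"""Digital differential expression between two small-RNA libraries.

The design has one pooled library per condition, so significance cannot come
from replicate variance.  Instead each tag count is modelled as Poisson: if an
sRNA contributes ``x`` tags among ``N1`` clean tags in library 1 and ``y`` tags
among ``N2`` in library 2, the probability of observing ``y`` given ``x`` under
equal expression is the Audic-Claverie statistic

    P(y | x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)

which is the posterior predictive of a Poisson rate with a flat prior — a
negative binomial in ``y`` with ``x+1`` shape and success probability
``N1/(N1+N2)``.  The two-sided p-value doubles the smaller tail of the
cumulative sum over ``i <= y``.

Expression is reported in TPM (tags per million clean tags), with a small
positive floor substituted for zero counts so that log2 ratios stay finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "DifferentialResult",
    "tpm",
    "log2_ratio",
    "poisson_pmf",
    "ac_conditional",
    "ac_pvalue",
    "bonferroni",
    "fdr_bh",
    "call_regulation",
    "differential_expression",
]

DEFAULT_ZERO_FLOOR = 0.001
DEFAULT_FDR_THRESHOLD = 0.001
DEFAULT_LFC_THRESHOLD = 1.0


@dataclass
class DifferentialResult:
    """Per-sRNA outcome of the two-library comparison.

    ``log2_ratio`` is log2(tpm_b / tpm_a), i.e. condition b (stress) relative
    to condition a (control); its sign determines up/down.
    """

    srna_id: str
    count_a: int
    count_b: int
    tpm_a: float
    tpm_b: float
    log2_ratio: float
    p_value: float
    p_bonferroni: float = field(default=float("nan"))
    fdr: float = field(default=float("nan"))
    regulation: str = "ns"


def tpm(count: int, library_total: int, zero_floor: float = DEFAULT_ZERO_FLOOR) -> float:
    """Tags-per-million normalisation: count * 1e6 / library_total.

    Zero counts return ``zero_floor`` (default 0.001) instead of 0 so that
    downstream log ratios are finite.
    """
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return zero_floor
    return count * 1e6 / library_total


def log2_ratio(tpm_a: float, tpm_b: float) -> float:
    """log2 fold change of b over a; both TPMs must be strictly positive."""
    if tpm_a <= 0 or tpm_b <= 0:
        raise ValueError("TPM values must be positive (apply the zero floor first)")
    return math.log2(tpm_b / tpm_a)


def poisson_pmf(x: int, lam: float) -> float:
    """Poisson probability e^-lam * lam^x / x!, evaluated in log space."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if x < 0:
        raise ValueError("x must be a non-negative integer")
    return math.exp(x * math.log(lam) - lam - math.lgamma(x + 1))


def _ac_log_pmf(y: np.ndarray, x: int, n1: float, n2: float) -> np.ndarray:
    log_r = math.log(n2) - math.log(n1)
    log_1pr = math.log1p(n2 / n1)
    return (
        y * log_r
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * log_1pr
    )


def ac_conditional(y: int, x: int, n1: float, n2: float) -> float:
    """Audic-Claverie term P(y | x) for library totals n1, n2."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative integers")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    return float(np.exp(_ac_log_pmf(np.array([y], dtype=float), x, n1, n2)[0]))


def ac_pvalue(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic-Claverie p-value.

    S = sum_{i=0}^{y} P(i|x); the p-value is 2S when S <= 0.5, else 2(1-S),
    clamped to [0, 1].  The upper branch sums the complementary tail directly
    (rather than subtracting from 1) to avoid catastrophic cancellation when
    S is close to 1.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative integers")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    i = np.arange(y + 1, dtype=float)
    s_low = math.fsum(np.exp(_ac_log_pmf(i, x, n1, n2)))
    if s_low <= 0.5:
        p = 2.0 * s_low
    else:
        p = 2.0 * _ac_upper_tail(x, y, n1, n2)
    return min(max(p, 0.0), 1.0)


def _ac_upper_tail(x: int, y: int, n1: float, n2: float) -> float:
    """sum_{i > y} P(i|x), summed in blocks until a geometric bound on the
    remaining tail is negligible (term ratio q*(x+i+1)/(i+1) -> q < 1)."""
    q = n2 / (n1 + n2)
    total = 0.0
    i0 = y + 1
    block = 4096
    while True:
        i = np.arange(i0, i0 + block, dtype=float)
        terms = np.exp(_ac_log_pmf(i, x, n1, n2))
        total += math.fsum(terms)
        i0 += block
        last = terms[-1]
        rho = q * (x + i0 + 1) / (i0 + 1)
        if last == 0.0:
            break
        if rho < 1.0 and last * rho / (1.0 - rho) < 1e-17 * max(total, 1e-300):
            break
    return total


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni correction: min(1, m*p) with m the number of tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)

def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def call_regulation(
    log2_ratios: Sequence[float],
    fdrs: Sequence[float],
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> list[str]:
    """Classify each sRNA as 'up', 'down', or 'ns'.

    'up' requires fdr <= fdr_threshold and log2_ratio >= lfc_threshold;
    'down' is symmetric with log2_ratio <= -lfc_threshold.
    """
    calls = []
    for lfc, q in zip(log2_ratios, fdrs, strict=True):
        if q <= fdr_threshold and lfc >= lfc_threshold:
            calls.append("up")
        elif q <= fdr_threshold and lfc <= -lfc_threshold:
            calls.append("down")
        else:
            calls.append("ns")
    return calls


def differential_expression(
    ids: Sequence[str],
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    library_total_a: int,
    library_total_b: int,
    zero_floor: float = DEFAULT_ZERO_FLOOR,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> list[DifferentialResult]:
    """Full per-sRNA comparison of two libraries.

    Computes floored TPMs, log2 ratios, Audic-Claverie p-values, Bonferroni
    and BH-FDR corrections over the tested set, and up/down/ns calls.
    """
    n = len(ids)
    if not (len(counts_a) == len(counts_b) == n):
        raise ValueError("ids, counts_a and counts_b must have equal length")
    tpms_a = [tpm(c, library_total_a, zero_floor) for c in counts_a]
    tpms_b = [tpm(c, library_total_b, zero_floor) for c in counts_b]
    lfcs = [log2_ratio(a, b) for a, b in zip(tpms_a, tpms_b)]
    pvals = np.array(
        [ac_pvalue(x, y, library_total_a, library_total_b) for x, y in zip(counts_a, counts_b)]
    )
    p_bonf = bonferroni(pvals)
    qvals = fdr_bh(pvals)
    calls = call_regulation(lfcs, qvals, fdr_threshold, lfc_threshold)
    return [
        DifferentialResult(
            srna_id=str(ids[i]),
            count_a=int(counts_a[i]),
            count_b=int(counts_b[i]),
            tpm_a=tpms_a[i],
            tpm_b=tpms_b[i],
            log2_ratio=lfcs[i],
            p_value=float(pvals[i]),
            p_bonferroni=float(p_bonf[i]),
            fdr=float(qvals[i]),
            regulation=calls[i],
        )
        for i in range(n)
    ]
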