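"""Target prediction and hypergeometric term enrichment."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps
from Bio.Seq import Seq

from saltmir.enrich import (
    EnrichmentInput,
    enrich,
    hypergeom_p,
    predict_targets,
)

MIRNA = "TGACAGAAGAGAGTGAGCACA"  # 21 nt


def _transcript_with_site(mirna, flank_left="GGCCTT" * 5, flank_right="CCAAGG" * 5):
    return flank_left + str(Seq(mirna).reverse_complement()) + flank_right


class TestPredictTargets:
    def test_perfect_site_penalty_zero(self):
        hits = predict_targets({"m1": MIRNA}, {"g1": _transcript_with_site(MIRNA)})
        assert len(hits) == 1 and hits[0].penalty_score == 0.0

    def test_single_seed_mismatch_costs_two(self):
        site = list(str(Seq(MIRNA).reverse_complement()))
        # miRNA position 10 faces site index L - 10
        idx = len(MIRNA) - 10
        site[idx] = {"A": "C", "C": "A", "G": "A", "T": "C"}[site[idx]]
        transcript = "GGCCTT" * 5 + "".join(site) + "CCAAGG" * 5
        hits = predict_targets({"m1": MIRNA}, {"g1": transcript})
        assert len(hits) == 1 and hits[0].penalty_score == 2.0

    def test_heavy_seed_damage_not_emitted(self):
        site = list(str(Seq(MIRNA).reverse_complement()))
        for p in range(2, 7):  # five seed mismatches -> penalty 10
            idx = len(MIRNA) - p
            site[idx] = {"A": "C", "C": "A", "G": "A", "T": "C"}[site[idx]]
        transcript = "GGCCTT" * 5 + "".join(site) + "CCAAGG" * 5
        assert predict_targets({"m1": MIRNA}, {"g1": transcript}) == []

    def test_gu_wobble_costs_half(self):
        # miRNA position 16 (outside 2-13): target base complementary->wobble
        site = list(str(Seq(MIRNA).reverse_complement()))
        p = 16
        idx = len(MIRNA) - p
        m_base = MIRNA[p - 1]
        if m_base in ("G", "T"):
            site[idx] = "T" if m_base == "G" else "G"
            transcript = "GGCCTT" * 5 + "".join(site) + "CCAAGG" * 5
            hits = predict_targets({"m1": MIRNA}, {"g1": transcript})
            assert hits[0].penalty_score == 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            predict_targets({}, {"g": "ACGT"})


def enumeration_oracle(N, n, M, m):
    """P(overlap >= m) by enumerating every n-subset of an N-universe."""
    term = set(range(M))
    hits = 0
    total = 0
    for subset in itertools.combinations(range(N), n):
        total += 1
        if len(term.intersection(subset)) >= m:
            hits += 1
    return hits / total


class TestHypergeomP:
    def test_m_zero_is_one(self):
        assert hypergeom_p(EnrichmentInput(N=50, n=10, M=5, m=0)) == 1.0

    def test_all_draws_in_term(self):
        assert hypergeom_p(EnrichmentInput(N=10, n=5, M=5, m=5)) == pytest.approx(
            1 / 252, rel=1e-12
        )

    def test_term_covers_universe(self):
        assert hypergeom_p(EnrichmentInput(N=8, n=3, M=8, m=3)) == pytest.approx(1.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentInput(N=10, n=5, M=3, m=4)

    def test_exhaustive_enumeration_all_small_cases(self):
        """Exact agreement with subset enumeration for every N <= 12."""
        for N in range(1, 13):
            for n in range(0, N + 1):
                for M in range(0, N + 1):
                    for m in range(0, min(n, M) + 1):
                        got = hypergeom_p(EnrichmentInput(N=N, n=n, M=M, m=m))
                        want = enumeration_oracle(N, n, M, m)
                        assert got == pytest.approx(want, abs=1e-10), (N, n, M, m)

    def test_matches_scipy_survival_function(self):
        for N, n, M, m in [(100, 20, 30, 10), (500, 50, 40, 8), (1000, 100, 5, 3)]:
            want = sps.hypergeom.sf(m - 1, N, M, n)
            assert hypergeom_p(EnrichmentInput(N=N, n=n, M=M, m=m)) == pytest.approx(
                want, rel=1e-10
            )

    def test_monotone_in_m(self):
        ps = [hypergeom_p(EnrichmentInput(N=60, n=20, M=15, m=m)) for m in range(0, 15)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


def _universe(n_genes=100, n_terms=10, genes_per_term=10, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    gene_terms = {g: [] for g in genes}
    for t in range(n_terms):
        members = rng.choice(n_genes, size=genes_per_term, replace=False)
        for g in members:
            gene_terms[genes[g]].append((f"T{t}", f"term {t}", "biological_process"))
    return genes, gene_terms


class TestEnrich:
    def test_single_gene_single_term_closed_form(self):
        genes = [f"g{i}" for i in range(100)]
        gene_terms = {g: [] for g in genes}
        gene_terms["g0"] = [("T0", "only term", "biological_process")]
        res = enrich(gene_terms, genes, ["g0"])
        assert len(res) == 1
        assert res[0].p_value == pytest.approx(0.01, rel=1e-9)
        assert res[0].p_corrected == pytest.approx(0.01, rel=1e-9)
        assert res[0].significant

    def test_null_calibration(self):
        """Random target sets: few terms reach Bonferroni significance."""
        genes, gene_terms = _universe(seed=5)
        rng = np.random.default_rng(5)
        sig = 0
        tested = 0
        for _ in range(200):
            targets = list(rng.choice(genes, size=10, replace=False))
            res = enrich(gene_terms, genes, targets)
            sig += sum(r.significant for r in res)
            tested += len(res)
        assert tested > 0
        assert sig / tested <= 0.05

    def test_go_and_kegg_paths_identical(self):
        """The same machinery fed identical maps yields identical numbers."""
        genes, gene_terms = _universe(seed=9)
        kegg_map = {
            g: [(t[0].replace("T", "ko"), t[1], "Metabolism") for t in terms]
            for g, terms in gene_terms.items()
        }
        targets = genes[:12]
        go_res = enrich(gene_terms, genes, targets)
        kegg_res = enrich(kegg_map, genes, targets)
        assert [(r.p_value, r.p_corrected) for r in go_res] == [
            (r.p_value, r.p_corrected) for r in kegg_res
        ]

    def test_zero_target_terms_only_in_full_report(self):
        genes, gene_terms = _universe(seed=2)
        res = enrich(gene_terms, genes, [genes[0]])
        assert all(r.m >= 1 for r in res)
        full = enrich(gene_terms, genes, [genes[0]], full_report=True)
        assert any(r.m == 0 and r.p_value == 1.0 for r in full)
        assert len(full) >= len(res)

    def test_empty_background_fails(self):
        with pytest.raises(ValueError):
            enrich({}, [], [])

    def test_targets_outside_background_fail(self):
        with pytest.raises(ValueError):
            enrich({"g1": []}, ["g1"], ["g2"])
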