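"""Weighted base-pair maximisation folding and hairpin/siRNA candidate calls."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saltmir.hairpin import (
    TagLocation,
    brute_force_fold,
    call_novel_mirnas,
    call_sirna_pairs,
    dinucleotide_shuffle,
    fold_max_pairing,
    locate_tags,
)
from saltmir.preprocess import SmallRNATag
from saltmir.simulate import SyntheticConfig, generate_reference

SEQ_ALPHABET = "ACGT"


class TestFoldMaxPairing:
    def test_perfect_stem(self):
        f = fold_max_pairing("GGGAAACCC", min_loop=3)
        assert f.dot_bracket == "(((...)))"
        assert f.pair_count == 3
        assert f.score == 9

    def test_no_complementarity(self):
        f = fold_max_pairing("AAAAAA")
        assert f.pair_count == 0 and f.dot_bracket == "......"

    @pytest.mark.parametrize("seq", ["A", "GC", "GAC", "GAAC"])
    def test_too_short_for_loop(self, seq):
        assert fold_max_pairing(seq, min_loop=3).pair_count == 0

    def test_non_acgt_fails(self):
        with pytest.raises(ValueError):
            fold_max_pairing("ACGN")

    def test_structure_is_well_formed(self):
        f = fold_max_pairing("GCGCTTAAAGCGCAAAGGGTTTCCC")
        assert len(f.dot_bracket) == len(f.sequence)
        depth = 0
        for c in f.dot_bracket:
            depth += {"(": 1, ")": -1, ".": 0}[c]
            assert depth >= 0
        assert depth == 0

    def test_matches_brute_force_on_random_sequences(self):
        """DP optimum equals exhaustive non-crossing maximisation (len <= 12)."""
        rng = random.Random(42)
        for _ in range(300):
            n = rng.randint(1, 12)
            seq = "".join(rng.choice(SEQ_ALPHABET) for _ in range(n))
            assert fold_max_pairing(seq).score == brute_force_fold(seq), seq

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet=SEQ_ALPHABET, min_size=1, max_size=12))
    def test_matches_brute_force_property(self, seq):
        assert fold_max_pairing(seq).score == brute_force_fold(seq)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet=SEQ_ALPHABET, min_size=1, max_size=30))
    def test_reverse_complement_antisymmetry_watson_crick(self, seq):
        """With Watson-Crick weights the optimum is strand-symmetric."""
        from Bio.Seq import Seq

        rc = str(Seq(seq).reverse_complement())
        a = fold_max_pairing(seq, wobble=False)
        b = fold_max_pairing(rc, wobble=False)
        assert a.score == b.score
        assert a.pair_count == b.pair_count


@pytest.fixture(scope="module")
def novel_reference():
    cfg = SyntheticConfig(seed=3, n_known_mirnas=4, n_novel_mirnas=6, n_other_loci=4)
    return cfg, generate_reference(cfg)


class TestCallNovelMirnas:
    def test_embedded_hairpins_are_called(self, novel_reference):
        _, sim_ref = novel_reference
        ref = sim_ref.reference
        novel = [l for l in sim_ref.loci if l.category == "novel_mirna"]
        tags = [SmallRNATag(l.sequence, 50) for l in novel]
        candidates = call_novel_mirnas(locate_tags(tags, ref), ref)
        assert len(candidates) == len(novel)
        assert all(c.verdict for c in candidates)

    def test_low_count_tags_skipped(self, novel_reference):
        _, sim_ref = novel_reference
        ref = sim_ref.reference
        tag = SmallRNATag(sim_ref.loci[-1].sequence, 2)  # below min_count=5
        assert call_novel_mirnas(locate_tags([tag], ref), ref) == []

    def test_shuffled_context_rarely_calls(self, novel_reference):
        """Empirical null: the mature in dinucleotide-shuffled flanks passes <= 5%."""
        _, sim_ref = novel_reference
        ref_seq = sim_ref.reference["chr1"]
        novel = [l for l in sim_ref.loci if l.category == "novel_mirna"]
        rng = random.Random(7)
        n_true = 0
        n_total = 100
        for i in range(n_total):
            loc = novel[i % len(novel)]
            ws, we = max(1, loc.start - 80), min(len(ref_seq), loc.end + 80)
            window = ref_seq[ws - 1 : we]
            off = loc.start - ws
            shuffled = dinucleotide_shuffle(window, rng)
            shuffled = shuffled[:off] + loc.sequence + shuffled[off + len(loc.sequence) :]
            ref = {"null": shuffled}
            tags = [SmallRNATag(loc.sequence, 50)]
            cands = call_novel_mirnas(locate_tags(tags, ref), ref)
            n_true += sum(c.verdict for c in cands)
        assert n_true / n_total <= 0.05

    def test_window_clipped_at_contig_end(self):
        stem = "G" * 10 + "AAAA" + "C" * 10
        ref = {"c": stem}
        tags = [SmallRNATag("G" * 10 + "AAAA" + "C" * 6, 10)]
        cands = call_novel_mirnas(locate_tags(tags, ref), ref, window_flank=80)
        assert cands and cands[0].window_start == 1 and cands[0].window_end == len(stem)


def test_dinucleotide_shuffle_preserves_dinucleotides():
    rng = random.Random(1)
    seq = "ACGTACGGTTACGATCGATCGGGTACTA"
    shuffled = dinucleotide_shuffle(seq, rng)
    def dinucs(s):
        counts = {}
        for a, b in zip(s, s[1:]):
            counts[a + b] = counts.get(a + b, 0) + 1
        return counts
    assert dinucs(shuffled) == dinucs(seq)
    assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]


class TestSiRNAPairs:
    def _loc(self, seq, start, strand, count=10):
        return TagLocation(SmallRNATag(seq, count), "chr1", start, start + len(seq) - 1, strand)

    def test_two_nt_overhang_duplex_detected(self):
        plus = self._loc("A" * 22, 101, "+")
        minus = self._loc("C" * 22, 99, "-")
        pairs = call_sirna_pairs([plus, minus])
        assert len(pairs) == 1 and pairs[0].overhang_check

    def test_blunt_duplex_rejected(self):
        plus = self._loc("A" * 22, 101, "+")
        minus = self._loc("C" * 22, 101, "-")
        assert call_sirna_pairs([plus, minus]) == []

    def test_21mers_fail_length_gate(self):
        plus = self._loc("A" * 21, 101, "+")
        minus = self._loc("C" * 21, 99, "-")
        assert call_sirna_pairs([plus, minus]) == []
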