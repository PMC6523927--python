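"""Call novel miRNA candidates by folding genomic windows into hairpins.

Each abundant unannotated tag is excised with 80 nt flanks and folded with
the weighted base-pair-maximisation DP; a positive verdict needs a well
paired window, the mature almost fully paired into one compact opposite-arm
helix, and a sufficient weighted score per base.
"""

from saltmir.hairpin import call_novel_mirnas, fold_max_pairing, locate_tags
from saltmir.preprocess import SmallRNATag
from saltmir.simulate import SyntheticConfig, generate_reference

# a toy stem-loop first: the fold and its dot-bracket string
fold = fold_max_pairing("GGGCGCAAAGCGCCC")
print("toy fold:", fold.sequence)
print("          " + fold.dot_bracket,
      f"({fold.pair_count} pairs, weighted score {fold.score})")

config = SyntheticConfig(seed=3, n_known_mirnas=4, n_novel_mirnas=5, n_other_loci=4)
sim_ref = generate_reference(config)
novel_loci = [l for l in sim_ref.loci if l.category == "novel_mirna"]
tags = [SmallRNATag(l.sequence, 50) for l in novel_loci]

candidates = call_novel_mirnas(locate_tags(tags, sim_ref.reference), sim_ref.reference)
print(f"\n{sum(c.verdict for c in candidates)} of {len(candidates)} windows called as "
      "novel miRNA precursors (all embedded hairpins should be recovered):")
for c in candidates:
    print(f"  {c.contig}:{c.window_start}-{c.window_end} arm={c.mature_arm} "
          f"paired={c.paired_fraction:.2f} score/base={c.score_density:.2f} "
          f"star={c.star_support} verdict={c.verdict}")
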