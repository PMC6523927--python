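# Methods

## Scope and model

saltmir re-implements the pooled-library small-RNA-seq workflow used in
two-condition plant stress studies: one sequencing library per condition, no
replicates, significance from count statistics alone. The atomic unit
throughout is the *tag* — a unique insert sequence with a per-library read
count. All stages are deterministic functions of their inputs and a single
seed.

## Read cleaning

Filters apply in a fixed order; each read is charged to exactly one
rejection rule so that clean reads plus rejections always equal the input
(a tested invariant):

1. mean Phred < `quality_floor` (default 20);
2. no 3′ adapter — detection is an exact substring match of the adapter's
   first 8 bases; the insert is everything before the first match
   (mismatch-tolerant trimming is deliberately out of scope);
3. 5′ contaminant — the insert begins with the leading 8 bases of the
   (distinct) 5′ primer sequence, when one is supplied. With
   first-occurrence 3′-adapter trimming an insert can never contain the 3′
   adapter seed, so this check necessarily targets a separate 5′ sequence;
4. empty insert (adapter at position 0);
5. poly-A: ≥ 80 % A;
6. insert outside the 18–28 nt analysis window.

The length-distribution report spans 16–36 nt and is taken from
pre-length-filter inserts, so the wider figure axis can be reproduced while
the stricter analysis window still governs what goes downstream. Percentages
in summary tables round half away from zero to 2 decimals, matching how the
published tables print.

## Annotation and the priority rule

Tags hit a locus when they align within the locus span, either orientation,
with ≤ `max_mismatch` substitutions (no indels; default 2, the
known-miRNA matching tolerance; exact matching is used for the genome-wide
"mapped" total). Mismatch counting is vectorised over tags grouped by
length. Multi-category tags resolve to the single highest-priority category
(miRNA > piRNA > snoRNA > Rfam > other sRNA), making category read counts a
partition of the clean total. piRNA is a stub category: the SVM-based
predictors used for piRNA in the field are out of scope, the category
exists so the priority rule and report columns are complete, and the
expected count is zero.

## Hairpin folding and novel miRNA calling

Folding is weighted base-pair maximisation (Nussinov-style O(n³) DP,
numba-compiled) with weights G–C = 3, A–T = 2, G–U = 1, hairpin loops of at
least 3 unpaired bases, and no pseudoknots. Traceback is deterministic:
pairing (i, j) wins ties over bifurcation, then the smallest split point.
The DP is verified against an exhaustive non-crossing-pairing maximiser for
all test sequences ≤ 12 nt. Under reverse complement the optimum is exactly
strand-symmetric only for the Watson–Crick weight set (a G–U pair maps to an
unpairable A–C); the symmetry test therefore runs with wobble disabled.

For each unannotated, genome-mapped tag with ≥ `min_count` (5) reads, a
window of the tag ± 80 nt is excised (clipped at contig ends) and folded.
The weighted score per base stands in for a free-energy model; no
nearest-neighbour thermodynamics are attempted. A window passes when:

- **(a)** ≥ 55 % of window bases are paired;
- **(b)** the mature pairs into one *compact opposite-arm helix*: at least
  max(16, ⌈0.85·L⌉) of the mature's L bases pair to partners inside a single
  interval of width L + 6 outside the mature (the +6 allows small bulges);
- **(c)** at most max(2, ⌊0.15·L⌋) mature bases pair anywhere else (within
  the mature or to stray positions) — the operational form of "the mature
  lies entirely on one arm";
- **(d)** weighted score / window length ≥ 0.85.

Rationale for the length-scaled (b)/(c): maximum-weight pairing pairs
roughly three quarters of *any* random window, so absolute thresholds alone
leave an appreciable false-call rate; requiring ~85 % of the mature in one
contiguous duplex is the discriminating signature of a genuine precursor
and matches how dedicated precursor callers gate duplex extent. With these
defaults, embedded true hairpins are recovered at 100 % across generator
seeds while matures re-embedded in dinucleotide-shuffled context pass in
≈ 0.3–2 % of windows (empirical null, tested at ≤ 5 %). All thresholds are
keyword arguments.

Star support is a simplified check: another window tag whose span covers
(nearly all of) the mature's pairing partners. siRNA duplex candidates are
pairs of 22–24 nt tags on opposite strands with `plus.start − minus.start =
plus.end − minus.end = 2`, i.e. a 2-nt 3′ overhang on each strand.

## Expression and the two-library Poisson test

TPM is count × 10⁶ / library clean-tag total; zero counts take a 0.001
floor so log₂ ratios stay finite (the convention visible in the published
tables, where count-0 rows print TPM 0.001). log₂ ratios are stress over
control on floored TPMs.

With library totals N₁, N₂ and counts x, y, the probability of y given x
under equal expression is P(y|x) = r^y · C(x+y, y) · (1+r)^−(x+y+1),
r = N₂/N₁ — the posterior predictive of a Poisson rate under a flat prior,
i.e. negative binomial with shape x+1 and success probability N₁/(N₁+N₂).
Terms are evaluated in log space (gammaln) and summed with exact
compensated summation. The two-sided p doubles the smaller tail of
S = Σ_{i≤y} P(i|x): p = 2S if S ≤ 0.5, else 2(1−S), clamped to [0, 1]; the
upper branch sums the complementary tail directly in blocks (with a
geometric bound on the truncated remainder) rather than subtracting from 1,
which would cancel catastrophically for extreme counts. The implementation
agrees with an arbitrary-precision direct-summation oracle to 1e-10
relative and, independently, with the negative-binomial CDF route.

Corrections: Bonferroni (min(1, m·p)) and Benjamini–Hochberg step-up
q-values (cross-checked against statsmodels). Calls: up iff FDR ≤ 0.001 and
log₂ ratio ≥ 1; down symmetric; otherwise ns. Under the synthetic null
(equal means, Poisson counts, 2 000 loci) the p ≤ 0.05 rate is 0.05 ± 0.02,
and spiked loci with |log₂ fc| ≥ 2 and mean ≥ 50 are recovered in the
correct direction with ≥ 90 % sensitivity at those thresholds — both are
acceptance-tested. No replicate-aware (negative binomial with estimated
dispersion) model is offered: the design this package serves has none.

## Targets and enrichment

Target prediction is a reverse-complement scan: each transcript window the
length of the miRNA is scored position-by-position (mismatch 1, G:U wobble
0.5, doubled at miRNA positions 2–13), and the best site per pair is
emitted at penalty ≤ 4. This is plumbing for enrichment, not a
thermodynamic target model.

Enrichment is the exact upper-tail hypergeometric probability of m or more
target genes among a term's M genes, given n targets in an N-gene annotated
background, computed with log-space binomials and verified against subset
enumeration for every N ≤ 12. Bonferroni correction runs over the tested
terms only (terms with ≥ 1 target gene); terms with no target gene appear
only in the optional full report, at p = 1. GO and KEGG use the identical
code path with different gene→term maps; annotation maps are taken as flat
(no ontology-graph propagation).

## Synthetic data

The generator emulates the statistical structure of the real experiment at
desk scale, not its biology:

- **Reference**: one contig of locus cassettes in random spacer context.
  Novel-miRNA cassettes are mature + 11 nt loop + reverse-complement arm, so
  folding provably recovers a stem-loop; known/decoy loci are plain random
  sequences. Ground-truth novel loci are tagged `novel-truth` in the GFF3
  and excluded from the known-annotation set the mapper sees.
- **Reads**: single-end 50 nt (insert + fixed 3′ adapter, padded/truncated),
  constant quality. Insert lengths follow a weight table dominated by 21 and
  24 nt. Star-arm reads accompany novel matures at ~10 % abundance with the
  2-nt Dicer offset.
- **Counts**: per-locus Poisson; the stress mean is the control mean times a
  per-locus fold change (drawn from {⅛, ¼, 4, 8} for a configurable fraction
  of loci, or supplied explicitly). Poisson-only noise is deliberate: the
  differential test assumes it, so calibration tests measure the test, not a
  mismatch between generator and test.
- **Junk**: a binomial fraction (default 10 %) of adapter-free, poly-A,
  short-insert, low-quality and clean-but-unmappable reads, exercising every
  cleaning filter and the unmapped remainder.
- Default scale is 50 000 reads per library — large enough for stable
  category fractions and tight Poisson calibration, small enough for
  second-scale runs.

What passing tests on this generator does **not** show: robustness to
sequencing error (reads are error-free), overdispersion beyond Poisson,
multi-mapping ambiguity on repetitive genomes, or realistic base
composition. Conclusions about real data should rest on the statistical
properties (calibration, sensitivity, exactness of the oracles), which the
generator is designed to measure cleanly.

## Numerical and design notes

- Percent rounding is half-away-from-zero at 2 decimals (Decimal-based), as
  summary tables print.
- The DE table takes the library *clean-tag totals* as TPM denominators.
- All percentages, ratios and calls in emitted TSVs are recomputable from
  the stage TSVs; the manifest stores the seed, thresholds and input
  hashes, never timestamps, so reruns are byte-identical.
- Pipeline enrichment runs against a generated synthetic transcriptome and
  flat GO/KEGG maps (one perfect target site per miRNA locus plus
  background genes); real annotation maps can be supplied through the
  library API instead.
- Known limitations: exact-substring adapter detection misses mutated
  adapters; substitution-only alignment misses indel variants; the fold
  model has no stacking energies; enrichment ignores the GO graph.
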