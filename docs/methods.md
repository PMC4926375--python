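# Methods

This note documents the statistics, the scanning rules, the synthetic
data model and the numerical conventions implemented in `mitocomp`,
and states what the synthetic benchmarks do and do not demonstrate
about real data.

## Genetic code and coordinates

All codon-level statistics use the invertebrate mitochondrial code
(NCBI translation table 5): UGA = Trp, AGA/AGG = Ser, AUA = Met, stops
UAA/UAG only, hence 62 sense codons. The 8-codon serine family is
split into its UCN and AGN halves — the halves are not connected by
single third-position changes and are conventionally reported
separately — leaving 21 synonymous families (twelve 2-fold, eight
4-fold, one 6-fold).

Coordinates are 1-based inclusive on the major strand (the strand
carrying most genes), matching GenBank; BED exports are 0-based
half-open. Spans wrapping the origin of the circular molecule are
unwrapped as suffix + prefix. Minor-strand genes are
reverse-complemented into coding orientation on extraction. Truncated
stop codons (a 3'-terminal T or TA completed to UAA by
polyadenylation) are recorded as annotations, not edited into the
sequence: composition uses the span as-is, while codon-level analyses
drop the trailing partial codon.

## Composition and skews

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C), computed per
partition (pooled PCGs, PCGs by strand, tRNAs, rRNAs, AT-rich region,
whole genome) and per codon position within each PCG strand class. N
bases are excluded from numerators and denominators; a skew with a
zero denominator is reported as NaN rather than zero. Codon-position
statistics pool bases across genes by default (a per-gene option
exists) — whether to pool or average per gene is a genuine choice and
pooling is the simpler estimator at these sample sizes.

## Codon-usage bias

* **RSCU**(c) = observed(c) × family size / family total; empty
  families give NaN, not 0.
* **ENC** (Wright 1990): per family with n ≥ 2 codons, the codon
  homozygosity F̂ = (n·Σp̂ᵢ² − 1)/(n − 1); families are averaged within
  each degeneracy class and ENC = Σ_class N_class / mean F̂_class,
  capped at 62. A class with no estimable family is imputed with the
  mean F̂ of the other classes; non-positive F̂ values are dropped from
  the class mean. Uniform usage at large n gives 62; one codon per
  family gives 21 (the family count).
* **CBI** = (N_pref − N_rand)/(N_total − N_rand) over families with
  synonymous choice, where N_rand is the preferred count expected
  under uniform synonymous usage. The default preferred set is the
  A-ending codon of every family (the observed major-strand
  preference); a U-ending set is provided for minor-strand genes, and
  any set can be passed explicitly.
* **Correlations** are ordinary least squares (scipy `linregress`);
  r² = squared Pearson correlation, reported unsigned where only the
  strength matters. Fewer than 3 points or zero variance yields a
  missing result with a warning.

## Ka/Ks (NG86)

Synonymous/nonsynonymous site fractions per codon are the share of
the nine single-nucleotide changes that preserve the amino acid, so
s + n = 3 exactly; changes creating a stop codon are counted as
nonsynonymous (the alternative — excluding them and renormalising —
breaks the per-codon site conservation this implementation
guarantees, and differs negligibly at these divergences). Codon pairs
differing at multiple positions are averaged over all minimal
pathways with equal weights; pathways through stop codons are
excluded unless every pathway is blocked. Proportions p = Sd/S and
Nd/N are corrected with d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is flagged
as saturated and excluded from gene-level means. Per gene, Ka and Ks
are means over all in-group pairs and ω is the ratio of those means
(ratio-of-means avoids the instability of per-pair ratios when a
pair's Ks is near zero); per-pair values remain available. Codons
containing gaps, N, or a stop in either sequence are dropped
pairwise. Inputs must be codon-aligned; alignment construction is out
of scope.

## RNA conservation (%INUC)

A column is identical iff every row carries the same non-gap base;
columns that are gaps in every row are excluded from denominators,
and a gap in any row makes a column non-identical (the conservative
reading — the alternative of ignoring gapped rows inflates
conservation). %INUC is the identical fraction over scored columns.
Region summaries pool identical/total column counts across families
sharing a mask label (column-weighted, not family-weighted). A
default 71-column cloverleaf mask ships with the package (acceptor
stem 7 bp, DHU stem 4/loop 8, anticodon stem 5/loop 7, variable 4,
TψC stem 5/loop 7); masks are plain "start end label" text files and
users supply their own per-family masks for real alignments, where
indels shift structural columns.

## Control-region scanners

* **T-stretches**: maximal perfect runs, ≥ 10 T on the major strand
  and ≥ 8 A on the major strand for the minor-strand stretches (the
  lower minor-strand threshold is the convention for these shorter
  elements); both reported in major-strand coordinates. A separate
  near-trnI report scans the region's 3' end for a 10-nt window with
  ≤ 2 non-T bases on the minor strand.
* **Microsatellites**: maximal (AT)n runs with n ≥ 5, both phases
  scanned, one hit per locus (longer phase wins).
* **Tandem repeats**: for each period 10–60 bp and left-maximal
  anchor, the array is extended while each base matches the base one
  period earlier, tolerating isolated mismatches but stopping at 3
  consecutive mismatches, then trimmed to end on a match. A call
  requires copy number ≥ 1.8 (one full copy plus ≥ 80% of a second),
  mean adjacent-copy identity ≥ 0.70, and an alignment score
  (+2/match, −7/mismatch) ≥ 16. The score gate is essential: in
  70–90% A+T sequence a single chance 10-mer adjacent match clears a
  bare 0.70 identity threshold about once per 250 anchors, so an
  identity rule alone would call repeats in almost every random
  region. Consensus units are column majorities; copy number is
  span/period to one decimal; position classes 5'/M/3' are thirds of
  the region by span midpoint. Overlapping calls whose periods are
  harmonics (one divides the other ±1) are merged keeping the highest
  (identity, then length) call; non-harmonic overlaps — genuinely
  nested repeat families — are all reported. This is a bespoke
  scanner, not a reimplementation of an alignment-scoring repeat
  finder; on real data its consensus sizes and copy numbers are
  comparable but per-call identity percentages need not match other
  tools.
* **Flank consensus**: fixed windows adjacent to an anchor T-stretch
  (longest on the requested strand), stacked without alignment;
  columns with ≥ 80% agreement emit the majority base, others X.
* **Stem-loops**: exhaustive search for perfect Watson–Crick stems
  ≥ 4 bp around loops of 3–7 nt, grown outward from each candidate
  loop (maximal by construction), ordered longest-stem then
  smallest-loop. All candidates are reported: A+T-rich sequence is
  highly self-complementary and alternative foldings are real.
  No thermodynamics — ΔG ranking is out of scope.
* **Spacer check**: the trnS(UCN)–ND1 intergenic gap is screened for
  the conserved motif TACTAA and compared against the column-majority
  consensus of the modal-length spacers (Hamming distance; genomes of
  other lengths report a missing distance rather than a forced
  alignment).

## Supermatrices

The four datasets are PCG (13 protein-coding genes), mtDNA (all 37
genes), and PCG12/mtDNA12 with third codon positions removed. Genes
are concatenated in the ancestral insect gene order (a packaged,
editable resource). Charsets partition every column exactly: one
charset per codon position per PCG block (NEXUS `start-end\3` ranges)
plus one pooled RNA charset (tRNAs are not split per gene — a
per-gene option was considered and rejected as 24 extra partitions of
~70 columns each carry no usable signal); per-gene block spans are
kept as provenance. Stripping recomputes charsets and commutes with
concatenation. Exports are relaxed PHYLIP and NEXUS with a commented
stub recording conventional Bayesian settings (GTR+I+G, 4 chains,
10⁶ generations, sample each 100, 25% burn-in) for users who run
tree inference externally; inference itself is out of scope.

## Synthetic data model

The generator emits a clade from a single explicit `numpy` generator
seeded once; no hidden global randomness.

* **Genes**: PCGs are built codon-wise — amino acids drawn from an
  insect-mitochondria-like frequency table, codons drawn within each
  synonymous family from a third-base model with A/T mass `pos3_at`
  (default 0.88) split A:T = 0.65:0.35 on the major strand and
  0.30:0.70 on the minor strand, and the G/C remainder split C-heavy
  (0.65) on the major strand. These defaults reproduce the
  composition regime of real beetle mitogenomes: ~70% A+T in PCGs,
  third positions far above first/second, A-skewed major-strand and
  T-skewed minor-strand third positions, and NNA/NNU-dominated codon
  families. Start codons are ATG; stops TAA, with COX1/ND4 given
  truncated T/TA stops by default so the incomplete-stop paths are
  exercised. tRNAs (71 nt) and rRNAs (1280/760 nt) are i.i.d. draws
  at their A+T targets (0.72/0.74).
* **Clade**: each derived genome mutates the ancestor independently —
  codon-wise for PCGs (synonymous resample at 0.06/codon,
  amino-acid change at 0.004/codon, so ω ≈ 0.03–0.15, the purifying
  regime of real mitochondrial PCGs; no stops ever introduced),
  per-site at 0.02 for RNAs (minor-strand tRNAs optionally faster),
  and per-site at 0.01 for the control-region background with planted
  elements and their flanking motifs protected by default.
* **Control region** (1000 bp default, A+T 0.90): planted elements —
  two tandem repeats (20 bp × 2.2 and 22 bp × 1.9, the size/copy
  regime reported for beetle control regions), a 14-T major-strand
  stretch with a stem-4/loop-5 hairpin planted 3' of it, an (AT)6
  microsatellite, and a 9-A minor-strand stretch flanked by AAAGC (5')
  and GTAA (3') — are placed at 5'/M/3' anchors without overlap, with
  guard bases chosen so each planted span is exactly maximal (a
  T-run is bounded by non-T, a repeat array by three
  period-mismatching bases, a hairpin by non-pairing bases). Truth
  records carry exact coordinates, unit sequences, copy numbers and
  flank spans. The conserved 17-bp spacer ATACTAAATTTTATTAA is
  planted verbatim between trnS(UCN) and ND1.
* **Whole-genome A+T calibration**: when a genome-wide target is set,
  the control-region background composition is solved to meet it
  given the realized coding partitions (feasible within roughly
  ±0.15 of the uncalibrated value; clipped with a warning outside
  that).
* The substitution process has no indels, so coordinates are shared
  across the clade and extracted genes are automatically aligned.

**What the synthetic benchmarks show — and don't.** Passing the
recovery and parameter-recovery suites shows the statistics and
scanners are implemented correctly and are well-behaved in the
composition/divergence regime of real insect mitogenomes. It does not
show robustness to features the generator omits: indels (real
repeat arrays grow and shrink by copy turnover), heteroplasmy,
annotation errors, gene rearrangements, rate heterogeneity along the
genome, or alignment uncertainty in RNA genes. Real-data workflows
should treat per-gene alignments and structure masks as curated
inputs.

## Problem sizes and determinism

Default benchmark sizes — 20 single-genome clades for element
recovery, 50 replicates of a 4-taxon × 200-codon two-level ω
contrast, a 10-point × 2000-codon bias gradient — were chosen so each
estimate's Monte-Carlo error is comfortably below the margin being
tested (e.g. ≥ 95% recovery is tested with ~120 elements). Every
stochastic routine takes an explicit seed or `numpy` Generator;
pipeline outputs and matrix exports contain no timestamps and are
byte-stable across reruns.

## Known limitations

* ENC small-sample behaviour follows Wright's estimator; genes with
  very few codons (ATP8-sized and below) give noisy ENC and the
  per-gene scope should be interpreted accordingly.
* The NG86 variant here (equal pathway weighting, Jukes–Cantor) is
  the classic estimator; codon-model ML methods will give different
  absolute rates, though gene rankings agree at low divergence.
* The tandem-repeat scanner's identity statistics are defined by its
  own extension rule and are not numerically interchangeable with
  other repeat finders' percent-match scores.
* rRNA boundary re-delimitation is not attempted; annotations are
  taken as given.
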