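# Methods

This note records the models, parameter choices and numerical decisions
behind each module, what the synthetic generator does and does not emulate,
and the known limitations.

## Synthetic diploid trio

The generator builds an ancestral genome (iid uniform ACGT), uses it as the
transmitted maternal haplotype, and derives the transmitted paternal
haplotype by planting heterozygous variants: SNVs at `snv_rate` per bp,
short indels at `indel_spec.rate` per bp with geometric lengths (p = 0.35,
truncated at 50 bp, insertions and deletions alternating), and structural
variants from explicit per-class counts and length ranges. Planted events
keep a 200-bp clear margin around one another, with bounded resampling (100
attempts, then a placement error) so truth tables stay unambiguous. Runs of
homozygosity are intervals where nothing is planted.

De novo mutations are planted on the child's two haplotypes after
transmission. The total count is Poisson with mean `dnm_rate ×
(L_mat + L_pat)` — the rate is per site per generation and the child carries
two transmitted haploid genomes, which is also the denominator convention of
the rate estimator — and the paternal share is Binomial(total,
`paternal_fraction`, default 2/3, the ratio observed in New World monkeys).

Default conditions are a captive primate trio at 30× depth, 10⁻³
heterozygosity, base-call error 10⁻³ and a DNM rate of 0.43×10⁻⁸; tests use
these unless a scenario states otherwise.

All randomness flows from one seed through named substreams (CRC32 of the
generator name spawns a `SeedSequence` key), so identical (config, seed)
yields byte-identical outputs and re-running one generator never perturbs
another.

### Site-call rendering

Every site of each reference (the child's maternal- and paternal-inherited
sequences) receives mother/father/child read draws: Poisson depth, binomial
allele sampling (het sites at p = 0.5), and a miscall rate of
`base_error / 3` toward the specific alternate base. On top of the iid
error, a small fraction of (site, individual) slots — 10⁻⁴ — are *error
hotspots* where the miscall rate toward one alternate base is 50×
`base_error`, capped at 0.25. This heavy tail emulates context-specific
systematic sequencing error; it is what gives the dual-reference
cross-validation something real to remove, since iid errors at realistic
rates essentially never assemble nine same-base miscalls at one site.
Genotypes are called by a three-genotype binomial likelihood; the genotype
quality is the scaled log-likelihood ratio between the best and second-best
genotype, capped at 99 (the study's qualities came from an external caller,
so a proxy with the same monotonicity is used). Genotype and quality depend
only on (depth, alt count) and are computed by table lookup.

The child's reads at a DNM site are drawn once and viewed from both
references (alt count k on one, depth − k on the other), so the allelic-
balance filter is consistent across references, as it is for real reads.
Inherited indel footprints are masked with a het-like smear on all three
individuals, which removes them from candidate and callable sets; truth sets
containing rearrangements are rejected, since per-site tables assume
colinear references and no downstream consumer needs them.

What the generator does **not** emulate: read mapping and mapping bias,
linked-read barcodes, GC- or repeat-dependent coverage, indel genotyping
errors, mosaicism, and reference gaps. Passing tests therefore show the
*downstream logic* is correct under honest sampling noise, not that the
pipeline is robust to mapping artifacts in real data.

## Heterozygosity spectrum

The built-in aligner indexes unique k-mers (k = 31) of the maternal
assembly, locates them in the paternal assembly on both strands (up to 4
occurrences, so duplications are kept), and chains anchors greedily:
successive anchors must advance on both sides by at most 2 kb with a
diagonal shift of at most 50 bp. The band doubles as the small/large indel
boundary: indels ≤ 50 bp stay inside one block, larger events break the
chain and surface as junctions. Chains need ≥ 3 anchors and ≥ 100 bp.
Blocks overlapping on *both* sides (duplicate representations of one locus
pair) are resolved toward the higher-identity block; one-sided overlap is
genuine duplication signal and is kept. The aligner is for toy genomes
(≤ 50 Mb total); real assemblies enter via `show-coords -TH` or PAF tables.

Within blocks, substrings are end-to-end aligned with edlib; because
unit-cost alignments may split one indel across co-optimal paths in
repetitive micro-context, clusters of nearby events are re-aligned with
affine gap scores (match 2, mismatch −3, open −6, extend −1) so each planted
indel is reported once, and indels are then left-normalized (VCF
convention). Junction classification applies a fixed precedence — CNV >
inverted translocation > inversion > translocation > large indel: two blocks
sharing sequence on one side whose mappings disagree (different chromosome
or diagonal) are a duplication; blocks off their chromosome's main collinear
chain (a weighted longest-increasing-subsequence over query order) are
translocations; reverse blocks collinear with their neighbours are
inversions; net junction length differences > 50 bp are large indels, unless
the gap is already explained by a relocated or duplicated block.

The overall heterozygosity divides summed heterozygous bases (SNVs count 1,
indels and SVs their length, counted once regardless of carrier haplotype)
by the maternal-side aligned length. ROH detection tiles each chromosome
with 100-kb windows, marks windows at or below 5% of the genome-wide mean
SNV density, merges runs and reports intervals ≥ 1 Mb; the density cutoff is
a package default, chosen so that Poisson fluctuations of a 0.1%-
heterozygosity background (mean ≈ 100 SNVs per window) essentially never
create false windows, while true variant-free windows always pass.

SV read-validation clips 600-bp junctions around every break point on both
haplotypes, requires an edlib infix match to a local long read at > 96%
identity over > 550 bp plus > 90% orientation-aware similarity between the
two haplotypes' SV regions, and falls back to a linked-read count ≥ 5 in the
flanking region; break points within 300 bp of a contig end are unresolved.

## Site QC

π is the probability that two reads drawn without replacement from the
pileup disagree; the pair terms are products of base depths, the only
reading that makes the statistic a heterozygosity. It is permutation-
invariant in the base labels and equals 1 − Σ C(n_b, 2)/C(D, 2). The
complex-site rule is a conjunction — π > 0.4 *and* third-highest depth > 5 —
because a clean 50/50 het site already has π ≈ 0.5; ties in "third highest"
are resolved by sorted value, not label. The evidence-chain decision table
(true variant: post-polish = corrected = short; sequencing error: post =
raw ≠ corrected, short; polishing error: pre = short ≠ post; otherwise
unresolved, including any decisive N) is this package's formalization; the
classes are checked to be mutually exclusive and exhaustive over the input
alphabet. Error rates divide class counts by assayed bases (default: sites
with complete chains).

## De novo mutation rate

Candidates require parents 0/0 and child 0/1 with all filters passed on the
discovery reference; validation requires parents 1/1 and child 0/1 plus the
depth/GQ/allelic-balance filters on the other reference (the parental-
alternative-read filter targets stray alt reads in 0/0 parents and is not
applied to genuinely 1/1 parents). Site-key lift-over uses the generator's
edit-derived offsets; ambiguous positions are "unmappable" and rejected.
Default filters: GQ ≥ 20, child allelic balance in [0.3, 0.7], per-individual
depth within [0.5×, 2×] its mean, parental alt reads = 0 — conventional trio
settings, all exposed as parameters.

Callability counts sites with both parents 0/0 and all three individuals
passing depth/GQ/alt filters. α is estimated by simulation: binomial allele
sampling at the reference's depth model, conditioned on the depth filter
(which cancels between numerator and denominator), rejected by the
allelic-balance and heterozygous-call GQ filters; with filters disabled α is
exactly 0 by construction. The CI is an exact Garwood interval on the summed
count, divided by the corrected denominator. Validation applies the AB
filter on both references, but with shared child reads the two views are
complementary and the filter decides once; residual per-reference GQ/depth
losses bias μ̂ down by a few percent, well inside the Poisson CI at
realistic counts.

## Sex linkage

Peak normalization estimates the modal per-window depth as the highest bin
of a histogram with width 5% of the median (nonzero windows only); this
presumes autosomes dominate the genome, which holds for any realistic
layout. Zero-male windows take a one-read-equivalent pseudocount and ratios
are capped at 10. Scaffold calls need ≥ 10 windows and an 0.8 window
majority; terminal runs of ≥ 25 ratio-≈1 windows (band [0.7, 1.3]) on an
otherwise sex-linked scaffold are annotated PAR and excluded from the vote.
Hi-C rescue uses `scipy.stats.mannwhitneyu` (two-sided) per scaffold with
more than five strengths on both sides, Benjamini–Hochberg across scaffolds,
and requires the median Y strength to exceed the autosome/X median — the
one-sided sanity condition that keeps significantly *weaker* interactions
from rescuing. The longest rule breaks match-length ties by earlier backbone
start; every junction adjacent to a placed contig gets exactly 1,000 N.

## Strata and dating

dN/dS is Nei–Gojobori (1986): per-codon synonymous site fractions averaged
over both sequences (mutations to stop codons count as non-synonymous),
differences averaged over mutational pathways that avoid stop-codon
intermediates (all pathways if none avoids them), Jukes–Cantor correction
−(3/4)·ln(1 − 4p/3) with p ≥ 3/4 reported as NaN (saturation). The
implementation is cross-checked against Biopython's NG86 in the tests.
Strata are the optimal contiguous least-squares segmentation of dS ordered
by X position (O(n²k) dynamic program); when k is not supplied it is chosen
by a BIC-style penalty with a variance floor of 1% of the dS range, which
keeps the penalty effective when within-stratum noise is tiny. Labels run
S1…Sk by decreasing mean dS (oldest first). Pairs flagged as recent
duplications with dS below 0.02 are excluded before segmentation. Dating is
T = d/(2r); per-generation rates convert via r = μ/g, and the generation
time must be supplied explicitly.

## Problem sizes in the test suite

The recovery tests run at sizes where every check is exact or tightly
bounded: heterozygosity spectrum on a 1-Mb two-chromosome diploid, DNM
recovery on twenty 10-Mb trios, sex-linkage on a 13-Mb layout over twenty
seeds, ROH on a 30-Mb chromosome, Hi-C FDR on 1,000 null scaffolds, and
strata on 999–9,999-bp CDS. These sizes give the estimators enough events
for their nominal coverage (e.g. ~10 expected DNMs per replicate) while a
full run of the suite stays in the minutes range.

## Known limitations

* The anchor aligner assumes mostly unique sequence; heavy repeat content
  defeats unique-anchor chaining (real assemblies should come in as external
  alignments).
* Per-site tables and lift-over support colinear truth (SNVs/indels);
  rearranged references need externally provided site maps.
* α covers genotype-filter losses only; it does not model mapping-induced
  losses, which the generator does not emulate.
* The Hi-C rescue models interaction strengths as exchangeable draws; real
  contact matrices have distance decay the generator does not reproduce.
* NG86 underestimates dS under strong transition/transversion bias compared
  with maximum-likelihood estimators; the estimator hook accepts
  alternatives.
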