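# Methods

## The measurement model

A lentiMPRA reads out the regulatory activity of a test sequence through the
barcodes transcribed from its integrated copies. For barcode *b* of a
sequence with transcription rate α and allele effect *e* (log2, modern −
archaic), the generator and the estimators both assume

    DNA_{b,r} ~ NB(mean = μ_b · s_r,            dispersion = φ_D)
    RNA_{b,r} ~ NB(mean = α · 2^{±e/2} · μ_b · s'_r, dispersion = φ_R)

where μ_b is the latent copy number of the barcode (lognormal across
barcodes), s_r and s'_r are replicate library-size factors, and the negative
binomial is parameterized mean/dispersion with variance μ + φμ². The allele
effect is split symmetrically (+e/2 on the modern allele, −e/2 on the
archaic) so that the pair-level α is effect-free and stays interpretable.
φ = 0 degenerates to Poisson; the defaults φ_D = 0.3 and φ_R = 0.5 are
typical reporter-assay overdispersion levels and are configurable.

## Quantification

UMIs are collapsed by exact match (no edit-distance merging): the count for
a (sequence, barcode, replicate, molecule) key is the number of distinct
UMIs observed. The expression readout per sequence is the aggregate RNA/DNA
ratio: normalized RNA UMIs summed over barcodes and replicates divided by
the same DNA sum. Normalization divides each replicate/molecule-class total
by the geometric mean of those totals across replicates — the simplest
library-size correction consistent with "UMI-normalized" abundances; it can
be switched off (`normalize=False`) to work on raw sums, since the exact
normalization used upstream of aggregate ratios is not uniquely determined.

The transcription-rate estimate α used for activity testing is this same
normalized ratio. It deliberately replaces a nested count-GLM
quantification: the ratio estimator is fully specified, scale-equivariant,
and on synthetic data its log correlates with the true α at r ≥ 0.9 under
the default generator settings (the test suite checks this). The cost is
that barcode-level covariates are not modeled during quantification.

## Activity calling

Two independent tests against the 100 base-scrambled controls, both at
FDR ≤ 0.05:

1. **MAD-score test.** z = (α − median(α_scr)) / (1.4826 · MAD(α_scr)); the
   1.4826 consistency constant makes z comparable to a standard-normal
   z-score, so the upper-tail normal probability is used as the p-value.
   BH correction runs over all tested sequences, positive controls included
   and scrambled sequences excluded. A zero MAD raises a degenerate-null
   error rather than producing infinities.
2. **Empirical ratio test.** Scrambled controls whose ratio lies more than
   2 sample SDs from the scrambled mean are pruned once (single pass, both
   tails) — such controls likely drive some expression by chance. The FDR of
   a sequence is then the fraction of remaining scrambled ratios at least as
   high as its own; ties count against the sequence, and 0 is a permitted
   value.

A pair is **active** iff some allele reaches the MAD-score FDR threshold,
both alleles have ≥ 10 barcodes, and the pair passes the empirical test. The
empirical test is evaluated on the pair's best (highest-ratio) allele by
default; `empirical_on="allele"` requires the same allele to pass both
tests. Both conventions are exposed because the underlying rule ("FDR ≤ 0.05
in at least one sequence") does not pin down which allele the second test
applies to.

## Differential activity

For each active pair, every (allele, barcode, replicate) cell yields an
activity a = log2((RNA_norm + 0.5)/(DNA_norm + 0.5)); the 0.5 pseudocount
keeps zero counts finite and is configurable. The full linear model
`a ~ replicate + allele` is compared to the reduced `a ~ replicate` with an
F-test on one degree of freedom; the allele coefficient is the LFC
(modern − archaic). This replaces a comparative count-GLM while preserving
its nesting structure (replicate in both models, allele only in the full
one) and being fully specifiable. BH runs over the active pairs of one cell
type. Exact LFC ties at 0 are deterministically assigned direction "up" so
downstream direction tables are reproducible.

Under the generator's null (2,000 pairs, 30 barcodes, 3 replicates) the raw
p-values are calibrated (fraction < 0.05 within 3 Monte-Carlo SEs of 0.05),
and with planted effects of SD 0.26 log2 units at 100 barcodes the estimated
LFCs correlate with truth at r ≈ 0.89 with |mean bias| < 0.01 — both
recomputed by `scripts/acceptance.py`.

Cross-cell-type direction concordance uses a one-sided binomial tail at
chance 0.5 for pairs differential in exactly two cell types, and chance
0.25 (= 2 fully concordant sign patterns of 2³) for pairs differential in
all three; the two-sided chance-0.5 value for the three-cell case is
reported alongside, since both conventions appear in practice and the
package takes no position on which is canonical. Replicate sign agreement is
tested against the 2/2³ = 25% chance level. Multi-set overlaps report
`expected = N·Π(|Sᵢ|/N)` and an exact tail probability (convolved
hypergeometrics) for up to three sets, Monte-Carlo beyond.

## Motif scanning and differential binding

Position probability matrices (MEME minimal format; only *directly
determined* motifs are used for TF attribution) are regularized with a 0.01
pseudocount and converted to log2-odds against an order-0, strand-symmetric
background estimated from the scanned sequences themselves. Single-variant
pairs are trimmed to ±30 bp around the variant (the longest motif length)
before scanning; multi-variant pairs are scanned untrimmed.

The p-value of a window score is exact: scores are discretized to a bin of
10⁻³ score units (grown if needed to keep the dynamic program under 10⁵
states) and the null distribution of the total integer score is built by
convolution over motif positions. Because observed scores are discretized
identically, the DP tail equals exhaustive enumeration over all 4^L words
exactly, which the test suite and the acceptance script verify at L ≤ 8.
Hits are reported at p ≤ 10⁻⁴; q-values are BH over every position × strand
scanned for that motif in the batch (a documented stand-in for FIMO's
q-value computation, which is not specified by the upstream description).

Allele comparison matches hits on (motif, strand, offset), requires
q ≤ 0.05 on at least one allele, and fills a missing allele's score with the
lowest score reported for that motif anywhere in the batch — an
underestimate of the true difference by construction, never an overestimate.
Per TF, the motif with the largest |score difference| represents the TF.
Downstream analyses drop TFs with FPKM < 1 or fewer than 10 differential
sites, test per-TF enrichment among differentially active vs other active
pairs (Fisher, BH), correlate score differences with LFCs (Pearson), and
run a global binomial test of direction agreement at chance 0.5.

## Target genes, enrichment, and genomic context

Variants are 1-based; all interval tracks are BED-style 0-based half-open;
window endpoints are inclusive. Gene links come from eQTLs within ±1 kb of
the variant, promoter-capture Hi-C fragments and putative enhancers within
±10 kb of the variant, and strand-aware promoter windows (5 kb upstream to
1 kb downstream of a TSS, "upstream" being 5′ of the gene — a deliberate
interpretation, since the upstream convention is gene-relative). Hi-C links
are tiered stringent when cell-matched, enhancer links when "elite". Loci
with no evidence fall back to the closest TSS regardless of distance, ties
broken toward the lower coordinate, so every locus has at least one link.

Term enrichment is hypergeometric against the genes linked to *active* loci
as the universe (controlling for the composition of the active set), with a
per-term minimum gene count (3 for phenotype-ontology-like tables, 5 for
organ-level tables) applied before BH. Phenotype direction tests take the
counts (annotated, divergent, direction-matching) for one gene plus
population totals; under the null half the divergent phenotypes match by
chance, giving a one-sided binomial on the matches and a hypergeometric on
divergent-and-matching against `round(N_divergent · 0.5)` population
successes. Feature-context enrichment builds a Fisher 2×2 of (active at
each RNA/DNA cutoff in 1–3.5 vs inactive) × (overlaps feature vs not), with
sex-chromosome loci removed and BH across all feature × cutoff tests of a
run. Methylation comparisons contrast per-locus modern-minus-archaic deltas
between up- and down-regulating loci (Welch t on the paired deltas),
optionally stratified by promoter / CpG-poor-promoter / enhancer context
(CpG density = CpG dinucleotides per window base, CpG-poor = bottom half).
Group mean comparisons (PhyloP, distances to TSS/eQTL) use Welch t-tests
with BH across the comparisons in one call.

## The synthetic-data generator

The generator emulates the study design: allele pairs plus 100 scrambled and
~300 positive controls, a target median of 96 barcodes per sequence (drawn
from a ≥1-truncated negative binomial whose mean is calibrated analytically
— by bisection on the truncated CDF — so the median hits the target), three
replicates of RNA and DNA, and the count model above. Activity truth is
spike-and-slab: 13% of pairs active (α multiplied by 3), 23% of those with a
nonzero allele effect drawn from N(0, 0.26²) — 0.26 log2 units being a 1.2×
fold change, the typical reported effect magnitude; all other effects are
exactly 0. Association reads get configurable rates of promiscuous,
low-support, low-quality, and discordant records; with all rates at zero the
association and counting stages recover the truth exactly (verified). All
randomness descends from a single seed through fixed per-operation streams,
so identical configurations give byte-identical outputs.

What the generator does **not** emulate: sequencing errors at base level,
barcode/UMI sequencing errors (so exact-match UMI collapsing is lossless by
construction), lentiviral integration-site effects, cell-type-specific
trans environments, correlated chromatin structure among loci, and linkage
between nearby variants. Passing tests therefore demonstrate the internal
correctness and calibration of the procedures under the stated model, not
robustness to those real-data artefacts.

One behavioural consequence of the truth model: true α values carry
lognormal jitter (SD 0.15) shared with the scrambled controls, so the upper
tail of "inactive" pairs genuinely overlaps the null. Pair-level precision
of the active call is therefore ~75–80% at desk scale rather than 95%,
while the all-null false-positive rate stays below nominal — both are
asserted as such in the tests.

## Numerical and design choices

- Filters are conjunctive; attrition reports attribute each removal to the
  first rejecting filter in the documented order.
- Repeat fraction = repeat-covered bases / 200 after merging overlapping
  repeat intervals.
- The reference is assumed to carry the ancestral allele (switchable), since
  both alleles must be constructible either way.
- Promiscuity of barcodes is assessed *after* the read-quality filters; a
  barcode whose second-oligo evidence consists only of filtered reads is not
  promiscuous. No majority-vote rescue.
- Barcode-read exactness (CIGAR/MD identity of the 15-mer) is represented by
  the all-bases-Q30 filter only; alignment-string checks belong to the
  aligner layer, which this package consumes rather than runs.
- The scrambled prune runs once, not iteratively.
- MAD = 0, empty backgrounds, all-pruned nulls, <2 replicates, and
  zero-variance fits raise typed errors instead of returning numbers.
- The SATB2-style hypergeometric: for the published parameterization
  (population 696, successes 217, draws 17, observed 12) the upper tail is
  8.4×10⁻⁴; the package reports this value for the stated parameters rather
  than tuning to any other figure.

## Problem sizes

Test-suite and acceptance-script simulations run at desk scale chosen for
statistical resolution per check: 2,000 pairs × 30 barcodes for null
calibration (binomial SE ≈ 0.005 on a 0.05 rate), 300 pairs × 100 barcodes
for effect recovery, 4^8 words for the PWM oracle, 1,000 vectors for the BH
oracle, and ~100–200 pairs for end-to-end round trips. The full suite and
the acceptance script each complete in about a minute on one CPU.
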