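# Methods

## Bisulfite conversion model

Sodium bisulfite deaminates unmethylated cytosine to uracil (sequenced as
T); 5-methylcytosine is protected. We model methylation at plus-strand CpG
cytosines only (non-CpG methylation, rare in vertebrate somatic tissue, is
off by default but explicit flags may opt in per position). Conversion of
the original-top (OT) strand is C→T at every cytosine not flagged
methylated; the original-bottom (OB) strand appears on the plus-strand view
as G→A at every guanine not paired with a methylated CpG. A conversion
*failure* leaves an unmethylated C unchanged and is applied stochastically
at rate `conversion_failure_rate`; all analytical paths (COBRA prediction)
use failure 0, only the simulator draws failures.

## COBRA informativeness

Digestion is evaluated on the plus strand of the converted template
(bisulfite PCR products are effectively single-sequence amplicons;
double-strand evaluation is available by converting the OB strand).
All IUPAC matches — including overlapping ones — contribute a cut at
`position + cut_offset`; duplicate cuts collapse and cuts at the ends of a
linear template do not cleave. An enzyme is *informative* when the
fragment-length multisets of the fully-methylated and fully-unmethylated
conversions differ. Because the unmethylated conversion retains no C at
all, and the methylated conversion retains C only at CpGs, informativeness
always traces to a site overlapping a CpG cytosine — sites whose IUPAC sets
never separate C from T can never be informative, a property the test suite
checks by brute force. Observed gel patterns are classified against the two
predictions with a per-fragment length tolerance of ±5% (typical agarose
resolution); matching both or neither yields "ambiguous".

The shipped default panel (TaqI/TaqαI, BstUI, HpyCH4IV, MspI, HhaI, MseI)
covers the common CpG-overlapping four-cutters plus one deliberately
non-CpG control enzyme; it is extensible via a tab-delimited enzyme file.

## CpG island detection

We use the Gardiner-Garden & Frommer criteria — span ≥ 200 bp, GC ≥ 0.5,
Obs/Exp CpG = count(CG)·N/(count(C)·count(G)) ≥ 0.6 — because they underlie
the common browser island tracks; all three thresholds are exposed.
Detection scans fixed windows (default 200 bp, step 1); windows containing
any non-ACGT base are disqualified. Overlapping or adjacent qualifying
windows merge, and each merged span is re-tested on its exact extent; a
failing span is trimmed one base off *both* ends per round until it
qualifies or falls below the minimum length. Symmetric trimming makes the
island set exactly mirror-invariant under reverse complement (CpG is its
own reverse complement), which the suite verifies; it can overshoot the
maximal qualifying sub-span by at most one base per round relative to
single-sided trimming. Obs/Exp with a zero denominator is defined as 0.
Every emitted island satisfies all three thresholds when recomputed on its
exact span, and the whole scanner is checked against an exhaustive
all-windows brute force.

Coordinates are 0-based half-open everywhere internally; 1-based positions
appear only in the count-table I/O formats. Gene bodies are the transcribed
span (5'UTR + exons + introns + 3'UTR); an island is a gene-body island iff
it overlaps ≥ `min_overlap` bp (default 1) of some gene body.

## Clone analysis

Clones are aligned globally (affine gaps) to the *untreated* reference
region under an asymmetric substitution scheme: any equality scores +2, and
reference-C vs clone-T also scores +2, so conversion is never penalised;
clone-C vs reference-T scores −3 (a C where the reference has none signals
error, not methylation); gap open −5, extend −2. The alignment engine is
Biopython's `PairwiseAligner` with this matrix; orientation is chosen by
best-of-two score against the clone and its reverse complement (ties →
forward). Calls: reference CpG C aligned to C → methylated, to T →
unmethylated, to a gap or any other base → ambiguous (excluded from
fractions). The conversion rate is the fraction of covered non-CpG
reference Cs read as T (defined as 1.0 when the region has none), and
identity is computed over aligned columns excluding end gaps, counting the
C↔T case as a match. QC defaults (conversion ≥ 0.95, identity ≥ 0.90)
follow common clone-bisulfite practice; both thresholds are parameters.
Lollipop matrices map calls to filled/open/missing cells; per-column
methylation fractions are filled/(filled+open).

## Differential methylation

Per-site tables (chrom, 1-based pos, strand, methylated count, unmethylated
count, context; a Bismark cytosine-report dialect is accepted) are filtered
to sites with total coverage ≥ 10 in *both* conditions — we read the
coverage gate at the level of individual covered cytosines, the natural
granularity of a cytosine report (replicates for a condition are summed
first). Retained sites inside each gene body are pooled: x = Σ converted
(unmethylated) reads, n = Σ total reads. The pooled two-proportion z-test
compares conversion ratios between conditions; z² equals the Pearson
chi-square of the 2×2 table without continuity correction (verified to
1e-9 relative tolerance), and a degenerate pooled proportion (0 or 1)
returns z = 0, p = 1 by convention. No continuity or multiple-testing
correction is applied by default — significance is a raw p < 1e-4
threshold, with Benjamini–Hochberg available behind a flag. Reports show
both the conversion ratio and the methylated fraction (1 − ratio), with
the effect described as the delta and fold change of the methylated
fraction.

## Synthetic data generator

The generator emulates the screen's study conditions with exact planted
truth. Each of `n_genes` genes is a three-exon model (5'UTR inside exon 1,
3'UTR inside exon 3) with a 300 bp CpG-dense island planted mid-intron-1;
one designated target gene's island is methylated at 0.8 in condition A and
0.2 in condition B (an intron-1 island hypomethylated when its de novo
methyltransferase is lost), while every other CpG has identical
probabilities in both conditions (islands 0.8, background 0.05).
Background sequence is i.i.d. at 45% GC with one-pass CpG depletion
(each CG destroyed with probability 0.8), matching the CpG-poor character
of vertebrate genomic background and suppressing spurious islands; island
cores are token streams emitting CG with probability 0.35 (GC ≈ 0.7,
Obs/Exp ≈ 2). Islands shorter than 200 bp are rejected at configuration
time because they cannot satisfy the island criteria.

RRBS libraries are emulated as a simultaneous MspI + TaqαI double digest
(fragments bounded by the union of cut sites) followed by inclusive
100–350 bp size selection; only CpGs on retained fragments receive
coverage. Planted islands are anchored by an MspI site at each end and
internal MspI/TaqαI sites are scrubbed from the core, so each island maps
to a single fragment of island length − 4 between the anchor cuts — this
keeps the planted truth's coverage unambiguous under size selection while
remaining faithful to why RRBS enriches CpG islands in the first place.
Coverage per covered CpG is zero-truncated Poisson with mean
`mean_coverage` (the simplest defensible count model); the methylated read
count is Binomial(coverage, p + (1−p)·failure) with failure defaulting to
0.005 — a plausible bisulfite failure rate, exposed in the configuration
since real efficiencies vary. Clone reads are OT-strand conversions of a
region under per-clone CpG states drawn Bernoulli from the profile, with
conversion failures at non-CpG cytosines only (CpG read states are drawn
explicitly) and optional uniform substitution errors.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawn keys, one stream per stage (reference, counts A, counts B, clones),
so identical configurations give byte-identical outputs.

What the simulator does *not* model: read-level errors and qualities, PCR
duplication and amplification bias, non-CpG methylation (off by default),
strand-split counts (tables carry collapsed plus-strand CpG sites), CNV or
mappability structure, and biological replicate variability beyond binomial
sampling. Passing tests therefore demonstrate the correctness of the
pipeline's computations under binomial sampling with known truth — not
robustness to the technical artifacts of real libraries.

## Problem sizes and operating characteristics

The suite's operating-characteristic checks use simulation sizes chosen to
make the statistical assertions sharp while keeping the whole suite quick:
the null calibration uses one 2,000-gene genome at 15x mean coverage
(type-I error at α = 0.05 within 3 binomial standard errors), power uses
200 independent two-gene replicates of the 0.8→0.2 target contrast at 15x
(≥ 95% of replicates flagged at p < 1e-4), and monotonicity of power in
effect size and coverage is checked on a 3×3 grid (Δ ∈ {0.03, 0.10, 0.30} ×
coverage ∈ {5, 15, 40}) with 60 replicates per cell and a 0.05 Monte-Carlo
allowance on the non-decrease comparisons.

## Known limitations

- The island scanner's windowed scan cannot detect islands shorter than the
  window; the default window equals the minimum island length.
- Global alignment penalises end gaps, so clones must span (approximately)
  the whole PCR region, as simulator clones do; partial reads would need
  end-gap-free scoring.
- Gene-body pooling assigns a site inside two overlapping gene bodies to
  both genes; the per-gene tests are then not independent.
- The two-proportion z-test inherits the normal approximation: genes with
  very few pooled reads (n of a few dozen) have discrete p-values and
  conservative-to-liberal calibration at extreme proportions; the
  degenerate-table convention (p = 1) is deliberately conservative.
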