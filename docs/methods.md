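# Methods

`scarsig` implements a pipeline for detecting homologous-recombination (HR)
deficiency in tumor/control sequencing data: supervised mutational-signature
decomposition, allele-specific copy-number / purity / ploidy estimation,
genomic-scar scoring, and HR-gene biallelic-event classification. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic-data experiments do and do not demonstrate.

## Mutational catalogs

Somatic SNVs are binned into the canonical 96 channels: six pyrimidine
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 16
flanking-base combinations. Purine-reference records are reverse-complemented
into the pyrimidine frame before lookup, so both strand encodings of a
mutation land in one channel. Records containing an ambiguous base (N) have
no defined channel; they are dropped and counted in the log.

Catalogs observed on a restricted target (e.g. exome capture) are corrected
for triplet-motif composition before decomposition against genome-derived
signatures: each channel count is multiplied by the ratio of the target
triplet frequency in the destination region set to that in the source set.
Frequency tables cover the 32 pyrimidine-centred triplets and are normalised
to sum to one; triplets absent from a region set receive a half-count
pseudo-frequency so correction ratios stay defined (ratios among observed
triplets are unaffected). The default correction direction is exome →
genome.

## Supervised signature decomposition

A sample's catalog column v is modelled as v ≈ W h, h ≥ 0, where W holds the
known signature probability vectors; h is fitted by non-negative least
squares (scipy's active-set solver). To improve specificity the fit runs
twice: after the first pass, signatures whose relative exposure h_k / N
(N = the sample's mutation count) falls below a signature-specific cutoff are
discarded, and the reduced set is refitted. Cutoffs act on relative
exposures, so they are scale-free; the packaged default table carries the 30
per-signature values (AC1–AC30 layout) calibrated by ROC analysis on 7042
reference tumors. A generic calibrator is also provided: given presence
labels it sweeps thresholds over first-pass relative exposures and returns
the maximiser of Youden's J (ties to the smaller threshold; best-J below 0.1
is flagged uninformative, a pragmatic default since near-zero J means the
labels carry no threshold information).

### Profile-likelihood confidence intervals

For a retained signature k, the exposure is fixed at a perturbed value
h_k = Ĥ_k + δ, the remaining retained exposures are refitted by NNLS on
v − h_k w_k, and residual log-likelihoods are computed under a zero-mean
Gaussian whose variance is the mean squared residual, re-estimated separately
for each model and floored at 1e-6 to avoid degenerate perfect fits. The
likelihood-ratio statistic D(δ) = 2(ℓℓ_initial − ℓℓ_alternative), clamped at
zero, is referred to a χ²(1) tail; the interval limits are the perturbations
where that tail probability equals (1 − level)/2, i.e. 0.025 per side at the
95% level (deviance threshold ≈ 5.02). Limits are found by geometric bracket
expansion plus Brent root-finding (tolerance 1e-4 mutations); bracketing is
guaranteed on a bounded interval, the lower limit is clamped at zero and an
upper limit that never reaches the threshold within [0, N] is reported at the
boundary with a flag.

**Known limitation.** The Gaussian residual likelihood is homoscedastic,
while multinomial counting noise has per-channel variance proportional to the
channel probability. For peaked signatures this understates the uncertainty
carried by the informative channels and the intervals under-cover: on
synthetic catalogs (N = 1000, three of ten Dirichlet(0.3) signatures active)
empirical 95% coverage is ≈ 0.80, whereas the identical procedure on
homoscedastic Gaussian-noise catalogs covers at ≈ 0.94 and flatter
signatures (Dirichlet concentration 1–3) cover at 0.90–0.94. The acceptance
suite asserts the nominal band and this assertion fails by design rather
than being widened; interval users should treat CIs on strongly peaked
signatures as optimistic.

### Per-Mbp normalisation and enrichment

Absolute exposures divided by the sequencing-target size (Mbp) make exome and
genome samples comparable. Cohort-versus-background detection counts per
signature are compared by two-sided Fisher exact tests with
Benjamini–Hochberg correction across signatures; the per-sample "detected"
criterion defaults to retained-after-two-pass with nonzero exposure, with
CI-excludes-zero available behind a flag.

## Purity, ploidy and allele-specific copy numbers

With tumor cell content ρ and tumor ploidy ψ, a segment of total copy number
TCN has expected tumor/control coverage ratio

    r = [ρ·TCN + 2(1 − ρ)] / [ρ·ψ + 2(1 − ρ)]

and an imbalanced segment with allele copy numbers CN_A ≤ CN_B has major
B-allele frequency

    b = [ρ·CN_B + (1 − ρ)] / [ρ·TCN + 2(1 − ρ)].

SNPs are heterozygous when the control alternative-allele fraction lies in
[0.3, 0.7] (bounds inclusive; the spec's inclusivity convention is tested at
the boundaries). Segments need at least 20 het SNPs to enter the fit.
Balance classification uses a Gaussian kernel density (absolute bandwidth
0.03) over the tumor alt-fraction distribution on a 501-point grid, with
peaks from `scipy.signal.find_peaks` at prominence ≥ 10% of the maximum:
a global maximum in [0.45, 0.55] is balanced, two or more peaks off-centre
imbalanced, one off-centre peak ambiguous; ambiguous segments are dropped.
The mean major-allele BAF uses the higher-read-count allele per SNP (ties
contribute 0.5), so b ≥ 0.5 by construction.

The (ρ, ψ) fit inverts the two relations on a grid — ρ ∈ [0.15, 1.0] step
0.01, ψ ∈ [1.0, 6.5] step 0.05 (the ranges are fixed; the steps resolve them
finely at trivial cost) — and scores each candidate by the
segment-length-weighted mean distance to the nearest allowed integer state:
|TCN − nearest even| for balanced segments, the mean of the two allele
distances (nearest non-negative integer) for imbalanced ones. Candidates
implying a negative copy number or a decrease of heterozygosity
DH = (2b − 1)·[ρ·TCN + 2(1 − ρ)]/(ρ·TCN) above one on any segment are
excluded (tolerance 1e-9). All grid-local minima (no worse than their ≤ 8
feasible neighbours) are returned ranked by distance; rank 1 is selected,
replacing visual inspection, and the full distance surface is emitted for
plotting. The (ρ, ψ) ↔ (c·ρ', ψ') lattice degeneracy inherent to this class
of estimators is visible as near-zero-distance alternative candidates; ties
resolve toward smaller ρ, then smaller ψ.

An independent purity estimate is taken from somatic SNVs on copy-neutral
(1,1) segments: clonal heterozygous variants there have expected VAF ρ/2, so
ρ_SNV = 2 × median VAF, capped at 1, requiring ≥ 10 qualifying SNVs. A
manual override (as used for low-purity samples) replaces the selected ρ and
recomputes segment copy numbers, with provenance recorded.

## Genomic-scar scores

Profiles are smoothed before counting: iteratively, the smallest segment
under 3 Mbp merges into the same-chromosome neighbour with the smaller total
copy-number difference (ties left); the absorbing segment keeps its state and
extends its span; a sub-threshold segment alone on a chromosome is retained.
Smoothing is idempotent.

- **LST**: a switch between the copy-number states of two adjacent segments,
  each larger than 10 Mbp, counts — unless the breakpoint separates two
  entire chromosome arms, operationalised as breakpoint within 1 Mbp of the
  centromere interval with each flanking segment covering ≥ 95% of its arm
  (both tolerances configurable). States default to the allele-specific pair
  (CN_A, CN_B), which captures copy-neutral LOH transitions; a flag restricts
  to total copy number. Intervening 3–10 Mbp segments break adjacency: no
  switch is counted across them (strict-adjacency reading, configurable by
  pre-filtering).
- **HRD-LOH**: LOH segments (minor allele copy number zero, total ≥ 1)
  larger than 15 Mbp count unless they cover ≥ 95% of their chromosome
  ("subchromosomal" needs a threshold; 95% is configurable).
- The combined instability score is their sum.

Copy-number states are compared after rounding to integers, since fitted
values are real-valued.

## HR-gene events and the paired look-up

A (likely) pathogenic germline variant (ACMG class ≥ 4, consumed as an input
label, never computed) plus a somatic second hit — wild-type-allele deletion,
copy-neutral LOH, or a somatic point mutation — is classified
biallelic-germline-somatic; two somatic hits are biallelic-somatic; one hit
is monoallelic. A biallelic copy-number loss reported together with retained
heterozygous SNPs at the locus is flagged inconsistent. Germline variants can
additionally be tested for tumor-versus-control allele-fraction enrichment
(two-proportion z-test at the 5% level, indeterminate below 20× coverage),
the expected footprint of wild-type-allele loss.

The paired-biopsy look-up merges variant keys (chrom, pos, ref, alt) from two
samples, drops rows under 20× coverage in either sample and germline-flagged
rows, and classifies the rest: shared when both samples show ≥ 2 alternative
reads (a configurable guard against sequencing error), otherwise private to
the supporting sample. Shared + private-A + private-B partition the retained
rows exactly, and swapping the tables swaps the private classes.

## The synthetic cohort generator

All downstream stages are tested against generated data with recorded truth.
Signature columns are symmetric-Dirichlet draws over the 96 channels
(concentration 0.3 by default — peaked, signature-like columns; larger values
give flatter shapes). Catalog columns are multinomial draws of exactly
N mutations from the mixture W h / |W h|₁, with burdens defaulting to the
modest 40–500 SNVs/sample range of the tumors the pipeline targets. Mutation
records are emitted on a random strand to exercise strand collapsing, and
rebuilding catalogs from records is an exact round trip.

Copy-number profiles follow the mixture model above: per-segment ratios carry
additive Gaussian noise (σ = 0.02, matching typical exome ratio scatter), and
het-SNP allele counts are exact binomial draws at the configured depth
(default 100×, with a 10% homozygous-SNP admixture for het-calling tests); a
noise-free mode emits exact expected fractions for closed-form recovery
tests. Het-SNP density defaults to 5/Mbp — a thinned stand-in for real SNP
density, sufficient to put ≥ 20 het SNPs on every multi-Mbp segment.
Tumor ploidy is the length-weighted mean copy number of the simulated genome
and is recorded as truth. Paired-biopsy tables emulate a joint re-genotyping
look-up (both samples carry counts for every merged variant); carrier samples
are floored at two supporting reads and non-carriers capped at one noise
read, so truth classes are exactly recoverable. All randomness flows from one
integer seed through per-sample `SeedSequence` spawns, making outputs
bit-identical for a fixed configuration.

What passing these tests does **not** show: the generator has no sequencing
errors or mapping artifacts, no subclonal copy-number states, no
signature-profile uncertainty (the true W is supplied to the fit), and its
segments are exact — real exome data adds segmentation error, GC and capture
biases, and germline contamination that the pipeline does not model.

## Problem sizes in the test and acceptance runs

Simulation-based checks use 200 catalog replicates at N = 1000 mutations
(3 of 10 signatures active), 20 noisy copy-number profiles on the packaged
3-chromosome toy genome (60/90/120 Mbp), 500 random segment profiles for the
scar-score oracle comparison, and 11-sample cohorts for the end-to-end
detection rates — sizes chosen to make Monte-Carlo rates stable at a few
percent while keeping a full run in minutes on one core.
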