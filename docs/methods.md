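# Methods

## The measurement problem

Gene amplification is hard to call from plasma cfDNA because tumour-derived
fragments are a variable, often small, fraction of a mostly normal-genome
pool. The approach implemented here quantifies the AR gene against reference
genes by droplet digital PCR, with *two independent multiplexed assays* that
cross-validate each other: AR-Amp-1/T877A reads AR exon 8 (mutant and
wild-type probes, so the same reaction types the T877A point mutation)
against chromosome-10 RPP30; AR-Amp-2 reads AR exons 1 and 2 against two
references, X-chromosomal MYM (ZMYM3) and chromosome-6 TBP. Three AR loci and
three reference genes between the two assays guard against locus-specific
artefacts (e.g. reference-gene instability in tumours, fragment
over/under-representation in cfDNA).

## Poisson quantification

A reaction is partitioned into n droplets of volume V (defaults: n = 20,000,
V = 0.85 nL — instrument nominals, both configurable). Template molecules
load droplets independently, so the count per droplet is Poisson with mean
λ = cV where c is the concentration in copies/µL. From the positive fraction
p̂ = n⁺/n:

    λ̂ = −ln(1 − p̂),   ĉ = λ̂ / V

The default 95% CI propagates the normal approximation on p̂ through the log
transform, λ_bounds = −ln(1 − (p̂ ± 1.96·√(p̂(1−p̂)/n))) — the convention of
instrument software; exact Clopper–Pearson inversion is available via
`ci_method="clopper-pearson"` (differences are negligible at n ≈ 20,000).
A fully positive well has undefined λ and raises a saturation error naming
the target rather than returning a guess. Replicate wells are merged by
pooling positives and totals before correction, which is the maximum-
likelihood merged estimator when volumes match (enforced).

Concentrations are per µL of *reaction*; conversion to per-µL-of-plasma
needs extraction/elution volumes the caller must supply explicitly.

## Amplitude model and gating

Amplitude multiplexing puts several targets on one optical channel at
distinct probe-concentration-tuned intensities. The simulator and the gating
model share the same geometry: a droplet's channel amplitude is baseline +
the *sum* of the single-positive levels of its positive targets in that
channel (combination droplets stack additively), plus Gaussian read noise;
an optional saturation cap compresses the top bands; "rain" (partial
amplification) rescales a configurable fraction of positive droplets
uniformly toward baseline and defaults to 0 so that calibration tests are
sharp.

Gating reproduces manual threshold-setting deterministically. Band centers
come from controls — negatives plus one single-positive population per
target (simulator truth labels when available, otherwise per-channel 1-D
k-means with one cluster per expected level). All 2^k subset-sum bands per
channel are enumerated; cut points sit at midpoints between adjacent
centers. Checks: a channel whose adjacent bands are closer than 4 pooled
noise SDs is rejected as inseparable (the built-in default levels give
≥ 25 SD separation); controls missing a population are rejected rather than
guessed at. Droplets in a band cell with no label (possible only with
user-supplied partial gate maps) are assigned to the nearest expected center
and flagged but *kept in the denominator* — dropping them would bias the
Poisson negative fraction. Combination droplets count once toward every
member target's positive count.

## Copy-number calling

With per-target concentrations in hand:

* AR-Amp-1/T877A: `AR CN = (WT + MT)/RPP30 × 2`
* AR-Amp-2: `AR CN = (AR-X1 + AR-X2)/(MYM* + TBP) × 2`, `MYM* = 2×MYM` for
  male samples. A normal male genome has one X, hence one MYM allele; the
  doubling puts the X-chromosomal reference on the diploid scale so that
  normal male and female genomes both read the references as "2 per genome".
  The generic `ar_copy_number` expresses the same rule for any design by
  rescaling each reference by 2/alleles-per-normal-cell(sex).
* Chromosome X: `Chr X CN = 2 × MYM/TBP` with *raw* MYM. Only the raw
  reading makes the formula self-consistent: a normal male then reads ~1 and
  the threshold of 2 corresponds to a genuine doubling. The quantity is
  calibrated for male samples; female input warns and reports as computed.

CN values are concentration ratios and therefore invariant under global
rescaling of the inputs (tested as a property). Amplification is called at
CN ≥ 2, boundary inclusive — the stated threshold is itself a positive
call. The threshold is deliberately conservative: it sits well above the
healthy-control range so specificity is protected at some cost in
sensitivity to low-level gains. A consequence surfaced by the worked
analyses: a normal female genome (true CN exactly 2) sits *on* the
threshold, so its call is noise-dominated — the screen is calibrated for
male cfDNA.

T877A is reported as mutant fraction MT/(MT+WT) (undefined when both are
zero) and "detected" requires ≥ 3 mutant-positive droplets — a pragmatic
floor against isolated false-positive events, config-exposed, standing in
for a formal limit-of-blank procedure. Cross-assay concordance reports both
CN values, the agreement of the amplification flags and their relative
difference; discordant samples are surfaced for review, never silently
resolved, because the two assays exist to confirm each other.

## Cohort statistics

* Healthy-control summary: min/max/mean and SEM (sample SD, n−1); the
  suggested threshold is max(2, healthy max rounded up to one decimal).
* Fisher's exact test: two-sided p as the sum of hypergeometric point
  probabilities ≤ the observed table's, with fixed margins (scipy's
  convention; verified in tests against exhaustive rational-arithmetic
  enumeration over *every* 2×2 table with grand total ≤ 40). The sample
  odds ratio (ad)/(bc) reports ∞ and NaN edge cases explicitly.
* Mann–Whitney: exact null for min(n) ≤ 8 without ties (verified against
  full permutation enumeration), tie-corrected normal approximation with
  continuity correction otherwise.
* Pearson r with a t-distribution p on n−2 df.
* Treatment association tables call a sample amplified only when *both*
  assays agree; discordant samples and samples missing treatment flags are
  excluded and counted, with a warning for the latter.

## The synthetic cohort

`simulate_cohort` emulates the study conditions end to end: 7 healthy male
controls (true CN ~ N(1.08, 0.16)), 16 hormone-sensitive and 31
castration-resistant patients; 9 CRPC patients carry true AR CN drawn
log-uniformly over 4–48-fold, the rest sit in the healthy-like band
(N(1.15, 0.22), clipped to ≤ 1.92); two HSPC patients carry T877A at 30% of
their AR copies; the highest-CN patient also carries a chromosome-X gain
placing Chr X CN at 4.3; one CRPC record lacks treatment information, and
the remaining 30 get treatment flags in fixed blocks so the association
margins (12 chemo⁺/18 chemo⁻, 14 ADT⁺/16 ADT⁻, 4 both) are set by design.
Per-sample cfDNA abundance is log-normal around ~35 genome equivalents/µL
— the dominant driver of per-sample measurement noise. Every sample is
measured by both assays on independent simulated 20,000-droplet wells with
gates derived from simulated controls.

What the generator does *not* emulate: tumour-fraction mixture structure
(the per-genome copy profile is the aggregate dosage directly, not a
normal/tumour mixture), linkage between nearby amplicons on the same cfDNA
fragment (all targets load independently — defensible because cfDNA
fragments are ~170 bp and the amplicons are tens of kilobases apart),
inter-well pipetting variation, rain and baseline drift (off by default),
and reference-gene instability. Passing calibration tests therefore
demonstrate correctness of the *analysis* under the stated measurement
model, not robustness to every failure mode of real cfDNA runs.

The X-gain patient is a designed cross-assay discordance: elevating MYM
depresses the AR-Amp-2 CN relative to AR-Amp-1 for that sample. Correlation
calibration therefore uses cohorts with the gain disabled
(`chrx_gain=None`), where the two assays share true CN exactly; the default
cohort keeps the gain, which is why its cross-assay r (~0.92) is slightly
below the shared-CN value (~0.999).

## Numerical and design choices

* Channel naming is fixed CH1 = FAM, CH2 = HEX (QX200 convention).
* Simulator default amplitude levels (e.g. AR-Amp-2 FAM bands at 4000/9000
  over baseline 1000, noise SD 120) were chosen once to keep all subset-sum
  bands ≥ 5 noise SDs apart, mirroring the clean cluster separation the
  assays were optimised for; they are free parameters of the assay config.
* Reported CN uses round-half-up (integer for pure samples, one decimal for
  sub-10 mixture values); raw CN is always retained at full precision.
  Published worked-example ratios were rounded by the original analysts from
  unprinted raw readings, so recomputation from printed concentrations can
  differ in the last printed digit; comparisons are made at printed
  precision.
* Problem sizes in the test-suite calibration checks (50 wells for CI
  coverage, 10 seeded cohorts for correlation, 20 seeds for occupancy laws)
  were chosen as the smallest runs that make the nominal rates statistically
  sharp.
* Degenerate inputs fail loudly and specifically: saturated wells, zero
  reference signal, inseparable bands, missing control populations,
  all-zero contingency tables, constant correlation inputs.

## Known limitations

* The amplification threshold and Chr X dosage have no validated female
  interpretation; female inputs are accepted with warnings.
* Gating assumes the additive band model; heavily rained or compressed wells
  need the manual-gate path (fully unsupervised 2-D clustering of dirty
  wells is out of scope).
* Mutation detection uses a fixed droplet-count floor, not a
  limit-of-blank calibrated per run.
* Per-µL-of-plasma conversion, AR splice variants and survival analysis are
  out of scope.
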