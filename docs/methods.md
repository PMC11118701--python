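# Methods

This note documents the models, parameter choices and numerical rules the
package implements, what the synthetic generators do and do not emulate,
and the design decisions taken where the underlying analysis left the
choice open.

## Coordinate conventions and the arm table

All internal coordinates are 0-based, half-open. SEG input is read as
1-based inclusive (the common SEG convention), BED as 0-based half-open;
each reader documents its dialect and the writer round-trips exactly.

The bundled arm table is GRCh38: 22 autosome lengths with centromere
(acen) boundaries from the UCSC cytoband track, giving 39 arms after
excluding the p arms of the acrocentric chromosomes 13, 14, 15, 21 and 22,
which carry no assembled unique sequence. Sex chromosomes are excluded
from all metrics: tumor/normal copy-number behavior on X/Y depends on
patient sex and is not modeled here. Users may substitute any BED4 arm
table.

## Segment reduction and ploidy

Mean ploidy is the length-weighted mean of total copy number. The integer
median ploidy is the length-weighted median with two fixed tie rules: when
the cumulative length reaches exactly 50% at a value boundary the lower
value is taken (conservative toward the less aberrant state), and halves
round up. Arm states are the length-weighted *mode* of the integer
(major, minor) states intersecting the arm — a mode rather than a mean so
that integer allelic states are preserved — with ties broken toward the
lower total copy number. Segments straddling a centromere are split at the
arm boundary and contribute their overlap to each side. Arms with no
overlapping segment default to diploid (1, 1) and are flagged uncovered:
absence of evidence must not create aberrations, and sparse exome
segmentations remain analyzable.

## The WGD randomization test

The null asks whether the observed fraction of arms with major allele copy
number ≥ 2 is explainable by random sequential unit aberrations rather
than a doubling event.

* **Nₛ** counts unit steps, Σ(|major−1| + |minor−1|): the null applies
  *sequential* aberrations, and a (3, 1) arm needs two sequential gains to
  arise, so the unit-step count is the internally consistent reading.
* **Pₛ** weights each (arm, allele, direction) by the fraction of samples
  deviating from 1 in that direction, adds one pseudo-count spread
  uniformly over all events (so quiet cohorts yield a proper uniform null
  rather than a degenerate one), and normalizes. Both per-sample and
  cohort estimation are supported; the choice is an explicit argument
  (`wgd_test(..., cohort=...)`), never a silent default, because the two
  modes give different nulls for heavily aberrated samples.
* **Simulation.** Each of the (default) 10,000 simulations starts all arms
  at (1, 1) and applies Nₛ i.i.d. events from Pₛ. A loss drawn for an
  allele already at 0 is re-drawn from Pₛ, up to 5 retries, then treated
  as a no-op, so copy numbers never go negative. The per-simulation
  statistic is the fraction of arms whose larger allele reaches ≥ 2.
* **Counting rule.** The p-value counts simulations with statistic ≥ the
  observed value. A strict-exceedance mode exists but is not the default:
  under strict counting an all-diploid sample (observed 0, all simulated
  statistics 0) would get p = 0 and be called WGD, which inverts the
  test's meaning for quiet precursor lesions. A (k+1)/(n+1) correction is
  available for users who prefer a never-zero estimate.
* **Classification.** WGD iff mean ploidy > 3, or ploidy ≤ 3 and
  p < 0.001. The ploidy branch does the work for heavily doubled genomes
  (ploidy ≈ 4); the randomization branch covers doubled-then-lost genomes
  near triploidy.

**Exact oracle.** `exact_null` enumerates the same process by dynamic
programming over arm states. The re-draw rule is folded in analytically:
at a state where the invalid (loss-at-zero) probability mass is q, a valid
event e has effective per-step probability p·(1−q^(R+1))/(1−q) and the
no-op has mass q^(R+1), with R the retry bound — so the enumeration is
exact for the Monte-Carlo process, not a no-op approximation. It is
feasible when (4·A)^Nₛ is small (toy genomes); the test suite uses it to
calibrate the Monte-Carlo null to within 3 Monte-Carlo standard errors on
a 4-arm genome across Nₛ ∈ {1,…,6}.

## CIN metrics

* **wGII** averages, over the autosomes in the arm table, the fraction of
  covered length whose rounded total copy number differs from the integer
  median ploidy. Averaging per chromosome (each chromosome weighted
  equally, length weighting *within* chromosomes) is the established wGII
  construction; comparing rounded integer CN against integer ploidy avoids
  float-equality artifacts, and makes the index ploidy-relative: a uniform
  tetraploid genome scores 0. Chromosomes with no covered length
  contribute 0 and are flagged.
* **SCNA burden** uses strict thresholds (total CN > 2.5 gain, < 1.5
  loss) over the evaluable region; segments under 50 supporting reads are
  excluded from numerator and denominator alike. When read counts are
  absent, filtering must be disabled explicitly (`min_reads=None`) rather
  than silently skipped.
* **Aneuploid chromosome count** is an arm-level proxy: a chromosome
  counts as aneuploid when any arm's total allele copy number differs from
  the integer median ploidy. The original analyses derive this from a
  mosaic allele-frequency mixture model on heterozygous loci; that model
  consumes raw allele counts which this package does not ingest, so no
  numeric equivalence with mixture-model counts is claimed — the proxy
  preserves the quantity's meaning (how many chromosomes deviate), not its
  estimator.
* **Gene calls** summarize a gene's copy number as the length-weighted
  mean of overlapping segments (the summarization is otherwise
  unspecified) and call gain at CN ≥ 3, loss at ≤ 1; uncovered genes are
  flagged rather than called neutral.

## SNV consensus filter

The cascade is evaluated in a fixed order and the audit records the first
failing clause, so audit counts partition the input. Two reading choices
are documented rather than silent:

* Clause precedence in the final gate is (AF ≥ 0.04 ∧ LOD ≥ 10) ∨ census —
  the only parse under which low-AF hotspot mutations in census genes
  survive, consistent with the rescue's purpose.
* The trusted-list bypass exempts a variant from the consensus clauses but
  **not** from the caller-level evidence gates (the bypass applies to
  "further" filtering after the evidence stage); a config switch
  (`trusted_bypasses_caller_thresholds`) widens the bypass for users who
  want list membership to dominate. A second switch
  (`census_exempt_from_dbsnp`) implements the common practice of letting
  census membership override dbSNP exclusion; it is off by default,
  matching the strict clause order.

LOD is supplied as a Mutect-style binomial log10 likelihood ratio,
log10[f^a (1−f)^(d−a) / (e^a (1−e)^(d−a))] with f = a/d and a configurable
error rate e (default 10⁻³), defined as 0 at a = 0; an externally provided
LOD column overrides the computed value. Indels and MNVs are dropped at
VCF ingestion (the filtered set is SNVs only). TMB is reported per
megabase by default, with a raw-count mode.

## Telomere content

A read is telomeric when it carries at least 6 telomere repeats per 100 bp
(scaled by read length). The threshold matches the default of the
established telomere-content estimators; it is configurable. Counting is
non-overlapping, greedy left-to-right, over two pattern families — the 11
forward hexamers and their reverse complements — scored separately with
the larger count taken, which makes classification exactly invariant under
reverse-complementing a read (greedy counting of fixed-length patterns is
direction-optimal). Content is telomeric reads per million total reads; no
GC-bias correction is applied (none is parameterized here), which largely
cancels in the tumor/normal ratio from the same platform and run. RTL
defaults to log2(tumor content / normal content) — so shortening is
negative and a halved content is exactly −1 — with a linear-ratio mode
available; output headers state the scale in use.

## Synthetic cohorts

The generators produce data with the statistical structure the analyses
assume, with truth recorded for every sample.

* **Copy number:** per sample, diploid arms; doubling with the stage's WGD
  probability; Poisson-many unit arm events (configurable gain/loss mix,
  floor at 0); optional focal events carved into single arms (0.1–5 Mb,
  ±2 copies). Default stage parameters follow the qualitative progression
  gradients: WGD probability 0 / 0.09 / 0.09 / 0.30 across
  AAH / AIS / MIA / ADC, arm-event rates 1 / 2 / 3 / 5, mean somatic SNV
  counts 20 / 40 / 60 / 100, and telomeric read fractions declining from
  5.0×10⁻⁴ to 3.5×10⁻⁴ against 6.0×10⁻⁴ for matched normal. These are
  stated simulation choices mirroring reported stage gradients, not
  estimates from patient data.
* **Variant calls:** true somatics draw AF from Beta(2, 6) (a
  clonal/subclonal mix at moderate purity), binomial alt counts at
  Poisson depth (mean 150 tumor / 100 normal), and are seen independently
  by each of the five callers with sensitivity 0.9 by default. dbSNP
  contaminants are planted with heterozygous-like AF and clean normals so
  that the annotation clause — not the evidence gates — must remove them;
  FFPE-type artifacts carry the artifact flag at low AF.
* **Telomere reads:** telomeric reads are tandem hexamer arrays (70%
  canonical, 30% uniform variants, random phase and strand); background is
  uniform random sequence.

What the generators do **not** emulate: sequencing error in reads, GC and
mappability bias, purity/contamination in copy-number segments, caller-
specific error profiles, and genuine genomic repeat structure (interstitial
telomeric sequence in real backgrounds). Passing recovery tests therefore
demonstrates correctness of the analysis logic under its own model
assumptions, not robustness to real-data artifacts.

## Problem sizes and numerics

The acceptance checks run at the sizes the analyses are designed for:
10,000-simulation nulls; 200 + 200 samples for WGD sensitivity/specificity;
20 replicate cohorts at n = 200/stage for prevalence recovery (coverage
judged against the exact central 95% binomial interval of the generating
probability, pooled over stage × replicate checks); 50 random profiles for
the wGII per-base oracle; 1,000 randomized calls for the filter oracle;
100,000 reads × 20 seeds × three fractions for telomere recovery; and 50
replicate cohorts at n = 50/stage for the Kruskal–Wallis trend checks.
Monte-Carlo agreement is always judged in Monte-Carlo standard-error
units, never by absolute tolerance. All simulations take explicit integer
seeds; fixed seeds reproduce results bit-for-bit, including written files.

## Known limitations

* Purity and subclonality are out of scope: integer arm states are taken
  at face value, so low-purity segmentations should be corrected upstream.
* The WGD test's randomization branch is calibrated for ploidy ≤ 3; its
  power near the boundary depends on how Pₛ is estimated (per-sample vs
  cohort), which is why that choice is surfaced.
* The aneuploidy count is an arm-level proxy (see above).
* Telomere content is platform-relative; absolute telomere length in kb is
  not estimated.
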