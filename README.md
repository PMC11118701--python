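# cinprecursor

Chromosomal-instability (CIN) analysis for lung adenocarcinoma precursors.

Preinvasive lung lesions progress through atypical adenomatous hyperplasia
(AAH), adenocarcinoma in situ (AIS) and minimally invasive adenocarcinoma
(MIA) to invasive adenocarcinoma (ADC). Along that spectrum, genomes
accumulate arm-level somatic copy-number aberrations, whole-genome doubling
(WGD), somatic point mutations and telomere shortening. `cinprecursor`
implements the analysis layer that quantifies these events from standard
inputs — segment-level allele-specific copy-number calls, per-caller somatic
SNV tables or VCFs, and sequencing reads — together with a synthetic-cohort
simulator so every stage can be validated against known ground truth without
access to controlled patient data.

## What it computes

**WGD randomization test.** A sample is an arm-resolution profile of integer
major/minor allele copy numbers over the 39 canonical autosomal arms. From it
the test takes *N*ₛ = Σ(|major−1| + |minor−1|), the number of unit
aberrations relative to diploid, and *P*ₛ, a smoothed categorical
distribution over events (arm × allele × gain/loss) estimated from deviation
frequencies (per sample or per cohort). Each of 10,000 simulations applies
*N*ₛ i.i.d. events from *P*ₛ to a diploid profile; the statistic is the
fraction of arms whose larger allele reaches ≥ 2, and the p-value is the
fraction of simulations reaching the observed value. A sample is WGD when
its mean ploidy exceeds 3, or when ploidy ≤ 3 and p < 0.001. An
exact-enumeration null (`exact_null`) provides an independent oracle on
small genomes.

**CIN metrics.** wGII (mean over autosomes of the length-fraction whose
copy number deviates from the sample's integer median ploidy), SCNA burden
(length-fraction of the evaluable region with total CN > 2.5 or < 1.5,
restricted to segments with ≥ 50 supporting reads), an arm-level
aneuploid-chromosome count, and per-gene focal gain/loss calls (CN ≥ 3 /
≤ 1).

**SNV consensus filter.** Calls from Mutect, Varscan2, Strelka2, Lancet and
SomaticSniper are merged by site; a variant is kept iff it passes
caller-level evidence gates (tumor AF ≥ 0.02, depth ≥ 20; normal AF ≤ 0.01,
depth ≥ 10) and either sits on a curated trusted list or is seen by ≥ 2
callers, is not artifact-flagged, is absent from dbSNP, and has tumor
AF ≥ 0.04 with LOD ≥ 10 (or lies in a cancer gene census gene). Every
decision is audited with its first failing clause. TMB is reported as a
count or per megabase.

**Telomere content.** Reads carrying ≥ 6 telomere repeat hexamers per
100 bp — canonical TTAGGG or the ten variant repeats TCAGGG, TGAGGG, TTGGGG,
TTCGGG, TTTGGG, ATAGGG, CATGGG, CTAGGG, GTAGGG, TAAGGG, either strand — are
counted as telomeric; content is telomeric reads per million, and relative
telomere length (RTL) is log2(tumor/normal), negative under shortening.

## Worked example

```python
from cinprecursor import (GenomeArms, StageParams, arm_profile,
                          simulate_cn_cohort, wgd_test)

arms = GenomeArms.default()
params = StageParams("ADC", n_samples=20, wgd_probability=0.30, arm_event_rate=5.0)
profiles, truths = simulate_cn_cohort(params, arms, seed=7)
for i, prof in enumerate(profiles[:6], start=0):
    res = wgd_test(arm_profile(prof, arms), arms, n_sims=10_000, seed=100 + i)
    print(res.sample_id, round(res.ploidy_used, 2), res.observed_stat,
          res.p_value, res.is_wgd)
```

prints (`examples/wgd_demo.py` shows the full cohort):

```
ADC_0000 2.01 0.051  0.6932 False
ADC_0005 4.18 1.000  0.0027 True
ADC_0015 4.01 1.000  0.0012 True
```

A quiet near-diploid sample has a small observed statistic and a large
p-value; doubled samples have every arm's major allele at ≥ 2 (observed
1.0) and ploidy ≈ 4, and are called WGD. The `examples/` directory holds
one short script per capability (arm profiling, CIN metrics, SNV filtering,
telomere content), each printing what it computes and what the numbers mean.

A thin CLI mirrors the library: `cinprecursor arms | profile | wgd | cin |
snv-filter | telomere | simulate` (see `cinprecursor --help`).

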