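"""Multi-caller merging, LOD, the consensus cascade and TMB."""

import math

import numpy as np
import pytest

from cinprecursor.snv_filter import (
    FilterConfig,
    VariantCall,
    binomial_lod,
    consensus_filter,
    effective_lod,
    merge_caller_sets,
    read_calls_tsv,
    tmb,
    write_calls_tsv,
)


def call(**kw) -> VariantCall:
    base = dict(
        chrom="chr1",
        pos=100,
        ref="A",
        alt="T",
        callers=frozenset({"mutect", "strelka2"}),
        tumor_depth=100,
        tumor_alt_count=10,
        tumor_af=0.10,
        normal_depth=60,
        normal_af=0.0,
    )
    base.update(kw)
    return VariantCall(**base)


class TestMergeCallerSets:
    def test_union_of_callers(self):
        a = call(callers=frozenset({"mutect"}))
        b = call(callers=frozenset({"strelka2"}))
        merged = merge_caller_sets({"mutect": [a], "strelka2": [b]})
        assert len(merged) == 1
        assert merged[0].callers == {"mutect", "strelka2"}

    def test_singleton_survives(self):
        a = call(callers=frozenset({"lancet"}))
        merged = merge_caller_sets({"lancet": [a]})
        assert merged[0].callers == {"lancet"}

    def test_conflicting_ref_raises(self):
        a = call(ref="A")
        b = call(ref="C", alt="G")
        with pytest.raises(ValueError, match="chr1:100"):
            merge_caller_sets({"mutect": [a], "strelka2": [b]})

    def test_evidence_from_priority_caller(self):
        a = call(callers=frozenset({"somaticsniper"}), tumor_af=0.5, tumor_alt_count=50)
        b = call(callers=frozenset({"mutect"}), tumor_af=0.1, tumor_alt_count=10)
        merged = merge_caller_sets({"somaticsniper": [a], "mutect": [b]})
        assert merged[0].tumor_af == 0.1  # mutect outranks somaticsniper

    def test_flags_or_combined(self):
        a = call(callers=frozenset({"mutect"}), in_dbsnp=True)
        b = call(callers=frozenset({"strelka2"}), in_census=True)
        merged = merge_caller_sets({"mutect": [a], "strelka2": [b]})
        assert merged[0].in_dbsnp and merged[0].in_census


class TestBinomialLod:
    def test_no_alt_reads_zero(self):
        assert binomial_lod(0, 100) == 0.0

    def test_all_alt_reads_closed_form(self):
        # f = 1: LOD = a * log10(1/e) = 3a at e = 1e-3
        for a in (1, 5, 40):
            assert binomial_lod(a, a, 1e-3) == pytest.approx(3.0 * a)

    def test_monotone_in_alt_count(self):
        for d in range(1, 201, 20):
            lods = [binomial_lod(a, d) for a in range(d + 1)]
            assert all(x <= y + 1e-12 for x, y in zip(lods, lods[1:]))

    def test_zero_depth_raises(self):
        with pytest.raises(ValueError):
            binomial_lod(0, 0)


def oracle_decision(v: VariantCall, c: FilterConfig) -> bool:
    """Direct transcription of the boolean keep rule, coded independently."""
    caller_level = (
        v.tumor_af >= c.min_tumor_af_call
        and v.tumor_depth >= c.min_tumor_depth
        and v.normal_af <= c.max_normal_af
        and v.normal_depth >= c.min_normal_depth
    )
    lod = v.lod if v.lod is not None else binomial_lod(v.tumor_alt_count, v.tumor_depth, c.error_rate)
    consensus = (
        len(v.callers) >= c.min_callers
        and not v.artifact_flagged
        and not v.in_dbsnp
        and ((v.tumor_af >= c.min_tumor_af_final and lod >= c.min_lod) or v.in_census)
    )
    return caller_level and (v.in_trusted_list or consensus)


def random_calls(n: int, seed: int) -> list[VariantCall]:
    rng = np.random.default_rng(seed)
    callers = ("mutect", "varscan2", "strelka2", "lancet", "somaticsniper")
    out = []
    for i in range(n):
        depth = int(rng.integers(5, 300))
        alt = int(rng.integers(0, depth + 1))
        # mix boundary-heavy AFs with the empirical a/d so thresholds get hit
        af = float(rng.choice([alt / depth, 0.02, 0.039, 0.04, 0.05, rng.random()]))
        out.append(
            VariantCall(
                chrom=f"chr{int(rng.integers(1, 23))}",
                pos=1000 + i,
                ref="A",
                alt="G",
                callers=frozenset(rng.choice(callers, size=int(rng.integers(1, 6)), replace=False)),
                tumor_depth=depth,
                tumor_alt_count=alt,
                tumor_af=af,
                normal_depth=int(rng.integers(0, 200)),
                normal_af=float(rng.choice([0.0, 0.005, 0.01, 0.02, rng.random() * 0.1])),
                in_dbsnp=bool(rng.random() < 0.2),
                in_census=bool(rng.random() < 0.2),
                in_trusted_list=bool(rng.random() < 0.1),
                artifact_flagged=bool(rng.random() < 0.2),
                lod=None if rng.random() < 0.5 else float(rng.random() * 30),
            )
        )
    return out


class TestConsensusFilter:
    def test_single_caller_rejected(self):
        kept, audit = consensus_filter([call(callers=frozenset({"mutect"}))])
        assert not kept
        assert audit[0].reason == "too_few_callers"

    def test_standard_keep(self):
        v = call(tumor_af=0.05, tumor_alt_count=5, lod=12.0)
        kept, audit = consensus_filter([v])
        assert kept == [v]
        assert audit[0].reason == "consensus"

    def test_census_rescues_low_af(self):
        v = call(tumor_af=0.03, tumor_alt_count=3, lod=15.0, in_census=True)
        kept, _ = consensus_filter([v])
        assert kept == [v]

    def test_dbsnp_rejected(self):
        v = call(callers=frozenset({"mutect", "strelka2", "lancet"}), in_dbsnp=True)
        kept, audit = consensus_filter([v])
        assert not kept
        assert audit[0].reason == "dbsnp"

    def test_artifact_rejected(self):
        v = call(callers=frozenset({"mutect", "strelka2", "lancet"}), artifact_flagged=True)
        kept, audit = consensus_filter([v])
        assert not kept
        assert audit[0].reason == "artifact"

    def test_trusted_list_bypasses_consensus_clauses(self):
        v = call(callers=frozenset({"mutect"}), in_trusted_list=True)
        kept, audit = consensus_filter([v])
        assert kept == [v]
        assert audit[0].reason == "trusted_list"

    def test_trusted_list_still_subject_to_caller_level_thresholds(self):
        v = call(in_trusted_list=True, tumor_af=0.01, tumor_alt_count=1)
        kept, audit = consensus_filter([v])
        assert not kept
        assert audit[0].reason == "low_tumor_af"

    def test_oracle_equivalence_on_randomized_calls(self):
        calls = random_calls(1000, seed=99)
        config = FilterConfig()
        kept, audit = consensus_filter(calls, config)
        kept_keys = {id(v) for v in kept}
        for v in calls:
            assert (id(v) in kept_keys) == oracle_decision(v, config)

    def test_audit_covers_every_input_with_one_reason(self):
        calls = random_calls(500, seed=7)
        kept, audit = consensus_filter(calls)
        assert len(audit) == len(calls)
        assert sum(a.kept for a in audit) == len(kept)
        assert all(a.reason for a in audit)

    def test_relaxing_thresholds_never_shrinks_kept_set(self):
        calls = random_calls(400, seed=21)
        strict = FilterConfig()
        kept_strict, _ = consensus_filter(calls, strict)
        relaxed_variants = [
            FilterConfig(min_tumor_af_call=0.0),
            FilterConfig(min_tumor_depth=0),
            FilterConfig(max_normal_af=1.0),
            FilterConfig(min_normal_depth=0),
            FilterConfig(min_callers=1),
            FilterConfig(min_tumor_af_final=0.0),
            FilterConfig(min_lod=0.0),
        ]
        strict_keys = {v.key for v in kept_strict}
        for cfg in relaxed_variants:
            kept_relaxed, _ = consensus_filter(calls, cfg)
            assert strict_keys <= {v.key for v in kept_relaxed}

    def test_supplied_lod_overrides_computed(self):
        v = call(tumor_af=0.05, tumor_alt_count=40, lod=2.0)  # computed LOD would pass
        kept, audit = consensus_filter([v])
        assert not kept
        assert audit[0].reason == "af_lod"
        assert effective_lod(v, FilterConfig()) == 2.0


class TestTmb:
    def test_per_mb(self):
        calls = random_calls(120, seed=0)
        assert tmb(calls, 40.0) == pytest.approx(3.0)

    def test_count_mode(self):
        assert tmb(random_calls(120, seed=0), mode="count") == 120

    def test_empty(self):
        assert tmb([], 40.0) == 0.0

    def test_bad_capture_size(self):
        with pytest.raises(ValueError):
            tmb([], 0.0)


VCF_TEXT = """\
##fileformat=VCFv4.2
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL
chr1\t100\t.\tA\tT\t.\tPASS\t.\tDP:AD\t100:90,10\t60:60,0
chr1\t200\t.\tG\tC,GA\t.\tPASS\t.\tDP:AD\t80:70,8,2\t50:50,0,0
chr1\t300\t.\tAT\tA\t.\tPASS\t.\tDP:AD\t90:80,10\t55:55,0
"""


class TestVcfReading:
    def test_reads_snvs_with_depths_and_afs(self, tmp_path):
        from cinprecursor.snv_filter import read_caller_vcf

        path = tmp_path / "mutect.vcf"
        path.write_text(VCF_TEXT)
        calls = read_caller_vcf(path, "mutect")
        # SNV at 100, multi-allelic at 200 keeps only the SNV alt, indel at 300 dropped
        assert [(c.pos, c.ref, c.alt) for c in calls] == [(100, "A", "T"), (200, "G", "C")]
        first = calls[0]
        assert first.callers == {"mutect"}
        assert first.tumor_depth == 100
        assert first.tumor_alt_count == 10
        assert first.tumor_af == pytest.approx(0.10)
        assert first.normal_af == 0.0


class TestRoundTrip:
    def test_tsv_round_trip(self, tmp_path):
        calls = random_calls(50, seed=13)
        path = tmp_path / "calls.tsv"
        write_calls_tsv(calls, path)
        again = read_calls_tsv(path)
        assert len(again) == len(calls)
        for a, b in zip(sorted(calls, key=lambda v: v.pos), sorted(again, key=lambda v: v.pos)):
            assert a.key == b.key
            assert a.callers == b.callers
            assert a.tumor_af == pytest.approx(b.tumor_af)
            assert a.in_dbsnp == b.in_dbsnp
            assert (a.lod is None) == (b.lod is None)
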