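"""wGII, SCNA burden, aneuploid chromosome counts and focal gene calls."""

import numpy as np
import pytest

from cinprecursor.arms import GenomeArms
from cinprecursor.cin_metrics import (
    GeneInterval,
    aneuploid_chromosome_count,
    gene_cn_calls,
    scna_burden,
    wgii,
)
from cinprecursor.cn_profile import Segment, SegmentProfile, arm_profile

from conftest import make_arm_profile, uniform_profile


def brute_force_wgii(profile: SegmentProfile, arms: GenomeArms) -> float:
    """Per-base oracle: materialize rounded CN on every base of every arm."""
    import math

    from cinprecursor.cn_profile import compute_ploidy

    _, mp = compute_ploidy(profile)
    fractions = []
    for chrom in arms.chromosomes:
        spans = [(a.start, a.end) for a in arms if a.chrom == chrom]
        lo = min(s for s, _ in spans)
        hi = max(e for _, e in spans)
        covered = np.zeros(hi - lo, dtype=bool)
        aberrant = np.zeros(hi - lo, dtype=bool)
        in_arm = np.zeros(hi - lo, dtype=bool)
        for s, e in spans:
            in_arm[s - lo : e - lo] = True
        for seg in profile.segments:
            if seg.chrom != chrom:
                continue
            sl = slice(max(seg.start, lo) - lo, min(seg.end, hi) - lo)
            covered[sl] = True
            if int(math.floor(seg.total_cn + 0.5)) != mp:
                aberrant[sl] = True
        covered &= in_arm
        aberrant &= in_arm
        fractions.append(aberrant.sum() / covered.sum() if covered.any() else 0.0)
    return float(np.mean(fractions))


class TestWgii:
    def test_diploid_genome_zero(self, toy_arms):
        prof = uniform_profile(toy_arms, 1, 1)
        value, uncovered = wgii(prof, toy_arms)
        assert value == 0.0
        assert not uncovered

    def test_tetraploid_genome_zero(self, toy_arms):
        # ploidy-relative definition: uniform CN 4 vs median ploidy 4
        prof = uniform_profile(toy_arms, 2, 2)
        assert wgii(prof, toy_arms)[0] == 0.0

    def test_one_chromosome_fully_gained(self, hg38_arms):
        segs = []
        for a in hg38_arms:
            cn = (2, 1) if a.chrom == "chr1" else (1, 1)
            segs.append(Segment(a.chrom, a.start, a.end, None, *cn))
        value, _ = wgii(SegmentProfile("s", segs), hg38_arms)
        assert value == pytest.approx(1 / 22)

    def test_matches_per_base_oracle_on_random_profiles(self):
        arms = GenomeArms.toy(4, 25_000)  # small enough for per-base arrays
        rng = np.random.default_rng(2024)
        for _ in range(50):
            segs = []
            for a in arms:
                cuts = np.sort(rng.choice(np.arange(a.start + 1, a.end), 3, replace=False))
                bounds = [a.start, *cuts.tolist(), a.end]
                for s, e in zip(bounds, bounds[1:]):
                    total = float(rng.choice([0.8, 1.0, 2.0, 2.4, 3.0, 4.1]))
                    segs.append(Segment(a.chrom, s, e, total))
            prof = SegmentProfile("s", segs)
            assert wgii(prof, arms)[0] == pytest.approx(brute_force_wgii(prof, arms), abs=1e-12)

    def test_uncovered_chromosome_contributes_zero_and_flagged(self, toy_arms):
        segs = [Segment("chr1", 0, 10_000_000, 3.0)]
        value, uncovered = wgii(SegmentProfile("s", segs), toy_arms)
        assert uncovered == {"chr2", "chr3", "chr4"}
        # chr1 fully aberrant (CN 3 vs median 3? median of covered is 3 -> 0)
        assert value == 0.0

    def test_invariant_under_segment_splitting(self, toy_arms):
        whole = uniform_profile(toy_arms, 2, 1)
        segs = []
        for a in toy_arms:
            mid = (a.start + a.end) // 2
            segs.append(Segment(a.chrom, a.start, mid, None, 2, 1))
            segs.append(Segment(a.chrom, mid, a.end, None, 2, 1))
        assert wgii(whole, toy_arms) == wgii(SegmentProfile("s", segs), toy_arms)

    def test_empty_profile_raises(self, toy_arms):
        with pytest.raises(ValueError, match="empty"):
            wgii(SegmentProfile("s", []), toy_arms)


class TestScnaBurden:
    def test_diploid_zero(self, toy_arms):
        prof = uniform_profile(toy_arms, 1, 1)
        assert scna_burden(prof) == (0.0, 0.0)

    def test_fractions_by_length(self):
        segs = [
            Segment("chr1", 0, 4000, 3.0, n_reads=100),
            Segment("chr1", 4000, 5000, 1.0, n_reads=100),
            Segment("chr1", 5000, 10_000, 2.0, n_reads=100),
        ]
        gain, loss = scna_burden(SegmentProfile("s", segs))
        assert gain == pytest.approx(0.4)
        assert loss == pytest.approx(0.1)

    def test_low_read_segments_excluded_entirely(self):
        segs = [
            Segment("chr1", 0, 5000, 3.0, n_reads=30),
            Segment("chr1", 5000, 10_000, 2.0, n_reads=100),
        ]
        gain, loss = scna_burden(SegmentProfile("s", segs), min_reads=50)
        assert (gain, loss) == (0.0, 0.0)

    def test_thresholds_are_strict(self):
        segs = [
            Segment("chr1", 0, 1000, 2.5, n_reads=100),
            Segment("chr1", 1000, 2000, 1.5, n_reads=100),
        ]
        assert scna_burden(SegmentProfile("s", segs)) == (0.0, 0.0)

    def test_no_evaluable_regions_raises(self):
        segs = [Segment("chr1", 0, 1000, 2.0, n_reads=10)]
        with pytest.raises(ValueError, match="no evaluable regions"):
            scna_burden(SegmentProfile("s", segs), min_reads=50)

    def test_filtering_disabled_without_read_counts(self):
        segs = [Segment("chr1", 0, 1000, 3.0)]
        gain, loss = scna_burden(SegmentProfile("s", segs), min_reads=None)
        assert gain == 1.0


class TestAneuploidChromosomeCount:
    def test_diploid_zero(self, hg38_arms):
        ap = make_arm_profile({n: (1, 1) for n in hg38_arms.names})
        assert aneuploid_chromosome_count(ap, 2) == 0

    def test_single_trisomic_chromosome(self, hg38_arms):
        states = {n: (1, 1) for n in hg38_arms.names}
        states["7p"] = (2, 1)
        states["7q"] = (2, 1)
        ap = make_arm_profile(states)
        assert aneuploid_chromosome_count(ap, 2) == 1

    def test_uniform_doubled_relative_to_tetraploid_median(self, hg38_arms):
        ap = make_arm_profile({n: (2, 2) for n in hg38_arms.names})
        assert aneuploid_chromosome_count(ap, 4) == 0

    def test_counts_chromosomes_not_arms(self, hg38_arms):
        states = {n: (1, 1) for n in hg38_arms.names}
        states["1p"] = (2, 1)
        states["1q"] = (3, 1)
        ap = make_arm_profile(states)
        assert aneuploid_chromosome_count(ap, 2) == 1


class TestGeneCnCalls:
    def test_threshold_calls(self):
        segs = [
            Segment("chr1", 0, 10_000, 5.0),
            Segment("chr2", 0, 10_000, 1.0),
            Segment("chr3", 0, 10_000, 2.0),
        ]
        prof = SegmentProfile("s", segs)
        genes = [
            GeneInterval("EGFR_like", "chr1", 1000, 2000),
            GeneInterval("TSG_like", "chr2", 1000, 2000),
            GeneInterval("neutral_gene", "chr3", 1000, 2000),
            GeneInterval("uncovered_gene", "chr9", 1000, 2000),
        ]
        calls = {c.gene: c for c in gene_cn_calls(prof, genes)}
        assert calls["EGFR_like"].call == "gain"
        assert calls["TSG_like"].call == "loss"
        assert calls["neutral_gene"].call == "neutral"
        assert calls["uncovered_gene"].call is None
        assert not calls["uncovered_gene"].covered

    def test_length_weighted_mean_over_boundary(self):
        segs = [
            Segment("chr1", 0, 1500, 4.0),
            Segment("chr1", 1500, 3000, 2.0),
        ]
        prof = SegmentProfile("s", segs)
        calls = gene_cn_calls(prof, [GeneInterval("g", "chr1", 1000, 2000)])
        assert calls[0].copy_number == pytest.approx(3.0)
        assert calls[0].call == "gain"  # >= 3 threshold is inclusive
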