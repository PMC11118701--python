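"""Copy-number-derived chromosomal instability metrics.

* :func:`wgii` — weighted genome instability index: for each autosome, the
  fraction of covered length whose (rounded) total copy number differs
  from the sample's integer median ploidy, averaged over chromosomes so
  every chromosome contributes equally regardless of its length.
* :func:`scna_burden` — fraction of the evaluable region with total copy
  number above 2.5 (gain) or below 1.5 (loss), restricted to segments
  supported by at least 50 reads when read counts are available.
* :func:`aneuploid_chromosome_count` — number of autosomes carrying at
  least one arm whose total allele copy number departs from the sample's
  integer median ploidy (an arm-level proxy for mosaic aneuploidy).
* :func:`gene_cn_calls` — per-gene focal gain/loss calls at copy number
  >= 3 / <= 1, with gene copy number as the length-weighted mean of
  overlapping segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .arms import GenomeArms
from .cn_profile import ArmProfile, SegmentProfile, compute_ploidy

__all__ = [
    "CinSummary",
    "GeneCnCall",
    "GeneInterval",
    "wgii",
    "scna_burden",
    "aneuploid_chromosome_count",
    "gene_cn_calls",
    "cin_summary",
]

GAIN_THRESHOLD = 2.5
LOSS_THRESHOLD = 1.5
MIN_READS = 50
FOCAL_GAIN_CN = 3.0
FOCAL_LOSS_CN = 1.0


@dataclass
class CinSummary:
    sample_id: str
    wgii: float
    scna_gain_fraction: float
    scna_loss_fraction: float
    n_aneuploid_chromosomes: int

    def __post_init__(self) -> None:
        for name in ("wgii", "scna_gain_fraction", "scna_loss_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.scna_gain_fraction + self.scna_loss_fraction > 1.0 + 1e-9:
            raise ValueError("gain + loss fractions exceed 1")


@dataclass(frozen=True)
class GeneInterval:
    gene: str
    chrom: str
    start: int
    end: int


@dataclass
class GeneCnCall:
    gene: str
    copy_number: float | None
    call: str | None  # "gain" | "loss" | "neutral" | None when uncovered
    covered: bool = True


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def wgii(profile: SegmentProfile, arms: GenomeArms) -> tuple[float, frozenset[str]]:
    """Weighted genome instability index and the set of uncovered chromosomes.

    Aberrance is judged on rounded integer total copy number versus the
    integer median ploidy, so a uniformly tetraploid genome scores 0.
    Chromosomes with no covered length contribute 0 and are flagged.
    """
    if not profile.segments:
        raise ValueError(f"{profile.sample_id}: empty profile")
    _, median_ploidy = compute_ploidy(profile)
    fractions: list[float] = []
    uncovered: set[str] = set()
    for chrom in arms.chromosomes:
        chrom_arms = [a for a in arms if a.chrom == chrom]
        covered = 0
        aberrant = 0
        for seg in profile.segments:
            if seg.chrom != chrom:
                continue
            for arm in chrom_arms:
                overlap = min(seg.end, arm.end) - max(seg.start, arm.start)
                if overlap <= 0:
                    continue
                covered += overlap
                if _round_half_up(float(seg.total_cn)) != median_ploidy:
                    aberrant += overlap
        if covered == 0:
            uncovered.add(chrom)
            fractions.append(0.0)
        else:
            fractions.append(aberrant / covered)
    return sum(fractions) / len(fractions), frozenset(uncovered)


def scna_burden(
    profile: SegmentProfile,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
    min_reads: int | None = MIN_READS,
) -> tuple[float, float]:
    """Length fractions of the evaluable region with CN gain and loss.

    ``min_reads`` filters the evaluable region (numerator and denominator)
    to segments with at least that many supporting reads; pass ``None`` to
    disable filtering when read counts are absent.
    """
    if not profile.segments:
        raise ValueError(f"{profile.sample_id}: empty profile")
    denom = 0
    gain_len = 0
    loss_len = 0
    for seg in profile.segments:
        if seg.total_cn is None:
            raise ValueError(f"{profile.sample_id}: total_cn required")
        if min_reads is not None:
            if seg.n_reads is None:
                raise ValueError(
                    f"{profile.sample_id}: n_reads required for min_reads filtering "
                    f"(disable with min_reads=None)"
                )
            if seg.n_reads < min_reads:
                continue
        denom += seg.length
        if seg.total_cn > gain_threshold:
            gain_len += seg.length
        elif seg.total_cn < loss_threshold:
            loss_len += seg.length
    if denom == 0:
        raise ValueError(f"{profile.sample_id}: no evaluable regions")
    return gain_len / denom, loss_len / denom


def aneuploid_chromosome_count(arm: ArmProfile, median_ploidy_int: int | None = None) -> int:
    """Autosomes with at least one arm whose total CN differs from ploidy."""
    mp = median_ploidy_int if median_ploidy_int is not None else arm.median_ploidy_int
    aneuploid: set[str] = set()
    for name, (major, minor) in arm.states.items():
        if major + minor != mp:
            aneuploid.add(name.rstrip("pq"))
    return len(aneuploid)


def gene_cn_calls(
    profile: SegmentProfile,
    genes: list[GeneInterval],
    gain_cn: float = FOCAL_GAIN_CN,
    loss_cn: float = FOCAL_LOSS_CN,
) -> list[GeneCnCall]:
    """Focal gain/loss calls per gene.

    Gene copy number is the length-weighted mean total CN of overlapping
    segments; genes with no overlapping segment get no call and are
    flagged uncovered.
    """
    calls: list[GeneCnCall] = []
    for gene in genes:
        weight = 0
        acc = 0.0
        for seg in profile.segments:
            if seg.chrom != gene.chrom:
                continue
            overlap = min(seg.end, gene.end) - max(seg.start, gene.start)
            if overlap <= 0:
                continue
            if seg.total_cn is None:
                raise ValueError(f"{profile.sample_id}: total_cn required")
            weight += overlap
            acc += overlap * float(seg.total_cn)
        if weight == 0:
            calls.append(GeneCnCall(gene.gene, None, None, covered=False))
            continue
        cn = acc / weight
        if cn >= gain_cn:
            call = "gain"
        elif cn <= loss_cn:
            call = "loss"
        else:
            call = "neutral"
        calls.append(GeneCnCall(gene.gene, cn, call))
    return calls


def cin_summary(
    profile: SegmentProfile,
    arm: ArmProfile,
    arms: GenomeArms,
    min_reads: int | None = MIN_READS,
) -> CinSummary:
    """One-row summary of the copy-number instability metrics."""
    w, _ = wgii(profile, arms)
    gain, loss = scna_burden(profile, min_reads=min_reads)
    return CinSummary(
        sample_id=profile.sample_id,
        wgii=w,
        scna_gain_fraction=gain,
        scna_loss_fraction=loss,
        n_aneuploid_chromosomes=aneuploid_chromosome_count(arm),
    )
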