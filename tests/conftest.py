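import numpy as np
import pytest

from cinprecursor.arms import GenomeArms
from cinprecursor.cn_profile import ArmProfile, Segment, SegmentProfile


@pytest.fixture(scope="session")
def hg38_arms() -> GenomeArms:
    return GenomeArms.default()


@pytest.fixture
def toy_arms() -> GenomeArms:
    """Four single-arm chromosomes of 10 Mb each."""
    return GenomeArms.toy(4, 10_000_000)


def make_arm_profile(
    states: dict[str, tuple[int, int]],
    sample_id: str = "s",
    mean_ploidy: float | None = None,
    median_ploidy_int: int | None = None,
) -> ArmProfile:
    """Arm profile with ploidy summaries derived from the arm states."""
    totals = [a + b for a, b in states.values()]
    mp = sum(totals) / len(totals) if mean_ploidy is None else mean_ploidy
    mpi = int(round(np.median(totals))) if median_ploidy_int is None else median_ploidy_int
    return ArmProfile(sample_id, dict(states), mean_ploidy=mp, median_ploidy_int=mpi)


def uniform_profile(
    arms: GenomeArms,
    major: int,
    minor: int,
    sample_id: str = "s",
    n_reads: int = 100,
) -> SegmentProfile:
    """One segment per arm, everywhere at the same allelic state."""
    segs = [
        Segment(a.chrom, a.start, a.end, None, major, minor, n_reads) for a in arms
    ]
    return SegmentProfile(sample_id, segs)
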