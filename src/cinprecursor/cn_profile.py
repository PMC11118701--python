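"""Segment-level copy-number profiles and their arm-level reduction.

A :class:`SegmentProfile` holds one sample's copy-number segments (total
and optionally allele-specific copy number, plus an optional supporting
read count).  :func:`compute_ploidy` summarizes it into a length-weighted
mean ploidy and an integer length-weighted median ploidy, and
:func:`arm_profile` reduces it to one integer (major, minor) allele state
per chromosome arm — the representation the whole-genome-doubling test and
the aneuploidy count operate on.

Internal coordinates are 0-based, half-open.  SEG input is read as
1-based inclusive; BED input as 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "Segment",
    "SegmentProfile",
    "ArmProfile",
    "load_segments",
    "write_segments",
    "compute_ploidy",
    "arm_profile",
]

from .arms import GenomeArms

SEG_COLUMNS = ["sample", "chrom", "start", "end", "total_cn", "major_cn", "minor_cn", "n_reads"]


@dataclass(frozen=True)
class Segment:
    """One copy-number segment, 0-based half-open."""

    chrom: str
    start: int
    end: int
    total_cn: float | None = None
    major_cn: int | None = None
    minor_cn: int | None = None
    n_reads: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment {self.chrom}:{self.start}-{self.end}: end must exceed start")
        if self.major_cn is not None and self.minor_cn is not None:
            if self.major_cn < self.minor_cn:
                raise ValueError(
                    f"segment {self.chrom}:{self.start}-{self.end}: major_cn < minor_cn"
                )
            if self.total_cn is None:
                object.__setattr__(self, "total_cn", float(self.major_cn + self.minor_cn))
        if self.total_cn is not None and self.total_cn < 0:
            raise ValueError("total_cn must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def allelic(self) -> bool:
        return self.major_cn is not None and self.minor_cn is not None


@dataclass
class SegmentProfile:
    """One sample's ordered, non-overlapping copy-number segments."""

    sample_id: str
    segments: list[Segment]
    histology: str = "unknown"

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (_chrom_key(s.chrom), s.start))
        prev: Segment | None = None
        for seg in self.segments:
            if prev is not None and seg.chrom == prev.chrom and seg.start < prev.end:
                raise ValueError(
                    f"{self.sample_id}: overlapping segments on {seg.chrom} "
                    f"([{prev.start},{prev.end}) and [{seg.start},{seg.end}))"
                )
            prev = seg

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class ArmProfile:
    """Integer (major, minor) allele copy numbers per chromosome arm."""

    sample_id: str
    states: dict[str, tuple[int, int]]  # arm name -> (major, minor)
    mean_ploidy: float
    median_ploidy_int: int
    uncovered_arms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name, (major, minor) in self.states.items():
            if major < minor:
                raise ValueError(f"arm {name}: major < minor")

    def majors(self, arm_names: list[str] | None = None) -> list[int]:
        names = arm_names if arm_names is not None else list(self.states)
        return [self.states[n][0] for n in names]


def _chrom_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome ordering: chr1..chr22 numerically, others after."""
    c = chrom.removeprefix("chr")
    return (int(c), "") if c.isdigit() else (10**6, c)


def _parse_row(fields: list[str], lineno: int, path: str, dialect: str) -> tuple[str, Segment]:
    def _opt_int(s: str) -> int | None:
        return None if s in ("", ".", "NA") else int(s)

    def _opt_float(s: str) -> float | None:
        return None if s in ("", ".", "NA") else float(s)

    try:
        sample, chrom = fields[0], fields[1]
        start, end = int(fields[2]), int(fields[3])
        total_cn = _opt_float(fields[4]) if len(fields) > 4 else None
        major_cn = _opt_int(fields[5]) if len(fields) > 5 else None
        minor_cn = _opt_int(fields[6]) if len(fields) > 6 else None
        n_reads = _opt_int(fields[7]) if len(fields) > 7 else None
        if dialect == "seg_1based":
            start -= 1  # 1-based inclusive -> 0-based half-open
        seg = Segment(chrom, start, end, total_cn, major_cn, minor_cn, n_reads)
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}:{lineno}: malformed segment row: {exc}") from exc
    return sample, seg


def load_segments(path: str | Path, dialect: str = "seg_1based") -> SegmentProfile:
    """Read a single-sample SEG/TSV file into a :class:`SegmentProfile`.

    Columns: ``sample chrom start end total_cn [major_cn minor_cn n_reads]``,
    tab-separated, optional header.  ``dialect`` selects the coordinate
    convention of the input: ``seg_1based`` (1-based inclusive, the SEG
    standard) or ``bed_0based`` (0-based half-open).
    """
    if dialect not in ("seg_1based", "bed_0based"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    segments: list[Segment] = []
    sample_id: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "sample":
                continue  # header
            sample, seg = _parse_row(fields, lineno, str(path), dialect)
            if sample_id is None:
                sample_id = sample
            elif sample != sample_id:
                raise ValueError(
                    f"{path}:{lineno}: multiple samples in one file "
                    f"({sample_id!r}, {sample!r}); use load_cohort"
                )
            segments.append(seg)
    return SegmentProfile(sample_id=sample_id or path.stem, segments=segments)


def load_cohort(path: str | Path, dialect: str = "seg_1based") -> list[SegmentProfile]:
    """Read a multi-sample SEG/TSV file, one profile per sample."""
    path = Path(path)
    by_sample: dict[str, list[Segment]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "sample":
                continue
            sample, seg = _parse_row(fields, lineno, str(path), dialect)
            by_sample.setdefault(sample, []).append(seg)
    return [SegmentProfile(s, segs) for s, segs in by_sample.items()]


def write_segments(
    profiles: SegmentProfile | list[SegmentProfile],
    path: str | Path,
    dialect: str = "seg_1based",
) -> None:
    """Write profiles to SEG/TSV; re-loading reproduces identical segments."""
    if isinstance(profiles, SegmentProfile):
        profiles = [profiles]
    offset = 1 if dialect == "seg_1based" else 0
    with open(path, "w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for prof in profiles:
            for s in prof.segments:
                fields = [
                    prof.sample_id,
                    s.chrom,
                    str(s.start + offset),
                    str(s.end),
                    "" if s.total_cn is None else repr(s.total_cn),
                    "" if s.major_cn is None else str(s.major_cn),
                    "" if s.minor_cn is None else str(s.minor_cn),
                    "" if s.n_reads is None else str(s.n_reads),
                ]
                fh.write("\t".join(fields) + "\n")


def weighted_median_int(values: list[float], weights: list[float]) -> int:
    """Length-weighted median rounded to the nearest integer.

    When the cumulative weight reaches exactly 50% at a value boundary the
    lower value is taken; rounding of halves is upward.
    """
    order = sorted(range(len(values)), key=lambda i: values[i])
    total = float(sum(weights))
    cum = 0.0
    half = total / 2.0
    median = values[order[-1]]
    for i in order:
        cum += weights[i]
        if cum >= half - 1e-9 * total:
            median = values[i]
            break
    import math

    return int(math.floor(median + 0.5))


def compute_ploidy(profile: SegmentProfile) -> tuple[float, int]:
    """Length-weighted mean ploidy and integer length-weighted median ploidy."""
    segs = [s for s in profile.segments]
    if not segs:
        raise ValueError(f"{profile.sample_id}: empty profile")
    if any(s.total_cn is None for s in segs):
        raise ValueError(f"{profile.sample_id}: total_cn required on every segment")
    lengths = [float(s.length) for s in segs]
    cns = [float(s.total_cn) for s in segs]
    total_len = sum(lengths)
    mean_ploidy = sum(l * c for l, c in zip(lengths, cns)) / total_len
    return mean_ploidy, weighted_median_int(cns, lengths)


def arm_profile(profile: SegmentProfile, arms: GenomeArms) -> ArmProfile:
    """Reduce a segment profile to one (major, minor) state per arm.

    Each arm takes the length-weighted modal allelic state of the segments
    intersecting it; segments straddling an arm boundary contribute only
    their overlap.  Ties go to the state with the lower total copy number
    (conservative toward diploid).  Arms with no overlapping segment
    default to the diploid state (1, 1) and are flagged as uncovered.
    """
    if not profile.segments:
        raise ValueError(f"{profile.sample_id}: empty profile")
    states: dict[str, tuple[int, int]] = {}
    uncovered: set[str] = set()
    for arm in arms:
        weights: dict[tuple[int, int], int] = {}
        for seg in profile.segments:
            if seg.chrom != arm.chrom:
                continue
            overlap = min(seg.end, arm.end) - max(seg.start, arm.start)
            if overlap <= 0:
                continue
            if not seg.allelic:
                raise ValueError(
                    f"{profile.sample_id}: allelic CN required on "
                    f"{seg.chrom}:{seg.start}-{seg.end} (intersects {arm.name})"
                )
            state = (seg.major_cn, seg.minor_cn)
            weights[state] = weights.get(state, 0) + overlap
        if not weights:
            states[arm.name] = (1, 1)
            uncovered.add(arm.name)
        else:
            # max weight; ties -> lower total CN, then lexicographic
            states[arm.name] = min(weights, key=lambda st: (-weights[st], st[0] + st[1], st))
    mean_ploidy, median_ploidy_int = compute_ploidy(profile)
    return ArmProfile(
        sample_id=profile.sample_id,
        states=states,
        mean_ploidy=mean_ploidy,
        median_ploidy_int=median_ploidy_int,
        uncovered_arms=frozenset(uncovered),
    )
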