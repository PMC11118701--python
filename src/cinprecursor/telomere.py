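"""Telomere content estimation from sequencing reads.

A read is classified as telomeric when it carries a sufficient density of
telomere repeat hexamers — the canonical TTAGGG or any of ten variant
repeats (TCAGGG, TGAGGG, TTGGGG, TTCGGG, TTTGGG, ATAGGG, CATGGG, CTAGGG,
GTAGGG, TAAGGG) — on either strand.  The default density threshold is
6 non-overlapping repeats per 100 bp, scaled to the read length.

Telomere content is reported as telomeric reads per million total reads;
relative telomere length (RTL) is the log2 ratio of tumor to matched
normal content, so negative values indicate telomere shortening.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "CANONICAL_REPEAT",
    "VARIANT_REPEATS",
    "TelomereRepeatSet",
    "TelomereContent",
    "classify_read",
    "telomere_content",
    "telomere_content_from_fastq",
    "relative_telomere_length",
    "iter_read_sequences",
]

CANONICAL_REPEAT = "TTAGGG"
VARIANT_REPEATS = (
    "TCAGGG",
    "TGAGGG",
    "TTGGGG",
    "TTCGGG",
    "TTTGGG",
    "ATAGGG",
    "CATGGG",
    "CTAGGG",
    "GTAGGG",
    "TAAGGG",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_THRESHOLD = 6.0  # repeats per 100 bp


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TelomereRepeatSet:
    """The canonical repeat, its variants, and both strand orientations."""

    canonical: str = CANONICAL_REPEAT
    variants: tuple[str, ...] = VARIANT_REPEATS

    def __post_init__(self) -> None:
        if len(self.canonical) != 6 or any(len(v) != 6 for v in self.variants):
            raise ValueError("telomere repeats must be hexamers")
        if len(self.variants) != 10:
            raise ValueError("exactly 10 variant repeats expected")

    @property
    def forward(self) -> tuple[str, ...]:
        return (self.canonical, *self.variants)

    @property
    def reverse(self) -> tuple[str, ...]:
        return tuple(reverse_complement(p) for p in self.forward)

    def patterns(self) -> tuple[re.Pattern, re.Pattern]:
        fwd = re.compile("|".join(self.forward))
        rev = re.compile("|".join(self.reverse))
        return fwd, rev


_DEFAULT_SET = TelomereRepeatSet()
_DEFAULT_FWD, _DEFAULT_REV = _DEFAULT_SET.patterns()
_VALID_RE = re.compile(r"^[ACGTN]+$")


@dataclass
class TelomereContent:
    """Telomeric read counts and per-million content for one sample."""

    sample_id: str
    telomeric_reads: int
    total_reads: int
    content: float  # telomeric reads per million total reads

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be > 0")
        if not (0 <= self.telomeric_reads <= self.total_reads):
            raise ValueError("telomeric_reads out of range")


def repeat_count(sequence: str, repeat_set: TelomereRepeatSet | None = None) -> int:
    """Non-overlapping telomere-repeat count: max of forward and reverse families."""
    if repeat_set is None:
        fwd, rev = _DEFAULT_FWD, _DEFAULT_REV
    else:
        fwd, rev = repeat_set.patterns()
    return max(len(fwd.findall(sequence)), len(rev.findall(sequence)))


def classify_read(
    sequence: str,
    min_repeats_per_100bp: float = DEFAULT_THRESHOLD,
    repeat_set: TelomereRepeatSet | None = None,
) -> bool:
    """True when the read's repeat density reaches the telomeric threshold.

    Non-overlapping occurrences of any repeat are counted separately for
    the forward and reverse-complement pattern families and the larger
    count is used; the read is telomeric when
    count >= min_repeats_per_100bp * len(sequence) / 100.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    if not _VALID_RE.match(seq):
        raise ValueError("sequence contains non-ACGTN characters")
    return repeat_count(seq, repeat_set) >= min_repeats_per_100bp * len(seq) / 100.0


def telomere_content(
    reads: Iterable[str],
    sample_id: str = "sample",
    min_repeats_per_100bp: float = DEFAULT_THRESHOLD,
    repeat_set: TelomereRepeatSet | None = None,
) -> TelomereContent:
    """Single-pass telomere content over a stream of read sequences."""
    telomeric = 0
    total = 0
    for seq in reads:
        total += 1
        if classify_read(seq, min_repeats_per_100bp, repeat_set):
            telomeric += 1
    if total == 0:
        raise ValueError(f"{sample_id}: no reads")
    return TelomereContent(
        sample_id=sample_id,
        telomeric_reads=telomeric,
        total_reads=total,
        content=1e6 * telomeric / total,
    )


def iter_read_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences from FASTQ (optionally gzipped) or SAM/BAM.

    All reads are scanned, mapped and unmapped alike.
    """
    import pysam

    path = Path(path)
    if path.suffix in (".sam", ".bam", ".cram"):
        mode = "rb" if path.suffix in (".bam", ".cram") else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
            for rec in af.fetch(until_eof=True):
                if rec.query_sequence:
                    yield rec.query_sequence
    else:
        with pysam.FastxFile(str(path)) as fx:
            for rec in fx:
                yield rec.sequence


def telomere_content_from_fastq(
    path: str | Path,
    sample_id: str | None = None,
    min_repeats_per_100bp: float = DEFAULT_THRESHOLD,
    repeat_set: TelomereRepeatSet | None = None,
) -> TelomereContent:
    """Telomere content of a FASTQ/SAM/BAM file."""
    sid = sample_id if sample_id is not None else Path(path).stem
    return telomere_content(iter_read_sequences(path), sid, min_repeats_per_100bp, repeat_set)


def relative_telomere_length(
    tumor: TelomereContent,
    normal: TelomereContent,
    scale: str = "log2",
) -> float:
    """Tumor-vs-normal relative telomere length.

    log2 scale (default): RTL < 0 means telomere shortening relative to
    the matched normal.  ``scale='linear'`` returns the plain ratio.
    """
    import math

    if normal.content <= 0:
        raise ValueError("normal telomere content must be > 0")
    ratio = tumor.content / normal.content
    if scale == "log2":
        return math.log2(ratio) if ratio > 0 else float("-inf")
    if scale == "linear":
        return ratio
    raise ValueError(f"scale must be 'log2' or 'linear', got {scale!r}")
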