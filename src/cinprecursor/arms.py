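"""Chromosome-arm reference tables.

Arm-level analyses (WGD testing, aneuploidy counting) operate on integer
allele copy-number states assigned per chromosome arm.  The default table
covers the 39 canonical autosomal arms of GRCh38: both arms of chromosomes
1-12 and 16-20, and only the q arms of the acrocentric chromosomes
13, 14, 15, 21 and 22, whose p arms carry no assembled unique sequence.
Sex chromosomes are excluded from every metric.

Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

__all__ = ["Arm", "GenomeArms", "ACROCENTRIC"]

# GRCh38 autosome lengths and centromere (acen) intervals, UCSC cytoband.
# chrom -> (length, cen_start, cen_end)
_HG38_AUTOSOMES: dict[str, tuple[int, int, int]] = {
    "chr1": (248956422, 121700000, 125100000),
    "chr2": (242193529, 91800000, 96000000),
    "chr3": (198295559, 87800000, 94000000),
    "chr4": (190214555, 48200000, 51800000),
    "chr5": (181538259, 46100000, 50000000),
    "chr6": (170805979, 58500000, 62600000),
    "chr7": (159345973, 58100000, 62100000),
    "chr8": (145138636, 43200000, 47200000),
    "chr9": (138394717, 42200000, 45500000),
    "chr10": (133797422, 38000000, 41600000),
    "chr11": (135086622, 51000000, 55800000),
    "chr12": (133275309, 33200000, 37800000),
    "chr13": (114364328, 16500000, 18900000),
    "chr14": (107043718, 16100000, 18200000),
    "chr15": (101991189, 17500000, 20500000),
    "chr16": (90338345, 35300000, 38400000),
    "chr17": (83257441, 22700000, 27400000),
    "chr18": (80373285, 15400000, 21500000),
    "chr19": (58617616, 24200000, 28100000),
    "chr20": (64444167, 25700000, 30400000),
    "chr21": (46709983, 10900000, 13000000),
    "chr22": (50818468, 13700000, 17400000),
}

#: Acrocentric autosomes whose p arms are excluded from the default table.
ACROCENTRIC = frozenset({"chr13", "chr14", "chr15", "chr21", "chr22"})


@dataclass(frozen=True)
class Arm:
    """One chromosome arm as a half-open genomic interval."""

    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if self.end <= self.start:
            raise ValueError(f"{self.name}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom.removeprefix('chr')}{self.arm}"


class GenomeArms:
    """An ordered, validated collection of chromosome arms.

    Arms within a chromosome must not overlap.  Iteration order is the
    input order; :meth:`default` yields arms sorted by chromosome then arm.
    """

    def __init__(self, arms: list[Arm]):
        by_chrom: dict[str, list[Arm]] = {}
        for a in arms:
            by_chrom.setdefault(a.chrom, []).append(a)
        for chrom, group in by_chrom.items():
            spans = sorted((a.start, a.end) for a in group)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping arms on {chrom}")
        self._arms = list(arms)

    def __iter__(self) -> Iterator[Arm]:
        return iter(self._arms)

    def __len__(self) -> int:
        return len(self._arms)

    def __getitem__(self, i: int) -> Arm:
        return self._arms[i]

    @property
    def names(self) -> list[str]:
        return [a.name for a in self._arms]

    @property
    def chromosomes(self) -> list[str]:
        """Distinct chromosomes in input order."""
        seen: dict[str, None] = {}
        for a in self._arms:
            seen.setdefault(a.chrom)
        return list(seen)

    @classmethod
    def default(cls, build: str = "hg38") -> "GenomeArms":
        """The 39 canonical autosomal arms of GRCh38."""
        if build not in ("hg38", "GRCh38"):
            raise ValueError(f"unknown build {build!r}; only hg38 is bundled")
        arms: list[Arm] = []
        for chrom, (length, cen_start, cen_end) in _HG38_AUTOSOMES.items():
            if chrom not in ACROCENTRIC:
                arms.append(Arm(chrom, "p", 0, cen_start))
            arms.append(Arm(chrom, "q", cen_end, length))
        return cls(arms)

    @classmethod
    def toy(cls, n_arms: int = 4, arm_length: int = 10_000_000) -> "GenomeArms":
        """A minimal genome of single-arm chromosomes, for tests and oracles."""
        if n_arms < 1:
            raise ValueError("n_arms must be >= 1")
        return cls([Arm(f"chr{i + 1}", "q", 0, arm_length) for i in range(n_arms)])

    @classmethod
    def from_bed(cls, path: str | Path) -> "GenomeArms":
        """Read arms from BED4 (chrom, start, end, name ending in p/q)."""
        arms: list[Arm] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: BED4 required (chrom start end name)")
                chrom, start, end, name = fields[:4]
                arm = name[-1]
                arms.append(Arm(chrom, arm, int(start), int(end)))
        return cls(arms)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for a in self._arms:
                fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.name}\n")
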