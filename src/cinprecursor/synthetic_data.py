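"""Synthetic cohorts with known ground truth.

Every analysis stage in this package consumes data that is controlled
access in real studies.  This module generates inputs with the same
statistical structure the analyses assume, with the generating truth
recorded, so each stage is testable end to end:

* copy-number cohorts — per sample, a diploid arm baseline optionally
  doubled (whole-genome doubling), then Poisson-many unit arm gains and
  losses and optional focal events;
* multi-caller variant call sets — true somatic SNVs (allele fractions
  drawn from a Beta(2, 6), a clonal/subclonal mix at moderate purity)
  seen by each caller with a per-caller sensitivity, plus dbSNP-listed
  contaminants and FFPE-type artifact calls;
* telomere read sets — a known fraction of reads drawn as tandem repeat
  arrays (canonical and variant units, random phase and strand) against a
  uniform-random background.

Stage defaults follow the qualitative gradients of lung-adenocarcinoma
progression: WGD prevalence 0%/9%/9%/30% across AAH/AIS/MIA/ADC, rising
arm-event and mutation rates, and telomere shortening relative to normal.
They are stated simulation choices, not estimates from patient data.

All generators take explicit seeds and never touch global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .arms import GenomeArms
from .cn_profile import Segment, SegmentProfile
from .snv_filter import VariantCall, KNOWN_CALLERS
from .telomere import CANONICAL_REPEAT, VARIANT_REPEATS, reverse_complement

__all__ = [
    "StageParams",
    "TruthRecord",
    "STAGES",
    "stage_defaults",
    "simulate_cn_cohort",
    "simulate_variant_calls",
    "simulate_telomere_reads",
    "write_fastq",
    "write_truth_tsv",
    "precision_recall",
]

STAGES = ("AAH", "AIS", "MIA", "ADC")


@dataclass(frozen=True)
class StageParams:
    """Generating parameters for one histologic stage."""

    stage: str
    n_samples: int = 25
    wgd_probability: float = 0.0
    arm_event_rate: float = 2.0  # mean unit arm aberrations per sample (Poisson)
    focal_event_rate: float = 0.0  # mean focal events per sample (Poisson)
    somatic_mutation_rate: float = 50.0  # mean true somatic SNVs per sample (Poisson)
    telomere_fraction: float = 4e-4  # telomeric read fraction

    def __post_init__(self) -> None:
        if not (0.0 <= self.wgd_probability <= 1.0):
            raise ValueError("wgd_probability must be in [0, 1]")
        if not (0.0 <= self.telomere_fraction <= 1.0):
            raise ValueError("telomere_fraction must be in [0, 1]")
        for name in ("arm_event_rate", "focal_event_rate", "somatic_mutation_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def stage_defaults(n_samples: int = 25) -> dict[str, StageParams]:
    """Default per-stage parameters (WGD prevalence 0/9/9/30%, rising rates)."""
    table = {
        "AAH": dict(wgd_probability=0.00, arm_event_rate=1.0, focal_event_rate=0.5,
                    somatic_mutation_rate=20.0, telomere_fraction=5.0e-4),
        "AIS": dict(wgd_probability=0.09, arm_event_rate=2.0, focal_event_rate=1.0,
                    somatic_mutation_rate=40.0, telomere_fraction=4.5e-4),
        "MIA": dict(wgd_probability=0.09, arm_event_rate=3.0, focal_event_rate=1.5,
                    somatic_mutation_rate=60.0, telomere_fraction=4.0e-4),
        "ADC": dict(wgd_probability=0.30, arm_event_rate=5.0, focal_event_rate=2.0,
                    somatic_mutation_rate=100.0, telomere_fraction=3.5e-4),
    }
    return {s: StageParams(stage=s, n_samples=n_samples, **kw) for s, kw in table.items()}


#: telomeric read fraction used for matched-normal read sets
NORMAL_TELOMERE_FRACTION = 6.0e-4


@dataclass
class TruthRecord:
    """Generating truth for one synthetic sample."""

    sample_id: str
    is_wgd: bool = False
    true_ploidy: float = 2.0
    true_somatic_sites: list[tuple[str, int, str, str]] = field(default_factory=list)
    true_telomere_fraction: float | None = None
    stage: str = "unknown"


# ---------------------------------------------------------------------------
# copy-number cohorts


def _apply_unit_events(
    states: np.ndarray,
    n_events: int,
    rng: np.random.Generator,
    gain_probability: float = 0.5,
    max_retries: int = 5,
) -> None:
    """Apply unit gains/losses in place; losses at 0 are re-drawn, then skipped."""
    n_arms = states.shape[0]
    for _ in range(n_events):
        for _retry in range(max_retries + 1):
            arm = int(rng.integers(n_arms))
            allele = int(rng.integers(2))
            delta = 1 if rng.random() < gain_probability else -1
            if delta < 0 and states[arm, allele] == 0:
                continue
            states[arm, allele] += delta
            break


def _sample_segments(
    states: np.ndarray,
    arms: GenomeArms,
    rng: np.random.Generator,
    focal_events: int,
    mean_reads: int = 200,
) -> list[Segment]:
    """Arm-resolution segments, with focal events carved into random arms."""
    focal_arms: dict[int, tuple[int, int, int]] = {}  # arm idx -> (start, end, delta)
    arm_list = list(arms)
    for _ in range(focal_events):
        for _retry in range(10):
            i = int(rng.integers(len(arm_list)))
            if i in focal_arms:
                continue
            a = arm_list[i]
            max_len = min(5_000_000, a.length // 2)
            if max_len < 100_000:
                continue
            flen = int(rng.integers(100_000, max_len))
            fstart = int(rng.integers(a.start, a.end - flen))
            delta = 2 if rng.random() < 0.5 else -2
            focal_arms[i] = (fstart, fstart + flen, delta)
            break
    segments: list[Segment] = []

    def _reads() -> int:
        return int(rng.poisson(mean_reads))

    for i, a in enumerate(arm_list):
        major, minor = int(states[i, 0]), int(states[i, 1])
        if i not in focal_arms:
            segments.append(Segment(a.chrom, a.start, a.end, None, major, minor, _reads()))
            continue
        fstart, fend, delta = focal_arms[i]
        if delta > 0:
            fmaj, fmin = major + delta, minor
        else:
            total = max(major + minor + delta, 0)
            fmaj, fmin = (total + 1) // 2, total // 2
        if fstart > a.start:
            segments.append(Segment(a.chrom, a.start, fstart, None, major, minor, _reads()))
        segments.append(Segment(a.chrom, fstart, fend, None, fmaj, fmin, _reads()))
        if fend < a.end:
            segments.append(Segment(a.chrom, fend, a.end, None, major, minor, _reads()))
    return segments


def simulate_cn_cohort(
    params: Sequence[StageParams] | StageParams,
    arms: GenomeArms | None = None,
    seed: int = 0,
    gain_probability: float = 0.5,
) -> tuple[list[SegmentProfile], list[TruthRecord]]:
    """Simulate copy-number profiles with known WGD and ploidy truth.

    Per sample: every arm starts at (1, 1); with probability
    ``wgd_probability`` both alleles are doubled; then Poisson-many unit
    gains/losses land on random (arm, allele) pairs (floor at 0;
    ``gain_probability`` sets the gain/loss mix), and optional focal
    events are carved into single arms.  Identical seeds give identical
    cohorts.
    """
    if isinstance(params, StageParams):
        params = [params]
    if arms is None:
        arms = GenomeArms.default()
    rng = np.random.default_rng(seed)
    profiles: list[SegmentProfile] = []
    truths: list[TruthRecord] = []
    for sp in params:
        for k in range(sp.n_samples):
            sample_id = f"{sp.stage}_{k:04d}"
            states = np.ones((len(arms), 2), dtype=np.int64)
            is_wgd = bool(rng.random() < sp.wgd_probability)
            if is_wgd:
                states *= 2
            _apply_unit_events(states, int(rng.poisson(sp.arm_event_rate)), rng, gain_probability)
            # keep major >= minor per arm
            states.sort(axis=1)
            states = states[:, ::-1]
            focal = int(rng.poisson(sp.focal_event_rate))
            segments = _sample_segments(states, arms, rng, focal)
            profile = SegmentProfile(sample_id, segments, histology=sp.stage)
            lengths = np.array([s.length for s in segments], dtype=float)
            totals = np.array([s.total_cn for s in segments], dtype=float)
            truths.append(
                TruthRecord(
                    sample_id=sample_id,
                    is_wgd=is_wgd,
                    true_ploidy=float((lengths * totals).sum() / lengths.sum()),
                    true_telomere_fraction=sp.telomere_fraction,
                    stage=sp.stage,
                )
            )
            profiles.append(profile)
    return profiles, truths


# ---------------------------------------------------------------------------
# multi-caller variant call sets

_BASES = "ACGT"


def _random_sites(
    rng: np.random.Generator, n: int, used: set[tuple[str, int]]
) -> list[tuple[str, int, str, str]]:
    sites: list[tuple[str, int, str, str]] = []
    while len(sites) < n:
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = int(rng.integers(10_000, 100_000_000))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[int(rng.integers(4))]
        while alt == ref:
            alt = _BASES[int(rng.integers(4))]
        sites.append((chrom, pos, ref, alt))
    return sites


def simulate_variant_calls(
    params: StageParams,
    seed: int = 0,
    *,
    caller_sensitivity: float = 0.9,
    germline_rate: float = 30.0,
    artifact_rate: float = 20.0,
    census_fraction: float = 0.05,
    trusted_fraction: float = 0.02,
    mean_tumor_depth: int = 150,
    mean_normal_depth: int = 100,
    af_beta: tuple[float, float] = (2.0, 6.0),
    sample_id: str = "sample",
) -> tuple[dict[str, list[VariantCall]], TruthRecord]:
    """Simulate per-caller somatic call tables with known truth.

    True somatic SNVs draw allele fractions from ``Beta(*af_beta)`` and
    are seen independently by each caller with ``caller_sensitivity``.
    Contaminants are dbSNP-listed sites that survive the depth/AF gates
    (so the annotation clause, not the evidence clause, must remove
    them), and FFPE-type artifact calls carry the artifact flag at low
    allele fraction.  Returns one call list per caller plus the truth.
    """
    rng = np.random.default_rng(seed)
    used: set[tuple[str, int]] = set()
    tables: dict[str, list[VariantCall]] = {c: [] for c in KNOWN_CALLERS}

    def _evidence(af: float) -> tuple[int, int, float, int, float]:
        depth = max(int(rng.poisson(mean_tumor_depth)), 30)
        alt = int(rng.binomial(depth, af))
        n_depth = max(int(rng.poisson(mean_normal_depth)), 15)
        return depth, alt, alt / depth, n_depth, 0.0

    def _emit(call: VariantCall, sensitivity: float) -> bool:
        seen = [c for c in KNOWN_CALLERS if rng.random() < sensitivity]
        for c in seen:
            tables[c].append(call)
        return bool(seen)

    # true somatic SNVs
    n_true = int(rng.poisson(params.somatic_mutation_rate))
    somatic_sites: list[tuple[str, int, str, str]] = []
    for chrom, pos, ref, alt_base in _random_sites(rng, n_true, used):
        af = float(rng.beta(*af_beta))
        depth, alt, t_af, n_depth, n_af = _evidence(af)
        call = VariantCall(
            chrom, pos, ref, alt_base,
            callers=frozenset({"truth"}),
            tumor_depth=depth, tumor_alt_count=alt, tumor_af=t_af,
            normal_depth=n_depth, normal_af=n_af,
            in_census=bool(rng.random() < census_fraction),
            in_trusted_list=bool(rng.random() < trusted_fraction),
        )
        _emit(call, caller_sensitivity)
        somatic_sites.append((chrom, pos, ref, alt_base))

    # dbSNP-listed contaminants (heterozygous-like AF, clean normal)
    for chrom, pos, ref, alt_base in _random_sites(rng, int(rng.poisson(germline_rate)), used):
        depth, alt, t_af, n_depth, n_af = _evidence(float(rng.beta(20, 20)))
        _emit(
            VariantCall(
                chrom, pos, ref, alt_base,
                callers=frozenset({"truth"}),
                tumor_depth=depth, tumor_alt_count=alt, tumor_af=t_af,
                normal_depth=n_depth, normal_af=n_af,
                in_dbsnp=True,
            ),
            0.98,
        )

    # FFPE-type artifacts, flagged by the artifact detectors
    for chrom, pos, ref, alt_base in _random_sites(rng, int(rng.poisson(artifact_rate)), used):
        depth, alt, t_af, n_depth, n_af = _evidence(float(rng.beta(1.5, 20)))
        _emit(
            VariantCall(
                chrom, pos, ref, alt_base,
                callers=frozenset({"truth"}),
                tumor_depth=depth, tumor_alt_count=alt, tumor_af=t_af,
                normal_depth=n_depth, normal_af=n_af,
                artifact_flagged=True,
            ),
            0.7,
        )

    # strip the construction marker; caller sets are assigned at merge time
    tables = {
        c: [VariantCall(**{**v.__dict__, "callers": frozenset({c})}) for v in calls]
        for c, calls in tables.items()
    }
    truth = TruthRecord(
        sample_id=sample_id,
        true_somatic_sites=somatic_sites,
        true_telomere_fraction=params.telomere_fraction,
        stage=params.stage,
    )
    return tables, truth


def precision_recall(
    kept: Sequence[VariantCall], truth_sites: Sequence[tuple[str, int, str, str]]
) -> tuple[float, float, float]:
    """(precision, recall, F1) of a kept set against the generating truth."""
    kept_keys = {v.key for v in kept}
    truth_set = set(truth_sites)
    tp = len(kept_keys & truth_set)
    precision = tp / len(kept_keys) if kept_keys else 1.0
    recall = tp / len(truth_set) if truth_set else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


# ---------------------------------------------------------------------------
# telomere read sets

_REPEAT_UNITS = (CANONICAL_REPEAT, *VARIANT_REPEATS)


def _telomeric_read(rng: np.random.Generator, read_length: int, canonical_weight: float) -> str:
    units: list[str] = []
    size = 0
    while size < read_length + 6:
        if rng.random() < canonical_weight:
            units.append(CANONICAL_REPEAT)
        else:
            units.append(_REPEAT_UNITS[1 + int(rng.integers(10))])
        size += 6
    offset = int(rng.integers(6))
    seq = "".join(units)[offset : offset + read_length]
    if rng.random() < 0.5:
        seq = reverse_complement(seq)
    return seq


def simulate_telomere_reads(
    n_reads: int,
    telomere_fraction: float,
    read_length: int = 100,
    seed: int = 0,
    canonical_weight: float = 0.7,
    sample_id: str = "sample",
) -> tuple[list[tuple[str, str]], TruthRecord]:
    """Simulate reads with a known telomeric fraction.

    Telomeric reads are tandem repeat arrays (a ``canonical_weight`` mix
    of TTAGGG and uniform variant units) at random phase and strand;
    background reads are uniform random sequence.  Returns (name,
    sequence) records in shuffled order plus the truth record.
    """
    if not (0.0 <= telomere_fraction <= 1.0):
        raise ValueError("telomere_fraction must be in [0, 1]")
    if read_length < 30:
        raise ValueError("read_length must be >= 30")
    rng = np.random.default_rng(seed)
    n_tel = int(rng.binomial(n_reads, telomere_fraction)) if n_reads else 0
    sequences = [_telomeric_read(rng, read_length, canonical_weight) for _ in range(n_tel)]
    # vectorized uniform-random background
    n_bg = n_reads - n_tel
    if n_bg:
        codes = np.frombuffer(b"ACGT", dtype=np.uint8)[
            rng.integers(0, 4, size=n_bg * read_length)
        ]
        blob = codes.tobytes().decode("ascii")
        sequences.extend(blob[i * read_length : (i + 1) * read_length] for i in range(n_bg))
    order = rng.permutation(n_reads)
    records = [(f"read_{i:07d}", sequences[j]) for i, j in enumerate(order)]
    truth = TruthRecord(sample_id=sample_id, true_telomere_fraction=telomere_fraction)
    return records, truth


def write_fastq(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_tsv(truths: Sequence[TruthRecord], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "sample_id": t.sample_id,
            "stage": t.stage,
            "is_wgd": t.is_wgd,
            "true_ploidy": t.true_ploidy,
            "n_true_somatic": len(t.true_somatic_sites),
            "true_telomere_fraction": t.true_telomere_fraction,
        }
        for t in truths
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
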