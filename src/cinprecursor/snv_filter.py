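"""Multi-caller somatic SNV consensus filtering and mutational burden.

Candidate SNVs from up to five somatic callers (Mutect, Varscan2,
Strelka2, Lancet, SomaticSniper) are merged by site and allele, then
passed through the consensus cascade:

caller-level thresholds (all variants)
    tumor allele fraction >= 0.02, tumor depth >= 20,
    normal allele fraction <= 0.01, normal depth >= 10;
trusted-list bypass
    variants on a curated trusted list skip all later clauses;
consensus clauses (everything else)
    1) called by at least two callers, 2) not flagged as an FFPE-type
    artifact, 3) absent from dbSNP, and 4) tumor allele fraction >= 0.04
    with LOD >= 10, or the site lies in a cancer gene census gene.

The LOD score is a binomial log10 likelihood ratio comparing the observed
alt counts under the empirical allele fraction against a sequencing-error
model; an externally supplied LOD overrides the computed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "KNOWN_CALLERS",
    "VariantCall",
    "FilterConfig",
    "FilterAudit",
    "merge_caller_sets",
    "binomial_lod",
    "consensus_filter",
    "tmb",
    "read_calls_tsv",
    "write_calls_tsv",
    "read_caller_vcf",
]

KNOWN_CALLERS = ("mutect", "varscan2", "strelka2", "lancet", "somaticsniper")

#: which caller's depths/AFs win when a variant is reported by several
CALLER_PRIORITY = ("mutect", "strelka2", "varscan2", "lancet", "somaticsniper")

_FLAG_FIELDS = ("in_dbsnp", "in_census", "in_trusted_list", "artifact_flagged")


@dataclass(frozen=True)
class VariantCall:
    """One candidate somatic SNV with its evidence and annotation flags."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    callers: frozenset[str]
    tumor_depth: int
    tumor_alt_count: int
    tumor_af: float
    normal_depth: int
    normal_af: float
    in_dbsnp: bool = False
    in_census: bool = False
    in_trusted_list: bool = False
    artifact_flagged: bool = False
    lod: float | None = None

    def __post_init__(self) -> None:
        if not self.callers:
            raise ValueError(f"{self.key}: callers must be non-empty")
        if not (0.0 <= self.tumor_af <= 1.0):
            raise ValueError(f"{self.key}: tumor_af out of [0, 1]")
        if self.tumor_alt_count > self.tumor_depth:
            raise ValueError(f"{self.key}: alt count exceeds depth")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.ref != "-" and self.alt != "-"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the consensus cascade (defaults per the pipeline)."""

    min_tumor_af_call: float = 0.02
    min_tumor_depth: int = 20
    max_normal_af: float = 0.01
    min_normal_depth: int = 10
    min_callers: int = 2
    min_tumor_af_final: float = 0.04
    min_lod: float = 10.0
    error_rate: float = 1e-3
    trusted_bypasses_caller_thresholds: bool = False
    census_exempt_from_dbsnp: bool = False

    def __post_init__(self) -> None:
        if self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")
        for name in (
            "min_tumor_af_call",
            "min_tumor_depth",
            "max_normal_af",
            "min_normal_depth",
            "min_tumor_af_final",
            "min_lod",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 < self.error_rate < 1.0):
            raise ValueError("error_rate must be in (0, 1)")


@dataclass
class FilterAudit:
    """Per-variant decision record: first failing clause, or pass route."""

    variant: VariantCall
    kept: bool
    reason: str  # pass routes: "consensus", "trusted_list"; else first failure


def merge_caller_sets(
    per_caller_calls: Mapping[str, Iterable[VariantCall]],
    priority: tuple[str, ...] = CALLER_PRIORITY,
) -> list[VariantCall]:
    """Union per-caller call tables into one record per unique variant.

    Records are keyed by (chrom, pos, ref, alt); the caller set is the
    union, depths/AFs come from the highest-priority caller reporting the
    variant, and annotation flags are OR-combined.  Conflicting reference
    alleles at one position raise.
    """
    rank = {c: i for i, c in enumerate(priority)}
    merged: dict[tuple[str, int, str, str], VariantCall] = {}
    ref_seen: dict[tuple[str, int], str] = {}
    source_rank: dict[tuple[str, int, str, str], int] = {}
    for caller, calls in per_caller_calls.items():
        for call in calls:
            if caller not in call.callers:
                call = replace(call, callers=frozenset({caller}))
            site = (call.chrom, call.pos)
            if site in ref_seen and ref_seen[site] != call.ref:
                raise ValueError(
                    f"conflicting ref alleles at {call.chrom}:{call.pos} "
                    f"({ref_seen[site]!r} vs {call.ref!r})"
                )
            ref_seen[site] = call.ref
            r = rank.get(caller, len(priority))
            if call.key not in merged:
                merged[call.key] = call
                source_rank[call.key] = r
                continue
            prev = merged[call.key]
            base = call if r < source_rank[call.key] else prev
            merged[call.key] = replace(
                base,
                callers=prev.callers | call.callers,
                **{f: getattr(prev, f) or getattr(call, f) for f in _FLAG_FIELDS},
                lod=base.lod
                if base.lod is not None
                else (prev.lod if prev.lod is not None else call.lod),
            )
            source_rank[call.key] = min(r, source_rank[call.key])
    return sorted(merged.values(), key=lambda v: (v.chrom, v.pos, v.ref, v.alt))


def binomial_lod(tumor_alt_count: int, tumor_depth: int, error_rate: float = 1e-3) -> float:
    """Binomial log10 likelihood ratio of variant vs sequencing error.

    log10[ f^a (1-f)^(d-a) / (e^a (1-e)^(d-a)) ] with f = a/d; 0 when a = 0.
    """
    if tumor_depth <= 0:
        raise ValueError("tumor_depth must be > 0")
    if not (0 <= tumor_alt_count <= tumor_depth):
        raise ValueError("alt count must be in [0, depth]")
    if not (0.0 < error_rate < 1.0):
        raise ValueError("error_rate must be in (0, 1)")
    a, d, e = tumor_alt_count, tumor_depth, error_rate
    if a == 0:
        return 0.0
    f = a / d
    lod = a * (math.log10(f) - math.log10(e))
    if a < d:
        lod += (d - a) * (math.log10(1.0 - f) - math.log10(1.0 - e))
    else:
        lod -= 0.0  # f = 1: the (d-a) term vanishes
    return lod


def effective_lod(call: VariantCall, config: FilterConfig) -> float:
    """The LOD used in filtering: supplied value, else computed binomial."""
    if call.lod is not None:
        return call.lod
    return binomial_lod(call.tumor_alt_count, call.tumor_depth, config.error_rate)


def consensus_filter(
    calls: Iterable[VariantCall],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[VariantCall], list[FilterAudit]]:
    """Apply the consensus cascade; return kept calls and a full audit.

    The audit covers every input variant; rejected variants carry the
    first failing clause, in cascade order: ``low_tumor_af``,
    ``low_tumor_depth``, ``high_normal_af``, ``low_normal_depth``,
    ``too_few_callers``, ``artifact``, ``dbsnp``, ``af_lod``.
    """
    kept: list[VariantCall] = []
    audit: list[FilterAudit] = []

    def reject(call: VariantCall, reason: str) -> None:
        audit.append(FilterAudit(call, False, reason))

    def keep(call: VariantCall, route: str) -> None:
        kept.append(call)
        audit.append(FilterAudit(call, True, route))

    for call in calls:
        trusted = call.in_trusted_list
        if not (trusted and config.trusted_bypasses_caller_thresholds):
            if call.tumor_af < config.min_tumor_af_call:
                reject(call, "low_tumor_af")
                continue
            if call.tumor_depth < config.min_tumor_depth:
                reject(call, "low_tumor_depth")
                continue
            if call.normal_af > config.max_normal_af:
                reject(call, "high_normal_af")
                continue
            if call.normal_depth < config.min_normal_depth:
                reject(call, "low_normal_depth")
                continue
        if trusted:
            keep(call, "trusted_list")
            continue
        if len(call.callers) < config.min_callers:
            reject(call, "too_few_callers")
            continue
        if call.artifact_flagged:
            reject(call, "artifact")
            continue
        if call.in_dbsnp and not (call.in_census and config.census_exempt_from_dbsnp):
            reject(call, "dbsnp")
            continue
        passes_af_lod = (
            call.tumor_af >= config.min_tumor_af_final
            and effective_lod(call, config) >= config.min_lod
        )
        if passes_af_lod or call.in_census:
            keep(call, "consensus")
        else:
            reject(call, "af_lod")
    return kept, audit


def tmb(kept: Iterable[VariantCall], capture_size_mb: float | None = None, mode: str = "per_mb") -> float:
    """Tumor mutational burden: mutation count, or count per megabase."""
    n = sum(1 for _ in kept)
    if mode == "count":
        return float(n)
    if mode != "per_mb":
        raise ValueError(f"mode must be 'per_mb' or 'count', got {mode!r}")
    if capture_size_mb is None or capture_size_mb <= 0:
        raise ValueError("capture_size_mb must be > 0 in per_mb mode")
    return n / capture_size_mb


# ---------------------------------------------------------------------------
# IO

_TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "callers",
    "tumor_depth",
    "tumor_alt_count",
    "tumor_af",
    "normal_depth",
    "normal_af",
    "in_dbsnp",
    "in_census",
    "in_trusted_list",
    "artifact_flagged",
    "lod",
]


def read_calls_tsv(path: str | Path, caller: str | None = None) -> list[VariantCall]:
    """Read a flat call table; ``caller`` overrides/supplies the caller set."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    calls: list[VariantCall] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        callers = (
            frozenset({caller})
            if caller is not None
            else frozenset(str(d.get("callers", "")).split(",")) - {""}
        )
        lod = d.get("lod")
        calls.append(
            VariantCall(
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref=str(d["ref"]),
                alt=str(d["alt"]),
                callers=callers,
                tumor_depth=int(d["tumor_depth"]),
                tumor_alt_count=int(d["tumor_alt_count"]),
                tumor_af=float(d["tumor_af"]),
                normal_depth=int(d["normal_depth"]),
                normal_af=float(d["normal_af"]),
                in_dbsnp=bool(d.get("in_dbsnp", False)),
                in_census=bool(d.get("in_census", False)),
                in_trusted_list=bool(d.get("in_trusted_list", False)),
                artifact_flagged=bool(d.get("artifact_flagged", False)),
                lod=None if lod is None or pd.isna(lod) else float(lod),
            )
        )
    return calls


def write_calls_tsv(calls: Iterable[VariantCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        d = {col: getattr(c, col) for col in _TSV_COLUMNS if col != "callers"}
        d["callers"] = ",".join(sorted(c.callers))
        rows.append(d)
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_caller_vcf(
    path: str | Path,
    caller: str,
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> list[VariantCall]:
    """Read one caller's VCF into VariantCall records (SNVs only).

    Allele fractions come from the FORMAT ``AF`` tag when present, else
    from ``AD``/``DP``; depth from ``DP``, else the sum of ``AD``.
    Multi-allelic records contribute one call per alt; non-SNV alleles
    are dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        t_idx = samples.index(tumor_sample)
        n_idx = samples.index(normal_sample)
    except ValueError as exc:
        raise ValueError(f"{path}: expected samples {tumor_sample}/{normal_sample}, found {samples}") from exc

    def _fmt(variant, tag: str):
        try:
            return variant.format(tag)
        except KeyError:  # tag not defined in the header
            return None

    def _sample_stats(variant, idx: int, alt_i: int) -> tuple[int, int, float]:
        ad = _fmt(variant, "AD")
        dp = _fmt(variant, "DP")
        depth = int(dp[idx][0]) if dp is not None else int(sum(max(x, 0) for x in ad[idx]))
        alt_count = int(ad[idx][alt_i + 1]) if ad is not None else 0
        af_arr = _fmt(variant, "AF")
        if af_arr is not None:
            af = float(af_arr[idx][min(alt_i, len(af_arr[idx]) - 1)])
        else:
            af = alt_count / depth if depth > 0 else 0.0
        return depth, alt_count, af

    calls: list[VariantCall] = []
    for variant in vcf:
        if len(variant.REF) != 1:
            continue
        for alt_i, alt in enumerate(variant.ALT):
            if len(alt) != 1:
                continue
            t_depth, t_alt, t_af = _sample_stats(variant, t_idx, alt_i)
            n_depth, _, n_af = _sample_stats(variant, n_idx, alt_i)
            calls.append(
                VariantCall(
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref=variant.REF,
                    alt=alt,
                    callers=frozenset({caller}),
                    tumor_depth=t_depth,
                    tumor_alt_count=min(t_alt, t_depth),
                    tumor_af=min(max(t_af, 0.0), 1.0),
                    normal_depth=n_depth,
                    normal_af=min(max(n_af, 0.0), 1.0),
                )
            )
    return calls


def write_audit_tsv(audit: Iterable[FilterAudit], path: str | Path) -> None:
    rows = [
        {
            "chrom": a.variant.chrom,
            "pos": a.variant.pos,
            "ref": a.variant.ref,
            "alt": a.variant.alt,
            "decision": "keep" if a.kept else "reject",
            "reason": a.reason,
        }
        for a in audit
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "decision", "reason"]).to_csv(
        path, sep="\t", index=False
    )
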