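"""Randomization test for whole-genome doubling (WGD).

A sample is represented as an arm-resolution profile of integer major and
minor allele copy numbers.  The test asks whether the observed proportion
of arms with major allele copy number >= 2 could have arisen from random
sequential unit aberrations rather than a doubling event:

* ``Ns`` — the total number of unit aberrations relative to diploid,
  ``sum(|major - 1| + |minor - 1|)`` over arms;
* ``Ps`` — a categorical probability table over events
  (arm x allele{major, minor} x direction{gain, loss}) estimated from the
  observed deviation frequencies, smoothed with one uniformly spread
  pseudo-count;
* the null applies ``Ns`` i.i.d. events drawn from ``Ps`` to a diploid
  (1, 1)-everywhere profile and records, per simulation, the proportion of
  arms whose larger allele reaches >= 2.

The Monte-Carlo p-value is the fraction of simulations whose statistic
reaches (>=, by default) the observed one; samples with mean ploidy <= 3
are called WGD when p < 0.001, and samples with ploidy > 3 are called WGD
outright.  An exact-enumeration null (:func:`exact_null`) serves as an
independent oracle on small genomes.

A loss drawn for an allele already at copy number 0 is re-drawn from
``Ps`` (up to ``max_retries`` times, then treated as a no-op), so the null
never produces negative copy numbers.  The exact null enumerates this
re-draw rule analytically: at a state where the invalid-event mass is
``q``, each valid event ``e`` has effective per-step probability
``p_e * (1 - q**(R+1)) / (1 - q)`` and the no-op has mass ``q**(R+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .arms import GenomeArms
from .cn_profile import ArmProfile

__all__ = [
    "AberrationModel",
    "WGDResult",
    "count_aberrations",
    "estimate_probs",
    "observed_wgd_statistic",
    "simulate_null",
    "exact_null",
    "classify_wgd",
    "wgd_test",
]

# Event encoding: index e in [0, 4A): arm = e // 4, allele = (e // 2) % 2
# (0 = major, 1 = minor), direction = e % 2 (0 = gain, 1 = loss).
_N_EVENT_KINDS = 4

DEFAULT_ALPHA = 0.001
DEFAULT_N_SIMS = 10_000
DEFAULT_MAX_RETRIES = 5


@dataclass
class AberrationModel:
    """Null model for one sample: event count Ns and event probabilities Ps."""

    n_aberrations: int
    probs: np.ndarray  # shape (A, 2, 2): arm x allele x direction
    arm_names: list[str]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.n_aberrations < 0:
            raise ValueError("n_aberrations must be >= 0")
        if self.probs.shape != (len(self.arm_names), 2, 2):
            raise ValueError(f"probs must have shape (A, 2, 2), got {self.probs.shape}")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be >= 0")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")

    @property
    def n_arms(self) -> int:
        return len(self.arm_names)

    @property
    def flat_probs(self) -> np.ndarray:
        """Probabilities flattened to event indices (see module docstring)."""
        return self.probs.reshape(-1)


@dataclass
class WGDResult:
    """Outcome of the WGD randomization test for one sample."""

    sample_id: str
    observed_stat: float
    p_value: float
    n_sims: int
    ploidy_used: float
    is_wgd: bool
    seed: int
    n_aberrations: int = 0


def count_aberrations(arm: ArmProfile) -> int:
    """Total unit gains/losses away from the diploid (1, 1) state (Ns)."""
    return sum(abs(maj - 1) + abs(mnr - 1) for maj, mnr in arm.states.values())


def observed_wgd_statistic(arm: ArmProfile, arm_names: Sequence[str] | None = None) -> float:
    """Proportion of arms with major allele copy number >= 2."""
    names = list(arm_names) if arm_names is not None else list(arm.states)
    if not names:
        raise ValueError("empty arm profile")
    return sum(arm.states[n][0] >= 2 for n in names) / len(names)


def estimate_probs(
    cohort: Iterable[ArmProfile],
    arm_names: Sequence[str],
) -> np.ndarray:
    """Event probabilities Ps estimated from deviation frequencies.

    For each (arm, allele, direction) the raw weight is the fraction of
    cohort samples whose allele at that arm deviates from 1 in that
    direction.  One pseudo-count is spread uniformly over all events so
    that no event has zero probability, then weights are normalized.
    A single-sample cohort yields per-sample probabilities.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    names = list(arm_names)
    counts = np.zeros((len(names), 2, 2), dtype=float)
    for prof in cohort:
        for i, name in enumerate(names):
            major, minor = prof.states[name]
            for allele, cn in ((0, major), (1, minor)):
                if cn > 1:
                    counts[i, allele, 0] += 1.0
                elif cn < 1:
                    counts[i, allele, 1] += 1.0
    counts /= len(cohort)
    counts += 1.0 / counts.size  # one pseudo-count spread uniformly
    probs = counts / counts.sum()
    # exact renormalization so the model validates at 1e-12
    return probs / probs.sum()


def build_model(
    arm: ArmProfile,
    arm_names: Sequence[str],
    cohort: Iterable[ArmProfile] | None = None,
) -> AberrationModel:
    """Ns from the sample; Ps from the cohort if given, else per-sample."""
    source = list(cohort) if cohort is not None else [arm]
    return AberrationModel(
        n_aberrations=count_aberrations(arm),
        probs=estimate_probs(source, arm_names),
        arm_names=list(arm_names),
    )


def _draw_events(rng: np.random.Generator, cum: np.ndarray, n: int) -> np.ndarray:
    return np.searchsorted(cum, rng.random(n), side="right").astype(np.int64)


def simulate_null(
    model: AberrationModel,
    observed_stat: float,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
    *,
    max_retries: int = DEFAULT_MAX_RETRIES,
    counting: str = "ge",
    plus_one: bool = False,
) -> tuple[float, np.ndarray]:
    """Monte-Carlo null for the WGD statistic.

    Each simulation starts every arm at (1, 1) and applies ``Ns`` events
    drawn i.i.d. from ``Ps``; a loss at copy number 0 is re-drawn up to
    ``max_retries`` times, then skipped.  Returns the p-value and the
    per-simulation statistics.  ``counting='ge'`` (default) counts
    simulations whose statistic is >= the observed one; ``'gt'`` counts
    strict exceedances.  ``plus_one`` applies the (k+1)/(n+1) correction.
    Identical seeds give identical results.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if counting not in ("ge", "gt"):
        raise ValueError(f"counting must be 'ge' or 'gt', got {counting!r}")
    rng = np.random.default_rng(seed)
    A = model.n_arms
    ns = model.n_aberrations
    p = model.flat_probs
    cum = np.cumsum(p)
    cum[-1] = 1.0
    state = np.ones((n_sims, A, 2), dtype=np.int16)
    if ns > 0:
        events = _draw_events(rng, cum, n_sims * ns).reshape(n_sims, ns)
        rows = np.arange(n_sims)
        for t in range(ns):
            e = events[:, t]
            pending = rows
            for _retry in range(max_retries + 1):
                arm_idx = e[pending] >> 2
                allele_idx = (e[pending] >> 1) & 1
                is_loss = (e[pending] & 1).astype(bool)
                cur = state[pending, arm_idx, allele_idx]
                invalid = is_loss & (cur == 0)
                ok = ~invalid
                sel = pending[ok]
                delta = np.where(is_loss[ok], -1, 1).astype(np.int16)
                state[sel, arm_idx[ok], allele_idx[ok]] += delta
                pending = pending[invalid]
                if pending.size == 0:
                    break
                e = e.copy()
                e[pending] = _draw_events(rng, cum, pending.size)
            # exhausted retries: remaining invalid events are no-ops
    stats = (state.max(axis=2) >= 2).mean(axis=1)
    if counting == "ge":
        k = int(np.sum(stats >= observed_stat - 1e-12))
    else:
        k = int(np.sum(stats > observed_stat + 1e-12))
    p_value = (k + 1) / (n_sims + 1) if plus_one else k / n_sims
    return p_value, stats


def exact_null(
    model: AberrationModel,
    observed_stat: float,
    max_states: int = 10**6,
    *,
    max_retries: int = DEFAULT_MAX_RETRIES,
    counting: str = "ge",
) -> float:
    """Exact Pr(statistic >= observed) under the same null as the MC test.

    Enumerates the event process by dynamic programming over arm states,
    folding the re-draw rule into per-state transition probabilities.
    Usable when the ordered-event space ``(4A)**Ns`` is at most
    ``max_states``; larger problems raise and should use Monte-Carlo.
    """
    A = model.n_arms
    ns = model.n_aberrations
    if (_N_EVENT_KINDS * A) ** ns > max_states:
        raise ValueError(
            f"event-sequence space (4*{A})^{ns} exceeds max_states={max_states}; "
            "use simulate_null"
        )
    p = model.flat_probs
    n_events = p.size

    def statistic_count(state: tuple[int, ...]) -> int:
        return sum(1 for a in range(A) if max(state[2 * a], state[2 * a + 1]) >= 2)

    # distribution over final statistic counts, memoized on (state, remaining)
    memo: dict[tuple[tuple[int, ...], int], dict[int, float]] = {}

    def go(state: tuple[int, ...], remaining: int) -> dict[int, float]:
        key = (state, remaining)
        if key in memo:
            return memo[key]
        if remaining == 0:
            out = {statistic_count(state): 1.0}
            memo[key] = out
            return out
        # invalid mass q: losses on alleles already at 0
        q = 0.0
        for e in range(n_events):
            if (e & 1) and state[2 * (e >> 2) + ((e >> 1) & 1)] == 0:
                q += p[e]
        noop_mass = q ** (max_retries + 1)
        scale = (1.0 - noop_mass) / (1.0 - q) if q < 1.0 else 0.0
        out: dict[int, float] = {}
        if noop_mass > 0.0 or q >= 1.0:
            mass = noop_mass if q < 1.0 else 1.0
            for stat, pr in go(state, remaining - 1).items():
                out[stat] = out.get(stat, 0.0) + mass * pr
        for e in range(n_events):
            if p[e] == 0.0:
                continue
            arm_i = e >> 2
            allele_i = (e >> 1) & 1
            idx = 2 * arm_i + allele_i
            if (e & 1) and state[idx] == 0:
                continue  # invalid: already folded into the no-op mass
            delta = -1 if (e & 1) else 1
            nxt = list(state)
            nxt[idx] += delta
            for stat, pr in go(tuple(nxt), remaining - 1).items():
                out[stat] = out.get(stat, 0.0) + p[e] * scale * pr
        memo[key] = out
        return out

    dist = go(tuple([1] * (2 * A)), ns)
    if counting == "ge":
        return sum(pr for stat, pr in dist.items() if stat / A >= observed_stat - 1e-12)
    return sum(pr for stat, pr in dist.items() if stat / A > observed_stat + 1e-12)


def classify_wgd(p_value: float, mean_ploidy: float, alpha: float = DEFAULT_ALPHA) -> bool:
    """WGD call: ploidy > 3 is WGD outright; at ploidy <= 3, p < alpha."""
    if not (0.0 <= p_value <= 1.0):
        raise ValueError("p_value must be in [0, 1]")
    if mean_ploidy <= 0:
        raise ValueError("mean_ploidy must be > 0")
    if mean_ploidy > 3:
        return True
    return p_value < alpha


def wgd_test(
    arm: ArmProfile,
    arms: GenomeArms,
    *,
    cohort: Iterable[ArmProfile] | None = None,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    counting: str = "ge",
    plus_one: bool = False,
) -> WGDResult:
    """End-to-end WGD test for one arm profile.

    ``Ps`` is estimated per-sample by default, or from ``cohort`` when
    provided (the choice is reported through the result, not silent).
    """
    names = arms.names
    model = build_model(arm, names, cohort=cohort)
    observed = observed_wgd_statistic(arm, names)
    p_value, _ = simulate_null(
        model, observed, n_sims=n_sims, seed=seed, counting=counting, plus_one=plus_one
    )
    return WGDResult(
        sample_id=arm.sample_id,
        observed_stat=observed,
        p_value=p_value,
        n_sims=n_sims,
        ploidy_used=arm.mean_ploidy,
        is_wgd=classify_wgd(p_value, arm.mean_ploidy, alpha),
        seed=seed,
        n_aberrations=model.n_aberrations,
    )
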