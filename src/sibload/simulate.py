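"""Synthetic line-extinction experiments and reproductive schedules.

The generator mirrors the statistical structure the analysis assumes, so
every pipeline stage is testable without the original lab records:

* **Line extinction.**  Each line runs serial sib-mating crosses; at
  generation g the cross passes copulation, fertility and development as
  three sequential conditional Bernoulli draws with stage-specific
  success probabilities expit(beta0_s + beta1_s * F_parents(g)).  A
  single (beta0, beta1) pair may be given instead, in which case success
  is drawn directly and no stage flags are emitted.  An optional
  per-line-per-generation maternal-effect lethal event kills the whole
  brood (development fails regardless of the draw) — the whole-brood,
  non-segregating failure class seen in real inbreeding experiments.

* **Reproductive schedules.**  Founder females draw adult-progeny counts
  per laying interval from a negative binomial around a hump-shaped mean
  schedule; inbred lines scale the means by per-line fitness multipliers,
  optionally delay laying by whole intervals, or are maternal-effect
  lethal (all counts zero).

Random streams are split per line with :class:`numpy.random.SeedSequence`
so adding lines never perturbs existing lines' trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .fitness import ReproSchedule
from .load_model import STAGES, CrossRecord
from .pedigree import parental_F_for_cross, sib_mating_F

__all__ = [
    "SimConfig",
    "ScheduleConfig",
    "simulate_line_extinction",
    "analytic_survival",
    "simulate_repro_schedules",
]


def _hump_weights(n_intervals: int, peak_scale_h: float = 12.0) -> np.ndarray:
    """Unimodal laying-schedule weights: w(x) ~ x * exp(-x / scale).

    Emulates the empirical brood profile of a mated Caenorhabditis female,
    which ramps up over the first hours of adulthood, peaks around half a
    day, and tails off.
    """
    mids = _interval_midpoints(n_intervals)
    w = mids * np.exp(-mids / peak_scale_h)
    return w / w.sum()


def _interval_bounds(n_intervals: int) -> list[tuple[float, float]]:
    """Laying intervals: 0-6 h from pairing, then consecutive 8-h plates."""
    bounds = [(0.0, 6.0)]
    for i in range(1, n_intervals):
        start = 6.0 + 8.0 * (i - 1)
        bounds.append((start, start + 8.0))
    return bounds


def _interval_midpoints(n_intervals: int) -> np.ndarray:
    return np.array([(s + e) / 2.0 for s, e in _interval_bounds(n_intervals)])


@dataclass(frozen=True)
class ScheduleConfig:
    """Generative parameters for reproductive-schedule simulation.

    ``founder_total_mean`` is the expected number of adult progeny of an
    outbred female summed over all intervals; per-interval means follow a
    hump-shaped profile.  ``dispersion`` is the negative-binomial size
    parameter (variance = mu + mu^2/dispersion); ``dispersion=inf`` gives
    Poisson counts.  ``line_multipliers`` scale the inbred means per line;
    ``line_delays`` shift laying by whole intervals; ``maternal_lethal_lines``
    zero out the corresponding line entirely.
    """

    n_founder_females: int = 6
    n_females_per_line: int = 6
    n_intervals: int = 8
    founder_total_mean: float = 250.0
    dispersion: float = 5.0
    line_multipliers: tuple[float, ...] = (0.9, 0.4, 0.1)
    line_delays: Optional[tuple[int, ...]] = None
    maternal_lethal_lines: Optional[tuple[bool, ...]] = None

    def __post_init__(self) -> None:
        if self.founder_total_mean <= 0:
            raise ValueError("founder_total_mean must be positive")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive (use inf for Poisson)")
        if any(m < 0 for m in self.line_multipliers):
            raise ValueError("line multipliers must be non-negative")
        n = len(self.line_multipliers)
        if self.line_delays is not None and len(self.line_delays) != n:
            raise ValueError("line_delays must match line_multipliers in length")
        if self.maternal_lethal_lines is not None and len(self.maternal_lethal_lines) != n:
            raise ValueError("maternal_lethal_lines must match line_multipliers in length")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a serial sib-mating experiment.

    Defaults reflect the canonical design: 108 independent lines inbred
    for up to 20 generations.  Exactly one of ``stage_betas`` (triples for
    copulation, fertility, development) or ``overall_betas`` must be set.
    """

    seed: int
    n_lines: int = 108
    max_generations: int = 20
    stage_betas: Optional[dict[str, tuple[float, float]]] = None
    overall_betas: Optional[tuple[float, float]] = None
    maternal_lethal_rate: float = 0.0
    strain_id: str = "sim"
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.max_generations < 1:
            raise ValueError("n_lines and max_generations must be positive")
        if (self.stage_betas is None) == (self.overall_betas is None):
            raise ValueError("set exactly one of stage_betas or overall_betas")
        if self.stage_betas is not None and set(self.stage_betas) != set(STAGES):
            raise ValueError(f"stage_betas must have keys {STAGES}")
        if not 0.0 <= self.maternal_lethal_rate <= 1.0:
            raise ValueError("maternal_lethal_rate must be a probability")

    def stage_probs(self, F: float) -> np.ndarray:
        """Per-stage success probabilities at parental inbreeding F."""
        if self.stage_betas is not None:
            return np.array(
                [expit(b0 + b1 * F) for b0, b1 in (self.stage_betas[s] for s in STAGES)]
            )
        b0, b1 = self.overall_betas
        return np.array([expit(b0 + b1 * F)])


# ---------------------------------------------------------------------------
# line-extinction simulation


def simulate_line_extinction(config: SimConfig) -> list[CrossRecord]:
    """Simulate serial sib-mating crosses for every line until extinction.

    Each surviving line contributes one record per generation up to
    ``max_generations``; a failed cross ends the line and later
    generations emit no records.  Deterministic under a fixed seed.
    """
    schedule = sib_mating_F(config.max_generations)
    F_by_gen = np.array(
        [parental_F_for_cross(g, schedule) for g in range(1, config.max_generations + 1)]
    )
    staged = config.stage_betas is not None
    probs = np.vstack([config.stage_probs(F) for F in F_by_gen])  # (gen, stage)

    records: list[CrossRecord] = []
    streams = np.random.SeedSequence(config.seed).spawn(config.n_lines)
    width = len(str(config.n_lines))
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        u = rng.random((config.max_generations, probs.shape[1]))
        u_lethal = rng.random(config.max_generations)
        line_id = f"{config.strain_id}-L{i + 1:0{width}d}"
        for g in range(1, config.max_generations + 1):
            p = probs[g - 1]
            draws = u[g - 1] < p
            lethal = u_lethal[g - 1] < config.maternal_lethal_rate
            if staged:
                copulated = bool(draws[0])
                fertile = bool(draws[1]) if copulated else None
                if fertile:
                    developed = False if lethal else bool(draws[2])
                else:
                    developed = None
                success = bool(copulated and fertile and developed)
            else:
                copulated = fertile = developed = None
                success = bool(draws[0]) and not lethal
            records.append(
                CrossRecord(
                    line_id=line_id,
                    generation=g,
                    F_parents=float(F_by_gen[g - 1]),
                    copulated=copulated,
                    fertile=fertile,
                    developed=developed,
                    success=success,
                )
            )
            if not success:
                break
    return records


def analytic_survival(config: SimConfig, generation: int) -> float:
    """Closed-form probability that a line survives through ``generation``.

    S(g) = prod_{t=1..g} (1 - maternal_lethal_rate) * prod_s p_s(F(t)),
    the oracle the Monte-Carlo survival fraction must converge to.
    """
    g = int(generation)
    if g < 0:
        raise ValueError("generation must be >= 0")
    if g == 0:
        return 1.0
    schedule = sib_mating_F(g)
    s = 1.0
    for t in range(1, g + 1):
        F = parental_F_for_cross(t, schedule)
        s *= (1.0 - config.maternal_lethal_rate) * float(np.prod(config.stage_probs(F)))
    return s


# ---------------------------------------------------------------------------
# reproductive-schedule simulation


def _draw_counts(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    counts = np.zeros(len(means), dtype=int)
    pos = means > 0
    if not pos.any():
        return counts
    if np.isinf(dispersion):
        counts[pos] = rng.poisson(means[pos])
    else:
        p = dispersion / (dispersion + means[pos])
        counts[pos] = rng.negative_binomial(dispersion, p)
    return counts


def simulate_repro_schedules(config: SimConfig) -> list[ReproSchedule]:
    """Simulate founder and inbred-line reproductive schedules.

    Founder females draw per-interval counts around the hump-shaped mean
    profile; each inbred line applies its multiplicative fitness effect
    and optional laying delay; maternal-lethal lines lay broods that yield
    no adults.  Deterministic under a fixed seed.
    """
    sc = config.schedule
    bounds = _interval_bounds(sc.n_intervals)
    base_means = sc.founder_total_mean * _hump_weights(sc.n_intervals)

    n_lines = len(sc.line_multipliers)
    delays = sc.line_delays or tuple(0 for _ in range(n_lines))
    lethal = sc.maternal_lethal_lines or tuple(False for _ in range(n_lines))

    # one stream per "line", founders counted as line 0
    streams = np.random.SeedSequence(config.seed).spawn(n_lines + 1)
    out: list[ReproSchedule] = []

    rng = np.random.default_rng(streams[0])
    for j in range(sc.n_founder_females):
        counts = _draw_counts(rng, base_means, sc.dispersion)
        out.append(
            ReproSchedule(
                female_id=f"{config.strain_id}-F{j + 1:02d}",
                strain_id=config.strain_id,
                role="founder",
                intervals=tuple((s, e, int(m)) for (s, e), m in zip(bounds, counts)),
            )
        )

    for k in range(n_lines):
        rng = np.random.default_rng(streams[k + 1])
        if lethal[k]:
            means = np.zeros(sc.n_intervals)
        else:
            means = sc.line_multipliers[k] * np.roll(base_means, delays[k])
            if delays[k] > 0:
                means[: delays[k]] = 0.0
        sid = f"{config.strain_id}-I{k + 1:02d}"
        for j in range(sc.n_females_per_line):
            counts = _draw_counts(rng, means, sc.dispersion)
            out.append(
                ReproSchedule(
                    female_id=f"{sid}-F{j + 1:02d}",
                    strain_id=sid,
                    role="inbred",
                    intervals=tuple((s, e, int(m)) for (s, e), m in zip(bounds, counts)),
                )
            )
    return out
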