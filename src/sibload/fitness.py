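"""Relative fitness of females from age-structured reproductive schedules.

Each assayed female contributes a schedule of adult-progeny counts per
laying interval (first interval 0-6 h from pairing, then 8-h transfers).
Her fitness score at growth rate r is the Lotka-Euler sum

    w(r) = sum_i m_i * exp(-r * x_i)

where m_i is the adult-progeny count of interval i and x_i its midpoint
age in hours.  The growth parameter r is solved so that the *mean* w of
the outbred founder females equals 1; every female's w at that shared r
is then her fitness relative to the founder population.  Early progeny
are weighted more heavily than late progeny, which is what distinguishes
w from a plain offspring count under overlapping generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import kruskal

__all__ = [
    "ReproSchedule",
    "FitnessEstimate",
    "euler_lotka_w",
    "solve_r",
    "relative_fitness",
    "strain_heterogeneity_test",
]


@dataclass(frozen=True)
class ReproSchedule:
    """One female's adult-progeny counts per laying interval.

    ``intervals`` is an ordered sequence of (start_h, end_h, adult_progeny)
    with ages in hours from the initial pairing.  Censored females (failed
    matings, desiccation before laying ended) are excluded from all
    estimation.
    """

    female_id: str
    strain_id: str
    role: str  # "founder" or "inbred"
    intervals: tuple[tuple[float, float, int], ...]
    censored: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("founder", "inbred"):
            raise ValueError("role must be 'founder' or 'inbred'")
        prev_end = -np.inf
        for start, end, m in self.intervals:
            if end <= start:
                raise ValueError("interval end must exceed its start")
            if start < prev_end:
                raise ValueError("intervals must be non-overlapping and increasing")
            if m < 0 or int(m) != m:
                raise ValueError("adult_progeny must be a non-negative integer")
            prev_end = end

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([(s + e) / 2.0 for s, e, _ in self.intervals])

    @property
    def counts(self) -> np.ndarray:
        return np.array([m for _, _, m in self.intervals], dtype=float)

    @property
    def total_progeny(self) -> int:
        return int(sum(m for _, _, m in self.intervals))


@dataclass(frozen=True)
class FitnessEstimate:
    """Per-female relative fitness at the founder-calibrated growth rate."""

    r: float  # per hour
    founder_strain: str
    w_by_female: Mapping[str, float]
    strain_by_female: Mapping[str, str]
    strain_means: Mapping[str, float] = field(default_factory=dict)


def euler_lotka_w(schedule: ReproSchedule, r: float, maturation_offset: float = 0.0) -> float:
    """Lotka-Euler fitness score w = sum m_i * exp(-r * x_i).

    ``maturation_offset`` (hours) optionally shifts every age by a fixed
    development time; the default 0 matches scoring from adulthood.
    """
    if schedule.censored:
        raise ValueError(f"female {schedule.female_id} is censored; no fitness is defined")
    if not schedule.intervals:
        return 0.0
    x = schedule.midpoints + maturation_offset
    return float(np.sum(schedule.counts * np.exp(-r * x)))


def _mean_w(schedules: Sequence[ReproSchedule], r: float, offset: float) -> float:
    return float(np.mean([euler_lotka_w(s, r, offset) for s in schedules]))


def solve_r(
    founders: Iterable[ReproSchedule],
    *,
    maturation_offset: float = 0.0,
    allow_nonpositive: bool = False,
    tol: float = 1e-12,
) -> float:
    """Growth rate r such that mean founder w(r) = 1.

    Mean w is strictly decreasing in r whenever founders have progeny, so
    the root is unique.  Requires mean total progeny > 1 for a positive
    root; ``allow_nonpositive=True`` admits r <= 0 for degenerate inputs.
    """
    founders = [s for s in founders if not s.censored]
    if not founders:
        raise ValueError("at least one non-censored founder schedule is required")
    mean_total = _mean_w(founders, 0.0, maturation_offset)
    if mean_total <= 1.0 and not allow_nonpositive:
        raise ValueError(
            f"mean founder progeny {mean_total:.3g} <= 1: no positive growth rate exists "
            "(pass allow_nonpositive=True to solve for r <= 0)"
        )
    f = lambda r: _mean_w(founders, r, maturation_offset) - 1.0
    lo, hi = (0.0, 1.0) if mean_total > 1.0 else (-1.0, 0.0)
    while f(hi) > 0:
        hi *= 2.0
    while f(lo) < 0:
        lo *= 2.0
        if lo == 0.0:
            lo = -1e-6
    r = brentq(f, lo, hi, xtol=tol, rtol=8.881784197001252e-16)
    assert abs(f(r)) < 1e-8
    return float(r)


def relative_fitness(
    inbred: Iterable[ReproSchedule],
    founders: Iterable[ReproSchedule],
    *,
    maturation_offset: float = 0.0,
) -> FitnessEstimate:
    """Fitness of inbred females relative to their outbred founder.

    Solves r on the founders (their mean w becomes 1 by construction) and
    evaluates every female's w at that r.  All founders must share one
    strain; comparisons are founder-vs-descendants, never across founders.
    """
    founders = [s for s in founders if not s.censored]
    inbred = [s for s in inbred if not s.censored]
    founder_strains = {s.strain_id for s in founders}
    if len(founder_strains) != 1:
        raise ValueError(f"founders must share one strain, got {sorted(founder_strains)}")
    r = solve_r(founders, maturation_offset=maturation_offset)
    w: dict[str, float] = {}
    strain: dict[str, str] = {}
    for s in founders + inbred:
        w[s.female_id] = euler_lotka_w(s, r, maturation_offset)
        strain[s.female_id] = s.strain_id
    means: dict[str, float] = {}
    for sid in dict.fromkeys(strain.values()):  # preserve order
        vals = [w[f] for f, st in strain.items() if st == sid]
        means[sid] = float(np.mean(vals))
    return FitnessEstimate(
        r=r,
        founder_strain=founder_strains.pop(),
        w_by_female=w,
        strain_by_female=strain,
        strain_means=means,
    )


def strain_heterogeneity_test(
    estimate: FitnessEstimate, strains: Sequence[str] | None = None
) -> tuple[float, float]:
    """Kruskal-Wallis test for fitness heterogeneity among inbred strains.

    Returns (H, p).  When every observation is tied the statistic is 0 and
    p is 1 (the tie-corrected H is undefined but its limit is no evidence
    of heterogeneity).
    """
    if strains is None:
        strains = [
            s for s in dict.fromkeys(estimate.strain_by_female.values())
            if s != estimate.founder_strain
        ]
    groups = []
    for sid in strains:
        vals = [
            w for f, w in estimate.w_by_female.items() if estimate.strain_by_female[f] == sid
        ]
        if len(vals) < 2:
            raise ValueError(f"strain {sid} has fewer than 2 females")
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError("at least 2 strains are required")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    H, p = kruskal(*groups)
    return float(H), float(p)
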