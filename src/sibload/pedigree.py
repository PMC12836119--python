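"""Inbreeding coefficients under serial full-sib mating.

Repeated brother-sister mating drives the inbreeding coefficient F (the
probability that the two alleles at a locus are identical by descent)
toward 1 according to the classical second-order recursion

    F_t = 0.25 * (1 + 2*F_{t-1} + F_{t-2})

with non-inbred, unrelated founders (F_0 = F_{-1} = 0).  The complement
1 - F_t decays asymptotically by a factor of (1 + sqrt(5))/4 ~ 0.809 per
generation, which is why line-extinction hazards stabilise late in a
sib-mating experiment.

Experiment generations are mapped to the F of the *crossed parents*: the
first cross pairs outbred individuals (F = 0), the second pairs their
non-inbred offspring (still F = 0), and cross g >= 3 pairs sibs with
F = F_{g-2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["InbreedingSchedule", "sib_mating_F", "parental_F_for_cross"]


@dataclass(frozen=True)
class InbreedingSchedule:
    """F after each of ``n_sib_generations`` consecutive sib matings.

    ``F_values[k]`` is the inbreeding coefficient of offspring after k
    consecutive full-sib matings; ``F_values[0] == 0`` (outbred founders).
    """

    n_sib_generations: int
    F_values: tuple[float, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_sib_generations < 0:
            raise ValueError("n_sib_generations must be non-negative")
        if len(self.F_values) != self.n_sib_generations + 1:
            raise ValueError("F_values must have length n_sib_generations + 1")

    def __len__(self) -> int:
        return len(self.F_values)

    def __getitem__(self, k: int) -> float:
        return self.F_values[k]


def sib_mating_F(n_generations: int) -> InbreedingSchedule:
    """Inbreeding coefficients after 0..n consecutive full-sib matings.

    Parameters
    ----------
    n_generations
        Number of consecutive sib matings (>= 0).

    Returns
    -------
    InbreedingSchedule
        ``F_values[k]`` for k = 0..n, computed by
        ``F_t = 0.25 * (1 + 2*F_{t-1} + F_{t-2})`` with F_0 = F_{-1} = 0.
    """
    n = int(n_generations)
    if n < 0:
        raise ValueError("n_generations must be >= 0")
    F = [0.0]
    f_prev2 = 0.0  # F_{-1}
    for _ in range(n):
        f_next = 0.25 * (1.0 + 2.0 * F[-1] + f_prev2)
        f_prev2 = F[-1]
        F.append(f_next)
    return InbreedingSchedule(n_sib_generations=n, F_values=tuple(F))


def parental_F_for_cross(generation: int, schedule: InbreedingSchedule) -> float:
    """F of the two individuals paired at a given experiment generation.

    Generations 1 and 2 pair non-inbred individuals (F = 0); generation
    g >= 3 pairs sibs whose own inbreeding coefficient is F_{g-2}.
    """
    g = int(generation)
    if g < 1:
        raise ValueError("generation must be >= 1")
    if g <= 2:
        return 0.0
    if g - 2 >= len(schedule):
        raise ValueError(
            f"schedule covers {schedule.n_sib_generations} sib generations; "
            f"cross generation {g} needs F_{g - 2}"
        )
    return schedule[g - 2]
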