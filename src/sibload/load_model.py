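"""Logistic genetic-load model for single-pair cross outcomes.

Each cross is a Bernoulli trial whose success probability R declines with
the parental inbreeding coefficient F:

    ln(R / (1 - R)) = beta0 + beta1 * F

The coefficients convert to Morton-style load parameters on the
pair-reproduction scale:

    A_R = -ln(R at F=0)           expressed load
    B_R = -ln(R at F=1 / R at F=0)  concealed load (positive iff beta1 < 0)

Because a successful reproduction event requires both partners to
function, A_R and B_R are approximately twice the per-individual Morton
A and B; :func:`individual_scale` applies that factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from .pedigree import InbreedingSchedule, parental_F_for_cross

__all__ = [
    "CrossRecord",
    "LoadFit",
    "FitDegenerateError",
    "DesignError",
    "fit_load_model",
    "stagewise_fits",
    "beta_to_load",
    "beta_from_load",
    "individual_scale",
    "predicted_success",
    "expected_survival_curve",
    "load_standard_errors",
    "STAGES",
]

STAGES = ("copulation", "fertility", "development")


class FitDegenerateError(RuntimeError):
    """The logistic fit is not identified (separation or no outcome variation)."""


class DesignError(ValueError):
    """The data lack the design needed for the model (e.g. a single F level)."""


@dataclass(frozen=True)
class CrossRecord:
    """One single-pair cross attempt with staged binary outcomes.

    ``fertile`` is only defined when the pair copulated; ``developed`` only
    when embryos were laid.  ``success`` means the cross yielded at least
    one L4 offspring of each sex, i.e. the line survived this generation.
    """

    line_id: str
    generation: int
    F_parents: float
    success: bool
    copulated: Optional[bool] = None
    fertile: Optional[bool] = None
    developed: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.generation < 1:
            raise ValueError("generation must be >= 1")
        if not 0.0 <= self.F_parents < 1.0:
            raise ValueError("F_parents must lie in [0, 1)")
        if self.fertile is not None and self.copulated is not True:
            raise ValueError("fertile must be missing when the pair did not copulate")
        if self.developed is not None and self.fertile is not True:
            raise ValueError("developed must be missing unless the cross was fertile")
        if self.success and self.copulated is not None:
            if not (self.copulated and self.fertile and self.developed):
                raise ValueError("a successful cross must pass every recorded stage")


@dataclass(frozen=True)
class LoadFit:
    """Fitted logistic coefficients and derived load parameters."""

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    A_R: float
    B_R: float
    p_beta1: float
    n_crosses: int
    stage: str = "overall"

    def predicted(self, F: float) -> float:
        return predicted_success(self, F)


# ---------------------------------------------------------------------------
# coefficient <-> load conversions


def beta_to_load(beta0: float, beta1: float) -> tuple[float, float]:
    """Convert logistic coefficients to (A_R, B_R).

    A_R = -ln(expit(beta0)); B_R = -ln(expit(beta0+beta1)/expit(beta0)).
    Computed via log1p-style identities so extreme coefficients do not
    underflow.
    """
    b0 = float(beta0)
    b1 = float(beta1)
    if not (math.isfinite(b0) and math.isfinite(b1)):
        raise ValueError("coefficients must be finite")
    # -ln(expit(x)) == ln(1 + e^(-x))
    A_R = float(np.logaddexp(0.0, -b0))
    B_R = float(np.logaddexp(0.0, -(b0 + b1)) - np.logaddexp(0.0, -b0))
    return A_R, B_R


def beta_from_load(A_R: float, B_R: float) -> tuple[float, float]:
    """Analytic inverse of :func:`beta_to_load`.

    Requires both implied success probabilities e^(-A_R) and e^(-A_R-B_R)
    to lie strictly inside (0, 1).
    """
    if not (math.isfinite(A_R) and math.isfinite(B_R)):
        raise ValueError("load parameters must be finite")
    if A_R <= 0.0 or A_R + B_R <= 0.0:
        raise ValueError("load parameters imply success probabilities outside (0, 1)")
    # A_R = ln(1 + e^(-beta0))  =>  beta0 = -ln(e^(A_R) - 1), via expm1 for accuracy
    beta0 = -math.log(math.expm1(A_R))
    beta1 = -math.log(math.expm1(A_R + B_R)) - beta0
    return beta0, beta1


def individual_scale(A_R: float, B_R: float) -> tuple[float, float]:
    """Per-individual Morton-scale load (A, B) = (A_R/2, B_R/2).

    A reproduction event needs two functional individuals, so the
    pair-scale coefficients are about twice the individual-survival ones.
    """
    return A_R / 2.0, B_R / 2.0


def predicted_success(fit: LoadFit, F: float) -> float:
    """Model success probability R = expit(beta0 + beta1 * F), F in [0, 1]."""
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must lie in [0, 1]")
    return float(expit(fit.beta0 + fit.beta1 * F))


def load_standard_errors(fit: LoadFit, cov: np.ndarray) -> tuple[float, float]:
    """Delta-method standard errors for (A_R, B_R).

    This is an extension beyond the published per-coefficient errors: the
    gradient of (A_R, B_R) in (beta0, beta1) is propagated through the
    coefficient covariance matrix ``cov``.
    """
    p0 = expit(fit.beta0)
    p1 = expit(fit.beta0 + fit.beta1)
    gA = np.array([-(1.0 - p0), 0.0])
    gB = np.array([(1.0 - p0) - (1.0 - p1), -(1.0 - p1)])
    cov = np.asarray(cov, dtype=float)
    return (
        float(np.sqrt(gA @ cov @ gA)),
        float(np.sqrt(gB @ cov @ gB)),
    )


# ---------------------------------------------------------------------------
# fitting


def _check_identified(F: np.ndarray, y: np.ndarray, stage: str) -> None:
    if len(np.unique(F)) < 2:
        raise DesignError(f"{stage}: fewer than 2 distinct F levels; slope not identified")
    if y.all():
        raise FitDegenerateError(f"{stage}: all-success outcome; no failures observed")
    if not y.any():
        raise FitDegenerateError(f"{stage}: all-failure outcome; no successes observed")
    # With one covariate, complete separation means every success lies
    # strictly on one side of every failure along F.
    if F[y == 1].max() < F[y == 0].min() or F[y == 1].min() > F[y == 0].max():
        raise FitDegenerateError(f"{stage}: complete separation of outcomes along F")


def _firth_fit(F: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100):
    """Firth-penalised logistic fit (Jeffreys-prior score correction)."""
    X = np.column_stack([np.ones_like(F), F])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        XtW = X.T * w
        info = XtW @ X
        info_inv = np.linalg.inv(info)
        # leverages of the weighted design
        h = np.einsum("ij,jk,ik->i", X * np.sqrt(w)[:, None], info_inv, X * np.sqrt(w)[:, None])
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    p = expit(eta)
    w = p * (1.0 - p)
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, cov


def _fit_binary(F: np.ndarray, y: np.ndarray, stage: str, firth: bool) -> LoadFit:
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float)
    if firth:
        try:
            _check_identified(F, y, stage)
            use_firth = False
        except FitDegenerateError:
            use_firth = True
        if use_firth:
            beta, cov = _firth_fit(F, y)
        else:
            beta, cov = _ml_fit(F, y)
    else:
        _check_identified(F, y, stage)
        beta, cov = _ml_fit(F, y)
    se = np.sqrt(np.diag(cov))
    z = beta[1] / se[1]
    p = 2.0 * float(norm.sf(abs(z)))
    A_R, B_R = beta_to_load(beta[0], beta[1])
    return LoadFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        se_beta0=float(se[0]),
        se_beta1=float(se[1]),
        A_R=A_R,
        B_R=B_R,
        p_beta1=p,
        n_crosses=len(y),
        stage=stage,
    )


def _ml_fit(F: np.ndarray, y: np.ndarray):
    X = sm.add_constant(F, has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(tol=1e-10, maxiter=200)
    if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 1e4):
        raise FitDegenerateError("maximum-likelihood fit did not identify finite coefficients")
    return np.asarray(res.params), np.asarray(res.cov_params())


def _records_arrays(records: Sequence[CrossRecord]):
    F = np.array([r.F_parents for r in records], dtype=float)
    y = np.array([1.0 if r.success else 0.0 for r in records])
    return F, y


def fit_load_model(
    records: Iterable[CrossRecord], *, firth: bool = False
) -> LoadFit:
    """Maximum-likelihood logistic fit of cross success on parental F.

    Returns coefficient estimates with observed-information standard
    errors, the two-sided Wald (z) p-value for beta1 = 0, and the derived
    load parameters A_R and B_R.

    Raises
    ------
    DesignError
        Fewer than two distinct F levels.
    FitDegenerateError
        All-same outcome or complete separation (unless ``firth=True``,
        which falls back to a Firth-penalised fit).
    """
    records = list(records)
    F, y = _records_arrays(records)
    return _fit_binary(F, y, "overall", firth)


def stagewise_fits(
    records: Iterable[CrossRecord], *, firth: bool = False
) -> Mapping[str, "LoadFit | FitDegenerateError | DesignError"]:
    """Conditional logistic fits for the three life-cycle stages.

    copulation ~ F on all records; fertility ~ F on copulated crosses;
    development ~ F on fertile crosses.  A stage whose fit is degenerate
    maps to the raised exception instead of a LoadFit, leaving the other
    stages unaffected.
    """
    records = list(records)
    subsets = {
        "copulation": [(r.F_parents, r.copulated) for r in records if r.copulated is not None],
        "fertility": [
            (r.F_parents, r.fertile) for r in records if r.copulated is True and r.fertile is not None
        ],
        "development": [
            (r.F_parents, r.developed) for r in records if r.fertile is True and r.developed is not None
        ],
    }
    out: dict[str, LoadFit | FitDegenerateError | DesignError] = {}
    for stage, pairs in subsets.items():
        if not pairs:
            out[stage] = FitDegenerateError(f"{stage}: no records carry this stage flag")
            continue
        F = np.array([f for f, _ in pairs], dtype=float)
        y = np.array([1.0 if s else 0.0 for _, s in pairs])
        try:
            out[stage] = _fit_binary(F, y, stage, firth)
        except (FitDegenerateError, DesignError) as err:
            out[stage] = err
    return out


# ---------------------------------------------------------------------------
# survival curves


def expected_survival_curve(
    fit: LoadFit,
    schedule: InbreedingSchedule,
    n_generations: int,
    mode: str = "inbreeding",
) -> np.ndarray:
    """Expected fraction of lines surviving each of generations 1..n.

    mode="constant" is the no-inbreeding-depression null, S_g = R(F=0)^g —
    pure exponential decay at the outbred failure rate.  mode="inbreeding"
    compounds the fitted per-generation success probabilities at the
    actual parental F of each cross, S_g = prod_{t<=g} R(F_parents(t)).
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if mode == "constant":
        R0 = predicted_success(fit, 0.0)
        return np.cumprod(np.full(n_generations, R0))
    if mode == "inbreeding":
        probs = [
            predicted_success(fit, parental_F_for_cross(g, schedule))
            for g in range(1, n_generations + 1)
        ]
        return np.cumprod(probs)
    raise ValueError("mode must be 'constant' or 'inbreeding'")
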