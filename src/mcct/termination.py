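"""Termination statistics for grid classification testing.

Implements the Wald likelihood-ratio machinery in three flavors:

* ``lr_sf`` — the per-dimension ratio using only that dimension's items
  (the factorized multidimensional reduction).
* ``lr_c``  — the ratio over *all* administered items, with non-target
  dimensions imputed at their conditional-normal expected values given
  the target bound, importing the between-dimension correlation.
* the pre-rule ``phi`` / ``choose_criterion`` pair that switches between
  the two based on the sign of the correlation-weighted product of the
  provisional estimates' deviations from the cutoffs.

All ratios are accumulated in log space internally; the public contract
is on the ratio scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .irt import ItemBank, ResponseRecord, _p3

__all__ = [
    "ClassificationSpec",
    "PopulationModel",
    "TerminationEvaluation",
    "ABOVE",
    "BELOW",
    "CONTINUE",
    "SF",
    "C",
    "PRE_RULE",
    "indifference_bounds",
    "wald_thresholds",
    "lr_sf",
    "lr_c",
    "log_lr_sf",
    "log_lr_c",
    "conditional_params",
    "phi",
    "choose_criterion",
    "decide",
    "decide_log",
    "forced_decide",
    "forced_decide_log",
]

# decision labels
ABOVE = "above"
BELOW = "below"
CONTINUE = "continue"

# criterion labels
SF = "SF"          # target-dimension items only
C = "C"            # conditional imputation of non-target dimensions
PRE_RULE = "P"     # switch SF <-> C via the phi pre-rule


def indifference_bounds(cutoff: float, delta: float) -> tuple[float, float]:
    """Lower/upper bounds ``(cutoff - delta, cutoff + delta)`` of the
    indifference region of total width ``2 delta``."""
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    return (cutoff - delta, cutoff + delta)


def wald_thresholds(alpha: float, beta: float) -> tuple[float, float]:
    """Wald decision thresholds ``A = (1 - beta)/alpha``, ``B = beta/(1 - alpha)``."""
    if not (0.0 < alpha < 0.5 and 0.0 < beta < 0.5):
        raise ValueError(f"alpha and beta must lie in (0, 0.5), got {alpha}, {beta}")
    return ((1.0 - beta) / alpha, beta / (1.0 - alpha))


@dataclass(frozen=True)
class ClassificationSpec:
    """Cutoffs, indifference region and error rates for one condition.

    Derived quantities: per-dimension bounds ``theta_L = cutoff - delta``
    and ``theta_U = cutoff + delta`` and Wald thresholds ``A``/``B``.
    """

    cutoffs: np.ndarray
    delta: float
    alpha: float = 0.05
    beta: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "cutoffs", np.atleast_1d(np.asarray(self.cutoffs, float)))
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        wald_thresholds(self.alpha, self.beta)  # validates rates

    @property
    def D(self) -> int:
        return self.cutoffs.size

    @property
    def theta_L(self) -> np.ndarray:
        return self.cutoffs - self.delta

    @property
    def theta_U(self) -> np.ndarray:
        return self.cutoffs + self.delta

    @property
    def A(self) -> float:
        return wald_thresholds(self.alpha, self.beta)[0]

    @property
    def B(self) -> float:
        return wald_thresholds(self.alpha, self.beta)[1]


@dataclass(frozen=True)
class PopulationModel:
    """Known multivariate-normal trait population (unit variances)."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, float))
        sigma = np.asarray(self.sigma, float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        if sigma.shape != (mu.size, mu.size):
            raise ValueError("sigma shape must match mu")
        if not np.allclose(sigma, sigma.T):
            raise ValueError("sigma must be symmetric")
        if np.any(np.linalg.eigvalsh(sigma) <= 0):
            raise ValueError("sigma must be positive definite")

    @classmethod
    def bivariate(cls, rho: float) -> "PopulationModel":
        """Standard bivariate normal with correlation *rho*."""
        if not -1.0 < rho < 1.0:
            raise ValueError(f"|rho| must be < 1, got {rho}")
        return cls(np.zeros(2), np.array([[1.0, rho], [rho, 1.0]]))

    @property
    def D(self) -> int:
        return self.mu.size

    @property
    def rho(self) -> float:
        """Correlation between dimensions 1 and 2."""
        s = self.sigma
        return float(s[0, 1] / np.sqrt(s[0, 0] * s[1, 1]))


@dataclass(frozen=True)
class TerminationEvaluation:
    """Outcome of evaluating one open dimension after a response."""

    dimension: int
    lr: float
    phi: float
    criterion_used: str
    decision: str
    forced: bool = False


def conditional_params(
    pop: PopulationModel, known_d: int, a: float, query_d: int
) -> tuple[float, float]:
    """Conditional mean/variance of trait *query_d* given trait
    *known_d* equals *a* (dimensions 1-based).

    ``mean = mu_q + (sigma_q / sigma_k) * rho * (a - mu_k)`` and
    ``var = (1 - rho^2) * sigma_q^2``.
    """
    if known_d == query_d:
        raise ValueError("known and query dimensions must differ")
    k, q = known_d - 1, query_d - 1
    s_k = np.sqrt(pop.sigma[k, k])
    s_q = np.sqrt(pop.sigma[q, q])
    rho = pop.sigma[k, q] / (s_k * s_q)
    if abs(rho) >= 1.0:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    mean = pop.mu[q] + (s_q / s_k) * rho * (a - pop.mu[k])
    var = (1.0 - rho**2) * pop.sigma[q, q]
    return float(mean), float(var)


def _gather(responses: Sequence[ResponseRecord], bank: ItemBank):
    idx = np.array([bank.index_of(r.item_id) for r in responses], dtype=np.int64)
    u = np.array([r.u for r in responses], dtype=bool)
    return idx, u


def _log_bernoulli_sum(a, b, c, theta_points, u, scale) -> float:
    p = _p3(a, b, c, theta_points, scale)
    return float(np.sum(np.where(u, np.log(p), np.log1p(-p))))


def log_lr_sf(
    target_d: int,
    responses: Sequence[ResponseRecord],
    bank: ItemBank,
    spec: ClassificationSpec,
    scale: float = 1.0,
) -> float:
    """Log likelihood ratio from target-dimension items only."""
    idx, u = _gather(responses, bank)
    if idx.size == 0:
        return 0.0
    m = bank.dimension[idx] == target_d
    if not m.any():
        return 0.0
    sub, u = idx[m], u[m]
    a, b, c = bank.a[sub], bank.b[sub], bank.c[sub]
    tU = spec.theta_U[target_d - 1]
    tL = spec.theta_L[target_d - 1]
    return _log_bernoulli_sum(a, b, c, tU, u, scale) - _log_bernoulli_sum(
        a, b, c, tL, u, scale
    )


def imputation_points(
    target_d: int, spec: ClassificationSpec, pop: PopulationModel
) -> tuple[np.ndarray, np.ndarray]:
    """Trait vectors used by the conditional criterion for target
    dimension *target_d*: numerator point (target at ``theta_U``,
    non-target at conditional means given ``theta_U``) and the
    denominator point (same with ``theta_L``)."""
    D = spec.D
    num = np.empty(D)
    den = np.empty(D)
    t = target_d - 1
    num[t] = spec.theta_U[t]
    den[t] = spec.theta_L[t]
    for e in range(1, D + 1):
        if e == target_d:
            continue
        num[e - 1] = conditional_params(pop, target_d, float(spec.theta_U[t]), e)[0]
        den[e - 1] = conditional_params(pop, target_d, float(spec.theta_L[t]), e)[0]
    return num, den


def log_lr_c(
    target_d: int,
    responses: Sequence[ResponseRecord],
    bank: ItemBank,
    spec: ClassificationSpec,
    pop: PopulationModel,
    scale: float = 1.0,
) -> float:
    """Log likelihood ratio over *all* administered items with
    conditional-mean imputation of the non-target dimensions."""
    idx, u = _gather(responses, bank)
    if idx.size == 0:
        return 0.0
    num, den = imputation_points(target_d, spec, pop)
    dims0 = bank.dimension[idx] - 1
    a, b, c = bank.a[idx], bank.b[idx], bank.c[idx]
    return _log_bernoulli_sum(a, b, c, num[dims0], u, scale) - _log_bernoulli_sum(
        a, b, c, den[dims0], u, scale
    )


def lr_sf(target_d, responses, bank, spec, scale: float = 1.0) -> float:
    """Likelihood ratio (ratio scale) from target-dimension items only."""
    return float(np.exp(log_lr_sf(target_d, responses, bank, spec, scale)))


def lr_c(target_d, responses, bank, spec, pop, scale: float = 1.0) -> float:
    """Likelihood ratio (ratio scale) with conditional imputation."""
    return float(np.exp(log_lr_c(target_d, responses, bank, spec, pop, scale)))


def phi(rho: float, theta_hat: np.ndarray, cutoffs: np.ndarray) -> float:
    """Pre-rule statistic ``rho * (th1 - cut1) * (th2 - cut2)``."""
    theta_hat = np.asarray(theta_hat, float)
    cutoffs = np.asarray(cutoffs, float)
    if theta_hat.size != 2 or cutoffs.size != 2:
        raise ValueError("the pre-rule is defined for exactly two dimensions")
    d = theta_hat - cutoffs
    return float(rho * d[0] * d[1])


def choose_criterion(phi_value: float) -> str:
    """Conditional criterion iff ``phi > 0``; factorized criterion elsewhere."""
    return C if phi_value > 0.0 else SF


def decide(lr: float, spec: ClassificationSpec) -> str:
    """Wald decision on the ratio scale: above iff ``lr >= A``, below iff
    ``lr < B``, otherwise continue."""
    if lr <= 0:
        raise ValueError(f"likelihood ratio must be positive, got {lr}")
    if lr >= spec.A:
        return ABOVE
    if lr < spec.B:
        return BELOW
    return CONTINUE


def decide_log(log_lr: float, spec: ClassificationSpec) -> str:
    """Wald decision in log space (engine fast path)."""
    if log_lr >= np.log(spec.A):
        return ABOVE
    if log_lr < np.log(spec.B):
        return BELOW
    return CONTINUE


def forced_decide(lr: float, spec: ClassificationSpec) -> str:
    """Forced classification at maximum length: whichever Wald threshold
    the log ratio is closer to wins; exact tie retains H0 (below)."""
    if lr <= 0:
        raise ValueError(f"likelihood ratio must be positive, got {lr}")
    return forced_decide_log(float(np.log(lr)), spec)


def forced_decide_log(log_lr: float, spec: ClassificationSpec) -> str:
    dist_a = abs(log_lr - np.log(spec.A))
    dist_b = abs(log_lr - np.log(spec.B))
    return ABOVE if dist_a < dist_b else BELOW
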