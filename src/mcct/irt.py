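"""Between-item multidimensional 3PL item response model.

Every item loads on exactly one dimension, so probabilities, Fisher
information and the likelihood all depend on a single component of the
trait vector, and trait estimation factorizes into independent
one-dimensional problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "ItemParameters",
    "ItemBank",
    "ResponseRecord",
    "DEFAULT_TRAIT_BOUNDS",
    "prob_3pl",
    "prob_rasch",
    "fisher_info",
    "simulate_response",
    "mle_estimate",
]

#: Trait estimates are clamped to this interval; perfect / all-wrong
#: response patterns land exactly on a bound.
DEFAULT_TRAIT_BOUNDS = (-4.0, 4.0)


@dataclass(frozen=True)
class ItemParameters:
    """3PL parameters for one item loading on a single dimension.

    Parameters
    ----------
    item_id
        Unique integer identifier.
    dimension
        1-based index of the loaded dimension.
    a
        Discrimination (logit slope), must be positive.
    b
        Difficulty on the logit scale.
    c
        Lower asymptote (guessing probability), in ``[0, 1)``.
    """

    item_id: int
    dimension: int
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"item {self.item_id}: discrimination a must be > 0, got {self.a}")
        if not 0.0 <= self.c < 1.0:
            raise ValueError(f"item {self.item_id}: guessing c must be in [0, 1), got {self.c}")
        if self.dimension < 1:
            raise ValueError(f"item {self.item_id}: dimension must be >= 1, got {self.dimension}")
        if not (np.isfinite(self.a) and np.isfinite(self.b) and np.isfinite(self.c)):
            raise ValueError(f"item {self.item_id}: non-finite parameter")


class ItemBank:
    """Ordered collection of between-item 3PL items.

    Stored column-wise (NumPy arrays) for fast vectorized access; the
    ``items`` property materializes :class:`ItemParameters` on demand.
    """

    def __init__(
        self,
        item_id: Sequence[int],
        dimension: Sequence[int],
        a: Sequence[float],
        b: Sequence[float],
        c: Sequence[float],
        D: int | None = None,
    ) -> None:
        self.item_id = np.asarray(item_id, dtype=np.int64)
        self.dimension = np.asarray(dimension, dtype=np.int64)
        self.a = np.asarray(a, dtype=np.float64)
        self.b = np.asarray(b, dtype=np.float64)
        self.c = np.asarray(c, dtype=np.float64)
        n = self.item_id.size
        for name in ("dimension", "a", "b", "c"):
            if getattr(self, name).size != n:
                raise ValueError(f"column '{name}' length mismatch")
        if n == 0:
            raise ValueError("item bank is empty")
        if np.unique(self.item_id).size != n:
            raise ValueError("item_ids are not unique")
        self.D = int(D) if D is not None else int(self.dimension.max())
        if self.dimension.min() < 1 or self.dimension.max() > self.D:
            raise ValueError(f"item dimensions must lie in 1..{self.D}")
        for d in range(1, self.D + 1):
            if not np.any(self.dimension == d):
                raise ValueError(f"dimension {d} has no items")
        if np.any(self.a <= 0):
            raise ValueError("all discriminations must be > 0")
        if np.any((self.c < 0) | (self.c >= 1)):
            raise ValueError("all guessing parameters must be in [0, 1)")
        self._index = {int(i): k for k, i in enumerate(self.item_id)}

    @classmethod
    def from_items(cls, items: Sequence[ItemParameters], D: int | None = None) -> "ItemBank":
        return cls(
            [it.item_id for it in items],
            [it.dimension for it in items],
            [it.a for it in items],
            [it.b for it in items],
            [it.c for it in items],
            D=D,
        )

    @property
    def n_items(self) -> int:
        return self.item_id.size

    def __len__(self) -> int:
        return self.n_items

    @property
    def items(self) -> list[ItemParameters]:
        return [self.params_at(k) for k in range(self.n_items)]

    def params_at(self, index: int) -> ItemParameters:
        """Item parameters at positional *index*."""
        return ItemParameters(
            int(self.item_id[index]),
            int(self.dimension[index]),
            float(self.a[index]),
            float(self.b[index]),
            float(self.c[index]),
        )

    def index_of(self, item_id: int) -> int:
        """Positional index of *item_id*; raises ``KeyError`` if unknown."""
        try:
            return self._index[int(item_id)]
        except KeyError:
            raise KeyError(f"unknown item_id {item_id}") from None

    def get(self, item_id: int) -> ItemParameters:
        return self.params_at(self.index_of(item_id))


@dataclass(frozen=True)
class ResponseRecord:
    """A scored dichotomous response to an administered item."""

    item_id: int
    u: int
    order: int = 0

    def __post_init__(self) -> None:
        if self.u not in (0, 1):
            raise ValueError(f"response u must be 0 or 1, got {self.u}")


def _p3(a, b, c, theta_component, scale=1.0):
    """Vectorized 3PL response probability with logistic constant *scale*."""
    return c + (1.0 - c) * expit(scale * a * (theta_component - b))


def prob_3pl(
    item: ItemParameters, theta: np.ndarray | Sequence[float], scale: float = 1.0
) -> float:
    """3PL probability of a correct response.

    ``P = c + (1 - c) / (1 + exp(-scale * a (theta_d - b)))`` where
    ``theta_d`` is the component of *theta* on the item's loaded
    dimension. *scale* is the logistic scaling constant: 1.0 for the
    pure logistic metric, 1.7 for the normal-ogive-approximating
    convention common in 3PL software (and required to reproduce the
    published simulation results; see README).
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=np.float64))
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    if theta.size < item.dimension:
        raise ValueError(
            f"trait vector of length {theta.size} lacks dimension {item.dimension}"
        )
    return float(_p3(item.a, item.b, item.c, theta[item.dimension - 1], scale))


def prob_rasch(b: float, theta: float) -> float:
    """Rasch (1PL) probability: logistic(theta - b)."""
    if not (np.isfinite(b) and np.isfinite(theta)):
        raise ValueError("inputs must be finite")
    return float(expit(theta - b))


def fisher_info(
    item: ItemParameters, theta: np.ndarray | Sequence[float], scale: float = 1.0
) -> float:
    """Fisher information of one 3PL item on its loaded dimension.

    ``I = (scale a)^2 (Q/P) ((P - c) / (1 - c))^2``; the D x D item
    information matrix puts this scalar at the (dim, dim) diagonal entry
    and zeros elsewhere (between-item loading).
    """
    p = prob_3pl(item, theta, scale)
    q = 1.0 - p
    return float((scale * item.a) ** 2 * (q / p) * ((p - item.c) / (1.0 - item.c)) ** 2)


def simulate_response(
    item: ItemParameters,
    theta_true: np.ndarray | Sequence[float],
    uniform_draw: float,
    scale: float = 1.0,
) -> int:
    """Score 1 iff *uniform_draw* < P(correct | theta_true)."""
    if not 0.0 <= uniform_draw < 1.0:
        raise ValueError(f"uniform_draw must be in [0, 1), got {uniform_draw}")
    return int(uniform_draw < prob_3pl(item, theta_true, scale))


# ---------------------------------------------------------------------------
# Maximum likelihood trait estimation
# ---------------------------------------------------------------------------

_INV_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _loglik_1d(theta: float, a, b, c, u) -> float:
    p = _p3(a, b, c, theta)
    return float(np.sum(np.where(u, np.log(p), np.log1p(-p))))


def mle_1d(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    u: np.ndarray,
    bounds: tuple[float, float] = DEFAULT_TRAIT_BOUNDS,
    tol: float = 1e-6,
    scale: float = 1.0,
) -> float:
    """Bounded 1-D Bernoulli-likelihood maximizer for a set of 3PL items.

    Coarse grid scan (guards against local optima the guessing floor can
    create) followed by golden-section refinement to *tol*. Perfect and
    all-wrong patterns clamp to the respective bound.
    """
    lo, hi = bounds
    u = np.asarray(u, dtype=bool)
    if u.all():
        return hi
    if not u.any():
        return lo
    a = scale * np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)

    grid = np.linspace(lo, hi, 33)  # step 0.25
    p = _p3(a[:, None], b[:, None], c[:, None], grid[None, :])
    ll = np.where(u[:, None], np.log(p), np.log1p(-p)).sum(axis=0)
    k = int(np.argmax(ll))
    left = grid[max(k - 1, 0)]
    right = grid[min(k + 1, grid.size - 1)]

    # golden-section maximization on [left, right]
    x1 = right - _INV_GOLDEN * (right - left)
    x2 = left + _INV_GOLDEN * (right - left)
    f1 = _loglik_1d(x1, a, b, c, u)
    f2 = _loglik_1d(x2, a, b, c, u)
    while right - left > tol:
        if f1 < f2:
            left, x1, f1 = x1, x2, f2
            x2 = left + _INV_GOLDEN * (right - left)
            f2 = _loglik_1d(x2, a, b, c, u)
        else:
            right, x2, f2 = x2, x1, f1
            x1 = right - _INV_GOLDEN * (right - left)
            f1 = _loglik_1d(x1, a, b, c, u)
    return float(0.5 * (left + right))


def mle_estimate(
    responses: Sequence[ResponseRecord],
    bank: ItemBank,
    bounds: tuple[float, float] = DEFAULT_TRAIT_BOUNDS,
    scale: float = 1.0,
) -> np.ndarray:
    """Per-dimension MLE of the trait vector.

    The between-item likelihood factorizes over dimensions; each
    dimension is maximized independently over *bounds*. A dimension with
    no administered items returns the population mean, 0.
    """
    idx = np.array([bank.index_of(r.item_id) for r in responses], dtype=np.int64)
    u = np.array([r.u for r in responses], dtype=bool)
    theta = np.zeros(bank.D)
    if idx.size == 0:
        return theta
    dims = bank.dimension[idx]
    for d in range(1, bank.D + 1):
        m = dims == d
        if not m.any():
            continue
        sub = idx[m]
        theta[d - 1] = mle_1d(
            bank.a[sub], bank.b[sub], bank.c[sub], u[m], bounds=bounds, scale=scale
        )
    return theta
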