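"""Bayesian item selection by posterior-information determinant.

The next item is the eligible candidate maximizing

    det( prior precision + accumulated item information + candidate info )

with every item's information evaluated at the *cutoff* vector, not at
the provisional estimate. Under between-item loading each item's
information matrix is a single diagonal entry, so the accumulated matrix
differs from the prior precision only on the diagonal and the candidate
update is rank-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .irt import ItemBank, ItemParameters, fisher_info
from .termination import PopulationModel

__all__ = ["SelectionContext", "posterior_info_determinant", "select_next_item"]


@dataclass
class SelectionContext:
    """Running selection state for one examinee.

    ``accumulated_info`` is the sum of administered items' D x D
    information matrices at the cutoff vector; ``prior_precision`` is
    the inverse of the known population covariance; ``eligible`` is the
    set of item_ids still available for administration.
    """

    accumulated_info: np.ndarray
    prior_precision: np.ndarray
    eligible: set[int]
    scale: float = 1.0

    @classmethod
    def fresh(
        cls, pop: PopulationModel, bank: ItemBank, scale: float = 1.0
    ) -> "SelectionContext":
        D = pop.D
        return cls(
            accumulated_info=np.zeros((D, D)),
            prior_precision=np.linalg.inv(pop.sigma),
            eligible=set(int(i) for i in bank.item_id),
            scale=scale,
        )


def posterior_info_determinant(
    ctx: SelectionContext, candidate: ItemParameters, cutoffs: np.ndarray
) -> float:
    """Determinant of the posterior information matrix after adding
    *candidate*'s information at the cutoff vector."""
    M = ctx.prior_precision + ctx.accumulated_info
    M = M.copy()
    d = candidate.dimension - 1
    M[d, d] += fisher_info(candidate, cutoffs, ctx.scale)
    if M.shape == (2, 2):
        return float(M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0])
    return float(np.linalg.det(M))


def select_next_item(
    ctx: SelectionContext, bank: ItemBank, cutoffs: np.ndarray
) -> int:
    """Item_id of the eligible candidate with the largest posterior
    information determinant; ties broken by lowest item_id."""
    best_id = -1
    best_det = -np.inf
    for k in range(bank.n_items):
        iid = int(bank.item_id[k])
        if iid not in ctx.eligible:
            continue
        det = posterior_info_determinant(ctx, bank.params_at(k), cutoffs)
        if det > best_det or (det == best_det and iid < best_id):
            best_det = det
            best_id = iid
    if best_id < 0:
        raise RuntimeError("item bank exhausted: no eligible candidates remain")
    return best_id


def record_administration(
    ctx: SelectionContext, item: ItemParameters, cutoffs: np.ndarray
) -> None:
    """Fold an administered item's information into the context and drop
    it from the eligible pool."""
    d = item.dimension - 1
    ctx.accumulated_info[d, d] += fisher_info(item, cutoffs, ctx.scale)
    ctx.eligible.discard(item.item_id)
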