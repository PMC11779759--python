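"""Single-examinee test administration loop.

The 5-step cycle per response: select the next item by posterior
information determinant at the cutoffs, score a simulated response,
update the per-dimension trait MLE, evaluate the active termination
criterion for every open dimension (for the pre-rule, recompute phi
and pick the criterion in real time), and decide / force-decide.

Because item information at the cutoffs and the imputed trait points of
the conditional criterion are constants for a given (bank, spec,
population) triple, a :class:`ConditionCache` precomputes per-item
information and per-item log-likelihood-ratio increments once, making
each administered item an O(1) update. ``administer_examinee`` without a
cache builds one on the fly; batch drivers share one across examinees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import termination as term
from .irt import ItemBank, ResponseRecord, _p3, mle_1d, mle_estimate
from .termination import (
    ABOVE,
    BELOW,
    C,
    CONTINUE,
    PRE_RULE,
    SF,
    ClassificationSpec,
    PopulationModel,
    TerminationEvaluation,
)

__all__ = [
    "TestState",
    "ExamineeResult",
    "ConditionCache",
    "administer_examinee",
    "evaluate_termination",
]

_CRITERIA = (SF, C, PRE_RULE)


@dataclass
class TestState:
    """Running record of one examinee's test."""

    __test__ = False  # not a pytest collection target

    records: list[ResponseRecord] = field(default_factory=list)
    k: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))
    theta_hat: np.ndarray = field(default_factory=lambda: np.zeros(2))
    status: list[str] = field(default_factory=lambda: ["open", "open"])
    forced: list[bool] = field(default_factory=lambda: [False, False])

    @classmethod
    def fresh(cls, D: int) -> "TestState":
        return cls(
            records=[],
            k=np.zeros(D, dtype=np.int64),
            theta_hat=np.zeros(D),
            status=["open"] * D,
            forced=[False] * D,
        )


@dataclass(frozen=True)
class ExamineeResult:
    """Final outcome of one administration."""

    theta_true: np.ndarray
    classifications: tuple[str, ...]
    correct: tuple[bool, ...]
    lengths: np.ndarray
    total_length: int
    forced: tuple[bool, ...]
    theta_hat: np.ndarray
    trace: list[dict] | None = None

    @property
    def correct_both(self) -> bool:
        return all(self.correct)

    @property
    def forced_both(self) -> bool:
        return all(self.forced)


class ConditionCache:
    """Per-(bank, spec, pop) constants shared across examinees."""

    def __init__(
        self,
        bank: ItemBank,
        spec: ClassificationSpec,
        pop: PopulationModel,
        scale: float = 1.0,
    ):
        if bank.D != 2 or spec.D != 2 or pop.D != 2:
            raise ValueError("the administration engine is implemented for D = 2")
        self.bank = bank
        self.spec = spec
        self.pop = pop
        self.scale = float(scale)
        dims0 = bank.dimension - 1
        self.dims0 = dims0
        cut_component = spec.cutoffs[dims0]
        p = _p3(bank.a, bank.b, bank.c, cut_component, self.scale)
        self.info = (
            (self.scale * bank.a) ** 2
            * ((1.0 - p) / p)
            * ((p - bank.c) / (1.0 - bank.c)) ** 2
        )

        # per-dimension candidate order: decreasing info, then item_id
        self.order = []
        for d in range(2):
            idx = np.flatnonzero(dims0 == d)
            key = np.lexsort((bank.item_id[idx], -self.info[idx]))
            self.order.append(idx[key])

        # log-LR increments for the conditional criterion, per target
        # dimension; the factorized criterion uses the same increments
        # restricted to items loading on the target dimension.
        self.d_correct = np.empty((2, bank.n_items))
        self.d_wrong = np.empty((2, bank.n_items))
        for t in range(2):
            num, den = term.imputation_points(t + 1, spec, pop)
            p_num = _p3(bank.a, bank.b, bank.c, num[dims0], self.scale)
            p_den = _p3(bank.a, bank.b, bank.c, den[dims0], self.scale)
            self.d_correct[t] = np.log(p_num) - np.log(p_den)
            self.d_wrong[t] = np.log1p(-p_num) - np.log1p(-p_den)

        self.prior_precision = np.linalg.inv(pop.sigma)
        self.log_A = math.log(spec.A)
        self.log_B = math.log(spec.B)
        self.rho = pop.rho


def _classify_true(theta_true: np.ndarray, cutoffs: np.ndarray) -> list[str]:
    return [ABOVE if t > c else BELOW for t, c in zip(theta_true, cutoffs)]


def administer_examinee(
    theta_true,
    bank: ItemBank,
    spec: ClassificationSpec,
    pop: PopulationModel,
    criterion: str,
    rng: np.random.Generator,
    min_items: int = 3,
    max_items: int = 30,
    cache: ConditionCache | None = None,
    trace: bool = False,
    scale: float = 1.0,
) -> ExamineeResult:
    """Administer a complete two-dimension classification test.

    *criterion* is one of ``"SF"``, ``"C"``, ``"P"``. Returns the final
    classifications, correctness against the sign of
    ``theta_true - cutoff``, per-dimension lengths and forced flags.
    *scale* is the logistic constant of the response model; ignored if
    *cache* is given (the cache carries its own).
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {_CRITERIA}, got {criterion!r}")
    if cache is None:
        cache = ConditionCache(bank, spec, pop, scale)
    theta_true = np.asarray(theta_true, dtype=float)

    ptr = [0, 0]
    m00 = cache.prior_precision[0, 0]
    m11 = cache.prior_precision[1, 1]
    off2 = cache.prior_precision[0, 1] * cache.prior_precision[1, 0]
    k = [0, 0]
    log_lr_c = [0.0, 0.0]
    log_lr_sf = [0.0, 0.0]
    status = ["open", "open"]
    forced = [False, False]
    theta_hat = np.zeros(2)
    dim_items: list[list[int]] = [[], []]
    dim_resp: list[list[bool]] = [[], []]
    records: list[ResponseRecord] = []
    steps: list[dict] | None = [] if trace else None
    need_mle = criterion == PRE_RULE

    a_arr, b_arr, c_arr = cache.bank.a, cache.bank.b, cache.bank.c
    cutoffs = spec.cutoffs

    while any(s == "open" for s in status) or k[0] < min_items or k[1] < min_items:
        # --- selection: best candidate per eligible dimension, then the
        # larger posterior-information determinant (tie: lower item_id)
        best_idx = -1
        best_det = -np.inf
        best_id = -1
        for d in range(2):
            if status[d] != "open" and k[d] >= min_items:
                continue
            if ptr[d] >= cache.order[d].size:
                continue
            idx = int(cache.order[d][ptr[d]])
            info = cache.info[idx]
            det = (m00 + info) * m11 - off2 if d == 0 else m00 * (m11 + info) - off2
            iid = int(cache.bank.item_id[idx])
            if det > best_det or (det == best_det and iid < best_id):
                best_det, best_idx, best_id = det, idx, iid
        if best_idx < 0:
            raise RuntimeError("item bank exhausted before all decisions were made")
        d_item = int(cache.dims0[best_idx])
        ptr[d_item] += 1

        # --- response
        p_true = _p3(
            a_arr[best_idx],
            b_arr[best_idx],
            c_arr[best_idx],
            theta_true[d_item],
            cache.scale,
        )
        u = bool(rng.random() < p_true)

        # --- bookkeeping
        k[d_item] += 1
        if d_item == 0:
            m00 += cache.info[best_idx]
        else:
            m11 += cache.info[best_idx]
        inc = cache.d_correct if u else cache.d_wrong
        log_lr_c[0] += inc[0, best_idx]
        log_lr_c[1] += inc[1, best_idx]
        log_lr_sf[d_item] += inc[d_item, best_idx]
        dim_items[d_item].append(best_idx)
        dim_resp[d_item].append(u)
        records.append(ResponseRecord(best_id, int(u), order=len(records)))

        if need_mle:
            sub = np.asarray(dim_items[d_item])
            theta_hat[d_item] = mle_1d(
                a_arr[sub],
                b_arr[sub],
                c_arr[sub],
                np.asarray(dim_resp[d_item]),
                scale=cache.scale,
            )

        # --- evaluate every open dimension (gated below the minimum)
        ph = float("nan")
        for d in range(2):
            evaluated = status[d] == "open" and k[d] >= min_items
            crit = None
            llr = float("nan")
            if evaluated:
                if criterion == PRE_RULE:
                    ph = (
                        cache.rho
                        * (theta_hat[0] - cutoffs[0])
                        * (theta_hat[1] - cutoffs[1])
                    )
                    crit = C if ph > 0.0 else SF
                else:
                    crit = criterion
                llr = log_lr_c[d] if crit == C else log_lr_sf[d]
                if llr >= cache.log_A:
                    status[d] = ABOVE
                elif llr < cache.log_B:
                    status[d] = BELOW
                elif k[d] >= max_items:
                    status[d] = (
                        ABOVE
                        if abs(llr - cache.log_A) < abs(llr - cache.log_B)
                        else BELOW
                    )
                    forced[d] = True
            if steps is not None:
                steps.append(
                    {
                        "step": len(records),
                        "item_id": best_id,
                        "item_dim": d_item + 1,
                        "u": int(u),
                        "eval_dim": d + 1,
                        "evaluated": evaluated,
                        "criterion_used": crit,
                        "phi": ph,
                        "log_lr": llr,
                        "decision": (
                            status[d] if evaluated and status[d] != "open" else CONTINUE
                        ),
                        "forced": evaluated and forced[d],
                        "theta_hat_1": theta_hat[0],
                        "theta_hat_2": theta_hat[1],
                    }
                )

    if not need_mle:
        theta_hat = mle_estimate(records, bank, scale=cache.scale)

    truth = _classify_true(theta_true, cutoffs)
    return ExamineeResult(
        theta_true=theta_true,
        classifications=tuple(status),
        correct=tuple(s == t for s, t in zip(status, truth)),
        lengths=np.asarray(k, dtype=np.int64),
        total_length=int(sum(k)),
        forced=tuple(forced),
        theta_hat=theta_hat.copy(),
        trace=steps,
    )


def evaluate_termination(
    state: TestState,
    bank: ItemBank,
    spec: ClassificationSpec,
    pop: PopulationModel,
    criterion: str,
    min_items: int = 3,
    max_items: int = 30,
    scale: float = 1.0,
) -> list[TerminationEvaluation]:
    """Evaluate the active criterion for every open dimension of *state*.

    Reference (non-incremental) implementation built on the batch
    likelihood-ratio functions; dimensions under the per-dimension
    minimum always continue.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {_CRITERIA}, got {criterion!r}")
    out: list[TerminationEvaluation] = []
    ph = term.phi(pop.rho, state.theta_hat, spec.cutoffs)
    for d in range(1, spec.D + 1):
        if state.status[d - 1] != "open":
            continue
        crit = term.choose_criterion(ph) if criterion == PRE_RULE else criterion
        if crit == C:
            lr = term.lr_c(d, state.records, bank, spec, pop, scale)
        else:
            lr = term.lr_sf(d, state.records, bank, spec, scale)
        if state.k[d - 1] < min_items:
            out.append(TerminationEvaluation(d, lr, ph, crit, CONTINUE, False))
            continue
        decision = term.decide(lr, spec)
        is_forced = False
        if decision == CONTINUE and state.k[d - 1] >= max_items:
            decision = term.forced_decide(lr, spec)
            is_forced = True
        out.append(TerminationEvaluation(d, lr, ph, crit, decision, is_forced))
    return out
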