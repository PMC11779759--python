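import math

import numpy as np
import pytest

from mcct.irt import ItemBank, ItemParameters, ResponseRecord, prob_3pl
from mcct.termination import (
    ABOVE,
    BELOW,
    C,
    CONTINUE,
    SF,
    ClassificationSpec,
    PopulationModel,
    choose_criterion,
    conditional_params,
    decide,
    forced_decide,
    imputation_points,
    indifference_bounds,
    log_lr_c,
    log_lr_sf,
    lr_c,
    lr_sf,
    phi,
    wald_thresholds,
)


def item(a=1.0, b=0.0, c=0.0, dim=1, iid=1):
    return ItemParameters(item_id=iid, dimension=dim, a=a, b=b, c=c)


def make_spec(cutoffs=(0.0, 0.0), delta=0.2, alpha=0.05, beta=0.05):
    return ClassificationSpec(np.asarray(cutoffs, float), delta, alpha, beta)


class TestIndifferenceBounds:
    def test_cutoff_two(self):
        assert indifference_bounds(2.0, 0.2) == (1.8, 2.2)

    def test_cutoff_zero(self):
        lo, hi = indifference_bounds(0.0, 0.2)
        assert lo == pytest.approx(-0.2) and hi == pytest.approx(0.2)

    def test_degenerate(self):
        assert indifference_bounds(1.3, 0.0) == (1.3, 1.3)

    def test_negative_delta(self):
        with pytest.raises(ValueError):
            indifference_bounds(0.0, -0.1)


class TestWaldThresholds:
    def test_nominal_rates(self):
        A, B = wald_thresholds(0.05, 0.05)
        assert A == pytest.approx(19.0)
        assert B == pytest.approx(1 / 19)

    def test_symmetric_rates_give_reciprocal(self):
        for r in (0.01, 0.1, 0.25):
            A, B = wald_thresholds(r, r)
            assert A == pytest.approx(1 / B)

    def test_monotone_in_alpha(self):
        assert wald_thresholds(0.01, 0.05)[0] > wald_thresholds(0.05, 0.05)[0]

    @pytest.mark.parametrize("alpha,beta", [(0.0, 0.05), (0.5, 0.05), (0.05, 0.6), (-0.1, 0.1)])
    def test_invalid_rates(self, alpha, beta):
        with pytest.raises(ValueError):
            wald_thresholds(alpha, beta)

    def test_spec_ordering_invariant(self):
        spec = make_spec()
        assert spec.A > 1 > spec.B > 0


class TestLrSf:
    def test_empty_is_one(self):
        bank = ItemBank.from_items([item()])
        assert lr_sf(1, [], bank, make_spec((0.0,))) == 1.0

    def test_single_rasch_item_oracle(self):
        # two-factor arithmetic oracle for one correct Rasch item at b=0,
        # bounds (-0.2, 0.2)
        bank = ItemBank.from_items([item(iid=1)])
        spec = make_spec((0.0,))
        got = lr_sf(1, [ResponseRecord(1, 1)], bank, spec)
        pu = 1 / (1 + math.exp(-0.2))
        pl = 1 / (1 + math.exp(0.2))
        assert got == pytest.approx(pu / pl, rel=1e-12)

    def test_other_dimension_items_have_no_effect(self):
        bank = ItemBank.from_items([item(iid=1, dim=1), item(iid=2, dim=2)])
        spec = make_spec()
        only = lr_sf(1, [ResponseRecord(1, 1)], bank, spec)
        both = lr_sf(1, [ResponseRecord(1, 1), ResponseRecord(2, 0)], bank, spec)
        assert only == both

    def test_correct_response_multiplies_by_factor_above_one(self):
        bank = ItemBank.from_items(
            [item(iid=1, a=1.1, b=0.3, c=0.1), item(iid=2, a=0.9, b=-0.5, c=0.2)]
        )
        spec = make_spec()
        before = lr_sf(1, [ResponseRecord(1, 0)], bank, spec)
        after = lr_sf(1, [ResponseRecord(1, 0), ResponseRecord(2, 1)], bank, spec)
        assert after > before

    def test_order_invariance(self):
        bank = ItemBank.from_items([item(iid=i, b=0.1 * i) for i in range(1, 6)])
        spec = make_spec()
        resp = [ResponseRecord(i, i % 2) for i in range(1, 6)]
        fwd = lr_sf(1, resp, bank, spec)
        rev = lr_sf(1, list(reversed(resp)), bank, spec)
        assert fwd == pytest.approx(rev, rel=1e-12)


class TestConditionalParams:
    def test_upper_bound_cutoff_two(self):
        pop = PopulationModel.bivariate(0.8)
        mean, var = conditional_params(pop, 2, 2.2, 1)
        assert mean == pytest.approx(1.76, abs=1e-12)
        assert var == pytest.approx(0.36, abs=1e-12)

    def test_lower_bound_cutoff_two(self):
        pop = PopulationModel.bivariate(0.8)
        mean, _ = conditional_params(pop, 2, 1.8, 1)
        assert mean == pytest.approx(1.44, abs=1e-12)

    def test_bounds_cutoff_zero(self):
        pop = PopulationModel.bivariate(0.8)
        assert conditional_params(pop, 2, 0.2, 1)[0] == pytest.approx(0.16, abs=1e-12)
        assert conditional_params(pop, 2, -0.2, 1)[0] == pytest.approx(-0.16, abs=1e-12)

    def test_independence(self):
        pop = PopulationModel.bivariate(0.0)
        mean, var = conditional_params(pop, 1, 3.0, 2)
        assert mean == 0.0
        assert var == 1.0

    def test_same_dimension_rejected(self):
        pop = PopulationModel.bivariate(0.5)
        with pytest.raises(ValueError):
            conditional_params(pop, 1, 0.0, 1)

    def test_degenerate_rho_rejected(self):
        with pytest.raises(ValueError):
            PopulationModel.bivariate(1.0)


class TestLrC:
    def test_reduces_to_sf_when_uncorrelated(self):
        bank = ItemBank.from_items(
            [item(iid=1, dim=1), item(iid=2, dim=2, a=1.2, b=0.4, c=0.1)]
        )
        spec = make_spec()
        pop = PopulationModel.bivariate(0.0)
        resp = [ResponseRecord(1, 1), ResponseRecord(2, 0)]
        assert lr_c(1, resp, bank, spec, pop) == pytest.approx(
            lr_sf(1, resp, bank, spec), rel=1e-12
        )

    def test_imputation_points_worked_example(self):
        # cutoff 2, delta 0.2, rho 0.8: numerator imputes (1.76, 2.2),
        # denominator (1.44, 1.8) when classifying dimension 2
        spec = make_spec((2.0, 2.0))
        pop = PopulationModel.bivariate(0.8)
        num, den = imputation_points(2, spec, pop)
        assert num == pytest.approx([1.76, 2.2], abs=1e-12)
        assert den == pytest.approx([1.44, 1.8], abs=1e-12)

    def test_correct_nontarget_response_increases_lr(self):
        bank = ItemBank.from_items(
            [item(iid=1, dim=1), item(iid=2, dim=2, a=1.0, b=0.0, c=0.0)]
        )
        spec = make_spec()
        pop = PopulationModel.bivariate(0.8)
        base = [ResponseRecord(1, 1)]
        with_correct = base + [ResponseRecord(2, 1)]
        with_wrong = base + [ResponseRecord(2, 0)]
        lr0 = lr_c(1, base, bank, spec, pop)
        assert lr_c(1, with_correct, bank, spec, pop) > lr0
        assert lr_c(1, with_wrong, bank, spec, pop) < lr0

    def test_brute_force_product_oracle(self):
        # independent oracle: explicit product of Bernoulli factors at
        # manually imputed trait points
        rng = np.random.default_rng(99)
        items = [
            item(
                iid=i,
                dim=1 + i % 2,
                a=float(rng.uniform(0.6, 1.6)),
                b=float(rng.uniform(-2, 2)),
                c=float(rng.uniform(0, 0.3)),
            )
            for i in range(1, 7)
        ]
        bank = ItemBank.from_items(items)
        spec = make_spec((1.0, -0.5))
        pop = PopulationModel.bivariate(0.6)
        resp = [ResponseRecord(i, int(rng.random() < 0.5)) for i in range(1, 7)]

        target = 1
        tU, tL = 1.2, 0.8
        num_pt = {1: tU, 2: 0.6 * tU + (-0.5)}  # cond mean: mu2 + rho*(tU - mu1)
        den_pt = {1: tL, 2: 0.6 * tL + (-0.5)}
        # mu = (0,0) margins: cond mean of dim2 given dim1=x is rho*x
        num_pt[2] = 0.6 * tU
        den_pt[2] = 0.6 * tL
        num = den = 1.0
        for r in resp:
            it = bank.get(r.item_id)
            pn = prob_3pl(it, np.array([num_pt[1], num_pt[2]]))
            pd_ = prob_3pl(it, np.array([den_pt[1], den_pt[2]]))
            num *= pn if r.u else (1 - pn)
            den *= pd_ if r.u else (1 - pd_)
        assert lr_c(target, resp, bank, spec, pop) == pytest.approx(
            num / den, rel=1e-12
        )


class TestPhi:
    def test_positive_quadrant(self):
        assert phi(0.8, np.array([1.0, 1.0]), np.zeros(2)) == pytest.approx(0.8)

    def test_discordant_quadrant(self):
        assert phi(0.8, np.array([1.0, -1.0]), np.zeros(2)) == pytest.approx(-0.8)

    def test_zero_correlation(self):
        assert phi(0.0, np.array([2.0, -3.0]), np.zeros(2)) == 0.0

    def test_joint_reflection_symmetry(self):
        cut = np.array([1.0, -1.0])
        th = np.array([1.7, -0.4])
        reflected = 2 * cut - th
        assert phi(0.5, th, cut) == pytest.approx(phi(0.5, reflected, cut))


class TestChooseCriterion:
    def test_positive(self):
        assert choose_criterion(0.8) == C

    def test_zero_goes_to_sf(self):
        assert choose_criterion(0.0) == SF

    def test_negative(self):
        assert choose_criterion(-0.3) == SF


class TestDecide:
    def test_at_threshold_a_is_above(self):
        spec = make_spec()
        assert decide(19.0, spec) == ABOVE

    def test_below_b(self):
        spec = make_spec()
        assert decide(0.05, spec) == BELOW

    def test_between(self):
        assert decide(1.0, make_spec()) == CONTINUE

    def test_exactly_b_continues(self):
        spec = make_spec()
        assert decide(spec.B, spec) == CONTINUE

    def test_nonpositive_lr(self):
        with pytest.raises(ValueError):
            decide(0.0, make_spec())
        with pytest.raises(ValueError):
            decide(-1.0, make_spec())


class TestForcedDecide:
    def test_closer_to_a(self):
        # |log 10 - log 19| < |log 10 - log(1/19)|
        assert forced_decide(10.0, make_spec()) == ABOVE

    def test_closer_to_b(self):
        assert forced_decide(0.1, make_spec()) == BELOW

    def test_tie_retains_null(self):
        # alpha = beta: log A = -log B so lr = 1 is log-equidistant
        assert forced_decide(1.0, make_spec()) == BELOW

    def test_nonpositive_lr(self):
        with pytest.raises(ValueError):
            forced_decide(0.0, make_spec())
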