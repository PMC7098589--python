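import numpy as np
import pytest

from foodpolicy.datasets import fruit_subsidy_20, three_food_demo
from foodpolicy.demand import (
    ExpenditureVector,
    FoodSystem,
    PEMatrix,
    PolicySpec,
    apply_policy,
    conditional_step,
    expenditure_step,
    fpi_percent_change,
    revealed_tfee,
    revealed_tfee_from_pct,
    run_policy_scenario,
    total_expenditure,
)


def two_food_system(q=(100.0, 100.0), p=(1.0, 1.0)):
    return FoodSystem(
        food_id=["a", "b"], q_b=list(q), p_b=list(p),
        energy_density=[400.0, 600.0],
        nutrient_content={"satfat": [10.0, 0.0], "sugar": [0.0, 20.0]},
    )


class TestTotalExpenditure:
    def test_hand_arithmetic(self):
        assert total_expenditure([100, 200], [1.00, 0.50]) == pytest.approx(2.00)

    def test_empty_basket(self):
        assert total_expenditure([0, 0, 0], [1.0, 2.0, 3.0]) == 0.0

    def test_single_food(self):
        assert total_expenditure([300], [2.00]) == pytest.approx(6.00)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            total_expenditure([1, 2], [1.0])

    def test_negative_price(self):
        with pytest.raises(ValueError, match="negative price"):
            total_expenditure([1], [-1.0])


class TestApplyPolicy:
    def test_safa_tax(self):
        system = FoodSystem(food_id=["butterish"], q_b=[100.0], p_b=[2.00],
                            energy_density=[3000.0],
                            nutrient_content={"satfat": [50.0]})
        p_a = apply_policy(system, PolicySpec(nutrient_taxes={"satfat": 2.00}))
        assert p_a[0] == pytest.approx(3.00)

    def test_empty_policy_identity(self):
        system = two_food_system()
        p_a = apply_policy(system, PolicySpec())
        np.testing.assert_allclose(p_a, system.p_b)

    def test_subsidy(self):
        system = two_food_system(p=(1.00, 1.00))
        p_a = apply_policy(system, PolicySpec(ad_valorem={"a": -0.20}))
        assert p_a[0] == pytest.approx(0.80)
        assert p_a[1] == pytest.approx(1.00)

    def test_unknown_nutrient(self):
        with pytest.raises(KeyError, match="sodium"):
            apply_policy(two_food_system(),
                         PolicySpec(nutrient_taxes={"sodium": 1.0}))

    def test_nonpositive_price(self):
        # a big enough per-nutrient subsidy can wipe out the price entirely
        with pytest.raises(ValueError, match="non-positive"):
            apply_policy(two_food_system(),
                         PolicySpec(nutrient_taxes={"satfat": -20.0}))

    def test_ad_valorem_must_exceed_minus_one(self):
        with pytest.raises(ValueError, match="-1"):
            PolicySpec(ad_valorem={"a": -1.0})


class TestFPI:
    def test_identity(self):
        system = two_food_system()
        assert fpi_percent_change(system, system.p_b) == pytest.approx(0.0)

    def test_equal_expenditure_half_effect(self):
        system = two_food_system()  # equal expenditure shares
        p_a = system.p_b * np.array([1.10, 1.0])
        assert fpi_percent_change(system, p_a) == pytest.approx(5.0)

    def test_uniform_scaling(self):
        system = two_food_system(q=(30.0, 250.0), p=(0.7, 2.2))
        assert fpi_percent_change(system, system.p_b * 1.2) == pytest.approx(20.0)


class TestConditionalStep:
    def test_two_food_worked_example(self):
        # equal expenditure of 1.00 each, own-PE -1, no cross effects,
        # +10% tax on food a
        system = two_food_system()
        pe = PEMatrix(epsilon=np.diag([-1.0, -1.0]))
        p_a = system.p_b * np.array([1.10, 1.0])
        dq = conditional_step(system, p_a, pe)
        assert dq[0] == pytest.approx(2.0 / 1.99 * 0.9 - 1.0, rel=1e-12)
        assert dq[1] == pytest.approx(2.0 / 1.99 - 1.0, rel=1e-12)
        assert 100 * dq[0] == pytest.approx(-9.548, abs=5e-4)
        assert 100 * dq[1] == pytest.approx(0.5025, abs=5e-5)
        post_exp = ((1 + dq) * system.q_b / 100 * p_a).sum()
        assert post_exp == pytest.approx(2.000, rel=1e-12)

    def test_no_price_change(self):
        system = two_food_system()
        pe = PEMatrix(epsilon=np.array([[-0.8, 0.1], [0.2, -1.2]]))
        dq = conditional_step(system, system.p_b, pe)
        np.testing.assert_allclose(dq, 0.0, atol=1e-15)

    def test_demo_system_expenditure_unchanged(self):
        system, pe = three_food_demo()
        p_a = apply_policy(system, fruit_subsidy_20())
        dq = conditional_step(system, p_a, pe)
        post = ((1 + dq) * system.q_b / 100 * p_a).sum()
        assert post == pytest.approx(system.x_b, rel=1e-12)

    def test_clamps_and_warns_on_negative_quantity(self):
        system = two_food_system()
        pe = PEMatrix(epsilon=np.diag([-15.0, -1.0]))
        p_a = system.p_b * np.array([1.10, 1.0])
        with pytest.warns(UserWarning, match="clamped"):
            dq = conditional_step(system, p_a, pe)
        assert np.all(1 + dq >= 0)
        post = ((1 + dq) * system.q_b / 100 * p_a).sum()
        assert post == pytest.approx(system.x_b, rel=1e-9)

    def test_misaligned_matrix(self):
        system = two_food_system()
        pe = PEMatrix(epsilon=np.diag([-1.0, -1.0, -1.0]))
        with pytest.raises(ValueError, match="dimension"):
            conditional_step(system, system.p_b, pe)


class TestExpenditureStep:
    def test_zero_price_change_identity(self):
        system = two_food_system()
        ee = ExpenditureVector(eta=np.ones(2))
        res = expenditure_step(system, system.p_b, np.zeros(2), ee, tfee=0.75)
        np.testing.assert_allclose(res.q_a, system.q_b, rtol=1e-12)
        assert res.x_a == pytest.approx(system.x_b, rel=1e-12)

    def test_tfee_zero_constant_expenditure(self):
        system = two_food_system()
        pe = PEMatrix(epsilon=np.array([[-1.0, 0.0], [0.0, -0.5]]))
        p_a = system.p_b * np.array([1.10, 1.0])
        dq = conditional_step(system, p_a, pe)
        res = expenditure_step(system, p_a, dq, ExpenditureVector(np.ones(2)),
                               tfee=0.0)
        assert res.x_a == pytest.approx(system.x_b, rel=1e-12)

    def test_fpi_plus_four_pct(self):
        # uniform +4% price rise, tfee 0.75, uniform eta -> X_A = 1.03 X_B
        system = two_food_system(q=(120.0, 80.0), p=(1.5, 2.5))
        pe = PEMatrix(epsilon=np.array([[-1.0, 0.1], [0.1, -0.7]]))
        p_a = system.p_b * 1.04
        dq = conditional_step(system, p_a, pe)
        res = expenditure_step(system, p_a, dq, ExpenditureVector(np.ones(2)),
                               tfee=0.75)
        assert res.x_a == pytest.approx(1.03 * system.x_b, rel=1e-9)
        # independent summation of q_a * p_a
        assert res.x_a == pytest.approx((res.q_a / 100 * res.p_a).sum(),
                                        rel=1e-15)

    def test_degenerate_ee_vector(self):
        system = two_food_system()
        pe = PEMatrix(epsilon=np.diag([-1.0, -1.0]))
        p_a = system.p_b * 1.05
        dq = conditional_step(system, p_a, pe)
        with pytest.raises(ValueError, match="degenerate"):
            expenditure_step(system, p_a, dq, ExpenditureVector(np.zeros(2)),
                             tfee=0.75)

    def test_engel_validation(self):
        system = two_food_system()
        bad = ExpenditureVector(eta=np.array([2.0, 2.0]), normalized=True)
        with pytest.raises(ValueError, match="Engel"):
            expenditure_step(system, system.p_b * 1.02, np.zeros(2), bad, 0.75)


class TestRunPolicyScenario:
    def test_null_policy_both_modes(self):
        system = two_food_system()
        pe = PEMatrix(epsilon=np.array([[-0.9, 0.2], [0.1, -1.1]]))
        ee = ExpenditureVector(np.ones(2))
        for mode in ("conventional", "tfee_adjusted"):
            res = run_policy_scenario(system, PolicySpec(), pe, ee=ee,
                                      tfee=0.75, mode=mode)
            np.testing.assert_allclose(res.q_a, system.q_b, rtol=1e-12)
            for summary in res.summaries.values():
                assert summary["post"] == pytest.approx(summary["pre"], rel=1e-12)

    def test_bad_mode(self):
        system = two_food_system()
        pe = PEMatrix(epsilon=np.diag([-1.0, -1.0]))
        with pytest.raises(ValueError, match="mode"):
            run_policy_scenario(system, PolicySpec(), pe, mode="magic")

    def test_tfee_mode_requires_inputs(self):
        system = two_food_system()
        pe = PEMatrix(epsilon=np.diag([-1.0, -1.0]))
        with pytest.raises(ValueError, match="requires"):
            run_policy_scenario(system, PolicySpec(), pe, mode="tfee_adjusted")

    def test_conventional_allows_expenditure_drift(self, small_bundle):
        system, pe, ee = small_bundle
        policy = PolicySpec(nutrient_taxes={"satfat": 2.0}, name="safa")
        res = run_policy_scenario(system, policy, pe, mode="conventional")
        assert res.mode == "conventional"
        assert res.delta_x is None
        # a conditional matrix transplanted to a random system drifts
        assert abs(res.x_a - res.x_b) > 1e-9

    def test_result_serializes(self, small_bundle):
        system, pe, ee = small_bundle
        policy = PolicySpec(ad_valorem={system.food_id[0]: 0.15})
        res = run_policy_scenario(system, policy, pe, ee=ee, tfee=0.6)
        d = res.to_dict()
        assert d["expenditure_change"]["units"] == "%"
        assert len(d["q_a_g_per_day"]) == system.n


class TestRevealedTFEe:
    def test_reported_arithmetic_fat_tax(self):
        assert revealed_tfee_from_pct(-1.92, 3.91) == pytest.approx(-0.49, abs=5e-3)

    def test_reported_arithmetic_subsidy(self):
        assert revealed_tfee_from_pct(0.72, -3.27) == pytest.approx(-0.22, abs=5e-3)

    def test_fixed_point(self, small_bundle):
        system, pe, ee = small_bundle
        policy = PolicySpec(nutrient_taxes={"sugar": 0.4})
        res = run_policy_scenario(system, policy, pe, ee=ee, tfee=0.75)
        assert revealed_tfee(res) == pytest.approx(0.75, rel=1e-9)

    def test_zero_fpi_error(self, small_bundle):
        system, pe, ee = small_bundle
        res = run_policy_scenario(system, PolicySpec(), pe, ee=ee, tfee=0.75)
        with pytest.raises(ValueError, match="zero FPI"):
            revealed_tfee(res)


class TestFoodSystemValidation:
    def test_shares_sum_to_one(self, small_bundle):
        system, _, _ = small_bundle
        assert system.shares.sum() == pytest.approx(1.0, abs=1e-12)

    def test_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            FoodSystem(food_id=["a", "a"], q_b=[1, 1], p_b=[1, 1],
                       energy_density=[1, 1])

    def test_nutrient_bounds(self):
        with pytest.raises(ValueError, match="sugar"):
            FoodSystem(food_id=["a"], q_b=[1], p_b=[1], energy_density=[1],
                       nutrient_content={"sugar": [150.0]})

    def test_positive_own_pe_warns(self):
        with pytest.warns(UserWarning, match="positive own-price"):
            PEMatrix(epsilon=np.array([[0.5]]))

    def test_positive_own_pe_strict_raises(self):
        with pytest.raises(ValueError, match="positive own-price"):
            PEMatrix(epsilon=np.array([[0.5]]), strict=True)
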