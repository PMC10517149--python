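import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omensim.behaviour_rules import (
    Action,
    DrugParameters,
    EnvLocal,
    RuleDistribution,
    RuleParameters,
    death_probability,
    division_probability,
    drug_effect,
    rule_distribution,
    sample_rule,
)
from omensim.model_core import Cell, CellState


def make_cell(state, birth=0, last_div=0, death=None, pos=(1, 1, 5)):
    return Cell(
        id=0,
        state=state,
        position=pos,
        birth_iteration=birth,
        last_division_iteration=last_div,
        death_iteration=death,
    )


def env(glu=1.0, o2=1.0, drug=0.0, depth=0.5):
    return EnvLocal(glu=glu, o2=o2, drug=drug, depth_frac=depth)


DRUG = DrugParameters(f=1.0, g=1.0, ic50=10.4, hill_coefficient=1.0, administered_dose=10.4)


class TestDrugEffect:
    def test_no_effect_without_drug(self):
        assert drug_effect(0.0, DRUG) == 0.0

    def test_half_effect_at_ic50(self):
        # administered dose = IC50, normalised concentration 1 -> C = IC50
        assert drug_effect(1.0, DRUG) == pytest.approx(0.5)

    def test_hill_one_at_three_ic50(self):
        d = DrugParameters(f=0, g=0, ic50=1.0, hill_coefficient=1.0, administered_dose=3.0)
        assert drug_effect(1.0, d) == pytest.approx(0.75)

    def test_none_drug_means_zero(self):
        assert drug_effect(5.0, None) == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            drug_effect(-0.1, DRUG)

    @given(st.floats(min_value=0, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_bounded_below_one(self, c):
        assert 0.0 <= drug_effect(c, DRUG) < 1.0

    def test_monotone_in_concentration(self):
        cs = np.linspace(0, 10, 50)
        vals = [drug_effect(c, DRUG) for c in cs]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestDivisionProbability:
    def test_direct_evaluation(self):
        # a=1, TLD=0.5, c=0.1, Glu=O2=1, f=0 -> 0.7
        cell = make_cell(CellState.CANCER_PROLIFERATING, last_div=0)
        p = RuleParameters(a=1, b=0, c=0.1, d=0, e=0)
        val = division_probability(cell, env(), p, None, iteration=36, total_iterations=72)
        assert val == pytest.approx(1 * 0.5 + 0.1 * 2)

    def test_all_terms_zero(self):
        cell = make_cell(CellState.CANCER_PROLIFERATING)
        p = RuleParameters(a=0, b=0, c=0, d=0, e=0)
        assert division_probability(cell, env(), p, None, iteration=10, total_iterations=72) == 0.0

    def test_clipped_at_one(self):
        # a=1, TLD=1, c=0.5, Glu=O2=1 -> raw 2.0 -> 1.0
        cell = make_cell(CellState.CANCER_PROLIFERATING, last_div=0)
        p = RuleParameters(a=1, b=0, c=0.5, d=0, e=0)
        assert division_probability(cell, env(), p, None, iteration=72, total_iterations=72) == 1.0

    def test_drug_term_subtracts(self):
        cell = make_cell(CellState.CANCER_PROLIFERATING, last_div=0)
        p = RuleParameters(a=0, b=0, c=0.25, d=0, e=0)
        base = division_probability(cell, env(), p, None, iteration=1, total_iterations=72)
        treated = division_probability(
            cell, env(drug=1.0), p, DRUG, iteration=1, total_iterations=72
        )
        assert treated == pytest.approx(base - 1.0 * 0.5)

    def test_wrong_state_rejected(self):
        cell = make_cell(CellState.CANCER_QUIESCENT)
        with pytest.raises(ValueError):
            division_probability(cell, env(), RuleParameters(1, 0, 0, 0, 0), None, iteration=1)


class TestDeathProbability:
    def test_direct_evaluation(self):
        # b=0.1, AGE=0.5, Glu=O2=1 -> 0.025
        cell = make_cell(CellState.CANCER_QUIESCENT, birth=0)
        p = RuleParameters(a=0, b=0.1, c=0, d=0, e=0)
        val = death_probability(cell, env(), p, None, iteration=36, total_iterations=72)
        assert val == pytest.approx(0.1 * 0.5 / 2)

    def test_zero_b_gives_zero(self):
        cell = make_cell(CellState.CANCER_QUIESCENT)
        p = RuleParameters(a=1, b=0, c=1, d=1, e=1)
        assert death_probability(cell, env(glu=0.3, o2=0.1), p, None, iteration=50) == 0.0

    def test_starvation_saturates_to_one(self):
        # b=1, AGE=1, Glu=O2=0.01 -> raw 50 -> 1.0
        cell = make_cell(CellState.CANCER_QUIESCENT, birth=0)
        p = RuleParameters(a=0, b=1, c=0, d=0, e=0)
        val = death_probability(
            cell, env(glu=0.01, o2=0.01), p, None, iteration=72, total_iterations=72
        )
        assert val == 1.0

    def test_nutrient_floor_avoids_division_by_zero(self):
        cell = make_cell(CellState.CANCER_QUIESCENT, birth=0)
        p = RuleParameters(a=0, b=1e-9, c=0, d=0, e=0)
        val = death_probability(
            cell, env(glu=0.0, o2=0.0), p, None, iteration=72, total_iterations=72
        )
        assert 0.0 <= val <= 1.0

    def test_wrong_state_rejected(self):
        cell = make_cell(CellState.CANCER_PROLIFERATING)
        with pytest.raises(ValueError):
            death_probability(cell, env(), RuleParameters(0, 1, 0, 0, 0), None, iteration=1)


class TestMonotonicity:
    P = RuleParameters(a=0.5, b=0.5, c=0.2, d=0.1, e=0.3)

    def test_division_nondecreasing_in_tld_and_nutrients(self):
        cell = lambda last: make_cell(CellState.CANCER_PROLIFERATING, last_div=last)
        vals_tld = [
            division_probability(cell(72 - k), env(), self.P, None, iteration=72)
            for k in range(0, 73, 8)
        ]
        assert all(b >= a for a, b in zip(vals_tld, vals_tld[1:]))
        vals_nut = [
            division_probability(cell(70), env(glu=g, o2=g), self.P, None, iteration=72)
            for g in np.linspace(0, 1, 11)
        ]
        assert all(b >= a for a, b in zip(vals_nut, vals_nut[1:]))

    def test_division_nonincreasing_in_drug(self):
        cell = make_cell(CellState.CANCER_PROLIFERATING, last_div=0)
        vals = [
            division_probability(
                cell, env(drug=dn), self.P, DRUG, iteration=36, total_iterations=72
            )
            for dn in np.linspace(0, 3, 13)
        ]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_death_nondecreasing_in_age_and_drug_nonincreasing_in_nutrients(self):
        vals_age = [
            death_probability(
                make_cell(CellState.CANCER_QUIESCENT, birth=72 - k),
                env(),
                self.P,
                None,
                iteration=72,
            )
            for k in range(0, 73, 8)
        ]
        assert all(b >= a for a, b in zip(vals_age, vals_age[1:]))
        cell = make_cell(CellState.CANCER_QUIESCENT, birth=0)
        vals_nut = [
            death_probability(cell, env(glu=g, o2=g), self.P, None, iteration=36)
            for g in np.linspace(0.05, 1, 11)
        ]
        assert all(b <= a for a, b in zip(vals_nut, vals_nut[1:]))


class TestRuleDistribution:
    def test_all_zero_params_residual_one(self):
        cell = make_cell(CellState.CANCER_PROLIFERATING)
        dist = rule_distribution(cell, env(), RuleParameters(0, 0, 0, 0, 0), None, 10, 72)
        assert all(v == 0 for v in dist.probabilities.values())
        assert dist.residual == 1.0
        assert set(dist.probabilities) == {Action.DIVIDE, Action.MIGRATE, Action.TO_QUIESCENT}

    def test_just_died_cannot_degrade(self):
        cell = make_cell(CellState.CANCER_DEAD, death=10)
        dist = rule_distribution(cell, env(), RuleParameters(0, 0, 0, 1, 0), None, 10, 72)
        assert dist.probabilities[Action.DEGRADE] == 0.0

    def test_degrade_grows_after_death(self):
        cell = make_cell(CellState.CANCER_DEAD, death=10)
        dist = rule_distribution(cell, env(), RuleParameters(0, 0, 0, 1, 0), None, 46, 72)
        assert dist.probabilities[Action.DEGRADE] == pytest.approx(36 / 72)

    def test_joint_rescaling_when_sum_exceeds_one(self):
        # arcs 0.8 (divide via c) and 0.6 (migrate via e) -> 0.8/1.4, 0.6/1.4
        cell = make_cell(CellState.CANCER_PROLIFERATING, last_div=0, pos=(1, 1, 5))
        p = RuleParameters(a=0, b=0, c=0.4, d=0, e=1.2)
        dist = rule_distribution(cell, env(depth=0.5), p, None, 0, 72)
        assert dist.probabilities[Action.DIVIDE] == pytest.approx(0.8 / 1.4)
        assert dist.probabilities[Action.MIGRATE] == pytest.approx(0.6 / 1.4)
        assert dist.residual == 0.0
        assert dist.total() == pytest.approx(1.0)

    def test_stromal_cells_have_no_rules(self):
        for s in (CellState.FIBROBLAST, CellState.MESOTHELIAL):
            with pytest.raises(ValueError, match="stromal"):
                rule_distribution(make_cell(s), env(), RuleParameters(0, 0, 0, 0, 0), None, 1, 72)

    def test_untreated_and_zero_fg_treated_identical(self):
        cell = make_cell(CellState.CANCER_PROLIFERATING, last_div=10)
        p = RuleParameters(a=0.3, b=0.2, c=0.1, d=0.1, e=0.2)
        inert = DrugParameters(f=0, g=0, ic50=10.4, administered_dose=10.4)
        d1 = rule_distribution(cell, env(drug=0.8), p, None, 40, 72)
        d2 = rule_distribution(cell, env(drug=0.8), p, inert, 40, 72)
        assert d1.probabilities == d2.probabilities

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.integers(min_value=0, max_value=72),
    )
    @settings(max_examples=80, deadline=None)
    def test_probabilities_always_valid(self, a, b, c, d, e, glu, o2, it):
        p = RuleParameters(a=a, b=b, c=c, d=d, e=e)
        for state in (CellState.CANCER_PROLIFERATING, CellState.CANCER_QUIESCENT):
            cell = make_cell(state)
            dist = rule_distribution(cell, env(glu=glu, o2=o2), p, None, it, 72)
            assert all(0.0 <= v <= 1.0 for v in dist.probabilities.values())
            assert 0.0 <= dist.residual <= 1.0
            assert dist.total() <= 1.0 + 1e-12


class TestSampleRule:
    def test_degenerate_distribution(self, rng):
        dist = RuleDistribution({Action.DIVIDE: 1.0}, 0.0)
        assert all(sample_rule(dist, rng) is Action.DIVIDE for _ in range(20))

    def test_all_zero_arcs_always_none(self, rng):
        dist = RuleDistribution({Action.DIVIDE: 0.0, Action.MIGRATE: 0.0}, 1.0)
        assert all(sample_rule(dist, rng) is Action.NONE for _ in range(20))

    def test_frequency_matches_binomial(self, rng):
        dist = RuleDistribution({Action.DIVIDE: 0.5}, 0.5)
        n = 10_000
        hits = sum(sample_rule(dist, rng) is Action.DIVIDE for _ in range(n))
        sigma = np.sqrt(n * 0.25)
        assert abs(hits - n * 0.5) < 3 * sigma
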