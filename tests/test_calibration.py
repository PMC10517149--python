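import itertools

import numpy as np
import pytest

from omensim.behaviour_rules import DrugParameters, RuleParameters
from omensim.calibration import (
    ExperimentalDataset,
    assemble_model_combinations,
    config_distance,
    grid_search_drug,
    grid_search_growth,
    score_adhesion,
    score_invasion,
    score_proliferation,
    total_score,
)
from omensim.validation_analysis import DoseResponseCurve


def make_dataset(setting="2D", eg=2.0, invasion=100.0, adhesion_level=1.0, with_dr=True):
    dr = None
    if with_dr:
        dr = {
            "cisplatin": DoseResponseCurve(
                drug="cisplatin",
                concentrations=np.array([0.0, 10.4, 50.0]),
                viability=np.array([1.0, 0.6, 0.3]) if setting == "2D" else np.array([1.0, 0.8, 0.5]),
            )
        }
    return ExperimentalDataset(
        eg=eg,
        invasion_count=invasion,
        adhesion={t: adhesion_level for t in (2, 3, 4)},
        tags={a: setting for a in ("proliferation", "invasion", "adhesion")},
        dose_response=dr,
    )


class TestScoreProliferation:
    @pytest.mark.parametrize(
        "c0,c72,eg,expected",
        [
            (100, 200, 2.0, 0.0),
            (100, 400, 2.0, 1.0),
            (100, 87, 0.87, 0.0),
            (100, 100, 2.0, 0.5),
            (50, 25, 0.5, 0.0),
            (100, 300, 2.0, 0.5),
            (100, 100, 0.87, 0.13 / 0.87),
            (200, 200, 1.0, 0.0),
            (100, 50, 2.0, 0.75),
            (10, 87, 0.87, 9.0),
        ],
    )
    def test_hand_computed(self, c0, c72, eg, expected):
        assert score_proliferation(c0, c72, eg) == pytest.approx(expected)

    def test_undershoot_and_overshoot_symmetric_in_magnitude(self):
        assert score_proliferation(100, 100, 2.0) == score_proliferation(100, 300, 2.0)

    def test_zero_initial_count_rejected(self):
        with pytest.raises(ValueError):
            score_proliferation(0, 100, 2.0)

    def test_signed_mode_keeps_direction(self):
        assert score_proliferation(100, 100, 2.0, signed=True) == pytest.approx(-0.5)


class TestScoreInvasion:
    @pytest.mark.parametrize(
        "i_sim,i_vitro,expected",
        [
            (100, 100, 0.0),
            (150, 100, 0.5),
            (50, 100, 0.5),
            (0, 100, 1.0),
            (190, 190, 0.0),
            (380, 190, 1.0),
            (95, 190, 0.5),
            (300, 100, 2.0),
            (100, 190, 90 / 190),
            (1, 100, 0.99),
        ],
    )
    def test_hand_computed(self, i_sim, i_vitro, expected):
        assert score_invasion(i_sim, i_vitro) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            score_invasion(10, 0)


class TestScoreAdhesion:
    def test_proportional_series_scores_zero(self):
        a = {2: 0.9, 3: 1.1, 4: 1.0}
        c = (0.9 * 7, 1.1 * 7, 1.0 * 7)
        assert score_adhesion(c, a) == pytest.approx(0.0)

    def test_hand_computed_flat_reference(self):
        # c=(50,80,100), a flat -> |0.5-1| + |0.8-1| + 0 = 0.7
        assert score_adhesion((50, 80, 100), {2: 1.0, 3: 1.0, 4: 1.0}) == pytest.approx(0.7)

    @pytest.mark.parametrize(
        "c,a,expected",
        [
            ((100, 100, 100), {2: 1, 3: 1, 4: 1}, 0.0),
            ((200, 100, 100), {2: 1, 3: 1, 4: 1}, 1.0),
            ((100, 100, 200), {2: 1, 3: 1, 4: 1}, 1.0),
            ((60, 80, 100), {2: 0.6, 3: 0.8, 4: 1.0}, 0.0),
            ((30, 80, 100), {2: 0.6, 3: 0.8, 4: 1.0}, 0.5),
            ((50, 50, 100), {2: 1, 3: 1, 4: 1}, 1.0),
            ((120, 90, 100), {2: 1.2, 3: 0.9, 4: 1.0}, 0.0),
            ((100, 90, 100), {2: 0.5, 3: 0.9, 4: 1.0}, 1.0),
            ((75, 100, 100), {2: 1, 3: 1, 4: 1}, 0.25),
            ((100, 75, 100), {2: 1, 3: 1, 4: 1}, 0.25),
        ],
    )
    def test_fixture_cases(self, c, a, expected):
        assert score_adhesion(c, a) == pytest.approx(expected)

    def test_scale_invariance_in_counts(self):
        a = {2: 0.7, 3: 1.3, 4: 1.0}
        assert score_adhesion((55, 70, 90), a) == pytest.approx(
            score_adhesion((550, 700, 900), a)
        )

    def test_zero_normaliser_rejected(self):
        with pytest.raises(ValueError):
            score_adhesion((10, 10, 0), {2: 1, 3: 1, 4: 1})
        with pytest.raises(ValueError):
            score_adhesion((10, 10, 10), {2: 1, 3: 1, 4: 0})


class TestTotalScoreAndDistance:
    def test_total_is_plain_sum(self):
        assert total_score(0, 0, 0) == 0
        assert total_score(0.2, 0.5, 0.7) == pytest.approx(1.4)
        assert total_score(0.7, 0.2, 0.5) == pytest.approx(1.4)

    def test_distance_cases(self):
        p1 = RuleParameters(1, 0.1, 0.1, 0.01, 0.1)
        p2 = RuleParameters(1, 0.5, 0.1, 0.01, 0.1)
        assert config_distance(p1, p1) == 0.0
        assert config_distance(p1, p2) == pytest.approx(0.4)
        assert config_distance(p1, p2) == config_distance(p2, p1)


class TestGridSearchEnumeration:
    GRID3 = (0.01, 0.1, 1.0)

    def test_dry_run_counts_paper_grid(self):
        from omensim.calibration import PAPER_GRID

        res = grid_search_growth(make_dataset(), None, PAPER_GRID, dry_run=True)
        assert res.n_configurations == 7**5 == 16_807

    def test_two_value_grid_enumerates_32(self):
        res = grid_search_growth(make_dataset(), None, (0.1, 1.0), dry_run=True)
        assert res.n_configurations == 32

    def test_injected_objective_matches_brute_force(self):
        target = RuleParameters(0.1, 0.01, 1.0, 0.1, 0.01)
        scorer = lambda p: config_distance(p, target)
        res = grid_search_growth(make_dataset(), None, self.GRID3, scorer=scorer)
        assert res.n_configurations == 3**5 == 243
        assert res.best_params == target
        assert res.best_score.s_total == 0.0
        # independent brute-force argmin over the same grid
        best = min(
            itertools.product(self.GRID3, repeat=5),
            key=lambda combo: (config_distance(RuleParameters(*combo), target), combo),
        )
        assert res.best_params.as_tuple() == best

    def test_tie_break_is_lexicographic(self):
        res = grid_search_growth(make_dataset(), None, (0.1, 1.0), scorer=lambda p: 0.0)
        assert res.best_params.as_tuple() == (0.1, 0.1, 0.1, 0.1, 0.1)
        res2 = grid_search_growth(make_dataset(), None, (1.0, 0.1), scorer=lambda p: 0.0)
        assert res2.best_params.as_tuple() == (0.1, 0.1, 0.1, 0.1, 0.1)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search_growth(make_dataset(), None, (), scorer=lambda p: 0.0)

    def test_score_table_has_all_rows(self):
        res = grid_search_growth(
            make_dataset(), None, (0.1, 1.0), scorer=lambda p: sum(p.as_tuple())
        )
        assert len(res.table) == 32
        assert set(res.table.columns) >= {"a", "b", "c", "d", "e", "s_total"}


class TestGridSearchDrug:
    def test_two_value_grid_enumerates_4(self):
        res = grid_search_drug(None, ic50=10.4, grid_values=(0.1, 1.0), scorer=lambda d: d.f)
        assert res.n_configurations == 4

    def test_injected_objective_unique_minimum(self):
        target = (0.05, 0.001)
        scorer = lambda d: abs(d.f - target[0]) + abs(d.g - target[1])
        res = grid_search_drug(
            None, ic50=10.4, grid_values=(0.001, 0.05, 0.5), scorer=scorer
        )
        assert (res.best_params.f, res.best_params.g) == target

    def test_bad_ic50_rejected(self):
        with pytest.raises(ValueError):
            grid_search_drug(None, ic50=0.0, grid_values=(0.1,), scorer=lambda d: 0.0)


class TestModelCombinations:
    def test_eight_distinct_combinations(self):
        combos = assemble_model_combinations(make_dataset("2D"), make_dataset("3D", eg=0.87, invasion=190.0))
        assert len(combos) == 8
        assert [c.combination_id for c in combos] == list(range(1, 9))
        tag_vectors = {tuple(c.tags[a] for a in ("proliferation", "invasion", "adhesion")) for c in combos}
        assert len(tag_vectors) == 8

    def test_all_2d_and_all_3d_endpoints(self):
        d2 = make_dataset("2D")
        d3 = make_dataset("3D", eg=0.87, invasion=190.0, adhesion_level=1.1)
        combos = assemble_model_combinations(d2, d3)
        first, last = combos[0], combos[-1]
        assert first.eg == d2.eg and first.invasion_count == d2.invasion_count
        assert first.adhesion == d2.adhesion
        assert last.eg == d3.eg and last.invasion_count == d3.invasion_count
        assert last.adhesion == d3.adhesion

    def test_id_mapping_follows_results_convention(self):
        # 3D invasion appears in combinations 3, 4, 7, 8; 2D proliferation in 1-4
        combos = assemble_model_combinations(make_dataset("2D"), make_dataset("3D", eg=0.87))
        inv3d = [c.combination_id for c in combos if c.tags["invasion"] == "3D"]
        prolif2d = [c.combination_id for c in combos if c.tags["proliferation"] == "2D"]
        assert inv3d == [3, 4, 7, 8]
        assert prolif2d == [1, 2, 3, 4]

    def test_missing_dose_response_rejected(self):
        with pytest.raises(ValueError):
            assemble_model_combinations(make_dataset(with_dr=False), make_dataset("3D"))


class TestDatasetValidation:
    def test_bad_eg_rejected(self):
        with pytest.raises(ValueError):
            ExperimentalDataset(eg=0.0, invasion_count=10, adhesion={2: 1, 3: 1, 4: 1})

    def test_bad_adhesion_rejected(self):
        with pytest.raises(ValueError):
            ExperimentalDataset(eg=1.0, invasion_count=10, adhesion={2: 1, 3: 0, 4: 1})

    def test_bad_tags_rejected(self):
        with pytest.raises(ValueError):
            ExperimentalDataset(
                eg=1.0,
                invasion_count=10,
                adhesion={2: 1, 3: 1, 4: 1},
                tags={"proliferation": "4D"},
            )
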