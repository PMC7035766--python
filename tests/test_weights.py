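"""Ranked weight space: constraints, LPs, and tradeoff statements."""

import numpy as np
import pytest

from fitradeoff import (
    InconsistentStatementError,
    TradeoffStatement,
    WeightSpace,
    add_statement,
    max_additive_value,
    ranked_simplex_vertices,
    ratio_bounds,
    space_from_ranking,
    weight_bounds,
)
from conftest import random_problem


class TestSpaceFromRanking:
    def test_contains_a_strictly_ranked_vector(self, ranked_space):
        assert ranked_space.contains([0.4, 0.3, 0.2, 0.1])

    def test_equal_weights_infeasible_under_strict_ranking(self, ranked_space):
        assert not ranked_space.contains([0.25, 0.25, 0.25, 0.25])

    def test_rejects_ties_and_missing(self):
        with pytest.raises(ValueError, match="ties"):
            space_from_ranking(["a", "b", "a"])
        with pytest.raises(ValueError, match="two"):
            space_from_ranking(["a"])

    def test_two_criteria_closed_form_bounds(self):
        space = space_from_ranking(["top", "bottom"])
        b = weight_bounds(space)
        lo, hi = b["bottom"]
        assert hi == pytest.approx(0.5, abs=1e-5)
        assert lo == pytest.approx(0.0, abs=1e-5)
        lo1, hi1 = b["top"]
        assert (lo1, hi1) == pytest.approx((0.5, 1.0), abs=1e-5)


class TestWeightBounds:
    def test_four_criteria_simplex_geometry(self, ranked_space):
        b = weight_bounds(ranked_space)
        assert b["guidelines"] == pytest.approx((0.25, 1.0), abs=1e-5)
        assert b["ease_of_evaluation"][1] <= 0.25 + 1e-9

    def test_bounds_nest_after_statement(self, ranked_space):
        before = weight_bounds(ranked_space)
        stmt = TradeoffStatement("guidelines", "ease_of_use", 0.5, "b")
        after = weight_bounds(add_statement(ranked_space, stmt))
        assert after.nested_within(before)
        assert not before.nested_within(after) or before == after


class TestAddStatement:
    def test_b_answer_caps_top_weight(self, ranked_space):
        before, _ = ranked_space.solve(np.array([1.0, 0, 0, 0]))
        stmt = TradeoffStatement("guidelines", "ease_of_use", 0.5, "b")
        shrunk = add_statement(ranked_space, stmt)
        after, _ = shrunk.solve(np.array([1.0, 0, 0, 0]))
        assert after < before - 0.1  # k2 >= 0.5 k1 forces k1 well below 1

    def test_a_answer_near_one_is_nearly_vacuous(self, ranked_space):
        stmt = TradeoffStatement("guidelines", "ease_of_use", 0.999999, "a")
        before = weight_bounds(ranked_space)
        after = weight_bounds(add_statement(ranked_space, stmt))
        assert after.nested_within(before)
        for c in ranked_space.criteria:
            assert after[c] == pytest.approx(before[c], abs=1e-4)

    def test_contradictory_answers_raise(self, ranked_space):
        s1 = add_statement(
            ranked_space, TradeoffStatement("guidelines", "ease_of_use", 0.7, "a")
        )
        with pytest.raises(InconsistentStatementError):
            add_statement(
                s1, TradeoffStatement("guidelines", "ease_of_use", 0.7, "b")
            )

    def test_input_space_is_unchanged(self, ranked_space):
        n_before = len(ranked_space.constraints)
        add_statement(
            ranked_space, TradeoffStatement("guidelines", "ease_of_use", 0.5, "b")
        )
        assert len(ranked_space.constraints) == n_before

    def test_statement_must_point_down_the_ranking(self, ranked_space):
        with pytest.raises(ValueError, match="higher-ranked"):
            add_statement(
                ranked_space,
                TradeoffStatement("ease_of_use", "guidelines", 0.5, "a"),
            )

    def test_indifference_pins_the_ratio(self, ranked_space):
        stmt = TradeoffStatement("guidelines", "ease_of_use", 0.8, "indifferent")
        lo, hi = ratio_bounds(
            add_statement(ranked_space, stmt), "guidelines", "ease_of_use"
        )
        assert lo == pytest.approx(0.8, abs=1e-5)
        assert hi == pytest.approx(0.8, abs=1e-5)

    def test_level_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            TradeoffStatement("a", "b", 1.0, "a")


class TestRatioBounds:
    def test_ranking_only_interval_is_unit(self, ranked_space):
        lo, hi = ratio_bounds(ranked_space, "guidelines", "ease_of_use")
        assert lo == pytest.approx(0.0, abs=1e-5)
        assert hi == pytest.approx(1.0, abs=1e-4)

    def test_intervals_nest_after_statement(self, ranked_space):
        stmt = TradeoffStatement("guidelines", "ease_of_use", 0.5, "b")
        shrunk = add_statement(ranked_space, stmt)
        lo, hi = ratio_bounds(shrunk, "guidelines", "ease_of_use")
        assert lo == pytest.approx(0.5, abs=1e-5)
        assert hi <= 1.0 + 1e-9


class TestMaxAdditiveValue:
    def test_published_maxima(self, ranked_space, case_problem):
        v_ats, k_ats = max_additive_value(ranked_space, case_problem, "ATS")
        assert v_ats == pytest.approx(1.0, abs=1e-3)
        v_set, _ = max_additive_value(ranked_space, case_problem, "SET")
        assert v_set == pytest.approx(2 / 3, abs=1e-3)
        assert sum(k_ats.values()) == pytest.approx(1.0, abs=1e-6)

    def test_argmax_lies_in_the_space(self, ranked_space, case_problem):
        for alt in case_problem.alternative_ids:
            _, k = max_additive_value(ranked_space, case_problem, alt)
            assert ranked_space.contains(k, tol=1e-6)

    def test_agrees_with_vertex_enumeration_oracle(
        self, zero_delta_space, case_problem
    ):
        # any linear objective peaks at an equal-weight-prefix vertex
        verts = ranked_simplex_vertices(4)
        norm = case_problem.normalized()[list(zero_delta_space.criteria)]
        for alt in case_problem.alternative_ids:
            oracle = float((verts @ norm.loc[alt].to_numpy()).max())
            lp, _ = max_additive_value(zero_delta_space, case_problem, alt)
            assert lp == pytest.approx(oracle, abs=1e-7)

    def test_vertex_oracle_on_random_problems(self):
        rng = np.random.default_rng(42)
        verts = ranked_simplex_vertices(4)
        for _ in range(10):
            p = random_problem(rng)
            space = space_from_ranking(p.criterion_ids, delta=0.0)
            norm = p.normalized()
            for alt in p.alternative_ids:
                oracle = float((verts @ norm.loc[alt].to_numpy()).max())
                lp, _ = max_additive_value(space, p, alt)
                assert lp == pytest.approx(oracle, abs=1e-7)


def test_serialization_round_trip(ranked_space, tmp_path):
    stmt = TradeoffStatement("guidelines", "ease_of_use", 0.6, "b")
    space = add_statement(ranked_space, stmt)
    path = tmp_path / "space.json"
    space.to_json(path)
    back = WeightSpace.from_dict(__import__("json").loads(path.read_text()))
    assert back.criteria == space.criteria
    assert back.constraints == space.constraints
    assert back.statements == space.statements
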