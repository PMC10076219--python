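"""Binarization, three-valued formula evaluation and class assignment."""

import itertools
import random

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import bluepolicy as bp
from bluepolicy.classify import CrispMembership, RelevanceClass, Truth
from bluepolicy.errors import ConfigurationError, DataError, InputError
from bluepolicy.rules import AllOf, AnyOf, Leaf

from conftest import (
    TEN_COUNTRY_B12_CLASSES,
    make_table,
    oracle_evaluate,
    random_monotone_formula,
)

IN, OUT, MISSING = CrispMembership.IN, CrispMembership.OUT, CrispMembership.MISSING
greater_strict = bp.Condition("g", "x", "greater", 0.10, strict=True)


class TestBinarize:
    @pytest.mark.parametrize(
        "value,condition,expected",
        [
            (0.12, bp.Condition("c", "x", "greater", 0.10, strict=True), IN),
            (0.10, bp.Condition("c", "x", "greater", 0.10, strict=True), OUT),
            (0.10, bp.Condition("c", "x", "greater", 0.10, strict=False), IN),
            (0.08, bp.Condition("c", "x", "greater", 0.10, strict=False), OUT),
            (0.05, bp.Condition("c", "x", "less", 0.10, strict=True), IN),
            (0.10, bp.Condition("c", "x", "less", 0.10, strict=True), OUT),
            (0.10, bp.Condition("c", "x", "less", 0.10, strict=False), IN),
            (None, bp.Condition("c", "x", "greater", 0.10), MISSING),
        ],
    )
    def test_membership(self, value, condition, expected):
        assert bp.binarize(value, condition) is expected

    def test_non_finite_is_data_error_not_missing(self):
        with pytest.raises(DataError):
            bp.binarize(float("nan"), greater_strict)
        with pytest.raises(DataError):
            bp.binarize(float("inf"), greater_strict)


class TestEvaluateFormula:
    @pytest.mark.parametrize(
        "formula,memberships,expected",
        [
            # Kleene OR short-circuit: one true arm decides
            (AnyOf((Leaf("a"), Leaf("b"))), {"a": IN, "b": MISSING}, Truth.TRUE),
            # decisive missing under AND
            (AllOf((Leaf("a"), Leaf("b"))), {"a": IN, "b": MISSING}, Truth.UNKNOWN),
            # Kleene AND short-circuit: one false arm decides
            (AllOf((Leaf("a"), Leaf("b"))), {"a": OUT, "b": MISSING}, Truth.FALSE),
            (AnyOf((Leaf("a"), Leaf("b"))), {"a": OUT, "b": MISSING}, Truth.UNKNOWN),
            (Leaf("a"), {"a": MISSING}, Truth.UNKNOWN),
        ],
    )
    def test_kleene_cases(self, formula, memberships, expected):
        assert bp.evaluate_formula(formula, memberships) is expected

    def test_unreferenced_condition_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="zz"):
            bp.evaluate_formula(Leaf("zz"), {"a": IN})

    def test_matches_completion_oracle_on_random_formulae(self):
        """Strong-Kleene evaluation equals the brute-force oracle that
        enumerates every completion of the missing slots, over all 3^k
        membership assignments of random monotone formulae."""
        rng = random.Random(7)
        for _ in range(25):
            k = rng.randint(1, 6)
            cids = [f"c{i}" for i in range(k)]
            formula = random_monotone_formula(rng, cids)
            used = sorted(formula.condition_ids())
            for combo in itertools.product([IN, OUT, MISSING], repeat=len(used)):
                ms = dict(zip(used, combo))
                assert bp.evaluate_formula(formula, ms) is oracle_evaluate(formula, ms)

    def test_two_extreme_completions_suffice_for_monotone(self):
        """For monotone formulae the all-missing->OUT and ->IN
        completions pin the three-valued result (the evaluation
        contract)."""
        rng = random.Random(11)
        from conftest import eval_two_valued

        for _ in range(10):
            cids = [f"c{i}" for i in range(4)]
            formula = random_monotone_formula(rng, cids)
            used = sorted(formula.condition_ids())
            for combo in itertools.product([IN, OUT, MISSING], repeat=len(used)):
                ms = dict(zip(used, combo))
                low = {c: (m is IN) for c, m in ms.items()}  # MISSING -> OUT
                high = {c: (m is not OUT) for c, m in ms.items()}  # MISSING -> IN
                res = bp.evaluate_formula(formula, ms)
                if res is Truth.TRUE:
                    assert eval_two_valued(formula, low)
                elif res is Truth.FALSE:
                    assert not eval_two_valued(formula, high)
                else:
                    assert eval_two_valued(formula, high) and not eval_two_valued(formula, low)


class TestClassifyCountry:
    def test_both_conditions_satisfied_is_highly_relevant(self, default_rules):
        conditions, rulesets = default_rules
        b12 = next(rs for rs in rulesets if rs.policy_id == "nutrient_b12")
        row = {"sev_b12": 0.30, "bf_production": 20.0, "bf_imports": 0.0}
        assert bp.classify_country(row, b12, conditions) is RelevanceClass.HIGHLY_RELEVANT

    def test_decisive_missing_maps_to_missing_data(self, default_rules):
        conditions, rulesets = default_rules
        b12 = next(rs for rs in rulesets if rs.policy_id == "nutrient_b12")
        row = {"sev_b12": None, "bf_production": 20.0, "bf_imports": 0.0}
        assert bp.classify_country(row, b12, conditions) is RelevanceClass.MISSING_DATA

    def test_all_false_no_missing_is_less_relevant(self, default_rules):
        conditions, rulesets = default_rules
        b12 = next(rs for rs in rulesets if rs.policy_id == "nutrient_b12")
        row = {"sev_b12": 0.01, "bf_production": 0.0, "bf_imports": 0.0}
        assert bp.classify_country(row, b12, conditions) is RelevanceClass.LESS_RELEVANT

    def test_satisfied_or_arm_rescues_despite_missing(self, default_rules):
        """One known-high availability source suffices even when the
        other is unrecorded (Kleene OR)."""
        conditions, rulesets = default_rules
        b12 = next(rs for rs in rulesets if rs.policy_id == "nutrient_b12")
        row = {"sev_b12": 0.30, "bf_production": None, "bf_imports": 20.0}
        assert bp.classify_country(row, b12, conditions) is RelevanceClass.HIGHLY_RELEVANT


class TestClassifyAll:
    def test_ten_country_fixture_matches_hand_derivation(self, ten_country_table, default_rules):
        conditions, rulesets = default_rules
        result = bp.classify_all(ten_country_table, rulesets, conditions)
        got = result.classes["nutrient_b12"].to_dict()
        assert got == TEN_COUNTRY_B12_CLASSES
        counts = result.counts().loc["nutrient_b12"]
        assert counts.to_dict() == {
            "highly_relevant": 3,
            "relevant": 2,
            "less_relevant": 3,
            "missing_data": 2,
        }

    def test_row_order_invariance(self, ten_country_table, default_rules):
        conditions, rulesets = default_rules
        a = bp.classify_all(ten_country_table, rulesets, conditions)
        shuffled = bp.CountryIndicatorTable(
            data=ten_country_table.data.sample(frac=1, random_state=3),
            schema=ten_country_table.schema,
        )
        b = bp.classify_all(shuffled, rulesets, conditions)
        pd.testing.assert_frame_equal(a.classes, b.classes)

    def test_all_availability_missing_excludes_relevant_classes(self, default_rules):
        """With every availability indicator missing, no availability-
        requiring policy can resolve relevant: only missing_data or
        less_relevant are reachable (confirmed by enumerating both
        completions: availability can never be known-true)."""
        conditions, rulesets = default_rules
        avail_policies = {"nutrient_b12", "nutrient_omega3", "cvd_red_meat", "ghg_footprint"}
        t = make_table(
            {
                f"C{i:02d}": {
                    "sev_b12": 0.05 * i,
                    "sev_omega3": 0.09 * i,
                    "red_meat_intake": 20.0 * i,
                    "ruminant_meat_intake": 10.0 * i,
                    "cvd_burden": 2000.0 * i,
                    "bf_production": None,
                    "bf_imports": None,
                }
                for i in range(8)
            }
        )
        result = bp.classify_all(t, rulesets, conditions)
        for p in avail_policies:
            assert set(result.classes[p]) <= {"missing_data", "less_relevant"}

    def test_empty_table_is_input_error(self, default_rules):
        conditions, rulesets = default_rules
        empty = make_table({"AAA": {}})
        empty.data = empty.data.iloc[0:0]
        with pytest.raises(InputError):
            bp.classify_all(empty, rulesets, conditions)

    def test_partition_invariant(self, default_rules):
        conditions, rulesets = default_rules
        t = bp.emulate_study_shape(5, n_countries=60)
        counts = bp.classify_all(t, rulesets, conditions).counts()
        assert (counts.sum(axis=1) == 60).all()

    @settings(max_examples=30, deadline=None)
    @given(
        sev=st.floats(0, 1),
        prod=st.one_of(st.none(), st.floats(0, 50)),
        imports=st.one_of(st.none(), st.floats(0, 50)),
    )
    def test_monotonicity_flipping_out_to_in(self, default_rules, sev, prod, imports):
        """Raising any indicator through a greater-direction cutoff never
        moves a country away from relevance."""
        conditions, rulesets = default_rules
        b12 = next(rs for rs in rulesets if rs.policy_id == "nutrient_b12")
        order = {
            RelevanceClass.LESS_RELEVANT: 0,
            RelevanceClass.MISSING_DATA: 0,  # incomparable; exclude below
            RelevanceClass.RELEVANT: 1,
            RelevanceClass.HIGHLY_RELEVANT: 2,
        }
        row = {"sev_b12": sev, "bf_production": prod, "bf_imports": imports}
        base = bp.classify_country(row, b12, conditions)
        boosted = dict(row, sev_b12=1.0)  # above every sev cutoff
        after = bp.classify_country(boosted, b12, conditions)
        if base not in (RelevanceClass.MISSING_DATA,) and after not in (RelevanceClass.MISSING_DATA,):
            assert order[after] >= order[base]

    def test_long_frame_round_trip(self, ten_country_table, default_rules):
        conditions, rulesets = default_rules
        result = bp.classify_all(ten_country_table, rulesets, conditions)
        back = bp.ClassificationResult.from_long_frame(result.to_long_frame())
        pd.testing.assert_frame_equal(result.classes, back.classes)
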