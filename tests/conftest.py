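"""Shared fixtures: rule configs, hand-built tables, formula oracles."""

from __future__ import annotations

import itertools
import random

import numpy as np
import pandas as pd
import pytest

import bluepolicy as bp
from bluepolicy.classify import CrispMembership, Truth
from bluepolicy.rules import AllOf, AnyOf, Formula, Leaf


@pytest.fixture(scope="session")
def default_rules():
    """(conditions, rulesets) from the packaged default configuration."""
    return bp.load_rulesets(bp.default_rules_path())


def make_table(rows: dict[str, dict[str, float | None]]) -> bp.CountryIndicatorTable:
    """Build a table from {iso3: {indicator: value-or-None}}; unspecified
    indicators default to 0.0 (a valid in-bounds value for every kind)."""
    schema = bp.DEFAULT_SCHEMA
    data = {}
    for iso3, vals in rows.items():
        row = {ind: 0.0 for ind in schema.indicator_ids}
        for k, v in vals.items():
            row[k] = np.nan if v is None else v
        data[iso3] = row
    frame = pd.DataFrame.from_dict(data, orient="index")
    frame.index.name = "iso3"
    return bp.CountryIndicatorTable(data=frame, schema=schema)


@pytest.fixture
def ten_country_table() -> bp.CountryIndicatorTable:
    """Ten countries spanning all four classes for the B12 policy.

    Hand derivation against the default rules (highly: sev_b12 > 0.25
    AND (production > 10 OR imports > 10); relevant: sev_b12 > 0.10 AND
    same availability):

    C01 0.30/prod 20          -> highly
    C02 0.30/imports 20       -> highly (import arm of the OR)
    C03 0.15/prod 20          -> relevant (above base, not above strict)
    C04 0.25/prod 20          -> relevant (0.25 not > 0.25, strict)
    C05 0.05/prod 20          -> less (deficiency fails both tiers)
    C06 0.30/prod 5/imports 5 -> less (availability fails)
    C07 sev NA/prod 20        -> missing_data (decisive missing SEV)
    C08 0.30/prod NA/imports 5-> missing_data (availability undecidable)
    C09 0.30/prod NA/imports 20 -> highly (known import arm rescues)
    C10 0.05/prod NA          -> less (deficiency false makes AND false)
    """
    return make_table(
        {
            "C01": {"sev_b12": 0.30, "bf_production": 20.0},
            "C02": {"sev_b12": 0.30, "bf_imports": 20.0},
            "C03": {"sev_b12": 0.15, "bf_production": 20.0},
            "C04": {"sev_b12": 0.25, "bf_production": 20.0},
            "C05": {"sev_b12": 0.05, "bf_production": 20.0},
            "C06": {"sev_b12": 0.30, "bf_production": 5.0, "bf_imports": 5.0},
            "C07": {"sev_b12": None, "bf_production": 20.0},
            "C08": {"sev_b12": 0.30, "bf_production": None, "bf_imports": 5.0},
            "C09": {"sev_b12": 0.30, "bf_production": None, "bf_imports": 20.0},
            "C10": {"sev_b12": 0.05, "bf_production": None},
        }
    )


#: Expected B12 classes of the ten-country fixture (see docstring above).
TEN_COUNTRY_B12_CLASSES = {
    "C01": "highly_relevant",
    "C02": "highly_relevant",
    "C03": "relevant",
    "C04": "relevant",
    "C05": "less_relevant",
    "C06": "less_relevant",
    "C07": "missing_data",
    "C08": "missing_data",
    "C09": "highly_relevant",
    "C10": "less_relevant",
}


# ---------------------------------------------------------------------------
# Independent three-valued oracle: enumerate every completion of the
# MISSING slots with a plain two-valued evaluator.
# ---------------------------------------------------------------------------

def eval_two_valued(formula: Formula, assignment: dict[str, bool]) -> bool:
    if isinstance(formula, Leaf):
        return assignment[formula.condition_id]
    if isinstance(formula, AllOf):
        return all(eval_two_valued(c, assignment) for c in formula.children)
    if isinstance(formula, AnyOf):
        return any(eval_two_valued(c, assignment) for c in formula.children)
    raise TypeError(type(formula))


def oracle_evaluate(formula: Formula, memberships: dict[str, CrispMembership]) -> Truth:
    """Brute-force: TRUE iff every completion of the missing slots is
    true, FALSE iff every completion is false, UNKNOWN otherwise."""
    missing = sorted(c for c, m in memberships.items() if m is CrispMembership.MISSING)
    fixed = {c: (m is CrispMembership.IN) for c, m in memberships.items() if m is not CrispMembership.MISSING}
    outcomes = set()
    for combo in itertools.product([False, True], repeat=len(missing)):
        assignment = dict(fixed)
        assignment.update(zip(missing, combo))
        outcomes.add(eval_two_valued(formula, assignment))
    if outcomes == {True}:
        return Truth.TRUE
    if outcomes == {False}:
        return Truth.FALSE
    return Truth.UNKNOWN


def random_monotone_formula(rng: random.Random, condition_ids: list[str], depth: int = 0) -> Formula:
    """Random AND/OR tree over the given condition ids (no negation)."""
    if depth >= 3 or rng.random() < 0.4:
        return Leaf(rng.choice(condition_ids))
    node = AllOf if rng.random() < 0.5 else AnyOf
    k = rng.randint(2, 3)
    return node(tuple(random_monotone_formula(rng, condition_ids, depth + 1) for _ in range(k)))
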