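"""Crisp-set classification: binarization, three-valued evaluation,
relevance-class assignment.

Each country gets a binary membership (in/out) per condition — above or
below the pre-determined cutoff — with a third explicit MISSING state
when the underlying national value is absent. Solution formulae are
evaluated under strong Kleene three-valued logic: OR is true as soon as
one arm is true, AND is false as soon as one arm is false, and a
missing operand only yields UNKNOWN when it is genuinely decisive.
Because the formulae are monotone (AND/OR only), this is equivalent to
comparing the two extreme completions of the missing slots: true iff
still true with every missing set out, false iff still false with every
missing set in.

The four-class outcome per (country, policy):

* ``highly_relevant``  — the highly-relevant formula evaluates true;
* ``relevant``         — otherwise, the relevant formula evaluates true;
* ``less_relevant``    — both formulae evaluate false;
* ``missing_data``     — neither resolves true and at least one is
  undecidable because of missing values.

A satisfied OR arm thus rescues a country despite a missing co-variable:
one known-high blue-food source is enough to establish availability even
if the other is unrecorded.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DataError, InputError
from .rules import AllOf, AnyOf, Condition, Formula, Leaf, PolicyRuleSet, rules_digest
from .schema import CountryIndicatorTable

__all__ = [
    "CrispMembership",
    "Truth",
    "RelevanceClass",
    "RELEVANCE_CLASSES",
    "binarize",
    "evaluate_formula",
    "classify_country",
    "classify_all",
    "ClassificationResult",
]


class CrispMembership(Enum):
    IN = "in"
    OUT = "out"
    MISSING = "missing"


class Truth(Enum):
    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"


class RelevanceClass(str, Enum):
    HIGHLY_RELEVANT = "highly_relevant"
    RELEVANT = "relevant"
    LESS_RELEVANT = "less_relevant"
    MISSING_DATA = "missing_data"

    def __str__(self) -> str:  # pandas/CSV friendliness
        return self.value


#: Fixed reporting order of the four classes.
RELEVANCE_CLASSES: tuple[RelevanceClass, ...] = (
    RelevanceClass.HIGHLY_RELEVANT,
    RelevanceClass.RELEVANT,
    RelevanceClass.LESS_RELEVANT,
    RelevanceClass.MISSING_DATA,
)


def binarize(value: float | None, condition: Condition) -> CrispMembership:
    """Crisp membership of one value under one threshold condition.

    ``None`` marks a missing national value and maps to MISSING. A NaN
    or infinite float is rejected as a data error: by the table contract
    missingness is explicit, so a non-finite number reaching this point
    is a bug upstream, not an absent observation.
    """
    if value is None:
        return CrispMembership.MISSING
    value = float(value)
    if not math.isfinite(value):
        raise DataError(
            f"non-finite value {value!r} for condition {condition.condition_id!r}; "
            "missing values must be passed as None"
        )
    return CrispMembership.IN if condition.holds(value) else CrispMembership.OUT


def evaluate_formula(
    formula: Formula, memberships: Mapping[str, CrispMembership]
) -> Truth:
    """Strong Kleene evaluation of a monotone formula."""
    if isinstance(formula, Leaf):
        try:
            m = memberships[formula.condition_id]
        except KeyError:
            raise ConfigurationError(
                f"no membership for condition {formula.condition_id!r}"
            ) from None
        if m is CrispMembership.IN:
            return Truth.TRUE
        if m is CrispMembership.OUT:
            return Truth.FALSE
        return Truth.UNKNOWN
    if isinstance(formula, AnyOf):
        results = [evaluate_formula(c, memberships) for c in formula.children]
        if Truth.TRUE in results:
            return Truth.TRUE
        if all(r is Truth.FALSE for r in results):
            return Truth.FALSE
        return Truth.UNKNOWN
    if isinstance(formula, AllOf):
        results = [evaluate_formula(c, memberships) for c in formula.children]
        if Truth.FALSE in results:
            return Truth.FALSE
        if all(r is Truth.TRUE for r in results):
            return Truth.TRUE
        return Truth.UNKNOWN
    raise ConfigurationError(f"unknown formula node type: {type(formula).__name__}")


def _memberships_for(
    row: Mapping[str, float | None],
    condition_ids: Iterable[str],
    conditions: Mapping[str, Condition],
) -> dict[str, CrispMembership]:
    out: dict[str, CrispMembership] = {}
    for cid in condition_ids:
        try:
            cond = conditions[cid]
        except KeyError:
            raise ConfigurationError(f"condition {cid!r} not in the condition pool") from None
        out[cid] = binarize(row.get(cond.indicator_id), cond)
    return out


def classify_country(
    row: Mapping[str, float | None],
    ruleset: PolicyRuleSet,
    conditions: Mapping[str, Condition],
) -> RelevanceClass:
    """Assign one country to a relevance class for one policy.

    ``row`` maps indicator ids to values, with ``None`` for missing.
    """
    memberships = _memberships_for(row, ruleset.condition_ids(), conditions)
    hi = evaluate_formula(ruleset.highly_relevant, memberships)
    if hi is Truth.TRUE:
        return RelevanceClass.HIGHLY_RELEVANT
    lo = evaluate_formula(ruleset.relevant, memberships)
    if lo is Truth.TRUE:
        return RelevanceClass.RELEVANT
    if hi is Truth.FALSE and lo is Truth.FALSE:
        return RelevanceClass.LESS_RELEVANT
    return RelevanceClass.MISSING_DATA


@dataclass
class ClassificationResult:
    """Country x policy relevance classes plus run provenance.

    ``classes`` is indexed by iso3 (ascending) with one column per
    policy id holding the class value strings.
    """

    classes: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def policies(self) -> list[str]:
        return list(self.classes.columns)

    @property
    def n_countries(self) -> int:
        return len(self.classes)

    def country_class(self, iso3: str, policy_id: str) -> RelevanceClass:
        return RelevanceClass(self.classes.at[iso3, policy_id])

    def counts(self) -> pd.DataFrame:
        """Per-policy country counts over the four classes.

        The four counts partition the country set: they sum to the
        number of countries for every policy.
        """
        order = [c.value for c in RELEVANCE_CLASSES]
        out = pd.DataFrame(
            {p: self.classes[p].value_counts().reindex(order, fill_value=0) for p in self.policies}
        ).T
        out.index.name = "policy_id"
        out.columns.name = None
        return out.astype(int)

    def to_long_frame(self) -> pd.DataFrame:
        """Long (iso3, policy_id, relevance_class) frame, sorted by iso3
        then by configured policy order."""
        rows = [
            (iso3, p, self.classes.at[iso3, p])
            for iso3 in self.classes.index
            for p in self.policies
        ]
        return pd.DataFrame(rows, columns=["iso3", "policy_id", "relevance_class"])

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame, metadata: dict | None = None) -> "ClassificationResult":
        required = {"iso3", "policy_id", "relevance_class"}
        if not required.issubset(frame.columns):
            raise InputError(f"classification frame needs columns {sorted(required)}")
        valid = {c.value for c in RELEVANCE_CLASSES}
        bad = sorted(set(frame["relevance_class"]) - valid)
        if bad:
            raise InputError(f"unknown relevance class value(s): {bad}")
        wide = frame.pivot(index="iso3", columns="policy_id", values="relevance_class")
        if wide.isna().any().any():
            raise InputError("classification frame is not a full country x policy grid")
        # preserve first-appearance policy order from the long frame
        order = list(dict.fromkeys(frame["policy_id"]))
        wide = wide[order].sort_index()
        wide.columns.name = None
        return cls(classes=wide, metadata=metadata or {})


def classify_all(
    table: CountryIndicatorTable,
    rulesets: Sequence[PolicyRuleSet],
    conditions: Mapping[str, Condition],
) -> ClassificationResult:
    """Classify every country against every policy.

    Deterministic and order-invariant: permuting the input rows yields an
    identical result (the output index is sorted ascending by iso3).
    """
    if table.n_countries == 0:
        raise InputError("empty indicator table: nothing to classify")
    if not rulesets:
        raise ConfigurationError("no policy rule sets given")
    data: dict[str, list[str]] = {rs.policy_id: [] for rs in rulesets}
    index = sorted(table.iso3)
    for iso3 in index:
        row = table.row_values(iso3)
        for rs in rulesets:
            data[rs.policy_id].append(classify_country(row, rs, conditions).value)
    classes = pd.DataFrame(data, index=pd.Index(index, name="iso3"))
    result = ClassificationResult(
        classes=classes,
        metadata={
            "rules_digest": rules_digest(conditions, rulesets),
            "n_countries": len(index),
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
    )
    counts = result.counts()
    assert (counts.sum(axis=1) == len(index)).all(), "class counts must partition countries"
    return result
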