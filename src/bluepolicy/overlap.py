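"""Pairwise policy-overlap counts and proportions.

For the overlap analysis the two relevance tiers are combined: a country
counts as *relevant* for a policy when its class is highly relevant or
relevant. Each matrix cell (row, col) reports the number of countries
relevant for both policies as a proportion of the countries relevant for
the column policy, after excluding from the pair any country with
missing data for either policy. Counts are symmetric in (row, col);
proportions are not, because the denominator is the column policy's
relevant set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassificationResult, RelevanceClass
from .errors import InputError

__all__ = ["OverlapMatrix", "combined_relevant_set", "overlap_matrix", "percent_display"]

_RELEVANT = {RelevanceClass.HIGHLY_RELEVANT.value, RelevanceClass.RELEVANT.value}
_MISSING = RelevanceClass.MISSING_DATA.value


def combined_relevant_set(result: ClassificationResult, policy_id: str) -> set[str]:
    """Countries classed highly relevant or relevant for a policy."""
    if policy_id not in result.classes.columns:
        raise LookupError(f"policy {policy_id!r} not in classification result")
    col = result.classes[policy_id]
    return set(col.index[col.isin(_RELEVANT)])


def percent_display(proportion: float) -> int:
    """Integer percent, round half up (0.755 -> 76)."""
    return int(math.floor(100.0 * proportion + 0.5))


@dataclass
class OverlapMatrix:
    """Pairwise overlap summary.

    ``long`` has one row per ordered (row_policy, col_policy) pair with
    columns count, eligible_denominator, proportion and percent_display;
    proportion and percent_display are NA when the denominator is zero.
    ``relevant_totals`` are the unfiltered combined-relevant counts per
    policy (the parenthesized totals of the matrix header row).
    """

    policies: list[str]
    relevant_totals: dict[str, int]
    long: pd.DataFrame

    def cell(self, row_policy: str, col_policy: str) -> pd.Series:
        sub = self.long[
            (self.long["row_policy"] == row_policy) & (self.long["col_policy"] == col_policy)
        ]
        if sub.empty:
            raise LookupError(f"no cell ({row_policy!r}, {col_policy!r})")
        return sub.iloc[0]

    def matrix_frame(self) -> pd.DataFrame:
        """Square percent-display matrix (rows x columns of policies)."""
        out = pd.DataFrame(index=self.policies, columns=self.policies, dtype="object")
        for _, r in self.long.iterrows():
            out.at[r["row_policy"], r["col_policy"]] = (
                "NA" if pd.isna(r["percent_display"]) else int(r["percent_display"])
            )
        out.index.name = "row_policy"
        return out


def overlap_matrix(result: ClassificationResult) -> OverlapMatrix:
    """Compute the full pairwise overlap matrix from a classification.

    For each ordered pair, countries classed missing-data for either
    policy are excluded before counting; the proportion divides the
    both-relevant count by the column policy's relevant count among the
    eligible countries. With no missing data the denominator equals the
    column policy's total relevant count.
    """
    policies = result.policies
    if len(policies) < 2:
        raise InputError("overlap analysis needs at least two classified policies")
    relevant = {p: combined_relevant_set(result, p) for p in policies}
    missing = {
        p: set(result.classes.index[result.classes[p] == _MISSING]) for p in policies
    }
    totals = {p: len(relevant[p]) for p in policies}
    rows = []
    for row_p in policies:
        for col_p in policies:
            excluded = missing[row_p] | missing[col_p]
            col_relevant_eligible = relevant[col_p] - excluded
            # relevant countries are never missing for their own policy,
            # so the intersection needs no further filtering
            count = len(relevant[row_p] & relevant[col_p])
            denom = len(col_relevant_eligible)
            proportion = count / denom if denom else np.nan
            rows.append(
                (
                    row_p,
                    col_p,
                    count,
                    denom,
                    proportion,
                    percent_display(proportion) if denom else np.nan,
                )
            )
    long = pd.DataFrame(
        rows,
        columns=[
            "row_policy",
            "col_policy",
            "count",
            "eligible_denominator",
            "proportion",
            "percent_display",
        ],
    )
    return OverlapMatrix(policies=list(policies), relevant_totals=totals, long=long)
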