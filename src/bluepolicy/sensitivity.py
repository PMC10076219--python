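"""One-at-a-time threshold sensitivity analysis.

The classification is re-run with a single condition's cutoff replaced
by each value of a trial grid, leaving every other condition and all
formulae untouched, and the per-class country counts are recorded at
each grid point. The grid spans the full observed range of the scanned
indicator and additionally contains every observed unique value, so
every possible count transition is captured exactly — counts can only
change when the cutoff crosses an observed value.

For a greater-direction condition the combined relevant count
(highly relevant + relevant) of any policy using it is non-increasing
in the trial cutoff, a direct consequence of formula monotonicity.
Policies that never reference the scanned condition have constant
curves by construction ("leaving all else constant").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import RELEVANCE_CLASSES, classify_all
from .errors import ConfigurationError, InputError
from .rules import Condition, PolicyRuleSet
from .schema import CountryIndicatorTable

__all__ = ["SensitivityCurve", "build_grid", "oat_scan"]


@dataclass
class SensitivityCurve:
    """Class counts per policy along a cutoff grid for one condition.

    ``counts`` is long format with columns
    (condition_id, trial_cutoff, policy_id, relevance_class, n_countries);
    at every grid point the four class counts of each policy sum to the
    number of countries.
    """

    condition_id: str
    baseline_cutoff: float
    grid: np.ndarray
    counts: pd.DataFrame
    trajectories: pd.DataFrame | None = None

    def counts_at(self, trial_cutoff: float) -> pd.DataFrame:
        """Policy x class count table at one grid point."""
        sub = self.counts[np.isclose(self.counts["trial_cutoff"], trial_cutoff)]
        if sub.empty:
            raise KeyError(f"cutoff {trial_cutoff!r} not on the grid")
        out = sub.pivot(index="policy_id", columns="relevance_class", values="n_countries")
        return out[[c.value for c in RELEVANCE_CLASSES]]

    def baseline_counts(self) -> pd.DataFrame:
        """Counts at the configured (unperturbed) cutoff."""
        return self.counts_at(self.baseline_cutoff)


def build_grid(
    table: CountryIndicatorTable,
    condition: Condition,
    n_points: int = 101,
) -> np.ndarray:
    """Trial-cutoff grid spanning the full observed range of an indicator.

    Union of ``n_points`` equally spaced values over [min, max] of the
    observed (non-missing) values and all observed unique values, sorted
    ascending and de-duplicated. A constant indicator gives a
    single-point grid with a degenerate-scan warning.
    """
    if condition.indicator_id not in table.data.columns:
        raise InputError(f"indicator {condition.indicator_id!r} not in table")
    observed = table.data[condition.indicator_id].dropna().to_numpy(dtype=float)
    if observed.size == 0:
        raise InputError(
            f"indicator {condition.indicator_id!r} is entirely missing; cannot build a scan grid"
        )
    if n_points < 1:
        raise InputError("n_points must be >= 1")
    lo, hi = float(observed.min()), float(observed.max())
    if lo == hi:
        warnings.warn(
            f"indicator {condition.indicator_id!r} is constant at {lo:g}; sensitivity scan is degenerate"
        )
        return np.array([lo])
    spaced = np.linspace(lo, hi, n_points) if n_points > 1 else np.array([lo])
    return np.unique(np.concatenate([spaced, np.unique(observed)]))


def oat_scan(
    table: CountryIndicatorTable,
    rulesets: Sequence[PolicyRuleSet],
    conditions: Mapping[str, Condition],
    condition_id: str,
    grid: np.ndarray | Sequence[float],
    keep_trajectories: bool = False,
) -> SensitivityCurve:
    """Scan one condition's cutoff over a grid, re-classifying at each point.

    Counts (not country identities) are recorded per class per policy;
    pass ``keep_trajectories=True`` to additionally keep the per-country
    class at every grid point for debugging.
    """
    if condition_id not in conditions:
        raise ConfigurationError(f"condition {condition_id!r} not declared")
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise InputError("empty scan grid")
    base = conditions[condition_id]
    # the configured cutoff is always scanned, so the curve carries an
    # exact baseline point equal to the unperturbed classification
    grid = np.unique(np.append(grid, base.cutoff))
    if not any(condition_id in rs.condition_ids() for rs in rulesets):
        warnings.warn(
            f"condition {condition_id!r} is not referenced by any policy; curve will be flat"
        )
    rows = []
    trajs = {}
    for cutoff in grid:
        trial = dict(conditions)
        trial[condition_id] = base.with_cutoff(float(cutoff))
        result = classify_all(table, rulesets, trial)
        counts = result.counts()
        for policy_id in counts.index:
            for cls in RELEVANCE_CLASSES:
                rows.append(
                    (condition_id, float(cutoff), policy_id, cls.value, int(counts.at[policy_id, cls.value]))
                )
        if keep_trajectories:
            trajs[float(cutoff)] = result.classes
    counts_frame = pd.DataFrame(
        rows,
        columns=["condition_id", "trial_cutoff", "policy_id", "relevance_class", "n_countries"],
    )
    trajectories = None
    if keep_trajectories:
        trajectories = pd.concat(trajs, names=["trial_cutoff", "iso3"])
    return SensitivityCurve(
        condition_id=condition_id,
        baseline_cutoff=base.cutoff,
        grid=grid,
        counts=counts_frame,
        trajectories=trajectories,
    )


def plot_curve(curve: SensitivityCurve, policy_id: str, ax=None):
    """Count-versus-cutoff line plot for one policy (one line per class)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = curve.counts[curve.counts["policy_id"] == policy_id]
    for cls in RELEVANCE_CLASSES:
        line = sub[sub["relevance_class"] == cls.value]
        ax.plot(line["trial_cutoff"], line["n_countries"], label=cls.value, drawstyle="steps-post")
    ax.axvline(curve.baseline_cutoff, color="k", ls=":", lw=1, label="baseline cutoff")
    ax.set_xlabel(f"trial cutoff ({curve.condition_id})")
    ax.set_ylabel("countries")
    ax.set_title(policy_id)
    ax.legend(fontsize=8)
    return ax
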