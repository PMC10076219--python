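"""Synthetic country-indicator tables.

Two generation modes:

* :func:`generate_table` draws a table from configurable marginal
  families (beta for bounded shares, lognormal for skewed intake rates,
  uniform for scores, bernoulli for flags) coupled through a Gaussian
  copula so that a target Spearman rank-correlation matrix is honoured
  while the marginals are preserved exactly. Missingness is applied
  completely at random, per indicator, after value generation.

* :func:`plant_classifications` works backwards from a rule set: it
  constructs indicator rows inside the value regions that force each
  requested relevance class (including decisive missing cells for the
  missing-data class), so classification recovers the requested class
  counts exactly. This closes the loop for end-to-end testing.

Synthetic rows are keyed ``SY001, SY002, ...`` — a reserved shape that
cannot collide with real ISO3 codes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import RELEVANCE_CLASSES, RelevanceClass, classify_country
from .errors import ConfigurationError, ConstructionError
from .rules import Condition, PolicyRuleSet
from .schema import DEFAULT_SCHEMA, CountryIndicatorTable, IndicatorSchema

__all__ = [
    "MarginalSpec",
    "GeneratorConfig",
    "PlantSpec",
    "generate_table",
    "plant_classifications",
    "emulate_study_shape",
    "study_shape_config",
]

_FAMILIES = ("beta", "lognormal", "uniform", "bernoulli")


@dataclass(frozen=True)
class MarginalSpec:
    """One indicator's marginal distribution.

    Parameter meaning by family: ``beta(a, b)``; ``lognormal(mu, sigma)``
    on the log scale; ``uniform(low, high)``; ``bernoulli(p)``.
    An optional ``scale`` multiplies the draw (used to put lognormal
    intake rates on their natural units).
    """

    family: str
    params: tuple[float, ...]
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"unknown marginal family {self.family!r}")
        n_expected = {"beta": 2, "lognormal": 2, "uniform": 2, "bernoulli": 1}[self.family]
        if len(self.params) != n_expected:
            raise ConfigurationError(
                f"{self.family} marginal takes {n_expected} parameter(s), got {len(self.params)}"
            )

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Inverse CDF applied to copula uniforms."""
        if self.family == "beta":
            x = stats.beta.ppf(u, *self.params)
        elif self.family == "lognormal":
            mu, sigma = self.params
            x = stats.lognorm.ppf(u, s=sigma, scale=np.exp(mu))
        elif self.family == "uniform":
            lo, hi = self.params
            x = stats.uniform.ppf(u, loc=lo, scale=hi - lo)
        else:  # bernoulli
            x = (u > 1.0 - self.params[0]).astype(float)
        return x * self.scale

    def moments(self) -> tuple[float, float]:
        """Theoretical (mean, variance) on the output scale."""
        if self.family == "beta":
            m, v = stats.beta.stats(*self.params, moments="mv")
        elif self.family == "lognormal":
            mu, sigma = self.params
            m, v = stats.lognorm.stats(s=sigma, scale=np.exp(mu), moments="mv")
        elif self.family == "uniform":
            lo, hi = self.params
            m, v = stats.uniform.stats(loc=lo, scale=hi - lo, moments="mv")
        else:
            p = self.params[0]
            m, v = p, p * (1 - p)
        return float(m) * self.scale, float(v) * self.scale**2


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic table draw."""

    n_countries: int
    seed: int
    marginals: dict[str, MarginalSpec]
    dependence: pd.DataFrame | None = None  # Spearman rank correlations
    missing_rate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ConfigurationError("n_countries must be >= 1")
        for ind, rate in self.missing_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"missing rate for {ind!r} must be in [0,1], got {rate}")
        if self.dependence is not None:
            dep = self.dependence
            ids = list(self.marginals)
            if list(dep.index) != ids or list(dep.columns) != ids:
                dep = dep.reindex(index=ids, columns=ids).fillna(0.0)
                np.fill_diagonal(dep.values, 1.0)
            m = dep.to_numpy(dtype=float)
            if not np.allclose(m, m.T, atol=1e-12):
                raise ConfigurationError("dependence matrix must be symmetric")
            if not np.allclose(np.diag(m), 1.0):
                raise ConfigurationError("dependence matrix must have unit diagonal")
            if np.min(np.linalg.eigvalsh(m)) < -1e-10:
                raise ConfigurationError("dependence matrix is not positive semi-definite")
            self.dependence = pd.DataFrame(m, index=ids, columns=ids)


def _synth_keys(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"SY{i:0{width}d}" for i in range(1, n + 1)]


def generate_table(
    config: GeneratorConfig,
    schema: IndicatorSchema = DEFAULT_SCHEMA,
) -> CountryIndicatorTable:
    """Draw a synthetic table per the configuration.

    Gaussian-copula coupling: the configured Spearman correlations are
    converted to latent normal correlations via r = 2 sin(pi rho / 6),
    a latent multivariate normal is drawn, mapped to uniforms, and each
    uniform margin is pushed through its family's inverse CDF — so
    marginals hold exactly and rank dependence matches the target.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ids = list(config.marginals)
    k = len(ids)
    if config.dependence is not None:
        rho = config.dependence.to_numpy(dtype=float)
        latent = 2.0 * np.sin(np.pi * rho / 6.0)
        # conversion can nudge eigenvalues slightly negative; clip and renormalize
        w, v = np.linalg.eigh(latent)
        if w.min() < -1e-10:
            raise ConfigurationError("dependence matrix inadmissible after latent conversion")
        w = np.clip(w, 1e-12, None)
        latent = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(latent))
        latent = latent / np.outer(d, d)
        chol = np.linalg.cholesky(latent)
        z = rng.standard_normal((config.n_countries, k)) @ chol.T
    else:
        z = rng.standard_normal((config.n_countries, k))
    u = stats.norm.cdf(z)
    data = {}
    for j, ind in enumerate(ids):
        data[ind] = config.marginals[ind].ppf(u[:, j])
    frame = pd.DataFrame(data, index=pd.Index(_synth_keys(config.n_countries), name="iso3"))
    for ind in ids:
        rate = config.missing_rate.get(ind, 0.0)
        if rate > 0.0:
            mask = rng.random(config.n_countries) < rate
            frame.loc[mask, ind] = np.nan
    return CountryIndicatorTable(data=frame, schema=schema, provenance={i: "synthetic" for i in ids})


@dataclass(frozen=True)
class PlantSpec:
    """Requested class counts for one policy; counts sum to the table size."""

    policy_id: str
    target_counts: Mapping[RelevanceClass, int]

    def __post_init__(self) -> None:
        for cls, n in self.target_counts.items():
            if n < 0:
                raise ConfigurationError(f"negative target count for {cls}")

    @property
    def n_countries(self) -> int:
        return sum(self.target_counts.values())


def _candidate_values(
    indicator_id: str,
    conditions: Sequence[Condition],
    schema: IndicatorSchema,
) -> list[float | None]:
    """Representative values covering every cutoff-delimited region of an
    indicator, plus an explicit missing candidate."""
    lo, hi = (0.0, np.inf)
    if indicator_id in schema:
        lo, hi = schema[indicator_id].bounds  # type: ignore[misc]
    cuts = sorted({c.cutoff for c in conditions if c.indicator_id == indicator_id})
    edges = [lo] + [c for c in cuts if lo < c < hi] + [hi if np.isfinite(hi) else (max(cuts, default=0.0) * 2 + 1.0)]
    values: list[float | None] = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b > a:
            values.append((a + b) / 2.0)
    values.extend(c for c in cuts if lo <= c <= (hi if np.isfinite(hi) else np.inf))
    values.append(None)
    # dedupe, preserving order
    seen: set = set()
    out: list[float | None] = []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def plant_classifications(
    spec: PlantSpec,
    ruleset: PolicyRuleSet,
    conditions: Mapping[str, Condition],
    seed: int = 0,
    schema: IndicatorSchema = DEFAULT_SCHEMA,
) -> CountryIndicatorTable:
    """Construct a table whose classification recovers the target counts.

    For each requested class, the relevant indicators are assigned
    values from representative points of every cutoff-delimited region
    (and explicit missing), searched exhaustively until the classifier
    confirms the class; the winning assignment is replicated to the
    requested count. Indicators unused by the policy are set to the
    lower bound of their admissible range.

    Raises
    ------
    ConstructionError
        If some requested class is unreachable under the rule set.
    """
    if spec.policy_id != ruleset.policy_id:
        raise ConfigurationError(
            f"plant spec targets {spec.policy_id!r} but rule set is {ruleset.policy_id!r}"
        )
    used_conditions = [conditions[cid] for cid in sorted(ruleset.condition_ids())]
    indicator_ids = sorted({c.indicator_id for c in used_conditions})
    candidates = {
        ind: _candidate_values(ind, used_conditions, schema) for ind in indicator_ids
    }
    # deterministic exhaustive search for one representative row per class
    representatives: dict[RelevanceClass, dict[str, float | None]] = {}
    wanted = {cls for cls, n in spec.target_counts.items() if n > 0}
    for combo in itertools.product(*(candidates[i] for i in indicator_ids)):
        if representatives.keys() >= wanted:
            break
        row = dict(zip(indicator_ids, combo))
        cls = classify_country(row, ruleset, conditions)
        if cls in wanted and cls not in representatives:
            representatives[cls] = row
    unreachable = sorted((wanted - representatives.keys()), key=lambda c: c.value)
    if unreachable:
        raise ConstructionError(
            f"no indicator assignment yields class(es) {[c.value for c in unreachable]} "
            f"for policy {ruleset.policy_id!r}"
        )

    rng = np.random.default_rng(seed)
    n = spec.n_countries
    classes: list[RelevanceClass] = []
    for cls in RELEVANCE_CLASSES:
        classes.extend([cls] * spec.target_counts.get(cls, 0))
    rng.shuffle(classes)  # class order across rows is randomized; counts are exact

    rows = []
    for cls in classes:
        rep = representatives[cls]
        row = {}
        for ind in schema.indicator_ids:
            if ind in rep:
                row[ind] = np.nan if rep[ind] is None else rep[ind]
            else:
                lo, _ = schema[ind].bounds  # type: ignore[misc]
                row[ind] = lo
        rows.append(row)
    frame = pd.DataFrame(rows, index=pd.Index(_synth_keys(n), name="iso3"))
    return CountryIndicatorTable(data=frame, schema=schema, provenance={"*": "planted"})


def study_shape_config(seed: int, n_countries: int = 190) -> GeneratorConfig:
    """Generator configuration emulating the shape of the study's table.

    ~190 countries; nutrient summary exposure values beta-distributed
    with strong positive rank correlation between the B12 and omega-3
    deficiencies; intake rates and disease burden lognormal (right
    skewed); climate hazard uniform on [0,1]; 5% missingness per
    indicator, completely at random.
    """
    marginals = {
        "sev_b12": MarginalSpec("beta", (1.3, 4.5)),
        "sev_omega3": MarginalSpec("beta", (1.8, 2.4)),
        "red_meat_intake": MarginalSpec("lognormal", (3.2, 0.7)),
        "ruminant_meat_intake": MarginalSpec("lognormal", (2.5, 0.8)),
        "cvd_burden": MarginalSpec("lognormal", (8.0, 0.5)),
        "bf_production": MarginalSpec("lognormal", (2.2, 1.1)),
        "bf_imports": MarginalSpec("lognormal", (2.0, 0.9)),
        "bf_employment_share": MarginalSpec("beta", (1.0, 20.0)),
        "bf_export_share": MarginalSpec("beta", (1.0, 15.0)),
        "bf_nutrition_share": MarginalSpec("beta", (1.5, 8.0)),
        "climate_hazard": MarginalSpec("uniform", (0.0, 1.0)),
    }
    ids = list(marginals)
    dep = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)

    def set_rho(a: str, b: str, rho: float) -> None:
        dep.at[a, b] = rho
        dep.at[b, a] = rho

    set_rho("sev_b12", "sev_omega3", 0.7)       # correlated deficiencies
    set_rho("red_meat_intake", "ruminant_meat_intake", 0.6)
    set_rho("red_meat_intake", "cvd_burden", 0.3)
    set_rho("bf_production", "bf_export_share", 0.4)
    set_rho("bf_employment_share", "bf_nutrition_share", 0.4)
    return GeneratorConfig(
        n_countries=n_countries,
        seed=seed,
        marginals=marginals,
        dependence=dep,
        missing_rate={i: 0.05 for i in ids},
    )


def emulate_study_shape(seed: int, n_countries: int = 190) -> CountryIndicatorTable:
    """Convenience preset: one draw from :func:`study_shape_config`."""
    return generate_table(study_shape_config(seed, n_countries))
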