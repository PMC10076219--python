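"""Country-by-indicator table: schema, ingest, validation, harmonization.

The analysis consumes one wide table — one row per country keyed by an
ISO 3166-1 alpha-3 code, one column per national-average indicator.
Missingness is an explicit state (empty cell or ``NA`` in CSV, ``NaN``
in memory) and is never conflated with zero: a zero blue-food import
share is information, an empty cell is not.

Shares are stored on the unit interval (0.10, not 10); rates are
non-negative quantities in their stated units (typically g per person
per day or kg per person per year); scores are bounded continuous
values, by default on [0, 1].
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import HarmonizationError, InputError, SchemaError

__all__ = [
    "IndicatorSpec",
    "IndicatorSchema",
    "CountryIndicatorTable",
    "ValidationReport",
    "DEFAULT_SCHEMA",
    "load_indicator_table",
    "write_indicator_table",
    "validate_table",
    "harmonize_country_codes",
]

_VALUE_KINDS = ("share", "rate", "score", "flag")
_ISO3_RE = re.compile(r"^[A-Z]{3}$")
# Synthetic keys use a reserved SYnnn... format that cannot collide with
# real ISO3 codes (real codes are exactly three letters).
_SYNTH_RE = re.compile(r"^SY\d{3,}$")


@dataclass(frozen=True)
class IndicatorSpec:
    """Declaration of one indicator column.

    Parameters
    ----------
    indicator_id
        Stable lower_snake_case column name, the join key across data,
        rule config and outputs.
    value_kind
        One of ``share`` (unit interval), ``rate`` (non-negative with
        stated units), ``score`` (bounded continuous), ``flag`` (0/1).
    bounds
        Closed admissible interval. Derived from the kind when omitted:
        shares and scores get [0, 1], rates [0, inf), flags {0, 1}.
    """

    indicator_id: str
    description: str = ""
    value_kind: str = "rate"
    units: str = ""
    required_by: tuple[str, ...] = ()
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.value_kind not in _VALUE_KINDS:
            raise SchemaError(
                f"indicator {self.indicator_id!r}: value_kind {self.value_kind!r} "
                f"not one of {_VALUE_KINDS}"
            )
        if self.bounds is None:
            lo, hi = {
                "share": (0.0, 1.0),
                "score": (0.0, 1.0),
                "flag": (0.0, 1.0),
                "rate": (0.0, np.inf),
            }[self.value_kind]
            object.__setattr__(self, "bounds", (lo, hi))

    def in_bounds(self, value: float) -> bool:
        lo, hi = self.bounds  # type: ignore[misc]
        return lo <= value <= hi


class IndicatorSchema:
    """Ordered collection of :class:`IndicatorSpec` with unique ids."""

    def __init__(self, indicators: Iterable[IndicatorSpec]):
        self._specs: dict[str, IndicatorSpec] = {}
        for spec in indicators:
            if spec.indicator_id in self._specs:
                raise SchemaError(f"duplicate indicator_id {spec.indicator_id!r}")
            self._specs[spec.indicator_id] = spec

    @property
    def indicator_ids(self) -> list[str]:
        return list(self._specs)

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self._specs

    def __getitem__(self, indicator_id: str) -> IndicatorSpec:
        return self._specs[indicator_id]

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)


#: Canonical indicator set behind the four policy objectives: nutrient
#: summary exposure values (share of the population at risk of inadequate
#: intake), terrestrial meat intakes, cardiovascular disease burden,
#: blue-food availability and dependence, and climate hazard.
DEFAULT_SCHEMA = IndicatorSchema(
    [
        IndicatorSpec("sev_b12", "Summary exposure value, vitamin B12: share of population at risk of inadequate intake", "share"),
        IndicatorSpec("sev_omega3", "Summary exposure value, omega-3 (DHA+EPA): share of population at risk of inadequate intake", "share"),
        IndicatorSpec("red_meat_intake", "National average red meat intake", "rate", units="g/person/day"),
        IndicatorSpec("ruminant_meat_intake", "National average ruminant meat intake", "rate", units="g/person/day"),
        IndicatorSpec("cvd_burden", "Cardiovascular disease burden", "rate", units="DALYs per 100,000"),
        IndicatorSpec("bf_production", "Blue food domestic production", "rate", units="kg/person/year"),
        IndicatorSpec("bf_imports", "Blue food imports", "rate", units="kg/person/year"),
        IndicatorSpec("bf_employment_share", "Blue food share of national employment", "share"),
        IndicatorSpec("bf_export_share", "Blue food share of export revenue", "share"),
        IndicatorSpec("bf_nutrition_share", "Blue food share of animal-source nutrient supply", "share"),
        IndicatorSpec("climate_hazard", "Aggregate climate hazard score for the aquatic food system", "score"),
    ]
)


@dataclass
class CountryIndicatorTable:
    """Wide country x indicator table with explicit missingness.

    ``data`` is indexed by iso3 (ascending, unique, uppercase); indicator
    columns are float64 with ``NaN`` marking missing. An optional
    ``country_name`` column is carried through untouched.
    """

    data: pd.DataFrame
    schema: IndicatorSchema = field(default_factory=lambda: DEFAULT_SCHEMA)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise SchemaError(f"duplicate iso3 keys: {dups}")
        self.data = self.data.sort_index()
        self.data.index.name = "iso3"

    @property
    def n_countries(self) -> int:
        return len(self.data)

    @property
    def iso3(self) -> list[str]:
        return list(self.data.index)

    @property
    def indicator_columns(self) -> list[str]:
        return [c for c in self.data.columns if c in self.schema]

    def value(self, iso3: str, indicator_id: str) -> float | None:
        """Cell value, with ``None`` (not NaN) for missing."""
        v = self.data.at[iso3, indicator_id]
        return None if pd.isna(v) else float(v)

    def row_values(self, iso3: str) -> dict[str, float | None]:
        row = self.data.loc[iso3]
        return {
            c: (None if pd.isna(row[c]) else float(row[c]))
            for c in self.indicator_columns
        }


@dataclass
class ValidationReport:
    errors: list[tuple[str, str, str]]
    warnings: list[tuple[str, str, str]]
    n_countries: int
    missingness: dict[str, float]

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, c, "error", m) for i, c, m in self.errors]
        rows += [(i, c, "warning", m) for i, c, m in self.warnings]
        return pd.DataFrame(rows, columns=["iso3", "indicator", "severity", "message"])

    def __str__(self) -> str:
        lines = [f"{self.n_countries} countries; {len(self.errors)} errors, {len(self.warnings)} warnings"]
        for iso3, col, msg in self.errors:
            lines.append(f"  ERROR   {iso3} {col}: {msg}")
        for iso3, col, msg in self.warnings:
            lines.append(f"  warning {iso3} {col}: {msg}")
        return "\n".join(lines)


_MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none", "."}


def _parse_cell(raw: object) -> tuple[float, bool, bool]:
    """Return (value, is_missing, parse_failed) for one raw CSV cell."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan, True, False
    text = str(raw).strip()
    if text.lower() in _MISSING_TOKENS:
        return np.nan, True, False
    try:
        return float(text), False, False
    except ValueError:
        return np.nan, True, True


def load_indicator_table(
    path: str | Path,
    schema: IndicatorSchema = DEFAULT_SCHEMA,
) -> CountryIndicatorTable:
    """Read a country-indicator CSV into a :class:`CountryIndicatorTable`.

    Accepts the wide dialect (one row per country, one column per
    indicator) or the long dialect with exactly the columns
    ``iso3, indicator, value``, which is pivoted to wide. Empty cells and
    ``NA`` parse to missing; unparseable cells become missing with a
    warning naming the cell. Indicators declared in the schema but absent
    from the file are added as all-missing columns. Row order is
    normalized to ascending iso3.

    Raises
    ------
    InputError
        File absent or unreadable.
    SchemaError
        No iso3 column, or duplicate iso3 keys.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"indicator file not found: {path}")
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - delegated to pandas
        raise InputError(f"could not read {path}: {exc}") from exc

    if set(raw.columns) == {"iso3", "indicator", "value"}:
        raw = (
            raw.pivot(index="iso3", columns="indicator", values="value")
            .reset_index()
            .rename_axis(columns=None)
        )
    if "iso3" not in raw.columns:
        raise SchemaError(f"{path}: no 'iso3' column (columns: {list(raw.columns)})")

    keys = raw["iso3"].astype(str).str.strip().str.upper()
    dup = sorted(keys[keys.duplicated()].unique())
    if dup:
        raise SchemaError(f"{path}: duplicate iso3 keys: {dup}")

    columns: dict[str, object] = {}
    if "country_name" in raw.columns:
        columns["country_name"] = raw["country_name"].astype(str).values
    for ind in schema.indicator_ids:
        if ind not in raw.columns:
            warnings.warn(f"indicator column {ind!r} absent; added as all-missing")
            columns[ind] = np.full(len(raw), np.nan)
            continue
        parsed = np.empty(len(raw))
        for i, (iso3, cell) in enumerate(zip(keys, raw[ind])):
            value, is_missing, failed = _parse_cell(cell)
            parsed[i] = value
            if failed:
                warnings.warn(
                    f"unparseable cell ({iso3}, {ind}): {cell!r} treated as missing"
                )
        columns[ind] = parsed
    extra = [c for c in raw.columns if c not in schema and c not in ("iso3", "country_name")]
    if extra:
        warnings.warn(f"ignoring columns not in schema: {extra}")

    data = pd.DataFrame(columns, index=pd.Index(keys, name="iso3"))
    return CountryIndicatorTable(data=data, schema=schema)


def write_indicator_table(table: CountryIndicatorTable, path: str | Path) -> None:
    """Write the wide CSV dialect (missing as empty cells, LF endings)."""
    out = table.data.copy().sort_index()
    cols = ([c] if (c := "country_name") in out.columns else []) + [
        i for i in table.schema.indicator_ids if i in out.columns
    ]
    out[cols].to_csv(path, lineterminator="\n", float_format="%.10g", na_rep="")


def validate_table(
    table: CountryIndicatorTable,
    schema: IndicatorSchema | None = None,
) -> ValidationReport:
    """Check every populated cell against its indicator's declared bounds.

    Problems are reported, never raised: each out-of-bounds or non-finite
    value yields one error naming the cell, and per-indicator missingness
    fractions (missing count / n countries) are always computed.
    """
    schema = schema or table.schema
    errors: list[tuple[str, str, str]] = []
    warns: list[tuple[str, str, str]] = []
    missingness: dict[str, float] = {}
    n = table.n_countries
    for spec in schema:
        ind = spec.indicator_id
        if ind not in table.data.columns:
            warns.append(("*", ind, "column absent from table"))
            missingness[ind] = 1.0
            continue
        col = table.data[ind]
        n_missing = int(col.isna().sum())
        missingness[ind] = (n_missing / n) if n else 0.0
        for iso3, v in col.dropna().items():
            v = float(v)
            if not np.isfinite(v):
                errors.append((iso3, ind, f"non-finite value {v!r}"))
            elif not spec.in_bounds(v):
                lo, hi = spec.bounds  # type: ignore[misc]
                errors.append(
                    (iso3, ind, f"value {v:g} outside {spec.value_kind} bounds [{lo:g}, {hi:g}]")
                )
    return ValidationReport(errors=errors, warnings=warns, n_countries=n, missingness=missingness)


#: Minimal built-in name->ISO3 aliases for convenience; callers merging
#: real multi-source data should pass their own mapping.
BUILTIN_ALIASES: dict[str, str] = {
    "sweden": "SWE",
    "norway": "NOR",
    "chile": "CHL",
    "france": "FRA",
    "denmark": "DNK",
    "belgium": "BEL",
    "united states": "USA",
    "united states of america": "USA",
    "china": "CHN",
    "argentina": "ARG",
    "brazil": "BRA",
}


def harmonize_country_codes(
    table: CountryIndicatorTable,
    aliases: Mapping[str, str] | None = None,
) -> CountryIndicatorTable:
    """Re-key rows carrying country names to ISO3 codes.

    Rows already keyed by a code (three uppercase letters, or the
    reserved synthetic ``SYnnn`` form) pass through. Names are resolved
    case-insensitively through ``aliases`` (falling back to a small
    built-in list); unresolvable names are dropped with a warning. Two
    rows resolving to the same code is an error — no silent merges.
    Idempotent: harmonizing twice equals harmonizing once.
    """
    lookup = {k.strip().lower(): v.upper() for k, v in (aliases or BUILTIN_ALIASES).items()}
    new_keys: list[str] = []
    keep: list[bool] = []
    dropped: list[str] = []
    for key in table.data.index:
        k = str(key).strip()
        if _ISO3_RE.match(k.upper()) or _SYNTH_RE.match(k.upper()):
            new_keys.append(k.upper())
            keep.append(True)
        elif k.lower() in lookup:
            new_keys.append(lookup[k.lower()])
            keep.append(True)
        else:
            new_keys.append(k)
            keep.append(False)
            dropped.append(k)
    if dropped:
        warnings.warn(f"dropping rows with unresolvable country names: {dropped}")
    kept = pd.Series(new_keys)[keep]
    collisions = sorted(kept[kept.duplicated()].unique())
    if collisions:
        raise HarmonizationError(
            f"distinct rows resolve to the same iso3 (refusing to merge): {collisions}"
        )
    data = table.data[np.asarray(keep)].copy()
    data.index = pd.Index([k for k, ok in zip(new_keys, keep) if ok], name="iso3")
    return CountryIndicatorTable(data=data, schema=table.schema, provenance=dict(table.provenance))
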