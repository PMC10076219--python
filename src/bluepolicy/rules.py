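"""Rule configuration: threshold conditions and Boolean solution formulae.

A *condition* turns one indicator into a crisp membership by comparing
the national value against a cutoff (``greater`` or ``less`` direction,
strict or inclusive). A *solution formula* combines condition ids with
AND/OR connectives only — the monotone fragment, with no negation, so a
country can never become less relevant by crossing more thresholds.
A *policy rule set* holds one formula per relevance tier, evaluated in
fixed order (highly relevant before relevant).

Configuration is YAML::

    conditions:
      sev_b12_high: {indicator: sev_b12, direction: greater, cutoff: 0.10}
    policies:
      - policy_id: nutrient_b12
        label: Reduce vitamin B12 deficiency
        highly_relevant: {all: [sev_b12_very_high, {any: [bf_production_high, bf_imports_high]}]}
        relevant:        {all: [sev_b12_high,      {any: [bf_production_high, bf_imports_high]}]}

A ``not:`` key anywhere is rejected: monotonicity is guaranteed by
construction, and several invariants (one-at-a-time scan monotonicity,
the rescue semantics for missing data) depend on it.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ConfigurationError

__all__ = [
    "Condition",
    "Formula",
    "Leaf",
    "AllOf",
    "AnyOf",
    "PolicyRuleSet",
    "load_rulesets",
    "parse_rules_config",
    "rules_digest",
    "default_rules_path",
]


@dataclass(frozen=True)
class Condition:
    """A named threshold test on a single indicator.

    ``strict`` controls the boundary: a strict ``greater`` condition is
    the test ``value > cutoff`` (matching the ">10% of the population at
    risk" phrasing of the nutrient cutoffs); inclusive is ``>=``.
    Default is strict.
    """

    condition_id: str
    indicator_id: str
    direction: str  # "greater" | "less"
    cutoff: float
    strict: bool = True

    def __post_init__(self) -> None:
        if self.direction not in ("greater", "less"):
            raise ConfigurationError(
                f"condition {self.condition_id!r}: direction must be "
                f"'greater' or 'less', got {self.direction!r}"
            )
        if not math.isfinite(self.cutoff):
            raise ConfigurationError(
                f"condition {self.condition_id!r}: cutoff must be finite, got {self.cutoff!r}"
            )

    def with_cutoff(self, cutoff: float) -> "Condition":
        """Copy with a replaced cutoff (used by the one-at-a-time scan)."""
        return replace(self, cutoff=float(cutoff))

    def holds(self, value: float) -> bool:
        if self.direction == "greater":
            return value > self.cutoff if self.strict else value >= self.cutoff
        return value < self.cutoff if self.strict else value <= self.cutoff


class Formula:
    """Monotone Boolean expression tree over condition ids."""

    def condition_ids(self) -> set[str]:
        raise NotImplementedError

    def to_config(self) -> object:
        raise NotImplementedError


@dataclass(frozen=True)
class Leaf(Formula):
    condition_id: str

    def condition_ids(self) -> set[str]:
        return {self.condition_id}

    def to_config(self) -> object:
        return self.condition_id


@dataclass(frozen=True)
class AllOf(Formula):
    children: tuple[Formula, ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ConfigurationError("empty 'all' connective")

    def condition_ids(self) -> set[str]:
        return set().union(*(c.condition_ids() for c in self.children))

    def to_config(self) -> object:
        return {"all": [c.to_config() for c in self.children]}


@dataclass(frozen=True)
class AnyOf(Formula):
    children: tuple[Formula, ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ConfigurationError("empty 'any' connective")

    def condition_ids(self) -> set[str]:
        return set().union(*(c.condition_ids() for c in self.children))

    def to_config(self) -> object:
        return {"any": [c.to_config() for c in self.children]}


def parse_formula(node: object) -> Formula:
    """Parse a nested all/any structure into a :class:`Formula`."""
    if isinstance(node, str):
        return Leaf(node)
    if isinstance(node, Mapping):
        if "not" in node:
            raise ConfigurationError(
                "'not' connective is not allowed: formulae must be monotone (AND/OR only)"
            )
        keys = set(node)
        if keys == {"all"}:
            return AllOf(tuple(parse_formula(c) for c in node["all"]))
        if keys == {"any"}:
            return AnyOf(tuple(parse_formula(c) for c in node["any"]))
        raise ConfigurationError(
            f"formula node must be a condition id or a single 'all:'/'any:' mapping, got keys {sorted(keys)}"
        )
    raise ConfigurationError(f"unrecognized formula node: {node!r}")


@dataclass(frozen=True)
class PolicyRuleSet:
    """Per-policy solution formulae, one per relevance tier.

    The tier order is fixed: the highly-relevant formula is evaluated
    first; the relevant formula is only consulted when it does not
    resolve true.
    """

    policy_id: str
    label: str
    highly_relevant: Formula
    relevant: Formula

    def condition_ids(self) -> set[str]:
        return self.highly_relevant.condition_ids() | self.relevant.condition_ids()

    def formulae(self) -> list[tuple[str, Formula]]:
        return [("highly_relevant", self.highly_relevant), ("relevant", self.relevant)]


def parse_rules_config(config: Mapping) -> tuple[dict[str, Condition], list[PolicyRuleSet]]:
    """Validate and build the condition pool and policy rule sets."""
    if not isinstance(config, Mapping) or "conditions" not in config or "policies" not in config:
        raise ConfigurationError("rule config needs top-level 'conditions:' and 'policies:' keys")

    conditions: dict[str, Condition] = {}
    for cid, body in config["conditions"].items():
        if cid in conditions:
            raise ConfigurationError(f"duplicate condition id {cid!r}")
        try:
            conditions[cid] = Condition(
                condition_id=cid,
                indicator_id=str(body["indicator"]),
                direction=str(body["direction"]),
                cutoff=float(body["cutoff"]),
                strict=bool(body.get("strict", True)),
            )
        except KeyError as exc:
            raise ConfigurationError(f"condition {cid!r}: missing field {exc}") from exc

    rulesets: list[PolicyRuleSet] = []
    seen: set[str] = set()
    for body in config["policies"]:
        pid = str(body["policy_id"])
        if pid in seen:
            raise ConfigurationError(f"duplicate policy_id {pid!r}")
        seen.add(pid)
        rs = PolicyRuleSet(
            policy_id=pid,
            label=str(body.get("label", pid)),
            highly_relevant=parse_formula(body["highly_relevant"]),
            relevant=parse_formula(body["relevant"]),
        )
        undeclared = sorted(rs.condition_ids() - set(conditions))
        if undeclared:
            raise ConfigurationError(
                f"policy {pid!r} references undeclared condition(s): {undeclared}"
            )
        rulesets.append(rs)
    if not rulesets:
        raise ConfigurationError("no policies declared")
    return conditions, rulesets


def load_rulesets(path: str | Path) -> tuple[dict[str, Condition], list[PolicyRuleSet]]:
    """Load and validate a YAML rule configuration file."""
    path = Path(path)
    if not path.is_file():
        raise ConfigurationError(f"rule config not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    return parse_rules_config(config)


def rules_digest(
    conditions: Mapping[str, Condition], rulesets: Iterable[PolicyRuleSet]
) -> str:
    """SHA-256 of the canonicalized rule structure, for run provenance.

    The digest depends on the parsed content only — key order, comments
    and formatting of the YAML source do not affect it.
    """
    canon = {
        "conditions": {
            cid: {
                "indicator": c.indicator_id,
                "direction": c.direction,
                "cutoff": c.cutoff,
                "strict": c.strict,
            }
            for cid, c in sorted(conditions.items())
        },
        "policies": [
            {
                "policy_id": rs.policy_id,
                "highly_relevant": rs.highly_relevant.to_config(),
                "relevant": rs.relevant.to_config(),
            }
            for rs in rulesets
        ],
    }
    blob = json.dumps(canon, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()


def default_rules_path() -> Path:
    """Path of the packaged default rule configuration."""
    return Path(__file__).parent / "data" / "default_rules.yaml"
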