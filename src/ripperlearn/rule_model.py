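"""Conditions, rules and ordered rule sets (decision lists).

A :class:`Rule` is a conjunction of :class:`Condition` objects plus a class
consequent; a :class:`RuleSet` is an ordered list of rules closed by a default
class, evaluated first-match.  Matching is strict: a MISSING value fails every
condition, so the instance falls through to later rules or the default.

Rule text grammar (one rule per line, the last line is the default rule)::

    ruleset  := ruleline+
    ruleline := "IF" antecedent "THEN" class
    antecedent := "TRUE" | condition ("AND" condition)*
    condition  := attribute op value
    op         := "=" | "<=" | ">="

``=`` applies to categorical attributes, ``<=``/``>=`` to numeric thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import RuleParseError, SchemaError
from .tabular_data import MISSING, Dataset, DatasetSchema, Instance

OPERATORS = ("=", "<=", ">=")


@dataclass(frozen=True)
class Condition:
    """A single test: ``attribute = token`` or ``attribute <=/>= threshold``."""

    attribute: str
    operator: str
    value: object

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise ValueError(f"unknown operator {self.operator!r}")
        if self.operator in ("<=", ">="):
            object.__setattr__(self, "value", float(self.value))
        else:
            object.__setattr__(self, "value", str(self.value))

    def holds(self, value: object) -> bool:
        """Evaluate against a raw cell value; MISSING always fails."""
        if value is MISSING or value is None:
            return False
        if self.operator == "=":
            return str(value) == self.value
        x = float(value)
        return x <= self.value if self.operator == "<=" else x >= self.value

    def __str__(self) -> str:
        return f"{self.attribute} {self.operator} {_format_value(self.value)}"


def _format_value(v: object) -> str:
    if isinstance(v, float):
        return str(int(v)) if v == int(v) else repr(v)
    return str(v)


@dataclass(frozen=True)
class Rule:
    """An ordered conjunction of conditions implying a class."""

    antecedent: tuple[Condition, ...]
    consequent: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "antecedent", tuple(self.antecedent))
        object.__setattr__(self, "consequent", str(self.consequent))
        triples = [(c.attribute, c.operator, c.value) for c in self.antecedent]
        if len(set(triples)) != len(triples):
            raise ValueError("duplicate condition in rule antecedent")

    def __str__(self) -> str:
        if not self.antecedent:
            return f"IF TRUE THEN {self.consequent}"
        body = " AND ".join(str(c) for c in self.antecedent)
        return f"IF {body} THEN {self.consequent}"


@dataclass
class RuleSet:
    """Ordered decision list closed by an always-present default class."""

    rules: list[Rule] = field(default_factory=list)
    default_class: str = "0"

    def __post_init__(self) -> None:
        self.rules = list(self.rules)
        self.default_class = str(self.default_class)

    def __len__(self) -> int:
        return len(self.rules)

    def __str__(self) -> str:
        return serialize_rules(self)


@dataclass(frozen=True)
class CoverageStats:
    """Coverage counts of one rule: ``p`` positives, ``n`` negatives covered."""

    p: int
    n: int

    def __post_init__(self) -> None:
        if self.p < 0 or self.n < 0:
            raise ValueError("coverage counts must be non-negative")

    @property
    def cover(self) -> int:
        """Positive-cover alias used by the growth gain."""
        return self.p

    @property
    def rt(self) -> float | None:
        """Precision p/(p+n); None when the rule covers nothing."""
        total = self.p + self.n
        return self.p / total if total else None


def matches(rule: Rule, instance: Instance, schema: DatasetSchema | None = None) -> bool:
    """True iff every condition of ``rule`` holds on ``instance``.

    An empty antecedent matches everything; MISSING values fail their
    condition.  With ``schema`` given, unknown attributes raise SchemaError.
    """
    for cond in rule.antecedent:
        if schema is not None and not schema.has_attribute(cond.attribute):
            raise SchemaError(f"rule condition on unknown attribute {cond.attribute!r}")
        if not cond.holds(instance.value(cond.attribute)):
            return False
    return True


def coverage(rule: Rule, data: Dataset, positive_class: str) -> CoverageStats:
    """Exact (p, n) counts of ``rule`` over ``data`` w.r.t. ``positive_class``."""
    view = DatasetView(data)
    mask = view.rule_mask(rule)
    pos = view.labels_equal(positive_class)
    p = int(np.count_nonzero(mask & pos))
    n = int(np.count_nonzero(mask & ~pos))
    return CoverageStats(p, n)


def predict(ruleset: RuleSet, instance: Instance, schema: DatasetSchema | None = None) -> str:
    """Consequent of the first matching rule; default class if none matches."""
    for rule in ruleset.rules:
        if matches(rule, instance, schema):
            return rule.consequent
    return ruleset.default_class


def predict_dataset(ruleset: RuleSet, data: Dataset) -> list[str]:
    """Vectorized first-match predictions for every instance of ``data``."""
    return DatasetView(data).predictions(ruleset)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

FORMAT_VERSION = 1


def serialize_rules(ruleset: RuleSet) -> str:
    """Render a ruleset in the line grammar; the last line is the default rule."""
    lines = [str(rule) for rule in ruleset.rules]
    lines.append(f"IF TRUE THEN {ruleset.default_class}")
    return "\n".join(lines) + "\n"


def _parse_condition(tokens: list[str], lineno: int) -> Condition:
    if len(tokens) != 3:
        raise RuleParseError(f"line {lineno}: malformed condition {' '.join(tokens)!r}")
    attr, op, value = tokens
    if op not in OPERATORS:
        raise RuleParseError(f"line {lineno}: unknown operator {op!r}")
    if op in ("<=", ">="):
        try:
            value = float(value)
        except ValueError:
            raise RuleParseError(f"line {lineno}: non-numeric threshold {value!r}") from None
    return Condition(attr, op, value)


def parse_rule_line(line: str, lineno: int = 1) -> Rule:
    tokens = line.split()
    if len(tokens) < 4 or tokens[0] != "IF" or tokens[-2] != "THEN":
        raise RuleParseError(f"line {lineno}: expected 'IF ... THEN class', got {line!r}")
    consequent = tokens[-1]
    body = tokens[1:-2]
    if body == ["TRUE"]:
        return Rule((), consequent)
    conditions: list[Condition] = []
    current: list[str] = []
    for tok in body + ["AND"]:
        if tok == "AND":
            if not current:
                raise RuleParseError(f"line {lineno}: empty condition")
            conditions.append(_parse_condition(current, lineno))
            current = []
        else:
            current.append(tok)
    try:
        return Rule(tuple(conditions), consequent)
    except ValueError as exc:
        raise RuleParseError(f"line {lineno}: {exc}") from None


def parse_rules(text: str) -> RuleSet:
    """Parse rule text; the final line must be the default (empty-antecedent) rule."""
    lines = [(i, ln.strip()) for i, ln in enumerate(text.splitlines(), start=1) if ln.strip()]
    if not lines:
        raise RuleParseError("empty rule text: default rule line required")
    rules = [parse_rule_line(ln, i) for i, ln in lines]
    default = rules.pop()
    if default.antecedent:
        raise RuleParseError(
            f"line {lines[-1][0]}: last line must be the default rule 'IF TRUE THEN class'"
        )
    return RuleSet(rules, default.consequent)


def ruleset_to_document(ruleset: RuleSet, metadata: dict | None = None) -> dict:
    """Structured key-value form with a format version (JSON-serializable)."""
    doc = {
        "format_version": FORMAT_VERSION,
        "rules": [
            {
                "conditions": [
                    {"attribute": c.attribute, "operator": c.operator, "value": c.value}
                    for c in rule.antecedent
                ],
                "consequent": rule.consequent,
            }
            for rule in ruleset.rules
        ],
        "default_class": ruleset.default_class,
    }
    if metadata:
        doc["metadata"] = metadata
    return doc


def ruleset_from_document(doc: dict) -> RuleSet:
    if doc.get("format_version") != FORMAT_VERSION:
        raise RuleParseError(f"unsupported format_version {doc.get('format_version')!r}")
    rules = [
        Rule(
            tuple(
                Condition(c["attribute"], c["operator"], c["value"])
                for c in r["conditions"]
            ),
            r["consequent"],
        )
        for r in doc["rules"]
    ]
    return RuleSet(rules, doc["default_class"])


def save_ruleset(ruleset: RuleSet, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(ruleset_to_document(ruleset, metadata), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_ruleset(path) -> tuple[RuleSet, dict]:
    with open(path) as fh:
        doc = json.load(fh)
    return ruleset_from_document(doc), doc.get("metadata", {})


# ---------------------------------------------------------------------------
# Vectorized evaluation
# ---------------------------------------------------------------------------


class DatasetView:
    """Columnar (numpy) view of a Dataset for fast rule evaluation.

    Numeric columns become float arrays (NaN = missing); categorical columns
    become object arrays of tokens (None = missing).  Comparisons with NaN /
    None are False, which reproduces the "MISSING fails" matching contract.
    """

    def __init__(self, data: Dataset) -> None:
        self.schema = data.schema
        self.n = len(data)
        self._numeric: dict[str, np.ndarray] = {}
        self._categorical: dict[str, np.ndarray] = {}
        for spec in data.schema.attributes:
            if spec.is_numeric:
                col = np.array(
                    [
                        np.nan if inst.values[spec.name] is MISSING else float(inst.values[spec.name])
                        for inst in data.instances
                    ],
                    dtype=float,
                )
                self._numeric[spec.name] = col
            else:
                col = np.array(
                    [
                        None if inst.values[spec.name] is MISSING else str(inst.values[spec.name])
                        for inst in data.instances
                    ],
                    dtype=object,
                )
                self._categorical[spec.name] = col
        self.labels = np.array(
            [inst.label for inst in data.instances], dtype=object
        )

    def labels_equal(self, token: str) -> np.ndarray:
        return self.labels == token

    def condition_mask(self, cond: Condition) -> np.ndarray:
        if cond.attribute in self._numeric:
            col = self._numeric[cond.attribute]
            if cond.operator == "<=":
                return col <= cond.value
            if cond.operator == ">=":
                return col >= cond.value
            raise SchemaError(f"operator {cond.operator!r} invalid on numeric {cond.attribute!r}")
        if cond.attribute in self._categorical:
            if cond.operator != "=":
                raise SchemaError(
                    f"operator {cond.operator!r} invalid on categorical {cond.attribute!r}"
                )
            return self._categorical[cond.attribute] == cond.value
        raise SchemaError(f"unknown attribute {cond.attribute!r}")

    def rule_mask(self, rule: Rule, base: np.ndarray | None = None) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool) if base is None else base.copy()
        for cond in rule.antecedent:
            mask &= self.condition_mask(cond)
        return mask

    def covered_mask(self, rules: Sequence[Rule]) -> np.ndarray:
        """Instances matched by at least one rule."""
        covered = np.zeros(self.n, dtype=bool)
        for rule in rules:
            covered |= self.rule_mask(rule)
        return covered

    def predictions(self, ruleset: RuleSet) -> list[str]:
        out = np.full(self.n, ruleset.default_class, dtype=object)
        assigned = np.zeros(self.n, dtype=bool)
        for rule in ruleset.rules:
            m = self.rule_mask(rule) & ~assigned
            out[m] = rule.consequent
            assigned |= m
        return list(out)
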