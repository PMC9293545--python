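"""Static clinical knowledge base: banded attributes plus an eleven-rule screen.

The rule set is applied first-match in listed order and closed by a flagged
DEFAULT (no rule matched).  It is knowingly incomplete and partly shadowed:
rule 8 repeats the premises of rules 6-7 and is therefore unreachable under
listed order, and rule 11 is shadowed by rule 9.  Faithfulness to the
listed order is preserved; :func:`reachability_report` surfaces the shadowing
instead of repairing it.

Derived features:

* ``thallium_level`` — scan code 3 maps to ``less``; defect codes 6 and 7 to
  ``higher``.
* ``vessel_level`` — fluoroscopy count below the threshold (default 1) maps
  to ``less``, otherwise ``higher``.
* ``angina`` — exercise-induced angina flag, ``no`` / ``has``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .errors import ValidationError
from .rule_model import Condition, Rule, RuleSet
from .tabular_data import BAND_TABLE, MISSING, UNBANDED, discretize

OUTCOME_NO_DISEASE = "no_heart_disease"
OUTCOME_PRESENCE = "presence"
OUTCOME_PRESENCE_1 = "presence_1"
OUTCOME_PRESENCE_2 = "presence_2"
OUTCOMES = (OUTCOME_NO_DISEASE, OUTCOME_PRESENCE, OUTCOME_PRESENCE_1, OUTCOME_PRESENCE_2)

DEFAULT_RULE_ID = "DEFAULT"

CHEST_PAIN_TOKENS = {1: "typical_angina", 2: "atypical_angina", 3: "nonangina", 4: "asymptomatic"}

#: Fluoroscopy counts at or above this threshold count as "higher".
DEFAULT_VESSEL_THRESHOLD = 1


@dataclass(frozen=True)
class ContextRule:
    """One screening rule: required derived-feature values and an outcome."""

    rule_id: int
    conditions: tuple[tuple[str, str], ...]  # (feature, required value)
    outcome: str

    def applies(self, features: dict[str, object]) -> bool:
        return all(features.get(feat) == val for feat, val in self.conditions)


_CONTEXT_RULES: tuple[ContextRule, ...] = (
    ContextRule(1, (("thallium_level", "less"), ("chest_pain_type", "typical_angina")),
                OUTCOME_NO_DISEASE),
    ContextRule(2, (("thallium_level", "less"), ("chest_pain_type", "atypical_angina")),
                OUTCOME_NO_DISEASE),
    ContextRule(3, (("thallium_level", "less"), ("chest_pain_type", "nonangina")),
                OUTCOME_NO_DISEASE),
    ContextRule(4, (("thallium_level", "less"), ("chest_pain_type", "asymptomatic"),
                    ("vessel_level", "less")), OUTCOME_NO_DISEASE),
    ContextRule(5, (("thallium_level", "less"), ("chest_pain_type", "asymptomatic"),
                    ("vessel_level", "higher")), OUTCOME_PRESENCE_2),
    ContextRule(6, (("thallium_level", "higher"), ("vessel_level", "less"),
                    ("angina", "no")), OUTCOME_NO_DISEASE),
    ContextRule(7, (("thallium_level", "higher"), ("vessel_level", "less"),
                    ("angina", "has")), OUTCOME_PRESENCE),
    ContextRule(8, (("thallium_level", "higher"), ("vessel_level", "less")),
                OUTCOME_PRESENCE_2),
    ContextRule(9, (("family_history", "yes"),), OUTCOME_PRESENCE_1),
    ContextRule(10, (("medical_records", "yes"),), OUTCOME_PRESENCE_1),
    ContextRule(11, (("family_history", "yes"), ("medical_records", "yes")),
                OUTCOME_PRESENCE_1),
)


def load_context_ruleset() -> list[ContextRule]:
    """The eleven screening rules, in listed order."""
    return list(_CONTEXT_RULES)


@dataclass
class ContextPatientRecord:
    """Structured patient record for the context screen.

    Any field may be MISSING; conditions on missing features simply fail.
    """

    chest_pain: object = MISSING       # code 1-4
    cholesterol: object = MISSING      # mg/dl
    bp: object = MISSING               # mmHg
    blood_sugar: object = MISSING      # mg/dl
    ecg_st: object = MISSING           # ST depression
    thallium: object = MISSING         # code 3 / 6 / 7
    age: object = MISSING              # years
    gender: object = MISSING           # 1 male / 0 female
    smoking_years: object = MISSING
    drinking: object = MISSING         # 0 / 1
    family_history: object = MISSING   # count of conditions
    medical_records: object = MISSING  # count of conditions
    vessels: object = MISSING          # fluoroscopy count 0-3
    induced_angina: object = MISSING   # 0 / 1

    _CODE_RANGES = {
        "chest_pain": (1, 2, 3, 4),
        "thallium": (3, 6, 7),
        "gender": (0, 1),
        "drinking": (0, 1),
        "induced_angina": (0, 1),
        "vessels": (0, 1, 2, 3),
    }

    def __post_init__(self) -> None:
        for name, allowed in self._CODE_RANGES.items():
            v = getattr(self, name)
            if v is MISSING or v is None:
                setattr(self, name, MISSING)
                continue
            try:
                x = float(v)
            except (TypeError, ValueError):
                raise ValidationError(f"field {name!r}: non-numeric code {v!r}") from None
            if x not in allowed:
                raise ValidationError(f"field {name!r}: code {v!r} outside {allowed}")
            setattr(self, name, int(x))
        for name in ("cholesterol", "bp", "blood_sugar", "ecg_st", "age",
                     "smoking_years", "family_history", "medical_records"):
            v = getattr(self, name)
            if v is MISSING or v is None:
                setattr(self, name, MISSING)
                continue
            try:
                setattr(self, name, float(v))
            except (TypeError, ValueError):
                raise ValidationError(f"field {name!r}: non-numeric value {v!r}") from None


@dataclass
class ContextAssessment:
    outcome: str
    fired_rule: object  # int rule id or DEFAULT_RULE_ID
    band_trace: list = field(default_factory=list)

    @property
    def is_default(self) -> bool:
        return self.fired_rule == DEFAULT_RULE_ID


_BANDED_FIELDS = {
    "chest_pain": "chest_pain",
    "cholesterol": "cholesterol",
    "bp": "bp",
    "blood_sugar": "blood_sugar",
    "ecg_st": "ecg",
    "thallium": "thallium",
    "age": "age",
    "gender": "gender",
    "smoking_years": "smoking",
    "drinking": "drinking",
    "family_history": "family_history",
    "medical_records": "medical_records",
}


def derive_features(
    record: ContextPatientRecord, vessel_threshold: int = DEFAULT_VESSEL_THRESHOLD
) -> dict[str, object]:
    """Map raw record values onto the derived feature vocabulary of the rules."""
    features: dict[str, object] = {}
    if record.thallium is not MISSING:
        features["thallium_level"] = "less" if record.thallium == 3 else "higher"
    if record.chest_pain is not MISSING:
        features["chest_pain_type"] = CHEST_PAIN_TOKENS[record.chest_pain]
    if record.vessels is not MISSING:
        features["vessel_level"] = "less" if record.vessels < vessel_threshold else "higher"
    if record.induced_angina is not MISSING:
        features["angina"] = "has" if record.induced_angina == 1 else "no"
    if record.family_history is not MISSING:
        features["family_history"] = "yes" if record.family_history >= 1 else "no"
    if record.medical_records is not MISSING:
        features["medical_records"] = "yes" if record.medical_records >= 1 else "no"
    return features


def _band_trace(record: ContextPatientRecord) -> list[tuple[str, object, object]]:
    trace = []
    for field_name, band_attr in _BANDED_FIELDS.items():
        raw = getattr(record, field_name)
        if raw is not MISSING:
            trace.append((field_name, raw, discretize(band_attr, raw)))
    return trace


def assess(
    record: ContextPatientRecord,
    vessel_threshold: int = DEFAULT_VESSEL_THRESHOLD,
    history_priority: bool = False,
) -> ContextAssessment:
    """Run the record through the screening rules, first match wins.

    ``history_priority=True`` evaluates the history rules (9-11) before the
    physiology rules (1-8); the listed order is the default.  No match yields
    a flagged DEFAULT assessment with outcome ``no_heart_disease``.
    """
    features = derive_features(record, vessel_threshold)
    rules = load_context_ruleset()
    if history_priority:
        rules = [r for r in rules if r.rule_id >= 9] + [r for r in rules if r.rule_id < 9]
    trace = _band_trace(record)
    for rule in rules:
        if rule.applies(features):
            return ContextAssessment(rule.outcome, rule.rule_id, trace)
    return ContextAssessment(OUTCOME_NO_DISEASE, DEFAULT_RULE_ID, trace)


_FEATURE_GRID = {
    "thallium_level": ("less", "higher"),
    "chest_pain_type": tuple(CHEST_PAIN_TOKENS.values()),
    "vessel_level": ("less", "higher"),
    "angina": ("no", "has"),
    "family_history": ("no", "yes"),
    "medical_records": ("no", "yes"),
}


def reachability_report(history_priority: bool = False) -> dict:
    """Enumerate every derived-feature combination and audit the rule set.

    Returns reachable/unreachable rule ids and the fraction of combinations
    falling through to DEFAULT (documents the rule set's incompleteness).
    """
    rules = load_context_ruleset()
    if history_priority:
        rules = [r for r in rules if r.rule_id >= 9] + [r for r in rules if r.rule_id < 9]
    fired: dict[object, int] = {}
    names = list(_FEATURE_GRID)
    total = 0
    for combo in product(*(_FEATURE_GRID[n] for n in names)):
        features = dict(zip(names, combo))
        total += 1
        hit = DEFAULT_RULE_ID
        for rule in rules:
            if rule.applies(features):
                hit = rule.rule_id
                break
        fired[hit] = fired.get(hit, 0) + 1
    reachable = sorted(r.rule_id for r in rules if r.rule_id in fired)
    unreachable = sorted(r.rule_id for r in rules if r.rule_id not in fired)
    return {
        "reachable": reachable,
        "unreachable": unreachable,
        "default_fraction": fired.get(DEFAULT_RULE_ID, 0) / total,
        "combinations": total,
        "fired_counts": fired,
    }


def context_ruleset_as_rules() -> RuleSet:
    """Export the screen in the generic rule grammar over derived features."""
    rules = [
        Rule(
            tuple(Condition(feat, "=", val) for feat, val in r.conditions),
            r.outcome,
        )
        for r in _CONTEXT_RULES
    ]
    return RuleSet(rules, OUTCOME_NO_DISEASE)
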