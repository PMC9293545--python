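"""Synthetic tabular data with planted rule structure.

Attribute values are sampled independently (numeric uniform over the declared
range, categorical uniform over the declared categories); labels come from a
planted ground-truth rule set and are then flipped with a configurable noise
rate.  Because the noise rate is capped below 0.5, the planted rule set stays
the Bayes classifier of its own data — the anchor for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .rule_model import Condition, Rule, RuleSet, predict
from .tabular_data import AttributeSpec, Dataset, DatasetSchema, Instance, cleveland_schema


@dataclass(frozen=True)
class PlantedConcept:
    """Ground-truth labeler: a rule set, a label-noise rate, an optional class balance.

    ``positive_fraction`` (with ``positive_class``) requests an approximate
    class balance via quota sampling before noise is applied.
    """

    ruleset: RuleSet
    noise_rate: float = 0.0
    positive_fraction: float | None = None
    positive_class: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValidationError("noise_rate must lie in [0, 0.5)")
        if self.positive_fraction is not None:
            if not 0.0 < self.positive_fraction < 1.0:
                raise ValidationError("positive_fraction must lie in (0, 1)")
            if self.positive_class is None:
                raise ValidationError("positive_fraction requires positive_class")

    def class_tokens(self) -> list[str]:
        tokens = {r.consequent for r in self.ruleset.rules}
        tokens.add(self.ruleset.default_class)
        return sorted(tokens)


def _sample_value(spec: AttributeSpec, rng: np.random.Generator):
    if spec.is_numeric:
        lo, hi = spec.numeric_range or (0.0, 1.0)
        if spec.integer_valued:
            return float(rng.integers(int(lo), int(hi) + 1))
        return float(rng.uniform(lo, hi))
    return str(spec.categories[rng.integers(0, len(spec.categories))])


def _sample_instance(schema: DatasetSchema, rng: np.random.Generator) -> Instance:
    return Instance({spec.name: _sample_value(spec, rng) for spec in schema.attributes})


def generate_dataset(
    schema: DatasetSchema, concept: PlantedConcept, n: int, seed: int = 1
) -> Dataset:
    """Draw ``n`` labeled instances; deterministic in ``seed``."""
    if n < 0:
        raise ValidationError("n must be non-negative")
    rng = np.random.default_rng([seed, 0x5EED])
    tokens = concept.class_tokens()
    instances: list[Instance] = []

    if concept.positive_fraction is None:
        for _ in range(n):
            inst = _sample_instance(schema, rng)
            inst.label = predict(concept.ruleset, inst)
            instances.append(inst)
    else:
        want_pos = int(round(concept.positive_fraction * n))
        want_neg = n - want_pos
        got_pos = got_neg = 0
        attempts = 0
        while got_pos + got_neg < n:
            attempts += 1
            if attempts > 1000 * max(n, 1):
                raise ValidationError(
                    "could not reach the requested positive_fraction by rejection sampling"
                )
            inst = _sample_instance(schema, rng)
            inst.label = predict(concept.ruleset, inst)
            is_pos = inst.label == concept.positive_class
            if is_pos and got_pos < want_pos:
                got_pos += 1
            elif not is_pos and got_neg < want_neg:
                got_neg += 1
            else:
                continue
            instances.append(inst)

    if concept.noise_rate > 0 and len(tokens) > 1:
        for inst in instances:
            if rng.random() < concept.noise_rate:
                others = [t for t in tokens if t != inst.label]
                inst.label = others[rng.integers(0, len(others))]
    return Dataset(schema, instances)


def cleveland_concept() -> PlantedConcept:
    """Built-in planted concept over thal / ca / cp for Cleveland-like data."""
    rules = [
        Rule((Condition("thal", "=", "7"), Condition("ca", ">=", 1.0)), "1"),
        Rule((Condition("cp", "=", "4"), Condition("thal", "=", "6")), "1"),
    ]
    return PlantedConcept(RuleSet(rules, "0"))


def make_cleveland_like(n: int, seed: int = 1, noise_rate: float = 0.0) -> Dataset:
    """Cleveland-schema synthetic dataset labeled by the built-in concept."""
    concept = cleveland_concept()
    if noise_rate:
        concept = PlantedConcept(concept.ruleset, noise_rate)
    return generate_dataset(cleveland_schema(), concept, n, seed)
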