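"""Rule-set optimization rounds and the multiclass trainer.

Each optimization pass revisits every rule and grows two variants on the data
left uncovered by the other rules: a replacement grown from scratch and a
revision grown from the rule's own antecedent.  The variant (original,
replacement, revision) minimizing the total description length is kept, so a
round can never increase it.  A residual covering pass then restores
completeness for positives the pass may have orphaned, appending only rules
that do not increase the total description length.

Multiclass training learns rule blocks for classes in increasing frequency
order; the most frequent class becomes the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import mdl
from .errors import ValidationError
from .induction import InductionParams, _Learner, _combine, _stratified_partition, build_ruleset
from .rule_model import DatasetView, Rule, RuleSet, predict
from .tabular_data import Dataset, DatasetSchema, Instance


@dataclass(frozen=True)
class OptimizationParams:
    k: int = 2
    induction: InductionParams = field(default_factory=InductionParams)

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValidationError("k must be non-negative")


@dataclass(frozen=True)
class ClassOrdering:
    """Class tokens in ascending training frequency; the last is the default."""

    classes: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if list(self.counts) != sorted(self.counts):
            raise ValidationError("class frequencies must be non-decreasing along the order")

    @property
    def default_class(self) -> str:
        return self.classes[-1]


@dataclass
class OrderedClassifier:
    """Concatenated per-class decision list closed by the last-ordered class."""

    ruleset: RuleSet
    ordering: ClassOrdering
    seed: int = 1

    def predict(self, instance: Instance, schema: DatasetSchema | None = None) -> str:
        return predict(self.ruleset, instance, schema)

    def predict_dataset(self, data: Dataset) -> list[str]:
        return DatasetView(data).predictions(self.ruleset)


def _canonical_sort(data: Dataset) -> Dataset:
    """Order-independent canonicalization: sort rows by (label, rendered values)."""
    names = data.schema.predictor_names

    def key(inst: Instance):
        return (
            "" if inst.label is None else str(inst.label),
            tuple(repr(inst.values[n]) for n in names),
        )

    return Dataset(data.schema, sorted(data.instances, key=key))


def optimize_ruleset(
    ruleset: RuleSet,
    P: Dataset,
    N: Dataset,
    params: OptimizationParams | None = None,
    rng: np.random.Generator | None = None,
) -> RuleSet:
    """One optimization pass; total description length never increases."""
    params = params or OptimizationParams()
    ind = params.induction
    if rng is None:
        rng = np.random.default_rng(ind.seed)
    if len(P) == 0 and len(N) == 0:
        return RuleSet(list(ruleset.rules), ruleset.default_class)

    positive = ruleset.rules[0].consequent if ruleset.rules else None
    combined = _combine(P, N)
    view = DatasetView(combined)
    total_candidates = mdl.count_candidate_conditions(combined)
    if positive is None:
        # nothing to revise; fall through to the residual covering pass only
        positive_tokens = {i.label for i in P.instances if i.label is not None}
        positive = positive_tokens.pop() if len(positive_tokens) == 1 else None
    learner = _Learner(view, positive, ind) if positive is not None else None

    rules = list(ruleset.rules)
    if learner is not None:
        for i in range(len(rules)):
            others = rules[:i] + rules[i + 1 :]
            covered_others = view.covered_mask(others)
            u_mask = ~covered_others
            idx = np.flatnonzero(u_mask)
            labels = [combined.instances[j].label for j in idx]
            g_rel, p_rel = _stratified_partition(labels, ind.ratio, rng)
            grow_mask = np.zeros(view.n, dtype=bool)
            grow_mask[idx[g_rel]] = True
            prune_mask = np.zeros(view.n, dtype=bool)
            prune_mask[idx[p_rel]] = True

            variants = [rules[i]]
            if np.any(grow_mask & learner.pos):
                replacement = learner.grow(grow_mask)
                if replacement.antecedent:
                    replacement = learner.prune(replacement, prune_mask)
                variants.append(replacement)
                revision = learner.grow(grow_mask, seed_rule=rules[i])
                if revision.antecedent:
                    revision = learner.prune(revision, prune_mask)
                variants.append(revision)

            best_bits = None
            best_variant = rules[i]
            for variant in variants:
                trial = rules[:i] + [variant] + rules[i + 1 :]
                bits = learner.ruleset_bits(trial, total_candidates)
                if best_bits is None or bits < best_bits:
                    best_bits = bits
                    best_variant = variant
            rules[i] = best_variant

        # residual covering: re-cover orphaned positives, but only keep
        # appended rules that do not increase the description length
        uncovered_pos = learner.pos & ~view.covered_mask(rules)
        if np.any(uncovered_pos):
            residual_P = Dataset(
                combined.schema,
                [combined.instances[j] for j in np.flatnonzero(uncovered_pos)],
            )
            extra = build_ruleset(residual_P, N, ind, rng=rng)
            current_bits = learner.ruleset_bits(rules, total_candidates)
            for rule in extra.rules:
                trial_bits = learner.ruleset_bits(rules + [rule], total_candidates)
                if trial_bits <= current_bits:
                    rules.append(rule)
                    current_bits = trial_bits
    return RuleSet(rules, ruleset.default_class)


def ripper(
    P: Dataset,
    N: Dataset,
    params: OptimizationParams | None = None,
    rng: np.random.Generator | None = None,
) -> RuleSet:
    """Build a rule set then run k optimization rounds over it."""
    params = params or OptimizationParams()
    if rng is None:
        rng = np.random.default_rng(params.induction.seed)
    ruleset = build_ruleset(P, N, params.induction, rng=rng)
    for _ in range(params.k):
        ruleset = optimize_ruleset(ruleset, P, N, params, rng=rng)
    return ruleset


def class_ordering(data: Dataset) -> ClassOrdering:
    """Classes sorted by ascending frequency, ties broken lexicographically."""
    counts = data.class_counts()
    if not counts:
        raise ValidationError("dataset has no labeled instances")
    ordered = sorted(counts, key=lambda c: (counts[c], c))
    return ClassOrdering(tuple(ordered), tuple(counts[c] for c in ordered))


def train_multiclass(
    data: Dataset, params: OptimizationParams | None = None
) -> OrderedClassifier:
    """Learn an ordered decision list, one class block at a time.

    Classes are processed in increasing frequency order; instances covered by
    a finished block are excluded before learning the next class.  The most
    frequent class never gets rules — it is the default.
    """
    params = params or OptimizationParams()
    if len(data) == 0:
        raise ValidationError("cannot train on an empty dataset")
    data = _canonical_sort(data)
    ordering = class_ordering(data)
    rng = np.random.default_rng(params.induction.seed)

    pool = list(data.instances)
    all_rules: list[Rule] = []
    for token in ordering.classes[:-1]:
        P = Dataset(data.schema, [i for i in pool if i.label == token])
        N = Dataset(data.schema, [i for i in pool if i.label != token])
        if len(P) == 0:
            continue
        block = ripper(P, N, params, rng=rng)
        all_rules.extend(block.rules)
        if block.rules:
            keep = ~DatasetView(Dataset(data.schema, pool)).covered_mask(block.rules)
            pool = [inst for inst, k in zip(pool, keep) if k]
    ruleset = RuleSet(all_rules, ordering.default_class)
    return OrderedClassifier(ruleset=ruleset, ordering=ordering, seed=params.induction.seed)
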