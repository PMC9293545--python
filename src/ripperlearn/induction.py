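"""Rule growth, reduced-error pruning, and the covering loop that builds a rule set.

Growth adds the condition with maximal information gain

    gain = p_after * (log2(rt_after) - log2(rt_before)),   rt = p / (p + n)

until the rule covers no negative grow instances or no candidate improves.
Pruning deletes trailing condition suffixes, keeping the candidate maximizing
T = (p - n) / (p + n) on the prune set (ties go to the shortest candidate).
The covering loop accepts a rule unless its prune-set error is too high or its
coverage too small, removes covered instances, and stops when positives are
exhausted or the total description length exceeds the best seen so far by more
than the configured budget; a final reverse-order pass deletes any rule whose
removal lowers the total description length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import mdl
from .errors import ValidationError
from .mdl import MDLParams
from .rule_model import Condition, CoverageStats, DatasetView, Rule, RuleSet
from .tabular_data import Dataset

#: Sentinel gain for candidates that cover no positives (log of zero).
NEGATIVE_INFINITY = -math.inf


@dataclass
class GrowPruneSplit:
    grow: Dataset
    prune: Dataset
    ratio: float
    seed: int


@dataclass(frozen=True)
class InductionParams:
    """Parameters of the grow/prune covering loop."""

    ratio: float = 2.0 / 3.0
    seed: int = 1
    min_rule_coverage: int = 1
    max_prune_error: float = 0.5
    resplit_per_rule: bool = True
    mdl: MDLParams = field(default_factory=MDLParams)

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio < 1.0:
            raise ValidationError("ratio must lie strictly between 0 and 1")
        if not 0.0 < self.max_prune_error <= 1.0:
            raise ValidationError("max_prune_error must lie in (0, 1]")
        if self.min_rule_coverage < 0:
            raise ValidationError("min_rule_coverage must be non-negative")


def foil_gain(before: CoverageStats, after: CoverageStats) -> float:
    """Information gain of specialising a rule from ``before`` to ``after`` coverage.

    Returns :data:`NEGATIVE_INFINITY` when the specialised rule covers no
    positives (the candidate is discarded).
    """
    if before.rt is None or before.rt == 0.0:
        raise ValueError("cannot grow from a rule covering no positives")
    if after.p == 0:
        return NEGATIVE_INFINITY
    if after.rt is None:
        raise ValueError("after-coverage undefined")
    return after.p * (math.log2(after.rt) - math.log2(before.rt))


def _stratified_partition(
    labels: list[str | None], ratio: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (grow, prune) stratified by label; |grow| = round(ratio * n)."""
    n = len(labels)
    target = int(round(ratio * n))
    by_class: dict[object, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    classes = sorted(by_class, key=lambda c: (c is None, str(c)))
    # largest-remainder allocation so per-class counts sum to the target
    ideals = {c: ratio * len(by_class[c]) for c in classes}
    counts = {c: int(math.floor(ideals[c])) for c in classes}
    short = target - sum(counts.values())
    if short > 0:
        order = sorted(classes, key=lambda c: (-(ideals[c] - counts[c]), str(c)))
        for c in order[:short]:
            counts[c] += 1
    elif short < 0:
        order = sorted(classes, key=lambda c: ((ideals[c] - counts[c]), str(c)))
        for c in order[:-short]:
            counts[c] -= 1
    grow_idx: list[int] = []
    prune_idx: list[int] = []
    for c in classes:
        idx = np.array(by_class[c], dtype=int)
        rng.shuffle(idx)
        k = max(0, min(len(idx), counts[c]))
        grow_idx.extend(idx[:k])
        prune_idx.extend(idx[k:])
    return np.array(sorted(grow_idx), dtype=int), np.array(sorted(prune_idx), dtype=int)


def split_grow_prune(data: Dataset, params: InductionParams | None = None) -> GrowPruneSplit:
    """Deterministic stratified grow/prune partition of ``data``."""
    params = params or InductionParams()
    if len(data) < 2:
        raise ValidationError("need at least 2 instances to split")
    rng = np.random.default_rng(params.seed)
    grow_idx, prune_idx = _stratified_partition(data.labels(), params.ratio, rng)
    return GrowPruneSplit(
        grow=data.subset(grow_idx),
        prune=data.subset(prune_idx),
        ratio=params.ratio,
        seed=params.seed,
    )


class _Learner:
    """Vectorized grow/prune engine over a fixed combined dataset view."""

    def __init__(
        self,
        view: DatasetView,
        positive_class: str,
        params: InductionParams,
    ) -> None:
        self.view = view
        self.positive_class = positive_class
        self.params = params
        self.pos = view.labels_equal(positive_class)

    # -- candidate enumeration ------------------------------------------------

    def _candidates(self, covered: np.ndarray):
        """Yield candidate conditions in deterministic order.

        Attributes follow schema order; numeric thresholds come from distinct
        observed values among currently covered rows, ascending, '<=' before
        '>=' at each threshold.
        """
        view = self.view
        for spec in view.schema.attributes:
            if spec.is_numeric:
                col = view._numeric[spec.name][covered]
                vals = np.unique(col[~np.isnan(col)])
                for v in vals:
                    yield Condition(spec.name, "<=", float(v))
                    yield Condition(spec.name, ">=", float(v))
            else:
                for cat in spec.categories:
                    yield Condition(spec.name, "=", cat)

    # -- growth ---------------------------------------------------------------

    def grow(self, grow_mask: np.ndarray, seed_rule: Rule | None = None) -> Rule:
        conditions: list[Condition] = list(seed_rule.antecedent) if seed_rule else []
        covered = grow_mask.copy()
        for cond in conditions:
            covered &= self.view.condition_mask(cond)
        pos = self.pos
        existing = {(c.attribute, c.operator, c.value) for c in conditions}
        while True:
            p0 = int(np.count_nonzero(covered & pos))
            n0 = int(np.count_nonzero(covered) ) - p0
            if n0 == 0 or p0 == 0:
                break
            rt0 = math.log2(p0 / (p0 + n0))
            best_gain = 0.0
            best: tuple[Condition, np.ndarray] | None = None
            for cond in self._candidates(covered):
                key = (cond.attribute, cond.operator, cond.value)
                if key in existing:
                    continue
                cm = covered & self.view.condition_mask(cond)
                p1 = int(np.count_nonzero(cm & pos))
                if p1 == 0:
                    continue
                n1 = int(np.count_nonzero(cm)) - p1
                gain = p1 * (math.log2(p1 / (p1 + n1)) - rt0)
                if gain > best_gain + 1e-12:
                    best_gain = gain
                    best = (cond, cm)
            if best is None:
                break
            cond, covered = best
            conditions.append(cond)
            existing.add((cond.attribute, cond.operator, cond.value))
        return Rule(tuple(conditions), self.positive_class)

    # -- pruning --------------------------------------------------------------

    def prune(self, rule: Rule, prune_mask: np.ndarray) -> Rule:
        if not rule.antecedent:
            return rule
        pos = self.pos
        best_rule = None
        best_t = -math.inf
        covered = prune_mask.copy()
        # candidates are antecedent prefixes (trailing suffixes deleted),
        # shortest first so ties resolve to the shortest candidate
        prefix_masks: list[np.ndarray] = []
        for cond in rule.antecedent:
            covered = covered & self.view.condition_mask(cond)
            prefix_masks.append(covered)
        for keep in range(1, len(rule.antecedent) + 1):
            m = prefix_masks[keep - 1]
            p = int(np.count_nonzero(m & pos))
            n = int(np.count_nonzero(m)) - p
            t = 0.0 if p + n == 0 else (p - n) / (p + n)
            if t > best_t:
                best_t = t
                best_rule = Rule(rule.antecedent[:keep], rule.consequent)
        return best_rule

    def prune_error(self, rule: Rule, prune_mask: np.ndarray) -> float:
        m = self.view.rule_mask(rule, prune_mask)
        p = int(np.count_nonzero(m & self.pos))
        n = int(np.count_nonzero(m)) - p
        return n / (p + n) if p + n else 0.0

    # -- description length over the full view --------------------------------

    def ruleset_bits(self, rules, total_candidates: int) -> float:
        theory = sum(mdl.theory_dl(r, total_candidates, self.params.mdl) for r in rules)
        covered = self.view.covered_mask(rules)
        cover = int(covered.sum())
        fp = int(np.count_nonzero(covered & ~self.pos))
        fn = int(np.count_nonzero(~covered & self.pos))
        uncover = self.view.n - cover
        return theory + mdl.data_dl(cover, uncover, fp, fn, self.params.mdl)


def grow_rule(
    grow: Dataset, target_class: str, params: InductionParams | None = None
) -> Rule:
    """Grow a single rule on ``grow`` data by greedy gain maximization."""
    params = params or InductionParams()
    view = DatasetView(grow)
    learner = _Learner(view, target_class, params)
    if not np.any(learner.pos):
        raise ValidationError(f"grow set has no instance of class {target_class!r}")
    return learner.grow(np.ones(view.n, dtype=bool))


def prune_rule(
    rule: Rule, prune: Dataset, target_class: str, params: InductionParams | None = None
) -> Rule:
    """Reduced-error pruning of trailing suffixes against ``prune`` data."""
    params = params or InductionParams()
    view = DatasetView(prune)
    learner = _Learner(view, target_class, params)
    return learner.prune(rule, np.ones(view.n, dtype=bool))


def _combine(P: Dataset, N: Dataset) -> Dataset:
    return Dataset(P.schema, list(P.instances) + list(N.instances))


def _default_class(N: Dataset, fallback: str) -> str:
    counts = N.class_counts()
    if not counts:
        return fallback
    return max(sorted(counts), key=lambda c: counts[c])


def _positive_token(P: Dataset) -> str:
    tokens = {inst.label for inst in P.instances if inst.label is not None}
    if len(tokens) != 1:
        raise ValidationError(f"positive set must carry exactly one class token, got {tokens}")
    return tokens.pop()


def dl_prune_ruleset(
    rules: list[Rule],
    learner: _Learner,
    total_candidates: int,
) -> list[Rule]:
    """Reverse-order deletion of rules whose removal lowers total description length."""
    rules = list(rules)
    current = learner.ruleset_bits(rules, total_candidates)
    for i in range(len(rules) - 1, -1, -1):
        trial = rules[:i] + rules[i + 1 :]
        bits = learner.ruleset_bits(trial, total_candidates)
        if bits < current:
            rules = trial
            current = bits
    return rules


def prune_ruleset_dl(
    ruleset: RuleSet,
    P: Dataset,
    N: Dataset,
    params: InductionParams | None = None,
) -> RuleSet:
    """Public form of the final covering-pass pruning: reverse-order deletion
    of rules whose removal lowers the total description length of the set."""
    params = params or InductionParams()
    if not ruleset.rules:
        return RuleSet([], ruleset.default_class)
    combined = _combine(P, N)
    view = DatasetView(combined)
    learner = _Learner(view, ruleset.rules[0].consequent, params)
    total = mdl.count_candidate_conditions(combined)
    return RuleSet(dl_prune_ruleset(list(ruleset.rules), learner, total), ruleset.default_class)


def build_ruleset(
    P: Dataset,
    N: Dataset,
    params: InductionParams | None = None,
    rng: np.random.Generator | None = None,
) -> RuleSet:
    """Sequential covering of P against N with grow/prune and an MDL stop.

    Returns a decision list predicting P's class, with N's majority class as
    the default.
    """
    params = params or InductionParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if len(P) == 0:
        return RuleSet([], _default_class(N, fallback="0"))
    positive = _positive_token(P)
    default = _default_class(N, fallback=positive)

    combined = _combine(P, N)
    view = DatasetView(combined)
    learner = _Learner(view, positive, params)
    total_candidates = mdl.count_candidate_conditions(combined)

    active = np.ones(view.n, dtype=bool)
    rules: list[Rule] = []
    min_bits = learner.ruleset_bits(rules, total_candidates)
    static_split: tuple[np.ndarray, np.ndarray] | None = None

    while np.any(active & learner.pos):
        idx = np.flatnonzero(active)
        if params.resplit_per_rule or static_split is None:
            labels = [combined.instances[i].label for i in idx]
            g_rel, p_rel = _stratified_partition(labels, params.ratio, rng)
            static_split = (idx[g_rel], idx[p_rel])
        grow_idx, prune_idx = static_split
        grow_idx = grow_idx[active[grow_idx]]
        prune_idx = prune_idx[active[prune_idx]]
        grow_mask = np.zeros(view.n, dtype=bool)
        grow_mask[grow_idx] = True
        prune_mask = np.zeros(view.n, dtype=bool)
        prune_mask[prune_idx] = True

        if not np.any(grow_mask & learner.pos):
            break
        rule = learner.grow(grow_mask)
        if rule.antecedent:
            rule = learner.prune(rule, prune_mask)

        rule_mask = view.rule_mask(rule) & active
        p_covered = int(np.count_nonzero(rule_mask & learner.pos))
        err = learner.prune_error(rule, prune_mask)
        if err >= params.max_prune_error or p_covered < params.min_rule_coverage:
            break
        rules.append(rule)
        bits = learner.ruleset_bits(rules, total_candidates)
        if bits > min_bits + params.mdl.dl_budget_bits:
            rules = dl_prune_ruleset(rules, learner, total_candidates)
            return RuleSet(rules, default)
        min_bits = min(min_bits, bits)
        active &= ~rule_mask

    rules = dl_prune_ruleset(rules, learner, total_candidates)
    return RuleSet(rules, default)
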