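import math

import numpy as np
import pytest

from ripperlearn import mdl
from ripperlearn.errors import ValidationError
from ripperlearn.induction import (
    NEGATIVE_INFINITY,
    InductionParams,
    build_ruleset,
    foil_gain,
    grow_rule,
    prune_rule,
    prune_ruleset_dl,
    split_grow_prune,
)
from ripperlearn.rule_model import (
    Condition,
    CoverageStats,
    Rule,
    RuleSet,
    predict_dataset,
)
from ripperlearn.synth_data import PlantedConcept, generate_dataset, make_cleveland_like
from ripperlearn.tabular_data import Dataset, Instance


class TestSplit:
    def test_uci_sized_split(self):
        data = make_cleveland_like(303, seed=5)
        split = split_grow_prune(data, InductionParams(seed=5))
        assert len(split.grow) == 202  # round(2/3 * 303)
        assert len(split.prune) == 101

    def test_same_seed_identical(self):
        data = make_cleveland_like(60, seed=2)
        a = split_grow_prune(data, InductionParams(seed=9))
        b = split_grow_prune(data, InductionParams(seed=9))
        assert [i.values for i in a.grow.instances] == [i.values for i in b.grow.instances]
        assert [i.values for i in a.prune.instances] == [i.values for i in b.prune.instances]

    def test_union_is_input_multiset(self):
        data = make_cleveland_like(61, seed=3)
        split = split_grow_prune(data, InductionParams(seed=3))
        key = lambda i: tuple(sorted((k, repr(v)) for k, v in i.values.items()))
        combined = sorted(map(key, split.grow.instances)) + sorted(map(key, split.prune.instances))
        assert sorted(combined) == sorted(map(key, data.instances))

    def test_stratified_by_class(self):
        data = make_cleveland_like(300, seed=4)
        split = split_grow_prune(data, InductionParams(seed=4))
        for token, count in data.class_counts().items():
            grown = split.grow.class_counts().get(token, 0)
            assert abs(grown - (2 / 3) * count) <= 1

    def test_too_small_rejected(self):
        data = make_cleveland_like(1, seed=1)
        with pytest.raises(ValidationError):
            split_grow_prune(data, InductionParams())


class TestFoilGain:
    def test_frozen_arithmetic(self):
        gain = foil_gain(CoverageStats(10, 10), CoverageStats(6, 2))
        assert gain == pytest.approx(6 * (math.log2(0.75) - math.log2(0.5)))
        assert gain == pytest.approx(3.509775, abs=1e-5)

    def test_no_improvement_is_zero(self):
        assert foil_gain(CoverageStats(10, 10), CoverageStats(5, 5)) == pytest.approx(0.0)

    def test_zero_positive_cover_sentinel(self):
        assert foil_gain(CoverageStats(10, 10), CoverageStats(0, 3)) == NEGATIVE_INFINITY

    def test_no_positives_before_rejected(self):
        with pytest.raises(ValueError):
            foil_gain(CoverageStats(0, 10), CoverageStats(0, 2))


def _xy_data(simple_schema, rows):
    instances = []
    for x1, x2, c1, y in rows:
        instances.append(Instance({"x1": float(x1), "x2": float(x2), "x3": 0.0, "c1": c1}, y))
    return Dataset(simple_schema, instances)


class TestGrowRule:
    def test_single_threshold_recovered(self, simple_schema):
        rows = [(x, 0, "a", "1" if x <= 5 else "0") for x in range(1, 11)]
        rule = grow_rule(_xy_data(simple_schema, rows), "1")
        assert rule.antecedent == (Condition("x1", "<=", 5.0),)

    def test_pure_positives_give_empty_rule(self, simple_schema):
        rows = [(x, 0, "a", "1") for x in range(5)]
        rule = grow_rule(_xy_data(simple_schema, rows), "1")
        assert rule.antecedent == ()

    def test_no_positives_raises(self, simple_schema):
        rows = [(x, 0, "a", "0") for x in range(5)]
        with pytest.raises(ValidationError):
            grow_rule(_xy_data(simple_schema, rows), "1")

    def test_gain_tie_broken_by_attribute_order(self, simple_schema):
        # x1 and x2 carry identical information; earlier attribute must win
        rows = [(x, x, "a", "1" if x <= 5 else "0") for x in range(1, 11)]
        rule = grow_rule(_xy_data(simple_schema, rows), "1")
        assert rule.antecedent == (Condition("x1", "<=", 5.0),)

    def test_deterministic(self, simple_schema):
        rows = [(x, 10 - x, "a" if x % 2 else "b", "1" if x <= 4 else "0") for x in range(1, 11)]
        data = _xy_data(simple_schema, rows)
        assert grow_rule(data, "1") == grow_rule(data, "1")


class TestPruneRule:
    def test_full_rule_kept_when_tighter_wins(self, simple_schema):
        # prefix (x1<=50): 8 pos, 4 neg -> T=1/3; full rule adds x2<=50: 6 pos, 2 neg -> T=1/2
        rows = []
        rows += [(10, 10, "a", "1")] * 6   # full rule covers
        rows += [(10, 10, "a", "0")] * 2
        rows += [(10, 90, "a", "1")] * 2   # only the prefix covers
        rows += [(10, 90, "a", "0")] * 2
        rule = Rule((Condition("x1", "<=", 50), Condition("x2", "<=", 50)), "1")
        pruned = prune_rule(rule, _xy_data(simple_schema, rows), "1")
        assert pruned == rule

    def test_all_tied_gives_shortest(self, simple_schema):
        # every candidate covers equal positives and negatives -> T = 0 everywhere
        rows = [(10, 10, "a", "1"), (10, 10, "a", "0")]
        rule = Rule((Condition("x1", "<=", 50), Condition("x2", "<=", 50)), "1")
        pruned = prune_rule(rule, _xy_data(simple_schema, rows), "1")
        assert pruned.antecedent == (Condition("x1", "<=", 50),)

    def test_matches_brute_force_over_suffixes(self, simple_schema):
        rng = np.random.default_rng(11)
        rows = [
            (int(rng.integers(0, 20)), int(rng.integers(0, 20)),
             ["a", "b", "c"][rng.integers(0, 3)], str(rng.integers(0, 2)))
            for _ in range(30)
        ]
        data = _xy_data(simple_schema, rows)
        rule = Rule(
            (
                Condition("x1", "<=", 12),
                Condition("c1", "=", "a"),
                Condition("x2", ">=", 3),
            ),
            "1",
        )
        candidates = [Rule(rule.antecedent[:k], "1") for k in range(1, 4)]
        assert len(candidates) == 3

        def t_of(r):
            p = n = 0
            for inst in data.instances:
                if all(c.holds(inst.values[c.attribute]) for c in r.antecedent):
                    if inst.label == "1":
                        p += 1
                    else:
                        n += 1
            return 0.0 if p + n == 0 else (p - n) / (p + n)

        best = max(candidates, key=lambda r: (t_of(r), -len(r.antecedent)))
        assert prune_rule(rule, data, "1") == best


class TestBuildRuleset:
    def test_empty_positive_set(self, simple_schema):
        rows = [(x, 0, "a", "0") for x in range(10)]
        data = _xy_data(simple_schema, rows)
        rs = build_ruleset(Dataset(simple_schema, []), data, InductionParams())
        assert rs.rules == []
        assert rs.default_class == "0"

    def test_noiseless_threshold_concept(self, simple_schema, pn_split, accuracy_of):
        concept = PlantedConcept(
            RuleSet([Rule((Condition("x1", "<=", 40),), "1")], "0")
        )
        data = generate_dataset(simple_schema, concept, 200, seed=8)
        P, N = pn_split(data)
        rs = build_ruleset(P, N, InductionParams(seed=8))
        assert len(rs.rules) <= 2
        assert accuracy_of(rs, data) == 1.0

    def test_pure_noise_rarely_accepts_rules(self, simple_schema, pn_split):
        counts = []
        for seed in range(1, 21):
            rng = np.random.default_rng([seed, 77])
            data = generate_dataset(
                simple_schema, PlantedConcept(RuleSet([], "0")), 200, seed
            )
            for inst in data.instances:
                inst.label = "1" if rng.random() < 0.5 else "0"
            P, N = pn_split(data)
            rs = build_ruleset(P, N, InductionParams(seed=seed))
            counts.append(len(rs.rules))
        assert sum(c <= 1 for c in counts) >= 18
        assert max(counts) <= 3

    def test_termination_on_min_coverage(self, simple_schema, pn_split):
        data = generate_dataset(
            simple_schema,
            PlantedConcept(
                RuleSet([Rule((Condition("x2", ">=", 60),), "1")], "0"), noise_rate=0.1
            ),
            150,
            seed=13,
        )
        P, N = pn_split(data)
        rs = build_ruleset(P, N, InductionParams(seed=13, min_rule_coverage=5))
        # every accepted rule must cover at least 5 positives of the full data
        from ripperlearn.rule_model import coverage

        combined = Dataset(simple_schema, P.instances + N.instances)
        for rule in rs.rules:
            assert coverage(rule, combined, "1").p >= 5


class TestDlPruning:
    def test_never_increases_total_dl(self, simple_schema, pn_split, planted_ruleset):
        for seed in range(1, 11):
            data = generate_dataset(
                simple_schema, PlantedConcept(planted_ruleset, noise_rate=0.15), 150, seed
            )
            P, N = pn_split(data)
            rs = build_ruleset(P, N, InductionParams(seed=seed))
            junk = Rule((Condition("x3", ">=", 95),), "1")
            padded = RuleSet(rs.rules + [junk], rs.default_class)
            total = mdl.count_candidate_conditions(
                Dataset(simple_schema, P.instances + N.instances)
            )
            before = mdl.ruleset_dl(padded, P, N, total).total_bits
            pruned = prune_ruleset_dl(padded, P, N, InductionParams(seed=seed))
            after = mdl.ruleset_dl(pruned, P, N, total).total_bits
            assert after <= before + 1e-9
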