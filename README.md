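# ripperlearn

Sequential-covering rule induction for interpretable classification on tabular
clinical data, plus a static context-aware clinical screening rule set.

The learner is a RIPPER-style algorithm: rules are grown greedily by
information gain, pruned against a held-out prune split with the
`(p - n) / (p + n)` metric, accepted into an ordered decision list until a
description-length (MDL) budget is exceeded, and refined by optimization
rounds that compare each rule against a freshly grown replacement and a
revision by total description length. Multiclass problems are handled by
learning classes in increasing frequency order, with the most frequent class
as the default rule.

## Layout

| Module | Purpose |
| --- | --- |
| `ripperlearn.tabular_data` | Dataset schemas, CSV and Cleveland readers, clinical band discretizer |
| `ripperlearn.rule_model` | Conditions, rules, decision lists; matching, coverage, serialization |
| `ripperlearn.mdl` | Description-length accounting (theory + exception bits) |
| `ripperlearn.induction` | Grow/prune split, gain-driven growth, reduced-error pruning, covering loop |
| `ripperlearn.optimization` | Optimization rounds, top-level learner, multiclass trainer |
| `ripperlearn.evaluation` | Confusion counts, accuracy/precision/recall/specificity/F-score, cross-validation |
| `ripperlearn.context_engine` | Static 11-rule clinical screen over banded attributes |
| `ripperlearn.synth_data` | Synthetic data with planted rule structure and label noise |
| `ripperlearn.cli` | `ripperlearn` command: train / predict / evaluate / screen / simulate |

## CLI

```bash
# synthesize a Cleveland-like dataset with planted rule labels
ripperlearn simulate --n 300 --seed 1 --out data.csv

# train an ordered rule list (model is a versioned JSON document)
ripperlearn train data.csv --model model.json --seed 1 -v

# predict and evaluate
ripperlearn predict model.json data.csv --out predictions.csv
ripperlearn evaluate data.csv --folds 5 --seed 1

# run patient records through the clinical screening rules
ripperlearn screen records.csv --out assessments.csv
ripperlearn screen - --export-rules   # print the rule set in rule grammar
```

`train` and `evaluate` accept a flat `key=value` config file (`--config`);
explicit flags override the config. Every run prints a `key=value` prelude so
it can be reproduced from its log and a single seed.

Exit codes: `0` success, `2` usage, `3` I/O error, `4` schema/validation
error, `5` partial failure (some screen rows invalid).

### Cleveland data

`load_cleveland` reads either the headerless UCI `processed.cleveland.data`
layout (14 comma-separated columns) or a header-bearing CSV with the standard
column names; raw class values above 0 are collapsed to `1`. The file itself
is not bundled; point `RIPPERLEARN_CLEVELAND` at a local copy to enable the
record-count acceptance check.

## Notes

- Missing values (`?`) are preserved, never imputed; a missing value fails
  any rule condition, so the instance falls through to later rules.
- Clinical bands overlap by design; discretization is strictly first-match
  in declared order.
- The context rule set is applied in listed order, which leaves rule 8
  shadowed by rules 6–7 (and rule 11 by rule 9); `reachability_report()`
  documents this rather than repairing it.
- One circulating F-score variant puts a true-negative term in the
  denominator, disagreeing with the harmonic-mean definition; the standard F1
  is the default, and the legacy variant is available via `compute_metrics(..., f_score_variant="as_printed")`.
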