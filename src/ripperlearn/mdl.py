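"""Description-length accounting for rule sets.

Total cost = theory bits (encoding the rules) + data bits (encoding the
exceptions the decision list makes on the training data).  Used as the
stopping test during covering, for the final rule-set pruning pass and to
select among optimization variants.

The coding scheme is the classical one: each rule pays a redundancy-discounted
subset-selection cost for its conditions, and the data pays a
Quinlan-style exception cost where the larger of the covered/uncovered sides
is coded at an expected error rate and the smaller at its empirical rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .rule_model import DatasetView, Rule, RuleSet
from .tabular_data import MISSING, Dataset

#: Classical slack (bits) over the best description length seen so far.
DEFAULT_DL_BUDGET_BITS = 64.0

#: Alternative 11-bit budget seen in some transcriptions, selectable as a preset.
PRINTED_DL_BUDGET_BITS = 11.0


@dataclass(frozen=True)
class MDLParams:
    """Knobs of the description-length coding scheme."""

    redundancy_factor: float = 0.5
    expected_fp_over_err: float = 0.5
    dl_budget_bits: float = DEFAULT_DL_BUDGET_BITS

    def __post_init__(self) -> None:
        if self.dl_budget_bits <= 0:
            raise ValueError("dl_budget_bits must be positive")
        if not 0.0 <= self.expected_fp_over_err <= 1.0:
            raise ValueError("expected_fp_over_err must lie in [0, 1]")

    @classmethod
    def printed_budget(cls, **kwargs) -> "MDLParams":
        """Preset using the alternative 11-bit budget instead of the classical 64."""
        kwargs.setdefault("dl_budget_bits", PRINTED_DL_BUDGET_BITS)
        return cls(**kwargs)


@dataclass(frozen=True)
class DescriptionLength:
    theory_bits: float
    data_bits: float

    @property
    def total_bits(self) -> float:
        return self.theory_bits + self.data_bits


def subset_dl(n: int, k: int, p: float) -> float:
    """Bits to identify a k-subset of n items under inclusion probability p.

    Cost = -k*log2(p) - (n-k)*log2(1-p) with the 0*log2(0) := 0 convention.
    Impossible codes (k>0 with p=0, or k<n with p=1) return +inf.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability p={p} outside [0, 1]")
    bits = 0.0
    if k > 0:
        if p == 0.0:
            return math.inf
        bits -= k * math.log2(p)
    if n - k > 0:
        if p == 1.0:
            return math.inf
        bits -= (n - k) * math.log2(1.0 - p)
    return bits


def theory_dl(rule: Rule, total_candidate_conditions: int, params: MDLParams | None = None) -> float:
    """Bits to encode one rule given the size of the candidate condition pool."""
    params = params or MDLParams()
    k = len(rule.antecedent)
    if k == 0:
        return 0.0
    if total_candidate_conditions <= 0:
        raise ValueError("total_candidate_conditions must be positive for a non-empty rule")
    if k > total_candidate_conditions:
        raise ValueError("rule has more conditions than the candidate pool")
    bits = math.log2(k)
    if k > 1:
        bits += 2.0 * math.log2(math.log2(k))
    bits += subset_dl(total_candidate_conditions, k, k / total_candidate_conditions)
    return params.redundancy_factor * bits


def data_dl(cover: int, uncover: int, fp: int, fn: int, params: MDLParams | None = None) -> float:
    """Bits to encode the exceptions of a rule set on cover+uncover instances.

    The side (covered vs uncovered) holding more instances is coded at the
    expected error rate derived from ``expected_fp_over_err * (fp + fn)``; the
    smaller side is coded at its empirical error rate.
    """
    params = params or MDLParams()
    if min(cover, uncover, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if fp > cover:
        raise ValueError("fp cannot exceed cover")
    if fn > uncover:
        raise ValueError("fn cannot exceed uncover")
    total = cover + uncover
    bits = math.log2(total + 1)
    err = fp + fn
    expected_fp = params.expected_fp_over_err * err
    expected_fn = (1.0 - params.expected_fp_over_err) * err
    if cover >= uncover:
        p_cov = min(expected_fp / cover, 1.0) if cover else 0.0
        p_unc = fn / uncover if uncover else 0.0
    else:
        p_cov = fp / cover if cover else 0.0
        p_unc = min(expected_fn / uncover, 1.0) if uncover else 0.0
    bits += subset_dl(cover, fp, p_cov)
    bits += subset_dl(uncover, fn, p_unc)
    return bits


def count_candidate_conditions(data: Dataset) -> int:
    """Size of the condition pool over ``data``.

    Categorical attributes contribute |categories|; numeric attributes
    contribute two conditions (<=, >=) per distinct observed value.
    """
    total = 0
    for spec in data.schema.attributes:
        if spec.is_numeric:
            values = {
                float(inst.values[spec.name])
                for inst in data.instances
                if inst.values[spec.name] is not MISSING
            }
            total += 2 * len(values)
        else:
            total += len(spec.categories)
    return total


def _exception_counts(rules, pos_view: DatasetView, neg_view: DatasetView):
    cov_p = int(pos_view.covered_mask(rules).sum()) if pos_view.n else 0
    cov_n = int(neg_view.covered_mask(rules).sum()) if neg_view.n else 0
    cover = cov_p + cov_n
    uncover = pos_view.n + neg_view.n - cover
    fp = cov_n
    fn = pos_view.n - cov_p
    return cover, uncover, fp, fn


def ruleset_dl(
    ruleset: RuleSet,
    P: Dataset,
    N: Dataset,
    total_candidate_conditions: int,
    params: MDLParams | None = None,
) -> DescriptionLength:
    """Theory + exception bits of ``ruleset`` as a positive-class cover of P vs N.

    An instance counts as covered when any rule matches it; exceptions are
    covered negatives (fp) and uncovered positives (fn).
    """
    params = params or MDLParams()
    theory = sum(theory_dl(r, total_candidate_conditions, params) for r in ruleset.rules)
    cover, uncover, fp, fn = _exception_counts(
        ruleset.rules, DatasetView(P), DatasetView(N)
    )
    data_bits = data_dl(cover, uncover, fp, fn, params)
    return DescriptionLength(theory_bits=theory, data_bits=data_bits)
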