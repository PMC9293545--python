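import numpy as np
import pytest

from ripperlearn.rule_model import Condition, Rule, RuleSet
from ripperlearn.synth_data import PlantedConcept, generate_dataset
from ripperlearn.tabular_data import AttributeSpec, Dataset, DatasetSchema

# Two reference sample records (restecg is absent from the sample and left
# missing).
TABLE3_CSV = (
    "age,sex,cp,trestbps,chol,fbs,restecg,thalach,exang,oldpeak,slope,ca,thal,num\n"
    "55,0,3,115,322,0,?,160,0,1.6,2,0,7,0\n"
    "74,1,2,124,261,0,?,141,0,0.3,1,0,7,1\n"
)


@pytest.fixture
def table3_csv(tmp_path):
    path = tmp_path / "sample.csv"
    path.write_text(TABLE3_CSV)
    return path


@pytest.fixture
def simple_schema():
    return DatasetSchema(
        attributes=(
            AttributeSpec("x1", "numeric", numeric_range=(0, 100), integer_valued=True),
            AttributeSpec("x2", "numeric", numeric_range=(0, 100), integer_valued=True),
            AttributeSpec("x3", "numeric", numeric_range=(0, 100), integer_valued=True),
            AttributeSpec("c1", "categorical", ("a", "b", "c")),
        ),
        class_attribute=AttributeSpec("y", "categorical", ("0", "1")),
    )


@pytest.fixture
def planted_ruleset():
    return RuleSet(
        [
            Rule((Condition("x1", "<=", 30), Condition("c1", "=", "a")), "1"),
            Rule((Condition("x2", ">=", 70), Condition("x3", "<=", 40)), "1"),
        ],
        "0",
    )


@pytest.fixture
def make_planted(simple_schema, planted_ruleset):
    """Factory: planted-concept dataset of size n with optional noise."""

    def _make(n, seed, noise_rate=0.0):
        concept = PlantedConcept(planted_ruleset, noise_rate=noise_rate)
        return generate_dataset(simple_schema, concept, n, seed)

    return _make


def split_pn(data):
    """Split a labeled binary dataset into (positives '1', negatives)."""
    P = Dataset(data.schema, [i for i in data.instances if i.label == "1"])
    N = Dataset(data.schema, [i for i in data.instances if i.label != "1"])
    return P, N


@pytest.fixture
def pn_split():
    return split_pn


def training_accuracy(ruleset_or_model, data):
    from ripperlearn.rule_model import RuleSet as _RS, predict_dataset

    if isinstance(ruleset_or_model, _RS):
        preds = predict_dataset(ruleset_or_model, data)
    else:
        preds = ruleset_or_model.predict_dataset(data)
    return float(np.mean([p == inst.label for p, inst in zip(preds, data.instances)]))


@pytest.fixture
def accuracy_of():
    return training_accuracy
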