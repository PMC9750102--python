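import numpy as np
import pandas as pd
import pytest

from omicsqc import (
    EvaluationConfig,
    FixtureSpec,
    OmicsDataTable,
    SampleAnnotation,
    Scale,
    generate_dataset,
)


def make_table(values, name="T", scale=Scale.LOG2, features=None, samples=None):
    arr = np.asarray(values, dtype=float)
    features = features or [f"f{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(arr.shape[1])]
    return OmicsDataTable(
        name, pd.DataFrame(arr, index=features, columns=samples), scale
    )


def make_annotation(samples, classes=None, batches=None, order=None, is_qc=None):
    n = len(samples)
    df = pd.DataFrame(index=pd.Index(samples, name="sample"))
    df["class_label"] = classes or ["c1"] * n
    df["batch"] = batches or ["B1"] * n
    df["order"] = order if order is not None else np.nan
    df["is_qc"] = is_qc if is_qc is not None else False
    return SampleAnnotation(df)


@pytest.fixture
def config():
    return EvaluationConfig(random_seed=7)


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic dataset shared by read-only tests."""
    return generate_dataset(FixtureSpec(seed=11))
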