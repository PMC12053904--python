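import numpy as np
import pandas as pd
import pytest

from tideline.tables import FeatureTable, make_metadata


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    data = pd.DataFrame(
        [[2.0, 2.0, 0.0],
         [1.0, 0.0, 0.0],
         [3.0, 4.5, 1.5],
         [0.5, 0.5, 1.0]],
        index=["s1", "s2", "s3", "s4"], columns=["ga", "gb", "gc"])
    return FeatureTable(data, feature_kind="genus", value_kind="rpkm")


@pytest.fixture
def small_metadata():
    return make_metadata(
        ["s1", "s2", "s3", "s4"],
        ["2020-01-15", "2020-02-15", "2020-03-15", "2021-01-15"],
        stage=["pre", "pre", "pre", "spill"],
        period=["baseline", "baseline", "baseline", "post"])


def random_table(rng, n_samples, n_features, prefix="f"):
    data = pd.DataFrame(
        rng.uniform(0.1, 10.0, size=(n_samples, n_features)),
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"{prefix}{j}" for j in range(n_features)])
    return FeatureTable(data, feature_kind="taxon", value_kind="rpkm")
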