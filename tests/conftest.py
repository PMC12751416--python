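import warnings

import numpy as np
import pandas as pd
import pytest

from bacfilter.io import CountMatrix
from bacfilter.simulate import SimConfig, generate_experiment


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def experiment():
    """One default synthetic experiment shared across tests."""
    return generate_experiment(SimConfig(seed=7))


@pytest.fixture(scope="session")
def filter_counts(experiment):
    ids = experiment.meta.index[experiment.meta["compartment"] == "filter"]
    return experiment.counts.subset_samples(
        [s for s in experiment.counts.samples if s in ids]
    )


@pytest.fixture
def toy_counts():
    """3 taxa x 2 samples, hand-checkable."""
    return CountMatrix(
        pd.DataFrame(
            {"s1": [5, 0, 1], "s2": [2, 3, 0]},
            index=["t1", "t2", "t3"],
            dtype=np.int64,
        ),
        taxonomy={"t1": "Bacteria; Proteobacteria", "t2": "Bacteria; Chloroplast",
                  "t3": "Bacteria; Bacteroidota"},
    )
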