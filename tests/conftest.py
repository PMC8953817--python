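import logging

import numpy as np
import pandas as pd
import pytest

from mitecomm.datamodel import CommunityMatrix, EnvironmentTable
from mitecomm.synthetic import default_spec, generate

logging.getLogger("mitecomm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def preset_data():
    """The packaged study-preset synthetic survey (seed 1): 250 x 30."""
    return generate(default_spec(), 1)


@pytest.fixture
def toy_community():
    """4 samples, 3 species, 2 plots; small enough for hand arithmetic."""
    counts = pd.DataFrame(
        [[2, 0, 1], [1, 3, 0], [0, 1, 4], [0, 0, 2]],
        index=["s1", "s2", "s3", "s4"], columns=["x", "y", "z"])
    plot_of = pd.Series(["A", "A", "B", "B"], index=counts.index)
    return CommunityMatrix(counts, plot_of)


def make_community(counts, plots):
    counts = np.asarray(counts)
    idx = [f"s{i}" for i in range(counts.shape[0])]
    cols = [f"sp{j}" for j in range(counts.shape[1])]
    return CommunityMatrix(pd.DataFrame(counts, index=idx, columns=cols),
                           pd.Series(list(plots), index=idx))


@pytest.fixture
def env_round_trip_frame():
    return pd.DataFrame(
        {"VegCovr": [75.96, 57.28], "H": [69.0, 61.5], "Ts": [14.7, 17.0],
         "pH": [5.05, 4.55], "RPs": [1.30, 1.39]},
        index=["s1", "s2"])
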