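import numpy as np
import pandas as pd
import pytest

from meiocovar import NucleusMatrix, generate, male_like_config


def make_matrix(counts, axis=None, columns=None, sex_label=""):
    """Build a NucleusMatrix from a plain nested list / array."""
    counts = np.asarray(counts)
    n, m = counts.shape
    cols = columns or [f"chr{j + 1}" for j in range(m)]
    idx = pd.Index([f"n{i}" for i in range(n)], name="nucleus_id")
    cdf = pd.DataFrame(counts, index=idx, columns=cols)
    adf = None
    if axis is not None:
        adf = pd.DataFrame(np.asarray(axis, dtype=float), index=idx,
                           columns=cols)
    return NucleusMatrix(cdf, adf, sex_label)


@pytest.fixture(scope="session")
def male_small():
    """Male-like synthetic matrix, small but big enough for stable statistics."""
    return generate(male_like_config(n_nuclei=400, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
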