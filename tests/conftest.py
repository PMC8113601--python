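import numpy as np
import pandas as pd
import pytest

from radstack.core_data import LabelVector, OmicsDataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def imbalanced_labels():
    """100-sample cohort with the 4:1 sensitive:resistant imbalance."""
    ids = [f"S{i:03d}" for i in range(100)]
    y = np.zeros(100, dtype=int)
    y[:20] = 1
    np.random.default_rng(1).shuffle(y)
    return LabelVector.from_labels(ids, y)


@pytest.fixture
def small_dataset(rng):
    ids = [f"S{i:03d}" for i in range(30)]
    X = pd.DataFrame(
        rng.normal(size=(30, 6)),
        index=ids,
        columns=[f"f{j}" for j in range(6)],
    )
    return OmicsDataset("expression", "expression", X)
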