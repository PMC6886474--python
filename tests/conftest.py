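import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from molscreen.synthetic import SyntheticSpec, generate_training_dataset
from molscreen.table import ACTIVE, BINARY, CONTINUOUS, INACTIVE, FeatureTable


def make_table(X, y=None, binary=None, ic50=None, source=None, name="test"):
    """Build a FeatureTable from plain arrays."""
    X = np.asarray(X, float)
    n, d = X.shape
    cols = [f"F{j:02d}" for j in range(d)]
    rows = [f"R{i:03d}" for i in range(n)]
    if binary is None:
        binary = [False] * d
    kinds = pd.Series(
        [BINARY if b else CONTINUOUS for b in binary], index=cols
    )
    labels = None
    if y is not None:
        labels = pd.Series(
            [ACTIVE if v else INACTIVE for v in np.asarray(y)], index=rows
        )
    return FeatureTable(
        data=pd.DataFrame(X, index=rows, columns=cols),
        col_kind=kinds,
        labels=labels,
        ic50=None if ic50 is None else pd.Series(np.asarray(ic50, float), index=rows),
        source=None if source is None else pd.Series(list(source), index=rows),
        name=name,
    )


def small_labeled_table(seed=0, n=120, d_inf=3, d_noise=5, effect=1.5):
    """Random labeled table with a few informative continuous columns."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, d_inf + d_noise))
    X[:, :d_inf] += effect * y[:, None]
    return make_table(X, y=y)


@pytest.fixture
def labeled_table():
    return small_labeled_table()


@pytest.fixture
def train_dataset():
    spec = SyntheticSpec(
        n_active=120,
        n_inactive=80,
        n_informative=6,
        n_redundant=3,
        n_zero_variance=3,
        n_noise=8,
        effect_size=1.5,
        frac_binary=0.4,
        seed=11,
    )
    return generate_training_dataset(spec)
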