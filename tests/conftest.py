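import numpy as np
import pandas as pd
import pytest

from permsvr.io import CompoundRecord, CompoundTable


def make_table(X, ids=None, names=None, y=None, pkas=None):
    """Build a CompoundTable from a plain array (test helper)."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    ids = ids or [f"c{i}" for i in range(n)]
    names = names or [f"d{j}" for j in range(d)]
    records = [
        CompoundRecord(
            ids[i],
            pkas=None if pkas is None else pkas[i],
            log_peff=None if y is None else float(y[i]),
        )
        for i in range(n)
    ]
    return CompoundTable(records, pd.DataFrame(X, columns=names))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def linear_table(rng):
    """60 compounds, 3 descriptors, response linear in the first two."""
    X = rng.normal(size=(60, 3))
    y = -4.0 + 0.8 * X[:, 0] - 0.5 * X[:, 1] + 0.01 * rng.normal(size=60)
    return make_table(X, y=y), y
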