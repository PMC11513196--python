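import warnings

import numpy as np
import pandas as pd
import pytest

import stabnet as sn
from stabnet.datatypes import DataTable
from stabnet.transforms import standardize


def make_table(X: np.ndarray, role: str = "trait") -> DataTable:
    cols = [f"v{i:02d}" for i in range(X.shape[1])]
    return DataTable(pd.DataFrame(X, columns=cols), {c: role for c in cols})


def standardized_sample(spec, n, seed):
    tab = sn.sample_mvn(spec, n, seed=seed)
    out, _ = standardize(tab)
    return out


@pytest.fixture(scope="session")
def planted12():
    """Planted sparse model p=12 (16 edges, |rho| in [.2,.4]) with n=400 sample."""
    spec = sn.make_precision(12, 16 / 66, (0.2, 0.4), seed=100)
    table = standardized_sample(spec, 400, seed=200)
    return spec, table


@pytest.fixture(scope="session")
def fitted12(planted12):
    spec, table = planted12
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sn.AdaptiveGGM(table, B=200, seed=5).fit()
    return spec, table, res


@pytest.fixture(autouse=True)
def _quiet_numerics():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield
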