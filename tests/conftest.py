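import numpy as np
import pytest

from ensuq.adapters import register_technique


def _mean_factory(hp, seed):
    from sklearn.dummy import DummyRegressor

    return DummyRegressor(strategy="mean")


def _linreg_factory(hp, seed):
    from sklearn.linear_model import LinearRegression

    return LinearRegression()


def _knn1_factory(hp, seed):
    from sklearn.neighbors import KNeighborsRegressor

    return KNeighborsRegressor(n_neighbors=1)


register_technique("mean", _mean_factory)
register_technique("linreg", _linreg_factory)
register_technique("knn1", _knn1_factory)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table(tmp_path):
    """3-row compound CSV on disk."""
    path = tmp_path / "toy.csv"
    path.write_text("id,smiles,target\nA,CCO,4.0\nB,CCC,5.5\nC,c1ccccc1,6.25\n")
    return path
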