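import numpy as np
import pytest

import pedeval as pe


@pytest.fixture(scope="session")
def mdm_spec():
    return pe.load_fixture("table3_mdm")


@pytest.fixture(scope="session")
def global_weights():
    return pe.load_fixture("table3_global_weights")


@pytest.fixture(scope="session")
def af_mf_block():
    return pe.load_fixture("table3_af_mf")


@pytest.fixture(scope="session")
def index_matrix():
    return pe.load_fixture("table4_malmquist")


def make_panel(x, y, dmu_ids=None, period_ids=None, input_names=None, output_names=None):
    """Assemble a PanelDataset from (n, T, m) and (n, T, s) arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, T, m = x.shape
    s = y.shape[2]
    return pe.PanelDataset(
        dmu_ids=dmu_ids or [f"D{j}" for j in range(n)],
        period_ids=period_ids or [f"t{t}" for t in range(T)],
        input_names=input_names or [f"x{i}" for i in range(m)],
        output_names=output_names or [f"y{r}" for r in range(s)],
        x=x,
        y=y,
    )


@pytest.fixture
def two_dmu_panel():
    # A=(x=1,y=1) efficient, B=(x=2,y=1) half-efficient
    return make_panel([[[1.0]], [[2.0]]], [[[1.0]], [[1.0]]], dmu_ids=["A", "B"])


@pytest.fixture
def two_input_panel():
    # frontier point (1,1)->1; evaluated point (2,4)->1
    return make_panel(
        [[[1.0, 1.0]], [[2.0, 4.0]]], [[[1.0]], [[1.0]]], dmu_ids=["F", "Z"]
    )


def random_panel(rng, n=10, T=2, m=3, s=2):
    x = np.exp(rng.normal(1.0, 0.4, size=(n, T, m)))
    y = np.exp(rng.normal(0.5, 0.4, size=(n, T, s)))
    return make_panel(x, y)
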