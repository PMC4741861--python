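import numpy as np
import pandas as pd
import pytest

from lncgo.io_normalize import SignalMatrix
from lncgo.synth import FixtureSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, strictly positive RPM values."""
    data = pd.DataFrame(
        [[1.0, 3.0, 7.0, 15.0], [2.0, 2.0, 4.0, 8.0], [5.0, 1.0, 3.0, 1.0]],
        index=["G1", "G2", "G3"],
        columns=["cA", "cB", "cC", "cD"],
    )
    return SignalMatrix(feature_label="H3K4me3", data=data, state="rpm")


@pytest.fixture(scope="session")
def default_fixture():
    """One deterministic synthetic study shared across tests."""
    return generate(FixtureSpec(seed=42))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A small synthetic study written to disk for file-path tests."""
    out = tmp_path_factory.mktemp("fixture")
    spec = FixtureSpec(
        seed=7,
        n_terms=1,
        genes_per_term=25,
        n_background_genes=120,
        n_lncrnas_pos=10,
        n_lncrnas_neg=10,
    )
    generate(spec, out)
    return out
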