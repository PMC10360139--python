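import numpy as np
import pytest

from rbekit import flint, synthetic
from rbekit.lqm import LQParams


@pytest.fixture(scope="session")
def table_model():
    return flint.TABLE_DEFAULT


@pytest.fixture(scope="session")
def small_dataset():
    """Clean 30-record paired dataset on the three-point LET grid."""
    cfg = synthetic.GeneratorConfig(
        n_cell_lines=10, true_params=flint.TABLE_DEFAULT, seed=42
    )
    records, truth = synthetic.generate(cfg)
    return records, truth


@pytest.fixture(scope="session")
def continuum_dataset():
    """Clean 60-record dataset with LET drawn from the 0.5-37.8 continuum."""
    cfg = synthetic.GeneratorConfig(
        n_cell_lines=60,
        let_values=None,
        let_range=(0.5, 37.8),
        true_params=flint.TABLE_DEFAULT,
        seed=7,
    )
    records, truth = synthetic.generate(cfg)
    return records, truth


@pytest.fixture
def photon_curve():
    return LQParams(alpha=0.3, beta=0.03)


@pytest.fixture
def photon_curve_with_cov():
    cov = np.array([[0.0009, -0.000072], [-0.000072, 0.0000090]])
    return LQParams(alpha=0.3, beta=0.03, cov=cov)
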