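import numpy as np
import pytest

from handover.bayes import ModelParams
from handover.endpoint import CalibrationConfig, UncertaintyTable, calibrate_uncertainty


@pytest.fixture(scope="session")
def table() -> UncertaintyTable:
    """Default Monte-Carlo endpoint-uncertainty table (shared: ~0.5 s to build)."""
    return calibrate_uncertainty(
        CalibrationConfig(), np.arange(0.05, 1.001, 0.05), sigma=0.005, n_mc=1000, seed=1
    )


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture()
def shrinking_table() -> UncertaintyTable:
    """Synthetic isotropic table whose variance shrinks geometrically in fraction."""
    fractions = np.linspace(0.05, 1.0, 20)
    variances = 0.05 * 0.65 ** np.arange(20)
    covs = variances[:, None, None] * np.eye(2)[None, :, :]
    return UncertaintyTable(fractions, covs, {"family": "synthetic"})
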