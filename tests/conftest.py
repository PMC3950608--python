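import numpy as np
import pytest

from ringswitch import RingGrid, ModelParams, build_input
from ringswitch.response_characterization import calibrate_lambda_of_contrast


@pytest.fixture(scope="session")
def grid():
    return RingGrid()


@pytest.fixture(scope="session")
def base_params():
    return ModelParams()


@pytest.fixture(scope="session")
def contrast_map():
    """Calibrated operating-line map (anchored c50); shared across tests."""
    return calibrate_lambda_of_contrast()


@pytest.fixture(scope="session")
def simple_input(grid):
    return build_input(grid, "simple_1D")


@pytest.fixture(scope="session")
def complex_input_fig(grid):
    """The fixed-weight (w_1D = 0.5) barberpole input."""
    return build_input(grid, "complex", w_1D=0.5)


@pytest.fixture(scope="session")
def switching_params():
    """Slow-adaptation operating point used for the switching studies."""
    return ModelParams(lambda_=25.0, k_alpha=0.01, k_I=0.01,
                       tau_alpha=16500.0)


@pytest.fixture(scope="session")
def small_ensembles(contrast_map):
    """Two small stochastic ensembles (low/high contrast), shared by the
    switching-analysis tests to keep the suite fast."""
    from ringswitch.switching_analysis import run_switching_ensemble

    out = {}
    for j, c in enumerate((0.04, 0.08)):
        out[c] = run_switching_ensemble(c, contrast_map, n_reps=30,
                                        seed=101 + j)
    return out
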