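import numpy as np
import pytest

from vesolv.synthetic import SolubilizationParams


@pytest.fixture
def paper_condition_params():
    """Fast-solubilization condition used throughout: no cholesterol,
    doubled detergent; short pre-injection window to keep tests quick."""
    return SolubilizationParams(
        E0=0.46,
        E_plateau=0.22,
        t_E=1.2,
        t_L=17.6,
        f_loss=0.5,
        I_tot0=1000.0,
        t0=20.0,
        frame_dt=0.05,
        duration=170.0,
        background=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
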