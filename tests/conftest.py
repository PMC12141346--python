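import numpy as np
import pytest

from rlsm.data import SyntheticSpec
from rlsm.experiment import default_config
from rlsm.liquid import LiquidConfig
from rlsm.neurons import LIFParams
from rlsm.wta import RSTDPParams, WTAConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lif_noref():
    """LIF parameters with the refractory period disabled (closed-form tests)."""
    return LIFParams(t_ref=0.0)


@pytest.fixture
def tiny_spec():
    """A very small synthetic task for fast end-to-end tests."""
    return SyntheticSpec(
        n_classes=2,
        n_channels=20,
        n_samples_per_class=8,
        n_test_per_class=4,
        duration=0.2,
        seed=7,
    )


@pytest.fixture
def tiny_config(tiny_spec):
    cfg = default_config(synthetic=tiny_spec)
    import dataclasses

    small = LiquidConfig(
        n_neurons=27,
        grid_shape=(3, 3, 3),
        n_input_channels=tiny_spec.n_channels,
        seed=0,
    )
    wta = WTAConfig(n_excitatory=6, n_inhibitory=2)
    liquid2 = dataclasses.replace(
        small, n_input_channels=wta.n_excitatory, seed=1
    )
    return dataclasses.replace(cfg, liquid1=small, liquid2=liquid2, wta=wta)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield
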