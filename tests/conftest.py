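import numpy as np
import pytest

from fretbayes.data import FretDataset, SampleMeasurements
from fretbayes.simulate import SimulationConfig, default_kappa, simulate_dataset
from fretbayes.spectral import ModelParams


@pytest.fixture(scope="session")
def kappa():
    return default_kappa()


@pytest.fixture(scope="session")
def fig2_config():
    """Three cells at 0.2/1/5 uM, truth Kd = 1 uM, E_fr = 0.4, n = 10, 5% noise."""
    return SimulationConfig(
        params=ModelParams(Kd=1e-6, E_fr=0.4),
        D0_vec=(0.2e-6, 1e-6, 5e-6),
        A0_vec=(0.2e-6, 1e-6, 5e-6),
        n=10,
        kappa=default_kappa(),
        r=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def fig2_dataset(fig2_config):
    return simulate_dataset(fig2_config)


@pytest.fixture()
def single_sample(kappa):
    """One noisy sample at moderate concentrations for cheap likelihood tests."""
    cfg = SimulationConfig(
        params=ModelParams(Kd=1e-6, E_fr=0.4),
        D0_vec=(1e-6,),
        A0_vec=(8e-7,),
        n=6,
        kappa=kappa,
        r=0.05,
        seed=21,
    )
    return simulate_dataset(cfg).samples[0]


def make_sample(intensities, sample_id="s"):
    return SampleMeasurements(sample_id=sample_id, intensities=np.asarray(intensities, float))


def make_dataset(samples):
    return FretDataset(samples=list(samples))
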