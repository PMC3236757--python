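import numpy as np
import pytest

from econets.signals import Band
from econets.simulate import (
    SimulationConfig,
    TopologyConfig,
    null_strengths,
    planted_interaction_strengths,
)

BETA = Band("beta", 15.05, 31.25)


def scaled_cohort_config(
    seed: int,
    strengths: dict | None = None,
    n_per_group: int = 15,
    n_epochs: int = 1,
    n_channels: int = 16,
    duration_slope: float = -0.04,
) -> SimulationConfig:
    """Small-footprint study configuration used by the simulation checks.

    Single beta band at 125 Hz, 8-s epochs, 16 channels, a Watts-Strogatz
    coupling graph at cost 0.30 with 30% rewiring; planted-interaction
    strengths unless overridden.
    """
    return SimulationConfig(
        n_channels=n_channels,
        fs=125.0,
        epoch_len=8.0,
        n_epochs=n_epochs,
        n_per_group=n_per_group,
        bands=(BETA,),
        topology=TopologyConfig(model="ws", cost=0.30, rewire_p=0.3),
        coupling_strength=strengths or planted_interaction_strengths(),
        background_strengths={},
        lattice_strength=1.2,
        duration_slope=duration_slope,
        noise_sd=1.0,
        seed=seed,
    )


def null_cohort_config(seed: int, n_per_group: int = 5, n_channels: int = 16) -> SimulationConfig:
    """No planted effects: all four group x condition cells equal."""
    return scaled_cohort_config(
        seed,
        strengths=null_strengths(1.0),
        n_per_group=n_per_group,
        n_channels=n_channels,
        duration_slope=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
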