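"""Shared fixtures: simulated experiments at known noise levels.

Session-scoped because the generators are deterministic — every test sees
the same objects for a given seed, and the heavier end-to-end fixtures are
built once.
"""

from __future__ import annotations

import pytest

import lipidraft as lr

NOISE_FREE_SEED = 7
NOISY_SEED = 11


@pytest.fixture(scope="session")
def noise_free_experiment():
    """5 species/subclass, 2 groups x 3 replicates, all noise off."""
    config = lr.SimulationConfig(
        seed=NOISE_FREE_SEED,
        area_noise_sigma=0.0,
        rt_jitter_sd=0.0,
        fragment_noise_sigma=0.0,
        contaminant_peaks=0,
        n_decoy_library=0,
        n_unknown_features=0,
    )
    library, truth = lr.generate_library(config)
    features, samples, truth = lr.generate_experiment(library, truth, config)
    return config, library, features, samples, truth


@pytest.fixture(scope="session")
def noisy_experiment():
    """Default study conditions: log-normal area/fragment noise, RT jitter,
    10 decoys, 10 unknown features."""
    config = lr.SimulationConfig(seed=NOISY_SEED)
    library, truth = lr.generate_library(config)
    features, samples, truth = lr.generate_experiment(library, truth, config)
    return config, library, features, samples, truth


@pytest.fixture(scope="session")
def noise_free_quant(noise_free_experiment):
    """Identifications and quant records for the noise-free experiment."""
    _, library, features, samples, truth = noise_free_experiment
    identifications = lr.identify(features, library)
    records = lr.build_quant_table(identifications, features, samples, library)
    return identifications, records


@pytest.fixture(scope="session")
def small_library():
    """A compact library (1 species/subclass, no decoys) for I/O tests."""
    config = lr.SimulationConfig(seed=3, n_species_per_subclass=1, n_decoy_library=0)
    library, _ = lr.generate_library(config)
    return library
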