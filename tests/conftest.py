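import numpy as np
import pytest
from hypothesis import settings

from neuralign import SimulationConfig, generate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def small_sim_config(**overrides) -> SimulationConfig:
    """A scaled-down cohort used throughout the suite: 3 groups of a few
    subjects, few channels, short statements — the same generative model as
    the default configuration, just cheaper."""
    params = dict(
        group_sizes=(5, 5, 5),
        n_channels=8,
        sampling_rate=100.0,
        n_statements=6,
        statement_duration_range=(4.0, 6.0),
        pause_duration=1.0,
        shared_snr_schedule=((0.0, 0.1, 0.5), (0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
        seed=7,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


def planted_group(M, C, T, snr, seed, coupling=1.0, fs=150.0, band=(0.5, 4.0),
                  scale=True):
    """Directly synthesize one group's slot data with a planted rank-1 shared
    source (no event machinery), returning (data, source, mixing).

    With ``scale=False`` channels are mean-centered but not variance-scaled:
    noise is homoscedastic by construction, so the planted mixing vector stays
    the signal direction of the analyzed space — the clean design for
    activation-pattern recovery studies (per-channel standardization rescales
    the sensor geometry and with it the mixing direction).
    """
    from neuralign import generate_shared_source
    from neuralign.simulate import SimulationConfig as _SC, _band_noise

    rng = np.random.default_rng(seed)
    source = generate_shared_source(T / fs, band, fs, seed=int(rng.integers(2**31)))[:T]
    mixing = rng.standard_normal((M, C))
    mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)
    cfg = _SC(n_groups=1, group_sizes=(M,), n_channels=C, sampling_rate=fs,
              shared_snr_schedule=((0.0, 0.0, 0.0),), agreement_trend=(0.0,),
              agreement_baseline=(2.0,), source_band=band)
    data = []
    for i in range(M):
        noise = _band_noise(rng, (C, T), cfg)
        X = noise + coupling * snr * np.sqrt(C) * np.outer(mixing[i], source)
        X = X - X.mean(axis=1, keepdims=True)
        if scale:
            X = X / X.std(axis=1, keepdims=True)
        data.append(X)
    return data, source, mixing
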