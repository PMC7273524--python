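import numpy as np
import pytest

from tpewas import GeneticArchitecture, simulate_cohort, simulate_ecg


@pytest.fixture(scope="session")
def clean_ecg():
    """Zero-noise synthetic exercise ECG at the default protocol."""
    return simulate_ecg(seed=7)


@pytest.fixture(scope="session")
def noisy_ecg():
    """Synthetic ECG with 0.05 mV white noise and baseline wander."""
    return simulate_ecg(noise_sd=0.05, wander_amp=0.1, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """2,000 individuals x 500 variants, h2 = 0.156."""
    arch = GeneticArchitecture(
        n_individuals=2000, n_variants=500, h2=0.156, seed=42
    )
    return simulate_cohort(arch)


@pytest.fixture(scope="session")
def null_cohort():
    """2,000 individuals x 10,000 variants, h2 = 0 (null GWAS)."""
    arch = GeneticArchitecture(
        n_individuals=2000, n_variants=10000, h2=0.0, seed=13
    )
    return simulate_cohort(arch)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
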