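import numpy as np
import pytest

from fnirs_decnef import (
    EffectMap,
    Montage,
    NoiseSpec,
    extract_patterns,
    make_design,
    simulate_concentrations,
)


@pytest.fixture(scope="session")
def small_montage() -> Montage:
    """Four-channel montage with the standard wavelengths and rate."""
    return Montage(n_channels=4)


@pytest.fixture(scope="session")
def default_montage() -> Montage:
    return Montage()


@pytest.fixture(scope="session")
def small_schedule():
    """Six blocks per condition, enough for 4-bin averaging in tests."""
    return make_design(6, seed=11)


@pytest.fixture(scope="session")
def small_effect_session(small_montage, small_schedule):
    """Small conflict-effect session: (schedule, concentrations)."""
    effect = EffectMap.conflict(
        small_montage.n_channels, n_effect_channels=2
    )
    conc = simulate_concentrations(
        small_montage, small_schedule, effect, NoiseSpec(), seed=42
    )
    return small_schedule, conc


@pytest.fixture(scope="session")
def small_patterns(small_effect_session):
    schedule, conc = small_effect_session
    return extract_patterns(conc, schedule)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
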