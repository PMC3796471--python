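import numpy as np
import pytest
from hypothesis import settings

from anuraprop import propagation, signals, spl

settings.register_profile("ci", derandomize=True, max_examples=40,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tone_playback():
    """Tones-only broadcast program (29 probe tones, white noise, level
    reference), used by most propagation-chain tests."""
    return signals.assemble_playback(calls=[], seed=7)


@pytest.fixture(scope="session")
def mini_playback():
    """Small program (3 tones, 1 individual per species) for fast end-to-end
    checks."""
    tones = [signals.ToneSpec(f) for f in (500.0, 1000.0, 3000.0)]
    calls = [("Pp01", signals.NATIVE_CALL), ("Lc01", signals.INVASIVE_CALL)]
    return signals.assemble_playback(tones, calls, seed=7)


def flat_scenario(c: float = 0.0, *, noise_spl=None, gain_steps=None,
                  source_response=None, seed: int = 0,
                  locality: str = "test", substrate: str = "water"):
    """Scenario with a flat excess-attenuation rate of c dB/doubling."""
    return propagation.PropagationScenario(
        locality=locality, substrate=substrate,
        ea_freqs_hz=np.array([200.0, 5000.0]),
        ea_db_per_doubling=np.array([c, c]),
        noise_spl=noise_spl,
        gain_steps=gain_steps if gain_steps is not None else {},
        source_response=source_response, seed=seed)


@pytest.fixture(scope="session")
def noiseless_transect(tone_playback):
    """Noiseless flat-EA (c = 3 dB/doubling) transect of the tone program."""
    wave, sched = tone_playback
    return propagation.simulate_transect(wave, sched, flat_scenario(3.0),
                                         noise_duration=5.0)


@pytest.fixture(scope="session")
def noiseless_measurements(noiseless_transect):
    return spl.measure_transect(noiseless_transect)
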