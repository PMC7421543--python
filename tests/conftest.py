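import numpy as np
import pytest

import wristahi as wa
from wristahi.synthetic import SimConfig, simulate_recording


@pytest.fixture(scope="session")
def short_night():
    """One clean-ish 1-h synthetic night shared across test modules."""
    cfg = SimConfig(duration_h=1.0, target_ahi=25.0, artefact_rate_per_h=1.0, seed=11)
    return simulate_recording(cfg, seed=11)


@pytest.fixture(scope="session")
def analysed_night(short_night):
    rec, ann, truth = short_night
    rf = wa.extract_recording_features(rec)
    return rec, ann, truth, rf


def synthetic_pulse_train(
    duration_s: float,
    rate: float = 32.0,
    bpm: float = 60.0,
    amp_mod=None,
    gap=None,
    noise: float = 0.0,
    seed: int = 0,
):
    """Deterministic pulse train with known beat times for oracle tests.

    ``amp_mod(t)`` scales the per-beat amplitude; ``gap=(t0, t1)`` flattens the
    waveform in that interval.
    """
    rng = np.random.default_rng(seed)
    ibi = 60.0 / bpm
    beats = np.arange(0.25, duration_s - ibi, ibi)
    n = int(duration_s * rate)
    x = np.zeros(n)
    for i, t0 in enumerate(beats):
        t1 = t0 + ibi
        n0, n1 = int(np.ceil(t0 * rate)), min(int(np.ceil(t1 * rate)), n)
        tau = (np.arange(n0, n1) / rate - t0) / ibi
        shape = np.where(tau < 0.3, np.sin(np.pi * tau / 0.6) ** 2, np.exp(-(tau - 0.3) / 0.25))
        amp = amp_mod(t0) if amp_mod is not None else 1.0
        x[n0:n1] += amp * shape
    if noise > 0:
        x += rng.normal(0, noise, size=n)
    if gap is not None:
        x[int(gap[0] * rate) : int(gap[1] * rate)] = 0.0
    return x, beats
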