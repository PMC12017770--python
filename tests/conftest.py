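import numpy as np
import pytest

from vasoreact.synthetic import (
    KINETICS_20HZ,
    ResponseKinetics,
    StimulusProtocol,
    VesselScene,
)


@pytest.fixture
def scene():
    return VesselScene(noise_sd=0.0)


@pytest.fixture
def noisy_scene():
    return VesselScene()  # default 1% noise


@pytest.fixture
def protocol():
    return StimulusProtocol(20.0)


@pytest.fixture
def kinetics():
    return KINETICS_20HZ


@pytest.fixture
def null_kinetics():
    """No evoked response at all."""
    return ResponseKinetics(onset_latency=1.0, time_to_peak=2.0, peak_amplitude=0.0, recovery_tau=1.0)


def brute_force_onset(time, z, stim_onset, threshold, sustain, fallback):
    """Independent run-scan oracle for the sustained Z-crossing onset.

    Enumerates every post-stimulus sample as a candidate run start and
    checks the sustain criterion directly.
    """
    idx = np.flatnonzero(time >= stim_onset)
    dt = np.median(np.diff(time[idx])) if idx.size > 1 else 1.0
    need = int(np.ceil(sustain / dt))
    best = None
    direction = None
    for sign, label in ((-1, "constriction"), (1, "dilation")):
        for s in range(idx.size - need + 1):
            window = z[idx[s] : idx[s] + need]
            if np.all(sign * window > threshold):
                cand = time[idx[s]] - stim_onset
                if best is None or cand < best:
                    best, direction = cand, label
                break
    if best is None:
        return fallback, None
    return best, direction
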