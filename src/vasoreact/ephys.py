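"""Spike detection and per-pulse-interval spike success.

The spike success rate quantifies how faithfully a neuron follows an
optogenetic pulse train: each inter-pulse interval [pulse_i, pulse_{i+1})
is a success if it contains at least one action potential. At low train
frequencies the steady-state success rate is 100%; it falls at high
frequencies where channel kinetics and intrinsic firing properties limit
spike entrainment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeTrain", "PulseTrain", "SuccessResult", "detect_spikes", "spike_success_rate"]


@dataclass
class SpikeTrain:
    spike_times: np.ndarray  # s, strictly increasing

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")


@dataclass
class PulseTrain:
    pulse_times: np.ndarray  # s, strictly increasing pulse onsets
    pulse_width: float  # s

    def __post_init__(self):
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if self.pulse_times.size == 0:
            raise ValueError("pulse train must contain at least one pulse")
        diffs = np.diff(self.pulse_times)
        if np.any(diffs <= 0):
            raise ValueError("pulse times must be strictly increasing")
        if self.pulse_width <= 0:
            raise ValueError("pulse width must be positive")
        if np.any(diffs < self.pulse_width):
            raise ValueError("pulses overlap: inter-pulse interval shorter than pulse width")

    @classmethod
    def from_protocol(cls, protocol) -> "PulseTrain":
        """Build from a stimulus protocol (frequency, width, duration, onset)."""
        n = int(np.floor(protocol.frequency * protocol.train_duration))
        times = protocol.onset_time + np.arange(n) / protocol.frequency
        return cls(times, protocol.pulse_width)

    @property
    def period(self) -> float:
        if self.pulse_times.size >= 2:
            return float(np.median(np.diff(self.pulse_times)))
        return self.pulse_width  # degenerate single-pulse train


def detect_spikes(
    time: np.ndarray,
    voltage: np.ndarray,
    threshold: float = 0.0,
    refractory: float = 0.002,
) -> SpikeTrain:
    """Threshold-crossing spike detector with refractory de-duplication.

    One spike per upward crossing of ``threshold`` (mV); the spike time is
    the voltage peak of the supra-threshold excursion. Crossings closer
    than ``refractory`` s are merged. Requires uniform sampling.
    """
    time = np.asarray(time, dtype=float)
    voltage = np.asarray(voltage, dtype=float)
    if time.size == 0:
        return SpikeTrain(np.empty(0))
    dt = np.diff(time)
    if dt.size and not np.allclose(dt, dt[0], rtol=1e-3):
        raise ValueError("spike detection requires uniform sampling")
    above = voltage > threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    peaks: list[float] = []
    for c in crossings:
        end = c
        while end < voltage.size and above[end]:
            end += 1
        seg = slice(c, end)
        t_peak = time[seg][np.argmax(voltage[seg])]
        if peaks and t_peak - peaks[-1] < refractory:
            continue
        peaks.append(float(t_peak))
    return SpikeTrain(np.asarray(peaks))


@dataclass
class SuccessResult:
    success: np.ndarray  # per-interval boolean flags
    rate: float  # % over all intervals
    steady_state_rate: float  # % over the trailing fraction of the train
    n_intervals: int
    interval_edges: np.ndarray = field(repr=False, default=None)


def spike_success_rate(
    spikes: SpikeTrain,
    pulses: PulseTrain,
    steady_state_fraction: float = 0.5,
) -> SuccessResult:
    """Per-interval spike success flags and the overall/steady-state rate.

    Interval i is [pulse_i, pulse_{i+1}); the last interval closes one
    period after the final pulse. A success is ≥1 spike (peak time) inside
    the interval. The steady-state rate is computed over the trailing
    ``steady_state_fraction`` of intervals (default: final half), where
    the initial transient of reliable entrainment has settled.
    """
    if not 0 < steady_state_fraction <= 1:
        raise ValueError("steady_state_fraction must be in (0, 1]")
    edges = np.concatenate([pulses.pulse_times, [pulses.pulse_times[-1] + pulses.period]])
    counts, _ = np.histogram(spikes.spike_times, bins=edges)
    success = counts >= 1
    n = success.size
    tail = success[n - max(1, int(np.ceil(steady_state_fraction * n))):]
    return SuccessResult(
        success=success,
        rate=100.0 * float(success.mean()),
        steady_state_rate=100.0 * float(tail.mean()),
        n_intervals=n,
        interval_edges=edges,
    )
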