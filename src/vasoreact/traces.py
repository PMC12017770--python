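"""Core time-series containers shared across the pipeline.

All traces carry explicit timestamps in seconds; nothing downstream assumes
uniform sampling (ex vivo recordings mix 5 Hz, 1 Hz and 0.2 Hz phases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DiameterTrace", "RelativeTrace", "RoiTrace"]


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class DiameterTrace:
    """Per-timepoint luminal diameter of a single vessel.

    Parameters
    ----------
    time : array of s, strictly increasing.
    diameter : array of µm, same length as ``time``; NaN marks frames where
        the walls could not be resolved.
    baseline_window : (t0, t1) in s, the pre-stimulus reference period.
    stim_onset : s, start of the photostimulation train.
    stim_duration : s, length of the train.
    """

    time: np.ndarray
    diameter: np.ndarray
    baseline_window: tuple[float, float]
    stim_onset: float
    stim_duration: float
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.time = _as_float_array(self.time)
        self.diameter = _as_float_array(self.diameter)
        if self.time.ndim != 1 or self.time.shape != self.diameter.shape:
            raise ValueError("time and diameter must be 1-D arrays of equal length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        t0, t1 = self.baseline_window
        if not t0 < t1:
            raise ValueError("baseline_window must satisfy t0 < t1")
        if t1 > self.stim_onset + 1e-9:
            raise ValueError("baseline window must precede stimulus onset")
        if self.valid is None:
            self.valid = np.isfinite(self.diameter)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        finite = self.diameter[self.valid]
        if finite.size and np.any(finite <= 0):
            raise ValueError("valid diameters must be positive")

    @property
    def baseline_mask(self) -> np.ndarray:
        t0, t1 = self.baseline_window
        return (self.time >= t0) & (self.time <= t1) & self.valid


@dataclass
class RelativeTrace:
    """Relative change trace in percent (ΔD/D0 or ΔF/F0 or ΔT).

    ``baseline_mu`` / ``baseline_sigma`` are the mean and SD of ``dd`` over
    the pre-stimulus baseline, the reference for Z-scoring.
    """

    time: np.ndarray
    dd: np.ndarray
    baseline_window: tuple[float, float]
    stim_onset: float
    stim_duration: float
    baseline_mu: float = 0.0
    baseline_sigma: float = 0.0
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.time = _as_float_array(self.time)
        self.dd = _as_float_array(self.dd)
        if self.time.shape != self.dd.shape:
            raise ValueError("time and dd must have equal length")
        if self.valid is None:
            self.valid = np.isfinite(self.dd)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    def zscore(self) -> np.ndarray:
        if self.baseline_sigma <= 0:
            raise ValueError(
                "baseline sigma is zero: Z-score undefined on a noiseless baseline"
            )
        return (self.dd - self.baseline_mu) / self.baseline_sigma


@dataclass
class RoiTrace:
    """Fluorescence or transmittance samples over a region of interest.

    ``valid_mask`` flags usable samples; photostimulation bleed-through
    (ChR2-EYFP fluorescence entering the indicator channel) is recorded as
    ``False`` and excluded from every summary.
    """

    time: np.ndarray
    value: np.ndarray
    baseline_window: tuple[float, float]
    valid_mask: np.ndarray | None = None
    roi_descriptor: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = _as_float_array(self.time)
        self.value = _as_float_array(self.value)
        if self.time.shape != self.value.shape:
            raise ValueError("time and value must have equal length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.valid_mask is None:
            self.valid_mask = np.ones_like(self.value, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        t0, t1 = self.baseline_window
        if np.count_nonzero(self.baseline_mask) < 2:
            raise ValueError("baseline window must contain at least 2 valid samples")

    @property
    def baseline_mask(self) -> np.ndarray:
        t0, t1 = self.baseline_window
        return (self.time >= t0) & (self.time <= t1) & self.valid_mask
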