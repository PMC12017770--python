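"""ROI fluorescence (ΔF/F0) and intrinsic optical signal (ΔT) quantification.

ΔF/F0 follows the photometry convention (F − F0)/F0 with F0 the mean over
a 30 s pre-stimulus baseline; samples contaminated by photostimulation
bleed-through (the opsin-fusion fluorophore entering the indicator
channel) are masked and excluded from every summary. Transmitted-light
traces are reduced to ΔT = (Tt − T0)/T0; recordings whose maximal rate of
transmittance increase exceeds 2 %/s are excluded as spreading
depression.
"""

from __future__ import annotations

import warnings

import numpy as np

from .traces import RelativeTrace, RoiTrace

__all__ = [
    "dff",
    "max_dff_post_stim",
    "transmittance_change",
    "spreading_depression_gate",
    "DEFAULT_SD_RATE_LIMIT",
]

DEFAULT_SD_RATE_LIMIT = 2.0  # %/s, strict: excluded iff max rate > limit


def _relative(trace: RoiTrace, stim_onset: float | None, stim_duration: float | None) -> RelativeTrace:
    base = trace.value[trace.baseline_mask]
    f0 = float(base.mean())
    if f0 <= 0:
        raise ValueError("baseline level must be positive")
    dd = 100.0 * (trace.value - f0) / f0
    if stim_onset is None:
        stim_onset = trace.meta.get("stim_onset", trace.baseline_window[1])
    if stim_duration is None:
        stim_duration = trace.meta.get("stim_duration", 0.0)
    rt = RelativeTrace(
        trace.time,
        dd,
        trace.baseline_window,
        stim_onset,
        stim_duration,
        valid=trace.valid_mask.copy(),
    )
    sel = rt.valid & (rt.time >= trace.baseline_window[0]) & (rt.time <= trace.baseline_window[1])
    rt.baseline_mu = float(rt.dd[sel].mean())
    rt.baseline_sigma = float(rt.dd[sel].std(ddof=0))
    return rt


def dff(
    trace: RoiTrace,
    stim_onset: float | None = None,
    stim_duration: float | None = None,
) -> RelativeTrace:
    """ΔF/F0 in %, masked samples carried through as invalid gaps."""
    return _relative(trace, stim_onset, stim_duration)


def max_dff_post_stim(rt: RelativeTrace, stim_end: float, window: float = 10.0) -> float:
    """Maximum valid ΔF/F0 within ``window`` s after the end of the train.

    When masked samples fall inside the window (bleed-through overrunning
    the train end), the maximum is taken over the remaining valid samples
    and a gap warning is emitted.
    """
    sel = (rt.time >= stim_end) & (rt.time <= stim_end + window)
    if not sel.any():
        raise ValueError("no samples in the post-stimulus window")
    masked = sel & ~rt.valid
    if masked.any():
        warnings.warn(
            f"{int(masked.sum())} masked samples inside the post-stimulus window",
            stacklevel=2,
        )
    usable = sel & rt.valid
    if not usable.any():
        raise ValueError("no valid samples in the post-stimulus window")
    return float(rt.dd[usable].max())


def transmittance_change(trace: RoiTrace) -> RelativeTrace:
    """ΔT = (Tt − T0)/T0 in %, relative to the baseline mean transmittance."""
    return _relative(trace, None, None)


def spreading_depression_gate(
    dt_trace: RelativeTrace, rate_limit: float = DEFAULT_SD_RATE_LIMIT
) -> tuple[float, bool]:
    """Maximal rate of transmittance increase, and the exclusion flag.

    dΔT/dt is estimated by finite differences on the valid timestamped
    samples (central differences, one-sided at the ends). The recording is
    excluded iff the maximum rate strictly exceeds ``rate_limit``
    (default 2 %/s) — a rate of exactly 2 %/s passes.
    """
    t = dt_trace.time[dt_trace.valid]
    v = dt_trace.dd[dt_trace.valid]
    if t.size < 2:
        raise ValueError("need at least 2 valid samples to differentiate")
    rate = np.gradient(v, t)
    max_rate = float(rate.max())
    # strict boundary with a round-off guard: a ramp of exactly the limit
    # must pass even when finite differences land at limit + few ulp
    return max_rate, max_rate > rate_limit + 1e-9 * max(1.0, rate_limit)
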