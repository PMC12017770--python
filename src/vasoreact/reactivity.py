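"""Vascular response metrics on diameter traces.

The response of a vessel to a stimulus is expressed as the relative
diameter change ΔD/D0 (%), with D0 the mean diameter over the pre-stimulus
baseline. The scalar response magnitude is the area under the ΔD/D0 curve
over a post-stimulus window (%·s, trapezoidal rule); the response onset is
the first time the Z-scored trace stays beyond ±1.96 baseline SDs for at
least 10 s, with 1800 s as the explicit no-response sentinel. Traces whose
baseline relative standard deviation is 5% or more are flagged unstable
and excluded from group statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .traces import DiameterTrace, RelativeTrace

__all__ = [
    "OnsetResult",
    "ResponseSummary",
    "relative_change",
    "median_filter3",
    "baseline_stability",
    "response_auc",
    "detect_onset",
    "classify_response",
    "DEFAULT_Z_THRESHOLD",
    "DEFAULT_SUSTAIN_S",
    "DEFAULT_FALLBACK_S",
    "DEFAULT_RSD_LIMIT",
    "DEFAULT_AUC_WINDOW_S",
]

DEFAULT_Z_THRESHOLD = 1.96  # 95% two-sided criterion
DEFAULT_SUSTAIN_S = 10.0
DEFAULT_FALLBACK_S = 1800.0
DEFAULT_RSD_LIMIT = 5.0  # % — baseline stability gate
DEFAULT_AUC_WINDOW_S = 600.0  # first 10 min of recording after stimulus


def relative_change(trace: DiameterTrace) -> RelativeTrace:
    """ΔD/D0 in %, with baseline mean/SD attached for Z-scoring.

    D0 is the mean of valid baseline diameters; baseline μ and σ
    (population SD) are computed over the pre-stimulus samples of the
    resulting ΔD/D0 trace.
    """
    base = trace.diameter[trace.baseline_mask]
    if base.size < 2:
        raise ValueError("baseline window must contain at least 2 valid samples")
    d0 = float(base.mean())
    if d0 <= 0:
        raise ValueError("baseline diameter D0 must be positive")
    dd = 100.0 * (trace.diameter - d0) / d0
    rt = RelativeTrace(
        trace.time,
        dd,
        trace.baseline_window,
        trace.stim_onset,
        trace.stim_duration,
        valid=trace.valid.copy(),
    )
    _attach_baseline_stats(rt)
    return rt


def _attach_baseline_stats(rt: RelativeTrace) -> None:
    t0, t1 = rt.baseline_window
    sel = (rt.time >= t0) & (rt.time <= t1) & rt.valid
    vals = rt.dd[sel]
    rt.baseline_mu = float(vals.mean()) if vals.size else float("nan")
    rt.baseline_sigma = float(vals.std(ddof=0)) if vals.size else float("nan")


def median_filter3(rt: RelativeTrace) -> RelativeTrace:
    """Sliding three-point median filter; endpoints unchanged.

    Removes one-sample artifacts (transient focus loss) without displacing
    edges. On fewer than 3 samples this is the identity. Baseline μ/σ are
    recomputed on the smoothed trace.
    """
    dd = rt.dd.copy()
    if dd.size >= 3:
        stacked = np.vstack([rt.dd[:-2], rt.dd[1:-1], rt.dd[2:]])
        dd[1:-1] = np.median(stacked, axis=0)
    out = RelativeTrace(
        rt.time.copy(),
        dd,
        rt.baseline_window,
        rt.stim_onset,
        rt.stim_duration,
        valid=rt.valid.copy(),
    )
    _attach_baseline_stats(out)
    return out


def baseline_stability(trace: DiameterTrace, limit: float = DEFAULT_RSD_LIMIT) -> tuple[float, bool]:
    """Relative standard deviation of the baseline diameter, and the gate.

    rsd = 100·SD/mean (population SD) over the baseline window; the vessel
    passes iff rsd is strictly below ``limit`` (default 5%).
    """
    base = trace.diameter[trace.baseline_mask]
    if base.size == 0:
        raise ValueError("baseline window contains no valid samples")
    mean = float(base.mean())
    if mean <= 0:
        raise ValueError("baseline mean diameter must be positive")
    rsd = 100.0 * float(base.std(ddof=0)) / mean
    return rsd, rsd < limit


def response_auc(
    rt: RelativeTrace, window: tuple[float, float] | None = None
) -> float:
    """Area under ΔD/D0 over ``window``, trapezoidal rule, in %·s.

    Default window is [stim_onset, stim_onset + 600 s]. Invalid samples
    are bridged linearly between their valid neighbours (and reported via
    a warning); the window endpoints are included by interpolation so that
    closed forms (rectangles, ramps) are matched exactly.
    """
    if window is None:
        window = (rt.stim_onset, rt.stim_onset + DEFAULT_AUC_WINDOW_S)
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must satisfy t_start < t_end")
    tv = rt.time[rt.valid]
    dv = rt.dd[rt.valid]
    if tv.size < 2:
        raise ValueError("trace has fewer than 2 valid samples")
    if t0 < tv[0] - 1e-9 or t1 > tv[-1] + 1e-9:
        raise ValueError(
            f"window [{t0}, {t1}] s extends outside the valid trace "
            f"extent [{tv[0]}, {tv[-1]}] s"
        )
    n_bridged = int(np.count_nonzero(~rt.valid & (rt.time >= t0) & (rt.time <= t1)))
    if n_bridged:
        warnings.warn(f"{n_bridged} invalid samples bridged linearly in AUC window", stacklevel=2)
    inside = (tv > t0) & (tv < t1)
    t = np.concatenate([[t0], tv[inside], [t1]])
    d = np.concatenate([[np.interp(t0, tv, dv)], dv[inside], [np.interp(t1, tv, dv)]])
    return float(np.trapezoid(d, t))


@dataclass
class OnsetResult:
    onset: float  # s, relative to stimulation start
    detected: bool
    direction: str | None  # 'constriction' | 'dilation' | None


def detect_onset(
    rt: RelativeTrace,
    threshold: float = DEFAULT_Z_THRESHOLD,
    sustain: float = DEFAULT_SUSTAIN_S,
    fallback: float = DEFAULT_FALLBACK_S,
) -> OnsetResult:
    """Sustained Z-crossing onset detector.

    Scans samples at or after the stimulation start for the first run of
    consecutive valid samples whose Z-score stays beyond ``threshold`` on
    one side (below −threshold → constriction, above +threshold →
    dilation) for at least ``sustain`` seconds, evaluated as
    ceil(sustain/Δt) consecutive samples at the trace's own median rate.
    The onset is the run start relative to stimulation start; when no run
    qualifies the ``fallback`` sentinel (default 1800 s) is returned with
    ``detected=False``.
    """
    if not np.isfinite(rt.baseline_sigma) or rt.baseline_sigma <= 0:
        raise ValueError(
            "baseline sigma is zero or undefined: Z-score onset detection "
            "requires a noisy (non-degenerate) baseline"
        )
    z = (rt.dd - rt.baseline_mu) / rt.baseline_sigma
    sel = rt.time >= rt.stim_onset
    t = rt.time[sel]
    zs = z[sel]
    ok = rt.valid[sel]
    if t.size < 2:
        return OnsetResult(fallback, False, None)
    dt = float(np.median(np.diff(t)))
    need = max(1, math.ceil(sustain / dt))
    candidates = []
    for sign, label in ((-1, "constriction"), (+1, "dilation")):
        start = _first_sustained_run(ok & (sign * zs > threshold), need)
        if start is not None:
            candidates.append((t[start] - rt.stim_onset, label))
    if not candidates:
        return OnsetResult(fallback, False, None)
    onset, direction = min(candidates)
    return OnsetResult(float(onset), True, direction)


def _first_sustained_run(flags: np.ndarray, need: int) -> int | None:
    """Start index of the first run of ≥ ``need`` consecutive True values."""
    run = 0
    for i, b in enumerate(flags):
        run = run + 1 if b else 0
        if run >= need:
            return i - need + 1
    return None


@dataclass
class ResponseSummary:
    """Aggregated per-vessel response metrics."""

    auc: float  # %·s
    onset: float  # s relative to stimulation start
    onset_detected: bool
    peak_amplitude: float  # % (signed extremum of smoothed ΔD/D0)
    peak_time: float  # s (absolute trace time)
    classification: str  # constriction | dilation | none
    excluded: bool
    exclusion_reasons: list[str]
    baseline_rsd: float  # %
    d0: float  # µm

    def to_dict(self) -> dict:
        return asdict(self)


def _boxcar(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with edge renormalization."""
    if n <= 1:
        return x.copy()
    kern = np.ones(n)
    num = np.convolve(x, kern, mode="same")
    den = np.convolve(np.ones_like(x), kern, mode="same")
    return num / den


def classify_response(
    trace: DiameterTrace,
    *,
    window: tuple[float, float] | None = None,
    threshold: float = DEFAULT_Z_THRESHOLD,
    sustain: float = DEFAULT_SUSTAIN_S,
    fallback: float = DEFAULT_FALLBACK_S,
    rsd_limit: float = DEFAULT_RSD_LIMIT,
    sd_gate_failed: bool = False,
    peak_smooth_s: float = 30.0,
) -> ResponseSummary:
    """Full per-vessel summary: ΔD/D0 → smooth → AUC, onset, peak, gates.

    The peak is the signed extremum of the ΔD/D0 trace smoothed with a
    centred ``peak_smooth_s`` moving average (slow vasomotor responses:
    minutes-long kinetics; the extra smoothing suppresses the upward bias
    a pointwise extremum would pick up from sample noise). Exclusion flags
    (unstable baseline, spreading-depression gate failure signalled by the
    caller) never suppress the metrics themselves; an excluded vessel
    still reports its numbers alongside the reasons.
    """
    rsd, stable = baseline_stability(trace, rsd_limit)
    rt = median_filter3(relative_change(trace))
    if window is None:
        window = (rt.stim_onset, rt.stim_onset + DEFAULT_AUC_WINDOW_S)
    auc = response_auc(rt, window)
    onset = detect_onset(rt, threshold, sustain, fallback)
    in_win = (rt.time >= window[0]) & (rt.time <= window[1]) & rt.valid
    if not in_win.any():
        raise ValueError("no valid samples in the analysis window")
    dt = float(np.median(np.diff(rt.time)))
    n_smooth = max(1, int(round(peak_smooth_s / dt)))
    smoothed = _boxcar(rt.dd, n_smooth)
    i_peak = int(np.argmax(np.abs(smoothed[in_win])))
    peak_amplitude = float(smoothed[in_win][i_peak])
    # peak time from the lightly-filtered trace near the smoothed extremum:
    # the boxcar displaces an asymmetric peak, the pointwise extremum does not
    t_peak0 = rt.time[in_win][i_peak]
    near = in_win & (np.abs(rt.time - t_peak0) <= peak_smooth_s)
    j = int(np.argmax(np.abs(rt.dd[near])))
    peak_time = float(rt.time[near][j])
    classification = onset.direction if onset.detected else "none"
    reasons = []
    if not stable:
        reasons.append(f"baseline RSD {rsd:.2f}% >= {rsd_limit}%")
    if sd_gate_failed:
        reasons.append("spreading-depression gate failed (dΔT/dt > 2 %/s)")
    base = trace.diameter[trace.baseline_mask]
    return ResponseSummary(
        auc=auc,
        onset=onset.onset,
        onset_detected=onset.detected,
        peak_amplitude=peak_amplitude,
        peak_time=peak_time,
        classification=classification or "none",
        excluded=bool(reasons),
        exclusion_reasons=reasons,
        baseline_rsd=rsd,
        d0=float(base.mean()),
    )
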