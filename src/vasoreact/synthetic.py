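"""Synthetic inputs with the kinetic and statistical structure of the
optogenetic vasoconstriction experiments.

Every generator is seeded and bit-reproducible, and every rendered image
carries its per-frame ground-truth diameter so downstream extraction
error is directly measurable.

The emulated scene is a layer I penetrating arteriole (10–40 µm lumen,
~4 µm walls) imaged in transmitted-light gradient contrast at 0.1–1 Hz.
Photostimulation is a 10 s train of 5 ms pulses at 1–20 Hz. The evoked
constriction follows the high-frequency phenotype: onset within ~2 min of
the train, peak near 7 min, then slow recovery. Somatic calcium
transients rise during the train and decay over tens of seconds, with the
indicator channel masked during the train (opsin-fluorophore
bleed-through). Transmittance fields are flat unless a spreading-
depression-like fast ramp is injected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .coexpression import Exclusivity, ExpressionMatrix, Implication
from .imaging import ImageStack, LineScan
from .traces import DiameterTrace, RoiTrace

import pandas as pd

__all__ = [
    "StimulusProtocol",
    "ResponseKinetics",
    "VesselScene",
    "ExpressionSpec",
    "KINETICS_20HZ",
    "KINETICS_IN_VIVO_BIPHASIC",
    "generate_diameter_trace",
    "render_image_stack",
    "render_linescan",
    "generate_ca_trace",
    "generate_transmittance_field",
    "generate_expression_matrix",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Photostimulation pulse train: 10 s of 5 ms pulses by default."""

    frequency: float  # Hz
    pulse_width: float = 0.005  # s
    train_duration: float = 10.0  # s
    onset_time: float = 300.0  # s after recording start (5 min baseline)

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.pulse_width * self.frequency > 1:
            raise ValueError("duty cycle exceeds 1: pulse_width * frequency > 1")
        if self.train_duration <= 0:
            raise ValueError("train_duration must be positive")
        if self.onset_time < 0:
            raise ValueError("onset_time must be non-negative")

    @property
    def n_pulses(self) -> int:
        return int(math.floor(self.frequency * self.train_duration))

    @property
    def train_end(self) -> float:
        return self.onset_time + self.train_duration


@dataclass(frozen=True)
class ResponseKinetics:
    """Piecewise constriction template, amplitudes in % ΔD/D0.

    Negative ``peak_amplitude`` is constriction. The optional
    ``dilation_amplitude`` adds an initial dilation phase (a triangular
    bump filling [0, onset_latency]) for in-vivo-like biphasic responses.
    """

    onset_latency: float  # s after stimulation start
    time_to_peak: float  # s after stimulation start
    peak_amplitude: float  # %
    recovery_tau: float  # s
    dilation_amplitude: float = 0.0  # %

    def __post_init__(self):
        if not self.time_to_peak > self.onset_latency >= 0:
            raise ValueError("need time_to_peak > onset_latency >= 0")
        if self.recovery_tau <= 0:
            raise ValueError("recovery_tau must be positive")

    def shape(self, t_rel: np.ndarray) -> np.ndarray:
        """ΔD/D0 (%) at times relative to stimulation start."""
        t = np.asarray(t_rel, dtype=float)
        out = np.zeros_like(t)
        if self.dilation_amplitude and self.onset_latency > 0:
            half = self.onset_latency / 2
            rising = (t > 0) & (t <= half)
            falling = (t > half) & (t < self.onset_latency)
            out[rising] = self.dilation_amplitude * t[rising] / half
            out[falling] = self.dilation_amplitude * (self.onset_latency - t[falling]) / half
        ramp = (t >= self.onset_latency) & (t <= self.time_to_peak)
        span = self.time_to_peak - self.onset_latency
        out[ramp] = self.peak_amplitude * (t[ramp] - self.onset_latency) / span
        rec = t > self.time_to_peak
        out[rec] = self.peak_amplitude * np.exp(-(t[rec] - self.time_to_peak) / self.recovery_tau)
        return out


#: High-frequency (20 Hz-like) ex vivo constriction: onset ≈ 1.6 min,
#: peak ≈ 6.8 min; the amplitude is set so the 10-min response integral
#: is ≈ −3.7 × 10³ %·s.
KINETICS_20HZ = ResponseKinetics(
    onset_latency=96.0, time_to_peak=408.0, peak_amplitude=-12.4, recovery_tau=300.0
)

#: In-vivo-like biphasic template: dilation over the first 20 s after the
#: train, constriction peaking at 40 s; constriction amplitude set so the
#: 20–40 s integral is ≈ −290 %·s.
KINETICS_IN_VIVO_BIPHASIC = ResponseKinetics(
    onset_latency=20.0,
    time_to_peak=40.0,
    peak_amplitude=-29.0,
    recovery_tau=10.0,
    dilation_amplitude=10.0,
)


@dataclass(frozen=True)
class VesselScene:
    """Geometry and rendering parameters of the imaged arteriole.

    The cross-section intensity model is a trapezoid — dark walls, bright
    plateau lumen on an intermediate background — convolved with a
    Gaussian point-spread function, so that the half-depth width of the
    rendered lumen equals the nominal diameter analytically at zero noise.
    """

    lumen_diameter0: float = 20.0  # µm
    wall_thickness: float = 4.0  # µm
    orientation: float = 0.0  # degrees, vessel axis from vertical
    pixel_size: float = 0.5  # µm / px
    frame_interval: float = 1.0  # s (1 Hz optogenetic acquisition)
    noise_sd: float = 0.01  # additive Gaussian, fraction of baseline level
    # (≈1% baseline diameter RSD, the resting stability of accepted vessels)
    contrast: float = 1.0
    psf_sigma: float = 0.5  # µm
    background: float = 0.5  # intensity units
    allow_nonstandard: bool = False

    def __post_init__(self):
        if not self.allow_nonstandard and not 10.0 <= self.lumen_diameter0 <= 40.0:
            raise ValueError(
                "lumen_diameter0 outside the 10-40 µm selection range "
                "(set allow_nonstandard=True to override)"
            )
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def lumen_level(self) -> float:
        return self.background + 0.5 * self.contrast

    @property
    def wall_level(self) -> float:
        return self.background - 0.3 * self.contrast


def generate_diameter_trace(
    scene: VesselScene,
    protocol: StimulusProtocol,
    kinetics: ResponseKinetics,
    duration: float,
    seed: int,
    sample_interval: float | None = None,
) -> DiameterTrace:
    """Noisy diameter time series with the prescribed response kinetics.

    Flat baseline at ``scene.lumen_diameter0``, then the kinetic template
    applied from the stimulation onset, plus additive Gaussian noise of SD
    ``scene.noise_sd`` × baseline diameter. Identical arguments and seed
    give bit-identical traces.
    """
    if duration <= protocol.onset_time + protocol.train_duration:
        raise ValueError("duration must cover the baseline and the stimulus train")
    dt = scene.frame_interval if sample_interval is None else sample_interval
    rng = np.random.default_rng(seed)
    time = np.arange(0.0, duration + dt / 2, dt)
    dd = kinetics.shape(time - protocol.onset_time)
    d0 = scene.lumen_diameter0
    diam = d0 * (1.0 + dd / 100.0)
    diam = diam + rng.normal(0.0, scene.noise_sd * d0, size=diam.shape)
    return DiameterTrace(
        time,
        diam,
        baseline_window=(0.0, protocol.onset_time),
        stim_onset=protocol.onset_time,
        stim_duration=protocol.train_duration,
    )


def _slab(dist: np.ndarray, half_width: float, sigma: float) -> np.ndarray:
    """Indicator of |dist| < half_width convolved with a Gaussian of ``sigma``."""
    if sigma <= 0:
        return (np.abs(dist) < half_width).astype(float)
    s = sigma * math.sqrt(2.0)
    return 0.5 * (erf((half_width - dist) / s) + erf((half_width + dist) / s))


def _vessel_frame(
    shape: tuple[int, int],
    center: tuple[float, float],
    diameter_px: float,
    wall_px: float,
    orientation_deg: float,
    lumen: float,
    wall: float,
    background: float,
    psf_sigma_px: float,
    landmarks: np.ndarray | None = None,
) -> np.ndarray:
    """Render one frame: straight vessel plus optional landmark blobs.

    The trapezoid-times-PSF cross-section is evaluated analytically (erf
    edges), so the half-depth width of the rendered lumen equals
    ``diameter_px`` with no pixelation bias.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    th = np.deg2rad(orientation_deg)
    # signed perpendicular distance to the vessel axis through `center`
    dist = (xx - center[0]) * np.cos(th) - (yy - center[1]) * np.sin(th)
    img = (
        background
        + (wall - background) * _slab(dist, diameter_px / 2 + wall_px, psf_sigma_px)
        + (lumen - wall) * _slab(dist, diameter_px / 2, psf_sigma_px)
    )
    if landmarks is not None:
        for lx, ly, amp, sig in landmarks:
            r2 = (xx - lx - (center[0] - nx / 2)) ** 2 + (yy - ly - (center[1] - ny / 2)) ** 2
            img += amp * np.exp(-r2 / (2 * sig**2))
    return img


def render_image_stack(
    trace: DiameterTrace,
    scene: VesselScene,
    seed: int,
    frame_shape: tuple[int, int] | None = None,
    drift: np.ndarray | None = None,
    n_landmarks: int = 6,
) -> tuple[ImageStack, np.ndarray]:
    """Render a transmitted-light-like stack from a diameter trace.

    Returns the stack and the ground-truth per-frame diameter in px.
    ``drift`` (n_frames, 2) applies a rigid (dx, dy) translation of the
    whole scene per frame, for registration tests. A few dim Gaussian
    blobs emulate the cellular landmarks an experimenter uses to hold the
    focal plane, and give the registration 2-D structure along the vessel
    axis.
    """
    diam_px = trace.diameter / scene.pixel_size
    wall_px = scene.wall_thickness / scene.pixel_size
    max_extent = np.nanmax(diam_px) + 2 * wall_px
    if frame_shape is None:
        nx = int(2 * (math.ceil(max_extent / 2) + 20))
        frame_shape = (64, nx)
    ny, nx = frame_shape
    if max_extent >= nx:
        raise ValueError("vessel (diameter + walls) does not fit within the frame")
    rng = np.random.default_rng(seed)
    landmarks = np.column_stack(
        [
            rng.uniform(0, nx, n_landmarks),
            rng.uniform(0, ny, n_landmarks),
            rng.uniform(-0.15, -0.05, n_landmarks) * scene.contrast,
            rng.uniform(1.5, 3.0, n_landmarks),
        ]
    )
    frames = np.empty((trace.time.size, ny, nx))
    for i, d in enumerate(diam_px):
        off = drift[i] if drift is not None else (0.0, 0.0)
        frames[i] = _vessel_frame(
            frame_shape,
            (nx / 2 + off[0], ny / 2 + off[1]),
            d,
            wall_px,
            scene.orientation,
            scene.lumen_level,
            scene.wall_level,
            scene.background,
            scene.psf_sigma / scene.pixel_size,
            landmarks,
        )
    if scene.noise_sd > 0:
        frames += rng.normal(0.0, scene.noise_sd * scene.background, size=frames.shape)
    stack = ImageStack(
        frames,
        scene.pixel_size,
        scene.frame_interval,
        meta={"truth_diameter_px": diam_px.copy(), "orientation": scene.orientation},
    )
    return stack, diam_px.copy()


def render_linescan(
    trace: DiameterTrace,
    scene: VesselScene,
    line_rate: float,
    seed: int,
    length_px: int | None = None,
) -> tuple[LineScan, np.ndarray]:
    """Render a dye-filled-vessel line scan (bright lumen on dark field).

    Each line samples the instantaneous diameter (linear interpolation of
    the trace) at ``line_rate`` Hz. Returns the scan and the ground-truth
    diameter per line in px.
    """
    if line_rate <= 0:
        raise ValueError("line_rate must be positive")
    diam_px_trace = trace.diameter / scene.pixel_size
    max_d = np.nanmax(diam_px_trace)
    if length_px is None:
        length_px = int(2 * (math.ceil(max_d / 2) + 15))
    if length_px <= max_d:
        raise ValueError("scan line shorter than the vessel width")
    dt = 1.0 / line_rate
    t_lines = np.arange(0.0, trace.time[-1] + dt / 2, dt)
    diam_px = np.interp(t_lines, trace.time, diam_px_trace)
    x = np.arange(length_px, dtype=float)
    center = length_px / 2
    bg, lum = 0.1, 1.0
    rng = np.random.default_rng(seed)
    lines = np.empty((t_lines.size, length_px))
    sigma = scene.psf_sigma / scene.pixel_size
    for i, d in enumerate(diam_px):
        lines[i] = bg + (lum - bg) * _slab(x - center, d / 2, sigma)
    if scene.noise_sd > 0:
        lines += rng.normal(0.0, scene.noise_sd * lum, size=lines.shape)
    ls = LineScan(lines, dt, scene.pixel_size, meta={"truth_diameter_px": diam_px.copy()})
    return ls, diam_px.copy()


def generate_ca_trace(
    protocol: StimulusProtocol,
    peak_dff: float = 79.5,
    decay_tau: float = 20.0,
    baseline_f: float = 100.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    duration: float | None = None,
    sample_interval: float = 1.0,
) -> RoiTrace:
    """Somatic calcium-indicator trace with a bleed-through mask.

    Fluorescence rises linearly during the train to ``baseline_f × (1 +
    peak_dff/100)`` at the train end, then decays exponentially with
    ``decay_tau`` (tens of seconds). Samples falling inside the train are
    flagged invalid: the opsin-fusion fluorophore contaminates the
    indicator channel during photostimulation. Default peaks: 34.5%
    (2 Hz-like) and 79.5% (20 Hz-like, the default).
    """
    if baseline_f <= 0:
        raise ValueError("baseline_f must be positive")
    if duration is None:
        duration = protocol.train_end + 6 * decay_tau
    rng = np.random.default_rng(seed)
    time = np.arange(0.0, duration + sample_interval / 2, sample_interval)
    f = np.full_like(time, float(baseline_f))
    peak_f = baseline_f * (1.0 + peak_dff / 100.0)
    during = (time > protocol.onset_time) & (time <= protocol.train_end)
    f[during] = baseline_f + (peak_f - baseline_f) * (
        (time[during] - protocol.onset_time) / protocol.train_duration
    )
    after = time > protocol.train_end
    f[after] = baseline_f + (peak_f - baseline_f) * np.exp(
        -(time[after] - protocol.train_end) / decay_tau
    )
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd * baseline_f, size=f.shape)
    # bleed-through spans the pulse train; the sample at the train end is
    # the first clean one (photostimulation has just stopped)
    valid = ~((time >= protocol.onset_time) & (time < protocol.train_end))
    return RoiTrace(
        time,
        f,
        baseline_window=(max(0.0, protocol.onset_time - 30.0), protocol.onset_time),
        valid_mask=valid,
        roi_descriptor="soma",
        meta={"stim_onset": protocol.onset_time, "stim_duration": protocol.train_duration},
    )


def generate_transmittance_field(
    duration: float,
    sd_event: tuple[float, float, float] | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    sample_interval: float = 1.0,
    baseline_duration: float = 30.0,
) -> RoiTrace:
    """Baseline-normalized transmittance trace over a 100 µm × 100 µm ROI.

    ``sd_event`` = (onset s, rate %/s, amplitude %) injects a linear ramp
    of the given rate up to the given amplitude — a spreading-depression-
    like fast transient when the rate exceeds 2 %/s.
    """
    if duration <= baseline_duration:
        raise ValueError("duration must exceed the baseline period")
    rng = np.random.default_rng(seed)
    time = np.arange(0.0, duration + sample_interval / 2, sample_interval)
    value = np.ones_like(time)
    if sd_event is not None:
        onset, rate, amplitude = sd_event
        if amplitude < 0 or rate <= 0:
            raise ValueError("event rate must be positive and amplitude non-negative")
        ramp = np.clip((time - onset) * rate, 0.0, amplitude)
        value = value * (1.0 + ramp / 100.0)
    if noise_sd > 0:
        value = value + rng.normal(0.0, noise_sd, size=value.shape)
    return RoiTrace(
        time,
        value,
        baseline_window=(0.0, baseline_duration),
        roi_descriptor="100 µm x 100 µm square",
        meta={"sd_event": sd_event},
    )


@dataclass(frozen=True)
class ExpressionSpec:
    """Sampling plan for a boolean cells × transcripts detection matrix."""

    n_cells: int
    marginal_probs: dict = field(default_factory=dict)
    exclusive_pairs: tuple = ()
    implication_rules: tuple = ()  # (antecedent, (consequents...)) tuples

    def __post_init__(self):
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        for t, p in self.marginal_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {t} outside [0, 1]")

    def validate_consistency(self) -> None:
        p = self.marginal_probs
        for a, b in self.exclusive_pairs:
            if p.get(a, 0) >= 1.0 and p.get(b, 0) >= 1.0:
                raise ValueError(f"contradictory constraints: {a} and {b} both mandatory but exclusive")
        for ant, cons in self.implication_rules:
            if p.get(ant, 0) >= 1.0 and all(p.get(c, 0) <= 0.0 for c in cons):
                raise ValueError(
                    f"contradictory constraints: {ant} mandatory but all of {cons} excluded"
                )


def generate_expression_matrix(spec: ExpressionSpec, seed: int) -> ExpressionMatrix:
    """Sample a detection matrix honoring all constraints exactly.

    Per-cell rejection sampling: each transcript is an independent
    Bernoulli draw and the cell is redrawn until every exclusivity and
    implication rule holds, so unconstrained marginals converge to
    ``marginal_probs`` as the number of cells grows.
    """
    spec.validate_consistency()
    transcripts = list(spec.marginal_probs)
    probs = np.array([spec.marginal_probs[t] for t in transcripts])
    col = {t: i for i, t in enumerate(transcripts)}
    rng = np.random.default_rng(seed)

    def satisfies(row: np.ndarray) -> bool:
        for a, b in spec.exclusive_pairs:
            if row[col[a]] and row[col[b]]:
                return False
        for ant, cons in spec.implication_rules:
            if row[col[ant]] and not any(row[col[c]] for c in cons):
                return False
        return True

    rows = np.zeros((spec.n_cells, len(transcripts)), dtype=bool)
    max_tries = 10_000
    for i in range(spec.n_cells):
        for _ in range(max_tries):
            row = rng.random(len(transcripts)) < probs
            if satisfies(row):
                rows[i] = row
                break
        else:
            raise ValueError("constraints appear unsatisfiable: rejection sampling exhausted")
    frame = pd.DataFrame(
        rows, index=[f"cell{i + 1:03d}" for i in range(spec.n_cells)], columns=transcripts
    )
    return ExpressionMatrix(frame)


def expression_rules(spec: ExpressionSpec) -> list:
    """The spec's constraints as checkable rule objects."""
    rules: list = [Exclusivity(a, b) for a, b in spec.exclusive_pairs]
    rules += [Implication(ant, tuple(cons)) for ant, cons in spec.implication_rules]
    return rules
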