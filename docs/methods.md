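# Methods

`vasoreact` quantifies the vascular response of a single penetrating or
pial arteriole to a photostimulation pulse train, from raw time-lapse
images to group statistics. This note records the models, estimators and
numerical choices behind each stage, and what the bundled synthetic data
do and do not establish about real recordings.

## Vessel model and diameter estimation

**Scene model.** A straight arteriole is modelled in cross-section as a
trapezoidal intensity profile: a bright lumen plateau of diameter *D*
flanked by two dark wall bands of width *w* (default 4 µm) on an
intermediate background — the appearance of a vessel in transmitted-light
gradient contrast. The profile is convolved with a Gaussian point-spread
function (default σ = 0.5 µm). The renderer evaluates this convolution
analytically (erf edges) rather than rasterizing a binary mask and
filtering it, so the half-depth width of the rendered lumen equals *D*
exactly and extraction error can be attributed entirely to the estimator.
Dim Gaussian blobs emulate the cellular landmarks an experimenter keeps
in the field of view; they give the registration two-dimensional texture
along the otherwise translation-invariant vessel axis.

**Diameter definition.** Along a user-placed caliper perpendicular to the
vessel axis, the luminal diameter is the distance between the two
half-depth crossings — the points where intensity crosses midway between
each wall trough and the lumen plateau — located with sub-pixel linear
interpolation after a light Gaussian profile smoothing (σ = 0.5 px,
symmetric, so erf-shaped edges are not displaced). Whether published
caliper tools report this inner half-depth width or the trough-to-trough
distance is generally not documented; both are implemented
(`method="half_depth"` is the default, `"trough"` the alternative).
Frames without two resolvable wall minima (contrast below 10% of the
profile range) are reported as missing, never interpolated at
measurement time.

**Wall thickness** is measured on the baseline-averaged frame as the
dark-band width at half depth: from the outer background-to-wall
half-depth crossing to the inner wall-to-lumen crossing, averaged over
both walls.

**Registration** is translation-only (the imaged field is near-static;
rotation is out of scope), by upsampled cross-correlation against a
reference frame. Plain cross-correlation is used instead of pure phase
correlation: phase whitening weights all spatial frequencies equally and
is unreliable on these smooth, low-texture fields. Estimated shifts
beyond a configurable maximum (default 20 px) are clamped with a warning
so that degenerate inputs (pure noise) cannot produce arbitrary
translations.

**Line scans** (dye-filled vessels, bright on dark) are binned to 0.1 s,
the per-bin average profile reduced to its full width at half maximum
(background from the outer 10% of samples on each side), and the trace
resampled onto the uniform 0.1 s grid by linear interpolation; empty or
unmeasurable bins are interpolated and flagged invalid.

## Response metrics

**Relative diameter.** ΔD/D0 (%) with D0 the mean diameter over the
pre-stimulus baseline (default 5 min). Traces are smoothed with a sliding
three-point median filter (endpoints unchanged), which removes
single-sample artifacts such as transient focus loss without displacing
edges. Baseline μ and σ for Z-scoring are recomputed on the smoothed
trace; σ and the stability statistic use the population SD (ddof = 0).

**Stability gate.** A vessel is analysable only if the relative standard
deviation of its baseline diameter is strictly below 5%. Failing vessels
are flagged excluded but their metrics are still reported.

**AUC.** The response magnitude is the trapezoidal integral of ΔD/D0
over the post-stimulus window — 10 min for slice-style recordings, 20–40 s
after the train for in-vivo-style biphasic responses. Window endpoints
are included by linear interpolation (rectangles and ramps integrate
exactly); invalid samples inside the window are bridged linearly and
counted in a warning.

**Onset.** The onset is the first time after stimulation start at which
the Z-scored trace stays beyond ±1.96 (95% criterion) on one side for at
least 10 s, evaluated as ceil(10/Δt) consecutive samples at the trace's
own median rate; the crossing direction is reported (below −1.96 →
constriction, above +1.96 → dilation; the two-sided rule makes dilation
onsets detectable too). If no run qualifies, the 1800 s sentinel is
returned together with an explicit not-detected flag. A noiseless
baseline (σ = 0) is rejected with an error rather than producing an
undefined Z-score. With 1% baseline noise and the 10 s sustain the
false-positive rate on noise-only traces is far below 5% (the 1.96
threshold alone would not be: ten consecutive exceedances are required).

**Peak.** The peak amplitude is the signed extremum of the ΔD/D0 trace
smoothed with a centred 30 s moving average. A pointwise extremum of the
noisy trace is biased outward by extreme-value selection — about +1.5
percentage points at 1% sample noise, over 10% relative error on a
−12% peak — whereas these responses evolve over minutes, so 30 s
smoothing costs little kinetic fidelity. The peak *time* is read from
the median-filtered (unsmoothed) trace within ±30 s of the smoothed
extremum, because a boxcar displaces the maximum of an asymmetric peak.

## Photometry

ΔF/F0 = (F − F0)/F0 in %, F0 the mean over a 30 s pre-stimulus baseline.
Samples acquired during the pulse train are masked (opsin-fusion
fluorophore bleed-through into the indicator channel) and excluded from
every summary; the mask is half-open — the sample at the train end is the
first clean one. All operations work on timestamps, never on an assumed
uniform rate, because acquisition switches rate across baseline /
stimulation / recovery phases.

Transmitted-light intrinsic signals are reduced to ΔT = (Tt − T0)/T0 in
%. The spreading-depression gate computes dΔT/dt by finite differences on
the valid timestamped samples (central differences, one-sided at the
ends; no pre-smoothing by default) and excludes the recording iff the
maximum rate of increase strictly exceeds 2 %/s — a ramp of exactly
2 %/s passes, with a 1e-9 round-off guard so boundary fixtures are not
excluded by floating-point error.

## Spike success

Spikes are threshold crossings (default 0 mV) de-duplicated with a 2 ms
refractory interval; the spike time is the peak of the supra-threshold
excursion. Each inter-pulse interval [pulse_i, pulse_{i+1}) — the last
closing one period after the final pulse — succeeds if it contains at
least one spike peak. The interval count equals floor(frequency × train
duration). The steady-state rate is computed over the trailing half of
the intervals by default; the transient early entrainment window is not
standardized, so the fraction is configurable.

## Single-cell co-expression

Boolean cells × transcripts detection matrices are summarized as
per-transcript counts and percentages (exact ratios internally, integer
rounding only at presentation: 14/16 prints as 88%) and as pairwise
co-detection counts. Named groups (PGES = mPGES1/mPGES2/cPGES, PGFS =
PM-PGFS/CBR1/AKR1B3) are any-member-positive, the "and/or" convention.
Exclusivity and implication rules are checked exhaustively per cell.
`example_expression_matrix()` is a hand-constructed synthetic 16-cell
panel that reproduces the published detection-rate and co-expression
structure of layer II-III pyramidal cells exactly (COX-1 4/16, COX-2
5/16, never co-detected; cPGES 14/16; mPGES isoforms always with cPGES;
CBR1 always with a PGES; 3 of 4 COX-1 cells and all COX-2 cells
PGFS-positive).

## Statistics

Shapiro-Wilk per group (skipped with a warning and a nonparametric
fallback below n = 3) and a variance check — Brown-Forsythe across
groups, variance-ratio F-test against a named control — gate parametric
testing. Multi-group designs use one-way ANOVA or Kruskal-Wallis;
post hoc comparisons are all-pairs or many-to-one against the control,
with Benjamini-Hochberg FDR correction across the user-declared family
(the family boundary is an explicit input, not inferred). Many-to-one
comparisons are plain t-tests under FDR rather than the exact Dunnett
distribution; nonparametric post hoc pairs use Mann-Whitney under FDR
(no Dunn test in the dependency set). Two-group designs use
paired/unpaired t or Wilcoxon/Mann-Whitney. Mann-Whitney U is reported
as min(U, n1·n2 − U), the tabled convention. Identical paired samples
report t = 0, p = 1; zero-variance groups in unpaired designs raise an
explicit error instead of returning NaN. Summaries are mean ± SEM with
n, and significance tiers are *, **, *** at 0.05/0.01/0.001.

## Synthetic kinetics and defaults

The constriction template is piecewise: flat baseline, optional
triangular dilation phase filling [0, onset latency] (for in-vivo-like
biphasic responses), linear fall to the peak amplitude at the time to
peak, then exponential recovery. The high-frequency default
(`KINETICS_20HZ`) uses onset latency 96 s, time to peak 408 s, recovery
τ 300 s — the quoted response timings — with peak amplitude −12.4% so
that the 10 min integral of the template is ≈ −3.7 × 10³ %·s, the
magnitude of the strong-stimulation group response. The in-vivo template
(`KINETICS_IN_VIVO_BIPHASIC`) dilates over the first 20 s and constricts
to −29% at 40 s, putting the 20–40 s integral near −290 %·s. Default
trace noise is 1% of the baseline diameter, matching the resting
stability of accepted vessels (~1–1.6% RSD). Calcium defaults: peak
ΔF/F0 79.5% (high-frequency-like; 34.5% for the low-frequency case),
decay τ 20 s.

All generators take an explicit integer seed and are bit-reproducible;
every rendered stack and line scan carries its exact per-frame diameter,
so extraction error is measurable, not estimated.

## What the synthetic data do not show

The generator produces straight, in-focus, uniformly lit vessels with
additive Gaussian noise. Real recordings add focus drift along z (only
x-y translation is modelled or corrected), wall texture and nearby
structures that can capture the half-depth crossing, correlated noise
and photobleaching, curved or branching vessels, and physiological
vasomotion superimposed on the baseline. Passing the bundled suites
demonstrates that the estimators are unbiased and sample-accurate under
the stated model, not that they are robust to these artifacts; the
stability gate and the missing-frame policy are the first line of
defence on real data, not a guarantee.

## Problem sizes

The test suites run at reduced but non-trivial scale chosen to keep a
full run fast on one CPU: 50 rendered stacks per fidelity suite (3–4
frames each across the 10–40 µm range), 1000 noise-only traces for the
false-positive rate, 100 traces for parameter recovery, 1500–1800
samples per trace at 1 Hz. The acceptance script reruns the noise-only
onset end to end (1800 s at 1 Hz) plus the worked-example quantities.
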