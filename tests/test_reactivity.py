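"""ΔD/D0 metrics: relative change, filtering, stability, AUC, onset."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vasoreact.reactivity import (
    baseline_stability,
    classify_response,
    detect_onset,
    median_filter3,
    relative_change,
    response_auc,
)
from vasoreact.synthetic import (
    KINETICS_20HZ,
    ResponseKinetics,
    StimulusProtocol,
    VesselScene,
    generate_diameter_trace,
)
from vasoreact.traces import DiameterTrace, RelativeTrace

from conftest import brute_force_onset


def _trace(diams, dt=1.0, stim_onset=None, baseline_end=None):
    diams = np.asarray(diams, dtype=float)
    time = np.arange(diams.size) * dt
    if stim_onset is None:
        stim_onset = time[-1] + dt
    if baseline_end is None:
        baseline_end = min(stim_onset, time[-1])
    return DiameterTrace(time, diams, (0.0, baseline_end), stim_onset, 10.0)


def _rel(dd, dt=1.0, stim_onset=0.0, mu=0.0, sigma=1.0):
    dd = np.asarray(dd, dtype=float)
    time = np.arange(dd.size) * dt
    rt = RelativeTrace(time, dd, (0.0, max(stim_onset, dt)), stim_onset, 10.0)
    rt.baseline_mu = mu
    rt.baseline_sigma = sigma
    return rt


class TestRelativeChange:
    def test_constant_trace_is_zero(self):
        rt = relative_change(_trace([20.0] * 10))
        assert np.allclose(rt.dd, 0.0)

    def test_partial_fp_agonist_preconstriction_magnitude(self):
        # baseline 21.8 µm, constricted 20.9 µm → ΔD/D0 ≈ −4.13%
        tr = _trace([21.8] * 5 + [20.9] * 5, stim_onset=5.0, baseline_end=4.0)
        rt = relative_change(tr)
        assert rt.dd[-1] == pytest.approx(100 * (20.9 - 21.8) / 21.8, abs=1e-9)
        assert rt.dd[-1] == pytest.approx(-4.13, abs=0.005)

    def test_scale_invariance(self):
        d = np.array([20, 21, 19.5, 20, 18, 17.5])
        a = relative_change(_trace(d, stim_onset=4.0, baseline_end=3.0))
        b = relative_change(_trace(2 * d, stim_onset=4.0, baseline_end=3.0))
        assert np.allclose(a.dd, b.dd)

    def test_empty_baseline_rejected(self):
        tr = _trace([20.0] * 10, stim_onset=5.0, baseline_end=4.0)
        tr.valid[:5] = False
        with pytest.raises(ValueError):
            relative_change(tr)


class TestMedianFilter:
    @pytest.mark.parametrize(
        "before,after",
        [
            ([0, 10, 0], [0, 0, 0]),
            ([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]),
            ([1, 2, 9, 2, 1], [1, 2, 2, 2, 1]),
        ],
    )
    def test_examples(self, before, after):
        rt = median_filter3(_rel(before))
        assert np.allclose(rt.dd, after)

    def test_short_trace_identity(self):
        rt = median_filter3(_rel([3.0, 7.0]))
        assert np.allclose(rt.dd, [3.0, 7.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=40))
    def test_never_leaves_local_range(self, values):
        rt = median_filter3(_rel(values))
        arr = np.asarray(values)
        for i in range(1, len(values) - 1):
            lo, hi = arr[i - 1 : i + 2].min(), arr[i - 1 : i + 2].max()
            assert lo <= rt.dd[i] <= hi


class TestBaselineStability:
    def test_constant_baseline_passes(self):
        rsd, ok = baseline_stability(_trace([20.0] * 10))
        assert rsd == 0.0 and ok

    def test_alternating_20_22_passes(self):
        # population SD 1 around mean 21 → RSD 100/21 ≈ 4.76% < 5%
        rsd, ok = baseline_stability(_trace([20.0, 22.0] * 5))
        assert rsd == pytest.approx(100 / 21, rel=1e-9)
        assert ok

    def test_alternating_19_23_fails(self):
        rsd, ok = baseline_stability(_trace([19.0, 23.0] * 5))
        assert rsd == pytest.approx(200 / 21, rel=1e-9)
        assert not ok


class TestAuc:
    def test_zero_trace_zero_auc(self):
        rt = _rel(np.zeros(700))
        assert response_auc(rt, (0, 600)) == 0.0

    def test_rectangle(self):
        rt = _rel(np.full(700, -10.0))
        assert response_auc(rt, (0, 600)) == pytest.approx(-6.0e3, rel=1e-12)

    def test_linear_ramp(self):
        dd = np.linspace(0, -10, 601)
        rt = _rel(np.concatenate([dd, np.full(50, -10.0)]))
        assert response_auc(rt, (0, 600)) == pytest.approx(-3.0e3, rel=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        dd = rng.normal(size=700)
        a = response_auc(_rel(dd), (0, 600))
        assert response_auc(_rel(3.5 * dd), (0, 600)) == pytest.approx(3.5 * a, rel=1e-9)

    def test_window_additivity(self):
        rng = np.random.default_rng(1)
        dd = rng.normal(size=700)
        rt = _rel(dd)
        total = response_auc(rt, (0, 600))
        split = response_auc(rt, (0, 250)) + response_auc(rt, (250, 600))
        assert split == pytest.approx(total, rel=1e-9)

    def test_fractional_window_edges_interpolated(self):
        rt = _rel([0.0, 2.0, 2.0, 0.0])
        # ramp 0→2 over [0,1]: ∫[0.5,1] = 0.75; plateau ∫[1,2] = 2
        assert response_auc(rt, (0.5, 2.0)) == pytest.approx(2.75, rel=1e-12)
        assert response_auc(rt, (0, 1.5)) + response_auc(rt, (1.5, 3)) == pytest.approx(
            response_auc(rt, (0, 3)), rel=1e-12
        )

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            response_auc(_rel(np.zeros(100)), (0, 600))

    def test_masked_samples_bridged_with_warning(self):
        dd = np.full(100, -5.0)
        rt = _rel(dd)
        rt.valid[40:45] = False
        with pytest.warns(UserWarning, match="bridged"):
            auc = response_auc(rt, (0, 99))
        assert auc == pytest.approx(-5.0 * 99, rel=1e-9)


class TestOnset:
    def _noise_rel(self, seed, n=1500, stim=300.0):
        rng = np.random.default_rng(seed)
        dd = rng.normal(0, 1.0, n)
        rt = _rel(dd, stim_onset=stim)
        base = rt.time <= stim
        rt.baseline_mu = float(dd[base].mean())
        rt.baseline_sigma = float(dd[base].std())
        return rt

    def test_noise_only_returns_fallback(self):
        res = detect_onset(self._noise_rel(0))
        assert res.onset == 1800.0 and not res.detected

    def test_step_localized_and_matches_oracle(self):
        rt = self._noise_rel(1)
        rt.dd[rt.time >= 330.0] = -50.0
        res = detect_onset(rt)
        assert res.detected and res.direction == "constriction"
        assert abs(res.onset - 30.0) <= 1.0
        z = (rt.dd - rt.baseline_mu) / rt.baseline_sigma
        oracle, direction = brute_force_onset(rt.time, z, 300.0, 1.96, 10.0, 1800.0)
        assert res.onset == oracle and res.direction == direction

    def test_short_excursion_not_sustained(self):
        rt = self._noise_rel(2)
        sel = (rt.time >= 330.0) & (rt.time < 335.0)
        rt.dd[sel] = -50.0
        res = detect_onset(rt)
        assert res.onset == 1800.0 and not res.detected

    def test_dilation_direction_reported(self):
        rt = self._noise_rel(3)
        rt.dd[rt.time >= 400.0] = 50.0
        res = detect_onset(rt)
        assert res.direction == "dilation"
        assert abs(res.onset - 100.0) <= 1.0

    def test_zero_sigma_rejected(self):
        rt = _rel(np.zeros(100), stim_onset=10.0, sigma=0.0)
        with pytest.raises(ValueError, match="sigma"):
            detect_onset(rt)

    @pytest.mark.parametrize("seed", range(5))
    def test_sustain_monotonicity(self, seed):
        rt = self._noise_rel(seed)
        rt.dd[rt.time >= 350.0] -= 2.5  # marginal shift: runs break up
        onsets = [detect_onset(rt, sustain=s).onset for s in (5.0, 10.0, 20.0)]
        assert onsets == sorted(onsets)

    def test_agreement_with_oracle_on_random_traces(self):
        for seed in range(20):
            rt = self._noise_rel(seed, n=800)
            rt.dd[rt.time >= 340] -= np.random.default_rng(seed).uniform(2, 6)
            res = detect_onset(rt)
            z = (rt.dd - rt.baseline_mu) / rt.baseline_sigma
            oracle, _ = brute_force_onset(rt.time, z, 300.0, 1.96, 10.0, 1800.0)
            assert res.onset == oracle


class TestClassify:
    def test_flat_noise_trace_classified_none(self, noisy_scene, protocol, null_kinetics):
        tr = generate_diameter_trace(noisy_scene, protocol, null_kinetics, 1500, seed=0)
        s = classify_response(tr)
        assert s.classification == "none"
        assert s.onset == 1800.0
        assert abs(s.auc) < 300.0
        assert not s.excluded

    def test_peak_location_recovered(self, protocol):
        scene = VesselScene(noise_sd=0.0)
        kin = ResponseKinetics(50.0, 110.0, -6.0, 100.0)
        tr = generate_diameter_trace(scene, protocol, kin, 1500, seed=0)
        # vanishing noise: keeps baseline sigma nonzero for the Z-score
        # while leaving the trace effectively noiseless
        rng = np.random.default_rng(4)
        tr = DiameterTrace(
            tr.time,
            tr.diameter + rng.normal(0, 2e-4 * scene.lumen_diameter0, tr.time.size),
            tr.baseline_window,
            tr.stim_onset,
            tr.stim_duration,
        )
        s = classify_response(tr)
        assert s.classification == "constriction"
        assert s.peak_time == pytest.approx(300.0 + 110.0, abs=2.0)
        # the 30 s boxcar rounds this deliberately sharp kink downward a
        # little; the unsmoothed trace extremum carries the full amplitude
        assert s.peak_amplitude == pytest.approx(-6.0, abs=0.6)
        rt = median_filter3(relative_change(tr))
        assert rt.dd.min() == pytest.approx(-6.0, abs=0.1)

    def test_unstable_baseline_excluded_but_reported(self, protocol):
        scene = VesselScene(noise_sd=0.08, allow_nonstandard=True)
        tr = generate_diameter_trace(scene, protocol, KINETICS_20HZ, 1500, seed=1)
        s = classify_response(tr)
        assert s.excluded
        assert any("RSD" in r for r in s.exclusion_reasons)
        assert np.isfinite(s.auc)

    def test_sd_gate_failure_flagged(self, noisy_scene, protocol):
        tr = generate_diameter_trace(noisy_scene, protocol, KINETICS_20HZ, 1500, seed=2)
        s = classify_response(tr, sd_gate_failed=True)
        assert s.excluded
        assert any("spreading-depression" in r for r in s.exclusion_reasons)
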