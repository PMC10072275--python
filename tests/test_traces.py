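"""Tests of the core trace computation: power-law bleach fitting and
correction, rolling average, ΔF/F, evoked features, normalizations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmjcal.datatypes import BleachModel, StimWindow, Trace
from nmjcal.synthetic import MiniParams, NoiseParams, SimConfig, simulate_trace
from nmjcal.traces import (analyze_trace, batch_normalize, channel_ratio,
                           correct_bleach, dff, evoked_features, fit_bleach,
                           normalize_group_to_control,
                           normalize_timecourse_pair, rolling_average)


def power_trace(a, b, n, fr=50.0, stim=None):
    return Trace(a * np.power(np.arange(n) + 1.0, b), fr, stim)


class TestFitBleach:
    def test_noiseless_power_law_recovered_exactly(self):
        tr = power_trace(1000.0, -0.05, 100)
        model = fit_bleach(tr, prestim_end_frame=50)
        assert model.a == pytest.approx(1000.0, rel=1e-9)
        assert model.b == pytest.approx(-0.05, rel=1e-9)

    def test_constant_trace_gives_flat_model(self):
        tr = Trace(np.full(60, 500.0), 50.0)
        model = fit_bleach(tr, prestim_end_frame=60)
        assert model.a == pytest.approx(500.0, rel=1e-12)
        assert model.b == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_is_unbiased(self):
        # Monte-Carlo: mean recovered exponent within 0.005 of the truth
        rng = np.random.default_rng(0)
        bs = []
        for _ in range(500):
            values = 800.0 * np.power(np.arange(100) + 1.0, -0.08)
            values = values + rng.normal(0, 2.0, size=100)
            model = fit_bleach(Trace(values, 50.0), prestim_end_frame=100)
            bs.append(model.b)
        assert np.mean(bs) == pytest.approx(-0.08, abs=0.005)

    def test_nonpositive_prestim_values_rejected(self):
        values = np.linspace(10, -5, 50)
        tr = Trace(np.abs(values) + 1e-9, 50.0)
        tr.values[5] = -1.0
        with pytest.raises(ValueError):
            fit_bleach(tr, prestim_end_frame=50)

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            fit_bleach(power_trace(100.0, -0.02, 50), prestim_end_frame=2)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(0.1, 1e4), b=st.floats(-0.3, 0.0))
    def test_scale_equivariance(self, scale, b):
        tr = power_trace(100.0, b, 80)
        scaled = tr.replace_values(tr.values * scale)
        m1 = fit_bleach(tr, 80)
        m2 = fit_bleach(scaled, 80)
        assert m2.a == pytest.approx(m1.a * scale, rel=1e-9)
        assert m2.b == pytest.approx(m1.b, abs=1e-9)


class TestCorrectBleach:
    def test_trace_equal_to_curve_corrects_to_one(self):
        tr = power_trace(1000.0, -0.05, 100)
        model = fit_bleach(tr, 100)
        out = correct_bleach(tr, model)
        assert np.abs(out.values - 1.0).max() < 1e-12

    def test_forward_model_recovered_exactly(self):
        n = 200
        r = np.zeros(n)
        r[100:] = 0.8 * np.exp(-np.arange(100) / 30.0)
        pc = 900.0 * np.power(np.arange(n) + 1.0, -0.03)
        tr = Trace(pc * (1.0 + r), 50.0)
        model = BleachModel(a=900.0, b=-0.03, fit_window=(0, 100))
        out = dff(correct_bleach(tr, model))
        np.testing.assert_allclose(out.values, r, atol=1e-12)

    def test_noisy_prestim_mean_near_one(self):
        cfg = SimConfig(noise=NoiseParams(gaussian_sd=10.0), seed=8)  # 1% of baseline
        tr, _ = simulate_trace(cfg)
        model = fit_bleach(tr)
        out = correct_bleach(tr, model)
        pre = out.values[:tr.stim_onset_frame()]
        assert 0.99 < pre.mean() < 1.01


class TestRollingAverage:
    def test_constant_trace_unchanged(self):
        tr = Trace(np.full(20, 3.3), 10.0)
        np.testing.assert_allclose(rolling_average(tr, 5).values, tr.values,
                                   rtol=1e-12)

    def test_single_impulse_center_value(self):
        tr = Trace([0.0, 0.0, 5.0, 0.0, 0.0], 10.0)
        assert rolling_average(tr, 5).values[2] == pytest.approx(1.0)

    def test_matches_brute_force_mean(self, rng):
        # oracle: per-index mean over the symmetric in-bounds window
        for _ in range(20):
            v = rng.normal(size=rng.integers(5, 60))
            out = rolling_average(Trace(v, 10.0), 5).values
            h = 2
            for i in range(v.size):
                k = min(h, i, v.size - 1 - i)
                assert out[i] == pytest.approx(v[i - k:i + k + 1].mean(), rel=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            rolling_average(Trace(np.ones(10), 10.0), 4)


class TestEvokedFeatures:
    def test_triangular_pulse_geometry(self):
        # dff rises linearly to 1.0 at 2 s post-onset, back to 0 at 6 s
        fr = 10.0
        t = np.arange(120) / fr
        onset = 2.0
        d = np.interp(t, [onset, onset + 2.0, onset + 6.0], [0.0, 1.0, 0.0],
                      left=0.0, right=0.0)
        raw = Trace(np.full(120, 100.0), fr, StimWindow(onset, 0.5, 40.0))
        model = BleachModel(a=100.0, b=0.0, fit_window=(0, 20))
        feats = evoked_features(raw, model, raw.replace_values(d), noise_band_k=0.0)
        assert feats.time_to_peak_s == pytest.approx(2.0)
        assert feats.t50_recovery_s == pytest.approx(2.0)
        assert feats.t100_recovery_s == pytest.approx(4.0)
        assert feats.max_dff == pytest.approx(1.0)

    def test_never_recovering_trace_gives_null_t100(self):
        fr = 10.0
        d = np.concatenate([np.zeros(20), np.full(40, 2.0)])
        raw = Trace(np.full(60, 50.0), fr, StimWindow(2.0, 0.5, 40.0))
        model = BleachModel(a=50.0, b=0.0, fit_window=(0, 20))
        feats = evoked_features(raw, model, raw.replace_values(d))
        assert feats.t100_recovery_s is None
        assert feats.t50_recovery_s is None
        assert feats.max_dff == pytest.approx(2.0)
        assert feats.delta_F == pytest.approx(0.0)

    def test_resting_F_is_curve_at_last_prestim_frame(self):
        tr = power_trace(1000.0, -0.05, 500, stim=StimWindow(5.0, 1.0, 40.0))
        feats, _, model = analyze_trace(tr)
        onset = tr.stim_onset_frame()
        assert feats.resting_F == pytest.approx(model.predict(onset - 1))

    def test_missing_stim_metadata_rejected(self):
        tr = power_trace(100.0, -0.01, 50)
        model = fit_bleach(tr, 50)
        with pytest.raises(ValueError):
            evoked_features(tr, model, dff(correct_bleach(tr, model)))

    def test_time_features_invariant_to_onset_shift(self):
        # same response shape placed at two different onsets
        fr = 50.0
        feats = []
        for onset in (3.0, 6.0):
            cfg = SimConfig(stim=StimWindow(onset, 2.0, 40.0), duration_s=20.0,
                            seed=2)
            tr, _ = simulate_trace(cfg)
            feats.append(analyze_trace(tr)[0])
        assert feats[0].time_to_peak_s == pytest.approx(
            feats[1].time_to_peak_s, abs=1.0 / fr)
        assert feats[0].t50_recovery_s == pytest.approx(
            feats[1].t50_recovery_s, abs=1.0 / fr)

    def test_noiseless_pipeline_recovers_true_peak(self):
        cfg = SimConfig(seed=0)
        tr, truth = simulate_trace(cfg)
        model = fit_bleach(tr)
        d = dff(correct_bleach(tr, model))  # no smoothing: exact recovery
        feats = evoked_features(tr, model, d)
        assert feats.max_dff == pytest.approx(truth.true_peak_dff, abs=1e-6)


class TestNormalizations:
    def test_control_mean_maps_to_one(self):
        vals = [2.0, 4.0, 1.5]
        out = normalize_group_to_control(vals, ["WT", "WT", "mut"], "WT")
        np.testing.assert_allclose(out, [2 / 3, 4 / 3, 0.5])

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError):
            normalize_group_to_control([0.0, 0.0, 1.0], ["WT", "WT", "m"], "WT")

    def test_wt_span_set_to_exactly_100(self):
        wt = Trace(np.array([-0.2, 0.3, 0.8, 0.1]), 10.0)
        other = Trace(np.array([0.0, 0.2, 0.4, 0.1]), 10.0)
        w2, o2 = normalize_timecourse_pair(wt, other)
        assert np.ptp(w2.values) == pytest.approx(100.0, abs=1e-12)
        np.testing.assert_allclose(o2.values, other.values * 100.0)

    def test_already_spanning_100_unchanged(self):
        wt = Trace(np.array([0.0, 100.0, 40.0]), 10.0)
        w2, _ = normalize_timecourse_pair(wt, wt)
        np.testing.assert_allclose(w2.values, wt.values)

    def test_flat_wt_rejected(self):
        wt = Trace(np.full(10, 5.0), 10.0)
        with pytest.raises(ValueError):
            normalize_timecourse_pair(wt, wt)

    def test_batch_normalize_removes_gain_difference(self):
        # two setups with 2x gain difference but identical mutant/WT ratios
        values = [10.0, 5.0, 20.0, 10.0]
        genos = ["WT", "mut", "WT", "mut"]
        batches = ["rig1", "rig1", "rig2", "rig2"]
        out = batch_normalize(values, genos, batches, "WT")
        np.testing.assert_allclose(out, [1.0, 0.5, 1.0, 0.5])

    def test_batch_without_control_rejected(self):
        with pytest.raises(ValueError):
            batch_normalize([1.0, 2.0], ["mut", "mut"], ["b1", "b1"], "WT")

    def test_single_batch_equals_group_normalization(self, rng):
        vals = rng.uniform(1, 5, size=10)
        genos = ["WT"] * 5 + ["mut"] * 5
        one = batch_normalize(vals, genos, ["b"] * 10, "WT")
        two = normalize_group_to_control(vals, genos, "WT")
        np.testing.assert_allclose(one, two)


class TestGenotypeContrast:
    def test_mutant_to_wt_ratio_recovered(self):
        # WT scale 1.0 vs mutant scale 0.5, n=20 each, noise 2% of baseline
        rng = np.random.default_rng(42)
        means = {}
        for geno, scale in (("WT", 1.0), ("mutant", 0.5)):
            vals = []
            for k in range(20):
                cfg = SimConfig(genotype_scale=scale,
                                noise=NoiseParams(gaussian_sd=20.0),
                                seed=int(rng.integers(2 ** 31)))
                tr, _ = simulate_trace(cfg)
                vals.append(analyze_trace(tr)[0].max_dff)
            means[geno] = np.mean(vals)
        assert 0.45 < means["mutant"] / means["WT"] < 0.55


def test_channel_ratio_is_per_frame_division():
    num = Trace(np.array([2.0, 4.0, 6.0]), 10.0)
    den = Trace(np.array([2.0, 2.0, 3.0]), 10.0)
    np.testing.assert_allclose(channel_ratio(num, den).values, [1.0, 2.0, 2.0])
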