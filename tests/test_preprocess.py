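import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import backnirs as bn
from backnirs.mbll import DpfSpec, compute_dpf, forward_mbll, mbll_invert
from backnirs.preprocess import (PreprocessConfig, apply_ssr,
                                 detrend_and_baseline, preprocess_recording,
                                 segment, sg_bandpass,
                                 short_separation_regress)
from backnirs.simulate import SimulationParams, generate_protocol, simulate_recording
from backnirs.timeseries import ChannelTimeSeries, intensity_to_od
from tests.conftest import make_tensor

FS = 7.81


class TestDpf:
    def test_value_matches_hand_evaluation(self):
        # independent evaluation of the published general equation:
        # 223.3 + 0.05624*30^0.8493 - 5.723e-7*760^3 + 1.245e-3*760^2 - 0.9025*760
        assert compute_dpf(30, 760) == pytest.approx(6.2966005278, abs=1e-9)
        assert compute_dpf(30, 850) == pytest.approx(5.2343278278, abs=1e-9)

    @pytest.mark.parametrize("wavelength", [690, 760, 850, 950])
    def test_strictly_increasing_in_age(self, wavelength):
        ages = np.arange(0, 101, 10)
        vals = [compute_dpf(a, wavelength) for a in ages]
        assert np.all(np.diff(vals) > 0)

    def test_physiological_range(self):
        assert 4 <= compute_dpf(30, 760) <= 9
        assert 4 <= compute_dpf(30, 850) <= 9

    def test_out_of_range_wavelength_raises(self):
        with pytest.raises(ValueError):
            compute_dpf(30, 600)


class TestMbllInversion:
    def test_zero_od_gives_zero_chromophores(self, layout):
        labels = [(c.id, wl) for c in layout.channels for wl in (760, 850)]
        od = ChannelTimeSeries(np.zeros((36, 20)), labels)
        conc = mbll_invert(od, layout, DpfSpec(30.0))
        assert np.all(conc.values == 0.0)

    def test_roundtrip_exact(self, layout):
        rng = np.random.default_rng(1)
        labels = [(c.id, m) for c in layout.channels for m in ("O2Hb", "HHb")]
        conc = ChannelTimeSeries(rng.normal(0, 0.5, size=(36, 100)), labels,
                                 kind="chromophore")
        dpf = DpfSpec(33.5)
        back = mbll_invert(forward_mbll(conc, layout, dpf), layout, dpf)
        np.testing.assert_allclose(back.values, conc.values, rtol=1e-9, atol=1e-12)

    def test_pure_o2hb_od_pattern_yields_zero_hhb(self, layout):
        from backnirs.mbll import load_extinction_table
        table = load_extinction_table()
        dpf = DpfSpec(30.0)
        ch = layout.channel(5)
        d_cm = ch.separation_mm / 10
        # OD proportional to the O2Hb extinction column at each wavelength
        t = np.linspace(0, 1, 30)
        rows = {wl: table[wl]["O2Hb"] * 1e-6 * d_cm * dpf.dpf_by_wavelength[wl] * t
                for wl in (760, 850)}
        labels = [(c.id, wl) for c in layout.channels for wl in (760, 850)]
        values = np.zeros((36, 30))
        od = ChannelTimeSeries(values, labels)
        values[od.row_index(5, 760)] = rows[760]
        values[od.row_index(5, 850)] = rows[850]
        conc = mbll_invert(od, layout, dpf)
        np.testing.assert_allclose(conc.row(5, "HHb"), 0.0, atol=1e-12)
        np.testing.assert_allclose(conc.row(5, "O2Hb"), t, rtol=1e-9, atol=1e-12)


class TestSgBandpass:
    def _series(self, x):
        return ChannelTimeSeries(np.atleast_2d(x), [(1, "O2Hb")], FS,
                                 kind="chromophore")

    def test_annihilates_constants(self):
        out = sg_bandpass(self._series(np.full(2000, 3.7)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_annihilates_slow_cubic(self):
        t = np.arange(2000) / FS
        x = 1.0 + 0.01 * t + 1e-5 * t**2 - 1e-8 * t**3
        out = sg_bandpass(self._series(x))
        assert np.max(np.abs(out.values)) <= 1e-6 * np.max(np.abs(x))

    def test_frequency_response(self):
        # the 80 s third-degree trend filter tracks only <~0.02 Hz, so the
        # band-pass strongly attenuates 0.01 Hz and passes 0.08-0.2 Hz
        n = 8000
        t = np.arange(n) / FS
        sl = slice(n // 4, 3 * n // 4)

        def gain(freq):
            x = np.sin(2 * np.pi * freq * t)
            y = sg_bandpass(self._series(x)).values[0]
            return np.sqrt(2 * np.mean(y[sl] ** 2))

        assert gain(0.01) <= 0.20
        for f in (0.08, 0.12, 0.2):
            assert gain(f) >= 0.70

    def test_evoked_response_peak_preserved_within_25pct(self):
        # 5 s boxcar convolved with the canonical response, one event
        from backnirs.simulate import double_gamma_hrf
        n = 4000
        t = np.arange(n) / FS
        h = double_gamma_hrf(np.arange(0, 32, 1 / FS))
        box = np.zeros(n)
        onset = 1500
        box[onset:onset + int(round(5 * FS))] = 1.0
        resp = np.convolve(box, h)[:n]
        out = sg_bandpass(self._series(resp)).values[0]
        peak_in = resp.max()
        win = slice(onset, onset + int(round(20 * FS)))
        assert abs(out[win].max() - peak_in) <= 0.25 * peak_in

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError, match="trend window"):
            sg_bandpass(self._series(np.zeros(500)))


class TestSegmentation:
    def test_study_protocol_yields_15_trials_per_condition(
            self, preprocessed_tensor):
        for key, arr in preprocessed_tensor.data.items():
            assert arr.shape == (15, 99)

    def test_segment_sample_counts(self, preprocessed_tensor):
        t = preprocessed_tensor
        assert (t.pre_samples, t.stim_samples, t.post_samples) == (30, 39, 30)
        assert t.segment_length == 99
        assert t.onset_index == 30

    def test_single_event_single_segment(self, layout):
        proto = generate_protocol(1, 5, 15, 100, seed=0)
        labels = [(c.id, m) for c in layout.channels for m in ("O2Hb", "HHb")]
        series = ChannelTimeSeries(
            np.zeros((36, proto.n_samples())), labels, FS, kind="chromophore")
        tensor = segment(series, proto)
        assert all(arr.shape[0] == 1 for arr in tensor.data.values())

    def test_event_too_early_raises(self, layout):
        proto = generate_protocol(1, 5, 15, 2.0, seed=0)  # onset at 2 s < 3.9 s
        labels = [(1, "O2Hb")]
        series = ChannelTimeSeries(np.zeros((1, 800)), labels, FS,
                                   kind="chromophore")
        with pytest.raises(ValueError, match="outside the recording"):
            segment(series, proto)


class TestDetrendBaseline:
    def test_pure_line_maps_to_zero(self):
        t = np.arange(99.0)
        arr = np.stack([2.0 + 0.3 * t, -1.0 + 0.05 * t])
        tensor = make_tensor({(1, "PA30", "O2Hb"): arr})
        out = detrend_and_baseline(tensor)
        np.testing.assert_allclose(out.data[(1, "PA30", "O2Hb")], 0.0, atol=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_pre_isi_median_exactly_zero(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.normal(size=(5, 99))
        tensor = make_tensor({(3, "Brush", "HHb"): arr})
        out = detrend_and_baseline(tensor)
        med = np.median(out.data[(3, "Brush", "HHb")][:, :30], axis=1)
        np.testing.assert_allclose(med, 0.0, atol=1e-12)

    def test_step_on_line_recovered_within_10pct(self):
        t = np.arange(99.0)
        h = 1.0
        arr = (0.5 + 0.02 * t + np.where(t >= 30, h, 0.0))[None, :]
        tensor = make_tensor({(1, "PAPain", "O2Hb"): arr})
        out = detrend_and_baseline(tensor)
        win = bn.response_window_indices(99, FS, 30)
        got = np.median(out.data[(1, "PAPain", "O2Hb")][0, win.start:win.stop])
        assert abs(got - h) <= 0.10 * h

    def test_double_baselining_rejected(self):
        tensor = make_tensor({(1, "PA30", "O2Hb"): np.ones((2, 99))})
        out = detrend_and_baseline(tensor)
        with pytest.raises(ValueError, match="already baselined"):
            detrend_and_baseline(out)


class TestSsr:
    def test_proportional_short_removed_exactly(self):
        rng = np.random.default_rng(0)
        short = rng.normal(size=200)
        corrected, alpha = short_separation_regress(2.0 * short, short)
        assert alpha == pytest.approx(2.0)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-12)

    def test_orthogonal_signals_untouched(self):
        n = 400
        t = np.arange(n)
        long = np.sin(2 * np.pi * t / 50)
        short = np.cos(2 * np.pi * t / 50)  # orthogonal over full periods
        corrected, alpha = short_separation_regress(long, short)
        assert abs(alpha) < 1e-10
        np.testing.assert_allclose(corrected, long, atol=1e-9)

    def test_corrected_is_orthogonal_to_short(self):
        rng = np.random.default_rng(3)
        long, short = rng.normal(size=(2, 150))
        corrected, _ = short_separation_regress(long, short)
        assert abs(np.dot(corrected, short)) < 1e-9

    def test_flat_short_channel_yields_alpha_zero(self, caplog):
        long = np.arange(10.0)
        corrected, alpha = short_separation_regress(long, np.zeros(10))
        assert alpha == 0.0
        np.testing.assert_array_equal(corrected, long)

    def test_apply_ssr_uses_mapped_short_channel(self, layout):
        rng = np.random.default_rng(4)
        s_sma = rng.normal(size=(2, 99))
        s_s1 = rng.normal(size=(2, 99))
        arrays = {(2, "PA30", "O2Hb"): s_sma, (10, "PA30", "O2Hb"): s_s1,
                  (5, "PA30", "O2Hb"): 3.0 * s_sma,
                  (17, "PA30", "O2Hb"): -1.5 * s_s1}
        tensor = make_tensor(arrays)
        out, alphas = apply_ssr(tensor, layout, return_alphas=True)
        np.testing.assert_allclose(out.data[(5, "PA30", "O2Hb")], 0.0, atol=1e-10)
        np.testing.assert_allclose(out.data[(17, "PA30", "O2Hb")], 0.0, atol=1e-10)
        np.testing.assert_allclose(alphas[(5, "PA30", "O2Hb")], 3.0)
        np.testing.assert_allclose(alphas[(17, "PA30", "O2Hb")], -1.5)
        # short channels pass through untouched
        np.testing.assert_array_equal(out.data[(2, "PA30", "O2Hb")], s_sma)

    def test_apply_ssr_twice_is_idempotent(self, layout):
        rng = np.random.default_rng(5)
        arrays = {(2, "Brush", "HHb"): rng.normal(size=(3, 99)),
                  (10, "Brush", "HHb"): rng.normal(size=(3, 99)),
                  (4, "Brush", "HHb"): rng.normal(size=(3, 99)),
                  (12, "Brush", "HHb"): rng.normal(size=(3, 99))}
        once = apply_ssr(make_tensor(arrays), layout)
        _twice, alphas = apply_ssr(once, layout, return_alphas=True)
        for a in alphas.values():
            assert np.max(np.abs(a)) < 1e-10

    def test_missing_short_segments_raise(self, layout):
        tensor = make_tensor({(5, "PA30", "O2Hb"): np.ones((2, 99))})
        with pytest.raises(KeyError, match="short-channel"):
            apply_ssr(tensor, layout)

    def test_shared_superficial_component_suppressed(self, layout):
        # shared scalp signal, noiseless short channel: corrected long-channel
        # superficial residual has <= 1% of the superficial variance
        proto = generate_protocol(6, 5, 15, 100, seed=1)
        params = SimulationParams(
            seed=2, noise_sd_od=0.0, drift_slope_od_per_s=0.0,
            drift_walk_od=0.0, oscillators=[],
            hrf_amplitude={k: 0.0 for k in SimulationParams().hrf_amplitude})
        od, truth = simulate_recording(layout, proto, params)
        tensor = preprocess_recording(od, layout, params.subject_age_years, proto)
        pre_var = np.var(truth.superficial.row(5, "O2Hb"))
        assert pre_var > 0
        corrected = np.concatenate(
            [tensor.data[(5, c, "O2Hb")].ravel() for c in proto.conditions])
        assert np.var(corrected) <= 0.01 * pre_var

    def test_ssr_never_increases_cerebral_error(self, layout):
        # with a shared superficial component and noiseless short channel,
        # correcting can only bring the long channel closer to the cerebral
        # ground truth
        proto = generate_protocol(6, 5, 15, 100, seed=3)
        params = SimulationParams(seed=4, noise_sd_od=0.0,
                                  drift_slope_od_per_s=0.0, drift_walk_od=0.0,
                                  oscillators=[])
        od, truth = simulate_recording(layout, proto, params)
        cfg_ssr = PreprocessConfig()
        cfg_raw = PreprocessConfig(ssr_scope="segment")
        with_ssr = preprocess_recording(od, layout, params.subject_age_years,
                                        proto, cfg_ssr)
        # reference: same chain with SSR disabled entirely
        chromo = mbll_invert(od, layout, DpfSpec(params.subject_age_years))
        chromo = sg_bandpass(chromo)
        no_ssr = detrend_and_baseline(segment(chromo, proto))
        truth_chromo = sg_bandpass(truth.cerebral)
        truth_tensor = detrend_and_baseline(segment(truth_chromo, proto))
        for ch in (5, 17):
            for cond in proto.conditions:
                key = (ch, cond, "O2Hb")
                ref = truth_tensor.data[key]
                err_with = np.sqrt(np.mean((with_ssr.data[key] - ref) ** 2))
                err_without = np.sqrt(np.mean((no_ssr.data[key] - ref) ** 2))
                assert err_with <= err_without + 1e-12


class TestPipeline:
    def test_linearity_up_to_ssr(self, layout):
        proto = generate_protocol(4, 5, 15, 100, seed=6)
        params = SimulationParams(seed=7)
        od, _ = simulate_recording(layout, proto, params)
        scaled = od.copy_with(3.0 * od.values)
        dpf = DpfSpec(params.subject_age_years)

        def pre_ssr(o):
            return detrend_and_baseline(
                segment(sg_bandpass(mbll_invert(o, layout, dpf)), proto))

        a = pre_ssr(od)
        b = pre_ssr(scaled)
        for key in a.data:
            np.testing.assert_allclose(b.data[key], 3.0 * a.data[key],
                                       rtol=1e-9, atol=1e-12)

    def test_intensity_input_equivalent_to_od(self, layout):
        proto = generate_protocol(4, 5, 15, 100, seed=8)
        params = SimulationParams(seed=9)
        od, _ = simulate_recording(layout, proto, params)
        # synthesize intensities whose -log10(I/I_ref) reproduces the OD up
        # to the baseline-mean reference convention
        intensity = od.copy_with(10.0 ** (-od.values), kind="intensity")
        od_back = intensity_to_od(intensity, proto.baseline_s)
        t1 = preprocess_recording(od_back, layout, 33.5, proto)
        # the reference shift is a per-channel constant; the band-pass
        # removes constants, so the tensors agree
        t2 = preprocess_recording(od, layout, 33.5, proto)
        for key in t1.data:
            np.testing.assert_allclose(t1.data[key], t2.data[key],
                                       rtol=1e-7, atol=1e-9)
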