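"""Extraction branches: SG smoothing, envelope pipeline, TOF pickers, QC."""

import math
from dataclasses import replace

import numpy as np
import pytest

import sparktono as sp
from sparktono.synth_signals import analytic_arrival
from sparktono.tof_extraction import _lowpass_corner_hz


def _trace(x, fs=1e5, t0=0.0):
    return sp.SignalTrace(samples=np.asarray(x, dtype=float),
                          sample_rate_hz=fs, t0_s=t0)


class TestSavgol:
    def test_constant_trace_unchanged(self):
        tr = _trace(np.full(500, 3.7))
        out = sp.savgol_smooth(tr, 51, 3)
        np.testing.assert_allclose(out.samples, 3.7)

    def test_quadratic_reproduced_exactly(self):
        t = np.linspace(-1, 1, 400)
        tr = _trace(t ** 2)
        out = sp.savgol_smooth(tr, 41, 2)
        interior = slice(21, -21)
        np.testing.assert_allclose(out.samples[interior], t[interior] ** 2,
                                   atol=1e-12)

    def test_matches_sliding_least_squares_oracle(self, rng):
        """SG output equals an explicit per-window polynomial LS fit."""
        x = rng.normal(size=5000)
        window, order = 101, 3
        out = sp.savgol_smooth(_trace(x), window, order).samples
        half = window // 2
        idx = rng.choice(np.arange(half, x.size - half), size=100, replace=False)
        for i in idx:
            seg = x[i - half:i + half + 1]
            coeffs = np.polynomial.polynomial.polyfit(
                np.arange(-half, half + 1), seg, order)
            assert out[i] == pytest.approx(coeffs[0], abs=1e-9)

    def test_trace_shorter_than_window(self):
        with pytest.raises(sp.ExtractionError):
            sp.savgol_smooth(_trace(np.zeros(10)), 51, 3)


class TestThirdPositivePeak:
    def test_gated_sinusoid_third_peak_at_2p25_periods(self):
        fs, f = 1e5, 500.0
        t = np.arange(int(fs * 0.02)) / fs
        t_on = 5e-3
        x = np.where(t >= t_on, np.sin(2 * np.pi * f * (t - t_on)), 0.0)
        est = sp.third_positive_peak_tof(_trace(x, fs))
        assert est.qc == "accepted"
        assert est.tof_s == pytest.approx(t_on + 2.25 / f, abs=1.5 / fs)

    def test_all_negative_trace_rejected(self):
        est = sp.third_positive_peak_tof(_trace(-np.ones(100) - np.sin(
            np.linspace(0, 20, 100)) * 0.1))
        assert est.qc == "rejected"

    def test_two_lobe_packet_rejected(self):
        t = np.linspace(0, 1, 1000)
        x = np.exp(-((t - 0.5) / 0.05) ** 2) * np.cos(
            2 * np.pi * 2.0 * (t - 0.5))  # only a couple of positive lobes
        est = sp.third_positive_peak_tof(_trace(x))
        assert est.qc == "rejected"


class TestEnvelope:
    def test_zero_trace_zero_envelope(self):
        env = sp.envelope(_trace(np.zeros(4000)), sp.FilterSpec(
            median_window_points=5, mean_window_points=5))
        np.testing.assert_allclose(env.samples, 0.0)

    def test_unit_dc_gain(self):
        spec = sp.FilterSpec(median_window_points=9, mean_window_points=7)
        env = sp.envelope(_trace(np.ones(6000)), spec)
        interior = env.samples[500:-500]
        np.testing.assert_allclose(interior, 1.0, atol=1e-6)

    def test_time_shift_equivariance(self, rng):
        """envelope(shift(x)) == shift(envelope(x)) away from the edges."""
        fs = 1e5
        n, shift = 8000, 250
        t = np.arange(n) / fs
        x = np.exp(-((t - 0.03) / 0.004) ** 2) * np.cos(2 * np.pi * 800 * t)
        spec = sp.FilterSpec(median_window_points=9, mean_window_points=7)
        e1 = sp.envelope(_trace(x, fs), spec).samples
        e2 = sp.envelope(_trace(np.roll(x, shift), fs), spec).samples
        core = slice(2000, 6000)
        np.testing.assert_allclose(e2[core.start + shift:core.stop + shift],
                                   e1[core], atol=1e-6)

    def test_envelope_peak_at_packet_center(self, eye_trace_clean):
        cfg = sp.eye_config(20.0)
        spec = sp.FilterSpec().scaled_to(cfg.sample_rate_hz)
        env = sp.envelope(eye_trace_clean, spec)
        t_peak = np.argmax(env.samples) / cfg.sample_rate_hz
        assert abs(t_peak - analytic_arrival(cfg)) <= 1 / (
            2 * cfg.burst.center_frequency_hz)

    def test_unsatisfiable_lowpass_constraint(self):
        tr = _trace(np.zeros(4000), fs=8e3)  # Nyquist 4 kHz < 5 kHz constraint
        with pytest.raises(sp.ParameterError):
            sp.envelope(tr, sp.FilterSpec(median_window_points=3,
                                          mean_window_points=3))

    def test_corner_frequency_attenuation_design(self):
        # single-pass Butterworth magnitude is -50 dB at 5 kHz by construction
        from scipy import signal as ss
        spec = sp.FilterSpec()
        corner = _lowpass_corner_hz(spec)
        b, a = ss.butter(spec.lp_order, corner, fs=2e5, btype="low")
        _, h = ss.freqz(b, a, worN=[spec.lp_attenuation_freq_hz], fs=2e5)
        assert 20 * np.log10(abs(h[0])) == pytest.approx(-50.0, abs=0.1)


class TestPickers:
    def test_envelope_peak_single_maximum(self):
        fs = 1e5
        x = np.zeros(1000)
        x[200] = 1.0
        env = sp.EnvelopeTrace(samples=x, sample_rate_hz=fs)
        assert sp.envelope_peak_tof(env).tof_s == pytest.approx(200 / fs)

    def test_envelope_peak_tie_breaks_earliest(self):
        x = np.zeros(1000)
        x[[300, 600]] = 2.0
        env = sp.EnvelopeTrace(samples=x, sample_rate_hz=1e5)
        assert sp.envelope_peak_tof(env).tof_s == pytest.approx(300 / 1e5)

    def test_flat_envelope_rejected(self):
        env = sp.EnvelopeTrace(samples=np.ones(100), sample_rate_hz=1e5)
        assert sp.envelope_peak_tof(env).qc == "rejected"

    def test_energy_centroid_single_sample(self):
        fs = 1e6
        x = np.zeros(3000)
        x[1000] = 5.0
        est = sp.energy_centroid_tof(_trace(x, fs))
        assert est.tof_s == pytest.approx(1000 / fs)

    def test_energy_centroid_two_equal_samples(self):
        fs = 1e6
        x = np.zeros(5000)
        x[1000] = 2.0
        x[3000] = -2.0  # energy is amplitude-squared: sign-insensitive
        est = sp.energy_centroid_tof(_trace(x, fs))
        assert est.tof_s == pytest.approx(2000 / fs)

    def test_energy_centroid_zero_energy_rejected(self):
        assert sp.energy_centroid_tof(_trace(np.zeros(100))).qc == "rejected"

    def test_highest_peak(self):
        fs = 1e5
        x = np.zeros(1000)
        x[150] = 3.0
        assert sp.highest_peak_tof(_trace(x, fs)).tof_s == pytest.approx(150 / fs)

    def test_highest_peak_nonpositive_rejected(self):
        assert sp.highest_peak_tof(_trace(-np.ones(100))).qc == "rejected"

    def test_all_methods_within_half_carrier_period(self, eye_trace_clean):
        cfg = sp.eye_config(20.0)
        t_true = analytic_arrival(cfg)
        half = 1 / (2 * cfg.burst.center_frequency_hz)
        for method in ("envelope_peak", "energy_centroid", "highest_peak"):
            est = sp.extract_tof(eye_trace_clean, "eye", method=method)
            assert est.accepted
            assert abs(est.tof_s - t_true) <= half, method
        spec = sp.FilterSpec().scaled_to(cfg.sample_rate_hz)
        sm = sp.savgol_smooth(eye_trace_clean, spec.sg_window_odd, 3)
        est = sp.third_positive_peak_tof(sm)
        assert abs(est.tof_s - t_true) <= half, "third_peak"


class TestSnrAndQc:
    def test_identical_windows_zero_db(self, rng):
        x = rng.normal(size=10_000)
        tr = _trace(np.concatenate([x, x]), fs=1e6)
        policy = sp.QcPolicy(noise_window=(0.0, 0.01), signal_window=(0.01, 0.02))
        assert sp.snr_estimate(tr, policy) == pytest.approx(0.0, abs=1e-9)

    def test_sine_over_noise(self, rng):
        fs, n = 1e6, 200_000
        t = np.arange(n) / fs
        amp, sigma = 2.0, 0.25
        x = np.where(t < 0.1, rng.normal(0, sigma, n),
                     amp * np.sin(2 * np.pi * 5e3 * t))
        policy = sp.QcPolicy(noise_window=(0.0, 0.1), signal_window=(0.1, None))
        expected = 20 * math.log10(amp / (math.sqrt(2) * sigma))
        assert sp.snr_estimate(_trace(x, fs), policy) == pytest.approx(
            expected, abs=0.5)

    def test_zero_noise_rms_is_infinite(self):
        x = np.zeros(2000)
        x[1500:] = 1.0
        policy = sp.QcPolicy(noise_window=(0.0, 1e-3), signal_window=(1e-3, None))
        assert sp.snr_estimate(_trace(x, 1e6), policy) == math.inf

    def test_overlapping_windows_rejected(self):
        with pytest.raises(sp.ParameterError):
            sp.QcPolicy(noise_window=(0.0, 1e-3), signal_window=(5e-4, 2e-3))


@pytest.fixture(scope="module")
def sweep():
    cfg = sp.eye_config(seed=5)
    return sp.generate_pressure_series(cfg, list(range(10, 71, 10)), 3)


class TestBatchExtract:

    def test_noiseless_sweep_all_accepted(self, sweep):
        result = sp.batch_extract(sweep, "eye")
        assert len(result.table) == 21
        assert result.rejected_fraction == 0.0
        assert (result.table["qc"] == "accepted").all()

    def test_tof_monotone_decreasing_in_pressure(self, sweep):
        result = sp.batch_extract(sweep, "eye")
        mean_tof = result.table.groupby("reference_iop_mmHg")["tof_s"].mean()
        tofs = mean_tof.sort_index().to_numpy()
        assert np.all(np.diff(tofs) < 0)

    def test_noise_only_traces_rejected_and_counted(self, sweep):
        cfg = sp.eye_config(seed=99, snr_db=0.0)
        cfg = replace(cfg, burst=replace(cfg.burst, amplitude=0.0))
        traces = dict(sweep.traces)
        manifest = sweep.manifest.copy()
        for k in range(2):
            sid = f"noise_only_{k}"
            tr = sp.synthesize_trace(replace(cfg, seed=1000 + k))
            tr.meta["sample_id"] = sid
            traces[sid] = tr
            manifest.loc[len(manifest)] = {
                "file": f"{sid}.csv", "sample_id": sid, "mode": "eye",
                "reference_iop_mmHg": 20.0, "sweep_order": len(manifest)}
        ds = sp.TraceDataset(traces=traces, manifest=manifest)
        result = sp.batch_extract(ds, "eye")
        rejected = result.table.loc[result.table["qc"] == "rejected_low_snr"]
        assert set(rejected["sample_id"]) == {"noise_only_0", "noise_only_1"}
        assert result.rejected_fraction == pytest.approx(2 / 23)

    def test_override_flags_manually_corrected(self, sweep):
        sid = sweep.manifest["sample_id"].iloc[0]
        result = sp.batch_extract(sweep, "eye",
                                  overrides={sid: (1.23e-3, "visual fix")})
        row = result.table.set_index("sample_id").loc[sid]
        assert row["qc"] == "manually_corrected"
        assert row["tof_s"] == pytest.approx(1.23e-3)

    def test_unknown_override_id_raises(self, sweep):
        with pytest.raises(sp.ProtocolError):
            sp.batch_extract(sweep, "eye", overrides={"nope": (1e-3, "")})

    def test_extraction_deterministic(self, sweep):
        t1 = sp.batch_extract(sweep, "eye").table
        t2 = sp.batch_extract(sweep, "eye").table
        assert t1.equals(t2)

    def test_phantom_branch(self):
        cfg = sp.phantom_config(seed=6)
        ds = sp.generate_pressure_series(cfg, [20, 30, 40], 1)
        result = sp.batch_extract(ds, "phantom")
        assert (result.table["method"] == "third_peak").all()
        assert (result.table["qc"] == "accepted").all()
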