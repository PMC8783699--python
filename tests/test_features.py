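"""R-peak detection, SDPPG, per-cycle extraction and synthetic closure."""

import numpy as np
import pytest

from bpcluster.features import (
    ExtractionConfig,
    beat_windows,
    build_feature_table,
    detect_r_peaks,
    extract_hr,
    extract_pir,
    extract_ptt,
    extract_sbp_dbp,
    second_derivative_ppg,
)
from bpcluster.io import WaveformRecord
from bpcluster.synth import RegimeSpec, default_regimes, generate_beat_train


def spike_train(positions, n, fs=125.0, sigma_s=0.01):
    t = np.arange(n)
    ecg = np.zeros(n)
    for p in positions:
        ecg += np.exp(-0.5 * ((t - p) / (sigma_s * fs)) ** 2)
    return ecg


class TestDetectRPeaks:
    def test_known_spike_positions_recovered(self):
        pos = [60, 200, 330, 480, 610]
        peaks = detect_r_peaks(spike_train(pos, 750), 125.0)
        assert len(peaks) == 5
        assert np.all(np.abs(peaks - np.array(pos)) <= 1)

    def test_flat_signal_gives_empty_list(self):
        assert len(detect_r_peaks(np.zeros(500), 125.0)) == 0

    def test_refractory_keeps_larger_of_close_pair(self):
        # two spikes 0.1 s apart with 0.25 s refractory: larger survives
        n, fs = 500, 125.0
        t = np.arange(n)
        ecg = 0.6 * np.exp(-0.5 * ((t - 200) / 1.5) ** 2)
        ecg += 1.0 * np.exp(-0.5 * ((t - 212.5) / 1.5) ** 2)
        peaks = detect_r_peaks(ecg, fs, ExtractionConfig(refractory_s=0.25))
        assert len(peaks) == 1
        assert abs(peaks[0] - 212) <= 1

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            detect_r_peaks(np.zeros(100), 125.0)


class TestSecondDerivative:
    cfg = ExtractionConfig(smoothing_window_s=0.0)  # pure second difference

    def test_quadratic_has_constant_curvature(self):
        t = np.arange(50) / 10.0
        sd = second_derivative_ppg(t**2, 10.0, self.cfg)
        np.testing.assert_allclose(sd[1:-1], 2.0, atol=1e-9)

    def test_linear_ramp_has_zero_curvature(self):
        sd = second_derivative_ppg(np.linspace(0, 5, 100), 125.0, self.cfg)
        np.testing.assert_allclose(sd[1:-1], 0.0, atol=1e-7)

    def test_sine_matches_closed_form(self):
        fs, omega = 1000.0, 2 * np.pi * 2.0
        t = np.arange(3000) / fs
        sd = second_derivative_ppg(np.sin(omega * t), fs, self.cfg)
        expected = -(omega**2) * np.sin(omega * t)
        # central-difference truncation error bound: omega^4 h^2 / 12
        np.testing.assert_allclose(sd[1:-1], expected[1:-1],
                                   atol=1.5 * omega**4 / fs**2 / 12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            second_derivative_ppg(np.zeros(4), 125.0)


class TestPerCycleExtractors:
    def test_ptt_index_arithmetic(self):
        sdppg = np.zeros(400)
        sdppg[130] = 1.0
        r_peaks = np.array([100, 250])
        np.testing.assert_allclose(
            extract_ptt(r_peaks, sdppg, 125.0), [130 / 125 - 100 / 125])

    def test_ptt_gate_flags_late_peak(self):
        fs = 125.0
        sdppg = np.zeros(500)
        sdppg[int(100 + 0.9 * fs)] = 1.0  # 0.9 s after the R-peak
        ptt = extract_ptt(np.array([100, 400]), sdppg, fs,
                          ExtractionConfig(max_ptt_s=0.6))
        assert np.isnan(ptt[0])

    def test_pir_definition_and_inversion(self):
        ppg = np.concatenate([np.full(50, 0.5), np.full(50, 2.0)])
        win = [(0, 100)]
        assert extract_pir(ppg, win)[0] == pytest.approx(4.0)
        inv = ExtractionConfig(invert_pir=True)
        assert extract_pir(ppg, win, inv)[0] == pytest.approx(0.25)

    def test_pir_constant_window_is_one(self):
        assert extract_pir(np.full(60, 1.7), [(0, 60)])[0] == pytest.approx(1.0)

    def test_pir_nonpositive_window_flagged(self):
        assert np.isnan(extract_pir(np.zeros(60), [(0, 60)])[0])

    def test_pir_dc_offset_rescues_ac_coupled_window(self):
        ppg = np.concatenate([np.full(30, -0.5), np.full(30, 0.5)])
        cfg = ExtractionConfig(ppg_dc_offset=1.5)
        assert extract_pir(ppg, [(0, 60)], cfg)[0] == pytest.approx(2.0)

    def test_hr_arithmetic(self):
        assert extract_hr(np.array([0, 125]), 125.0)[0] == pytest.approx(60.0)
        assert extract_hr(np.array([0, 75]), 90.0)[0] == pytest.approx(72.0)

    def test_hr_fewer_than_two_peaks_empty(self):
        assert len(extract_hr(np.array([5]), 125.0)) == 0

    def test_sbp_dbp_max_min(self):
        abp = np.array([80.0, 100.0, 120.0, 95.0, 80.0])
        sbp, dbp = extract_sbp_dbp(abp, [(0, 5)])
        assert (sbp[0], dbp[0]) == (120.0, 80.0)

    def test_sbp_dbp_constant_cycle(self):
        sbp, dbp = extract_sbp_dbp(np.full(20, 90.0), [(0, 20)])
        assert (sbp[0], dbp[0]) == (90.0, 90.0)


class TestSyntheticClosure:
    """Feature recovery on noise-free synthetic records, per retained cycle."""

    @pytest.fixture(scope="class")
    def extracted(self, noise_free_population):
        out = []
        for rec in noise_free_population.records:
            table = build_feature_table(rec)
            truth = noise_free_population.truth
            truth = truth[truth["record_id"] == rec.record_id]
            merged = table.merge(truth, on=["record_id", "cycle_index"],
                                 suffixes=("_x", "_t"))
            assert len(merged) == len(table)
            out.append((rec, table, truth, merged))
        return out

    def test_all_complete_cycles_retained(self, extracted):
        for rec, table, truth, _ in extracted:
            assert len(table) >= 0.98 * (len(truth) - 1)

    def test_ptt_within_one_sample(self, extracted):
        for rec, _, _, m in extracted:
            assert np.abs(m["ptt_s_x"] - m["ptt_s_t"]).max() <= 1.0 / rec.sampling_rate_hz

    def test_pir_within_two_percent(self, extracted):
        for _, _, _, m in extracted:
            rel = np.abs(m["pir_ratio_x"] - m["pir_ratio_t"]) / m["pir_ratio_t"]
            assert rel.max() <= 0.02

    def test_hr_within_one_bpm(self, extracted):
        for _, _, _, m in extracted:
            assert np.abs(m["hr_bpm_x"] - m["hr_bpm_t"]).max() <= 1.0

    def test_sbp_dbp_exact_to_amplitude_resolution(self, extracted):
        for _, _, _, m in extracted:
            assert np.abs(m["sbp_mmHg_x"] - m["sbp_mmHg_t"]).max() <= 1e-9
            assert np.abs(m["dbp_mmHg_x"] - m["dbp_mmHg_t"]).max() <= 1e-9


class TestBuildFeatureTable:
    def test_beat_count_minus_one_rows(self):
        spec = default_regimes(n_beats=100, noise_sd_mmHg=0.0)[0]
        rec, truth = generate_beat_train(spec, 125.0, seed=0)
        table = build_feature_table(rec)
        assert len(table) == 99

    def test_all_zero_ppg_drops_every_cycle(self):
        spec = default_regimes(n_beats=30, noise_sd_mmHg=0.0)[0]
        rec, _ = generate_beat_train(spec, 125.0, seed=0)
        broken = WaveformRecord(rec.record_id, rec.sampling_rate_hz,
                                rec.ecg, np.zeros_like(rec.ppg), rec.abp)
        assert build_feature_table(broken).empty

    def test_ppg_shift_moves_every_ptt_equally(self):
        # delaying the PPG by m samples adds exactly m/fs to each cycle's PTT
        spec = RegimeSpec(regime_id=1, hr_mean_bpm=70, hr_sd=0.0, ptt_mean_s=0.2,
                          ptt_sd=0.0, pir_mean=1.8, pir_sd=0.0,
                          sbp_coeffs={"intercept": 120}, dbp_coeffs={"intercept": 80},
                          noise_sd_mmHg=0.0, n_beats=30)
        rec, _ = generate_beat_train(spec, 125.0, seed=0)
        m = 5
        shifted = WaveformRecord(rec.record_id, rec.sampling_rate_hz, rec.ecg,
                                 np.roll(rec.ppg, m), rec.abp)
        t0 = build_feature_table(rec)
        t1 = build_feature_table(shifted)
        merged = t0.merge(t1, on="cycle_index", suffixes=("_0", "_1"))
        np.testing.assert_allclose(
            merged["ptt_s_1"] - merged["ptt_s_0"], m / rec.sampling_rate_hz, atol=1e-12)

    def test_cycle_count_conservation(self, noise_free_population):
        rec = noise_free_population.records[0]
        table, ann = build_feature_table(rec, return_annotations=True)
        n_windows = len(ann.abp_cycle_bounds)
        n_dropped = n_windows - len(table)
        assert n_dropped >= 0
        assert len(table) + n_dropped == n_windows
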