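"""QC gates, triexponential template, sliding-template detection, summaries."""

import warnings

import numpy as np
import pytest

from synaptiq import (
    Recording,
    RecordingQC,
    SimEphysConfig,
    detect_events,
    integrate_charge,
    make_template,
    qc_pass,
    simulate_mpsc_trace,
    summarize_events,
)
from synaptiq.ephys import sliding_template_criterion

FS = 20_000.0


def _rec(samples, polarity="outward", qc=None):
    return Recording(np.asarray(samples, float), FS, polarity, qc=qc)


class TestQC:
    def _qc(self, holding=100.0, rs0=15.0, rs1=16.0):
        return RecordingQC(holding, rs0, rs1)

    def test_clean_recording_passes(self):
        ok, reasons = qc_pass(_rec(np.zeros(10), qc=self._qc()))
        assert ok and reasons == []

    def test_high_series_resistance_fails(self):
        ok, reasons = qc_pass(_rec(np.zeros(10), qc=self._qc(rs0=35.0, rs1=35.0)))
        assert not ok and any("resistance exceeds" in r for r in reasons)

    def test_series_resistance_drift_fails(self):
        # 20 -> 26 MOhm is a 30% change
        ok, reasons = qc_pass(_rec(np.zeros(10), qc=self._qc(rs0=20.0, rs1=26.0)))
        assert not ok and any("changed" in r for r in reasons)

    def test_excess_holding_current_fails(self):
        ok, reasons = qc_pass(_rec(np.zeros(10), qc=self._qc(holding=-250.0)))
        assert not ok and any("holding" in r for r in reasons)

    def test_all_violations_reported(self):
        ok, reasons = qc_pass(_rec(np.zeros(10), qc=RecordingQC(300.0, 40.0, 10.0)))
        assert not ok and len(reasons) == 3

    def test_missing_qc_metadata_rejected(self):
        with pytest.raises(ValueError):
            qc_pass(_rec(np.zeros(10)))


class TestTemplate:
    def test_biexponential_peak_time_closed_form(self):
        tr, td = 0.5, 5.0
        tpl = make_template(tr, td, decay_mix=1.0)
        t_star_ms = tr * np.log(1 + td / tr)
        assert abs(tpl.peak_time_ms - t_star_ms) <= 1e3 / FS  # within one sample

    def test_equal_decays_make_mix_irrelevant(self):
        a = make_template(0.5, 4.0, 4.0, decay_mix=0.2)
        b = make_template(0.5, 4.0, 4.0, decay_mix=0.9)
        np.testing.assert_allclose(a.waveform, b.waveform)

    def test_unit_peak_for_random_parameters(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tr = rng.uniform(0.1, 2.0)
            td1 = rng.uniform(tr + 0.1, 10.0)
            td2 = rng.uniform(tr + 0.1, 30.0)
            tpl = make_template(tr, td1, td2, decay_mix=rng.uniform(0, 1))
            assert abs(np.max(np.abs(tpl.waveform)) - 1.0) < 1e-9

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_template(-1.0, 3.0)
        with pytest.raises(ValueError):
            make_template(0.5, 3.0, decay_mix=1.5)

    def test_slow_rise_warns(self):
        with pytest.warns(UserWarning, match="slow-rise"):
            make_template(5.0, 3.0)


class TestDetection:
    TPL = make_template(0.5, 3.0, 12.0, decay_mix=0.7)

    def _single_event_trace(self, amp=20.0, onset_s=0.5, dur_s=2.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        s = rng.normal(0.0, noise, int(dur_s * FS)) if noise else np.zeros(int(dur_s * FS))
        i0 = int(onset_s * FS)
        s[i0 : i0 + self.TPL.n_samples] += amp * self.TPL.waveform
        return s

    def test_noise_free_single_event_exact(self):
        events = detect_events(_rec(self._single_event_trace()), self.TPL, 5.0)
        assert len(events) == 1
        e = events[0]
        assert abs(e.onset_s - 0.5) <= 1.0 / FS
        assert e.peak_amplitude_pA == pytest.approx(20.0, abs=0.1)
        assert e.charge_pC == pytest.approx(20.0 * self.TPL.integral_s(), rel=0.01)

    def test_constant_offset_invariance(self):
        s = self._single_event_trace(noise=2.0, seed=1)
        a = detect_events(_rec(s), self.TPL, 5.0)
        b = detect_events(_rec(s + 500.0), self.TPL, 5.0)
        assert [e.onset_s for e in a] == [e.onset_s for e in b]
        for ea, eb in zip(a, b):
            assert ea.peak_amplitude_pA == pytest.approx(eb.peak_amplitude_pA, abs=1e-6)

    def test_criterion_scale_invariance(self):
        s = self._single_event_trace(noise=2.0, seed=2)
        a = detect_events(_rec(s), self.TPL, 5.0)
        b = detect_events(_rec(3.0 * s), self.TPL, 5.0)
        assert len(a) == len(b) == 1
        assert a[0].criterion_value == pytest.approx(b[0].criterion_value, rel=1e-9)
        assert b[0].peak_amplitude_pA == pytest.approx(3.0 * a[0].peak_amplitude_pA)

    def test_sign_flip_with_polarity_switch(self):
        s = self._single_event_trace(noise=1.0, seed=3)
        out = detect_events(_rec(s, "outward"), self.TPL, 5.0)
        inw = detect_events(_rec(-s, "inward"), self.TPL, 5.0)
        assert [e.onset_s for e in out] == [e.onset_s for e in inw]
        assert inw[0].peak_amplitude_pA == pytest.approx(-out[0].peak_amplitude_pA)

    def test_pure_noise_false_positive_rate(self):
        # Monte-Carlo null: threshold 5 should essentially never fire on
        # Gaussian noise
        fp = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fp += len(detect_events(_rec(rng.normal(0, 2.0, int(10 * FS))), self.TPL, 5.0))
        assert fp <= 3  # <= ~1 false positive per minute over 200 s

    def test_amplitude_filter_rejects_sub_noise_events(self):
        s = self._single_event_trace(amp=5.0, noise=2.0, seed=4)
        events = detect_events(_rec(s), self.TPL, 5.0, min_amplitude_noise_sd=3.0)
        assert all(abs(e.peak_amplitude_pA) >= 3.0 * 1.5 for e in events)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_events(_rec(np.zeros(1000)), self.TPL, 0.0)

    def test_template_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sliding_template_criterion(np.zeros(100), self.TPL.waveform)

    def test_simulated_trace_recovery(self):
        cfg = SimEphysConfig(duration_s=60.0, seed=21)
        rec, truth = simulate_mpsc_trace(cfg)
        tpl = make_template(cfg.tau_rise_ms, cfg.tau_decay1_ms, cfg.tau_decay2_ms, cfg.decay_mix)
        events = detect_events(rec, tpl, 5.0)
        det = np.array([e.onset_s for e in events])
        used, tp = set(), 0
        for t in truth.event_onsets_s:
            d = np.abs(det - t)
            j = int(np.argmin(d))
            if d[j] <= 2e-3 and j not in used:
                used.add(j)
                tp += 1
        assert tp / len(truth.event_onsets_s) >= 0.90
        assert tp / len(events) >= 0.90
        amps = np.array([abs(e.peak_amplitude_pA) for e in events])
        assert abs(amps.mean() / truth.event_amplitudes_pA.mean() - 1) <= 0.05


class TestSummary:
    def test_rectangular_event_charge(self):
        # 10 pA for 10 ms -> 0.1 pC, exactly
        s = np.zeros(int(0.1 * FS))
        s[200 : 200 + int(0.01 * FS)] = 10.0
        assert integrate_charge(s, 0, len(s), 0.0, FS) == pytest.approx(0.1, abs=1e-12)

    def test_empty_events(self):
        summ = summarize_events([], 300.0)
        assert summ.frequency_hz == 0.0
        assert summ.total_charge_pC == 0.0
        assert summ.inter_event_intervals_s.size == 0

    def test_summary_identities(self):
        cfg = SimEphysConfig(duration_s=30.0, seed=13)
        rec, _ = simulate_mpsc_trace(cfg)
        tpl = make_template(cfg.tau_rise_ms, cfg.tau_decay1_ms, cfg.tau_decay2_ms, cfg.decay_mix)
        events = detect_events(rec, tpl, 5.0)
        summ = summarize_events(events, rec.duration_s)
        assert summ.frequency_hz * summ.duration_s == pytest.approx(summ.n_events)
        onsets = sorted(e.onset_s for e in events)
        assert summ.inter_event_intervals_s.sum() == pytest.approx(onsets[-1] - onsets[0])
        assert summ.total_charge_pC == pytest.approx(sum(e.charge_pC for e in events))
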