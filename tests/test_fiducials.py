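"""R-peak detection, pulse landmark location, beat pairing, reference BP."""

import numpy as np
import pytest

from pttbp import (
    SimConfig,
    annotate_beats,
    detect_pulse_landmarks,
    detect_r_peaks,
    pair_beats,
    reference_bp,
    simulate_subject,
)
from pttbp.fiducials import PulseLandmarks


class TestDetectRPeaks:
    def test_noise_free_record_recovered_exactly(self, clean_subject):
        _, record, gt = clean_subject
        peaks = detect_r_peaks(record.ecg, record.fs)
        assert np.array_equal(peaks[: gt.r_peaks.size], gt.r_peaks)

    def test_flat_signal_yields_empty(self):
        assert detect_r_peaks(np.zeros(1000), 125.0).size == 0

    def test_noisy_record_hits_99_percent_within_2_samples(self):
        cfg = SimConfig(duration_s=80, hr_bpm=75, noise_sigma=0.05, seed=11)
        record, gt = simulate_subject(cfg)
        peaks = detect_r_peaks(record.ecg, record.fs)
        hits = sum(
            1 for r in gt.r_peaks if np.min(np.abs(peaks - r)) <= 2
        )
        assert gt.r_peaks.size >= 99
        assert hits / gt.r_peaks.size >= 0.99

    def test_strictly_increasing_with_refractory(self, clean_subject):
        _, record, _ = clean_subject
        peaks = detect_r_peaks(record.ecg, record.fs)
        assert np.all(np.diff(peaks) >= int(0.2 * record.fs))


class TestDetectPulseLandmarks:
    def test_noise_free_landmarks_within_one_sample(self, clean_subject):
        _, record, gt = clean_subject
        lms = detect_pulse_landmarks(record.ppg, record.fs)
        by_onset = {lm.i_b: lm for lm in lms}
        for k in range(gt.n_beats):
            lm = by_onset.get(gt.i_b[k]) or by_onset.get(gt.i_b[k] + 1) \
                or by_onset.get(gt.i_b[k] - 1)
            assert lm is not None, f"beat {k}: onset not found"
            for name, truth in (("i_a", gt.i_a[k]), ("i_c", gt.i_c[k]),
                                ("i_e", gt.i_e[k]), ("i_g", gt.i_g[k])):
                assert abs(getattr(lm, name) - truth) <= 1, (k, name)

    def test_ordering_invariant_on_every_pulse(self, clean_subject):
        _, record, _ = clean_subject
        for lm in detect_pulse_landmarks(record.ppg, record.fs):
            assert lm.is_valid()

    def test_monotone_decay_pulse_dropped_and_counted(self):
        # sharp rise then pure exponential decay: no dicrotic wave exists
        period, n = 125, 8
        t = np.arange(period)
        pulse = np.where(t < 10, t / 10.0, np.exp(-(t - 10) / 30.0))
        x = np.tile(pulse, n)
        lms, stats = detect_pulse_landmarks(x, 125.0, with_stats=True)
        assert stats["n_pulses"] >= n - 1
        assert stats["n_dropped"] == stats["n_pulses"]
        assert lms == []

    def test_triangular_rise_max_slope_at_midpoint(self):
        # linear rise (constant slope): the max-slope point is the midpoint;
        # a small dicrotic bump on the fall keeps the pulse complete
        period = 120
        t = np.arange(period, dtype=float)
        pulse = np.zeros(period)
        rise, notch, dpk = 30, 60, 72
        pulse[: rise + 1] = np.linspace(0, 1, rise + 1)
        pulse[rise : notch + 1] = np.linspace(1, 0.25, notch - rise + 1)
        pulse[notch : dpk + 1] = 0.25 + 0.15 * np.sin(
            np.linspace(0, np.pi / 2, dpk - notch + 1)
        )
        pulse[dpk:] = 0.40 * np.linspace(1, 0, period - dpk)
        x = np.tile(pulse, 6)
        lms = detect_pulse_landmarks(x, 125.0)
        assert len(lms) >= 4
        for lm in lms[1:-1]:
            assert abs((lm.i_a - lm.i_b) - rise // 2) <= 1


def _uniform_landmarks(onsets):
    return [
        PulseLandmarks(i_b=o, i_a=o + 5, i_c=o + 15, i_e=o + 40, i_g=o + 50,
                       h_a=0.5, h_c=1.0, h_e=0.55, h_g=0.3)
        for o in onsets
    ]


class TestPairBeats:
    def test_uniform_delay_pairs_every_interior_beat(self):
        fs = 125.0
        r = np.arange(0, 5000, 100)
        lms = _uniform_landmarks(r + 31)  # 0.25 s delay
        beats = pair_beats(r, lms, fs, max_delay_s=0.6)
        assert len(beats) == len(r) - 1  # last beat lacks successors
        assert all(b.landmarks.i_b - b.r_index == 31 for b in beats)
        assert all(b.rr_s == pytest.approx(100 / fs) for b in beats)

    def test_delay_beyond_max_gives_zero_pairs(self):
        fs = 125.0
        r = np.arange(0, 5000, 100)
        lms = _uniform_landmarks(r + 90)  # 0.72 s > 0.6 s
        assert pair_beats(r, lms, fs, max_delay_s=0.6) == []

    def test_missing_pulse_resynchronizes(self):
        fs = 125.0
        r = np.arange(0, 5100, 100)  # 51 R-peaks
        onsets = list(r + 31)
        del onsets[25]  # one dropped pulse
        lms = _uniform_landmarks(np.array(onsets))
        beats = pair_beats(r, lms, fs, max_delay_s=0.6)
        paired_r = {b.r_index for b in beats}
        assert r[25] not in paired_r  # the gap is skipped, not mis-assigned
        assert all(b.landmarks.i_b - b.r_index == 31 for b in beats)
        assert len(beats) == len(r) - 2  # the gap beat and the final edge beat

    def test_output_not_longer_than_inputs(self, clean_subject):
        _, record, _ = clean_subject
        r = detect_r_peaks(record.ecg, record.fs)
        lms = detect_pulse_landmarks(record.ppg, record.fs)
        beats = pair_beats(r, lms, record.fs)
        assert len(beats) <= min(r.size, len(lms))


class TestReferenceBp:
    def test_constant_abp(self):
        assert reference_bp(np.full(100, 80.0), (10, 90)) == (80.0, 80.0)

    def test_half_sine_extremes(self):
        t = np.arange(101)
        abp = 60 + 60 * np.sin(np.pi * t / 100)
        sbp, dbp = reference_bp(abp, (0, 101))
        assert sbp == pytest.approx(120.0)
        assert dbp == pytest.approx(60.0)

    def test_simulated_beat_reference_exact(self, clean_subject):
        _, record, gt = clean_subject
        sbp, dbp = reference_bp(record.abp, (gt.i_b[0], gt.i_b[1]))
        assert sbp == pytest.approx(gt.sbp[0])
        assert dbp == pytest.approx(gt.dbp[0])

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            reference_bp(np.zeros(100), (50, 50))


def test_annotate_beats_full_chain(clean_subject):
    _, record, gt = clean_subject
    beats = annotate_beats(record)
    assert len(beats) >= gt.n_beats - 2
    for b in beats:
        b.validate()
        assert b.sbp_ref == pytest.approx(120.0)
        assert b.dbp_ref == pytest.approx(80.0)
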