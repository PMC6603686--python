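"""The 14 per-beat features and min-max normalization."""

import numpy as np
import pandas as pd
import pytest

from pttbp import (
    annotate_beats,
    compute_hr,
    compute_k,
    compute_morphology,
    compute_ptt,
    extract_features,
    minmax_normalize,
)
from pttbp.features import FEATURE_NAMES, FeatureDataset
from pttbp.fiducials import Beat, PulseLandmarks


def _beat(r=0, b=25, a=30, c=40, e=70, g=80, cycle_end=125, rr=0.8,
          h_a=0.5, h_c=1.0, h_e=0.55, h_g=0.3):
    lm = PulseLandmarks(i_b=b, i_a=a, i_c=c, i_e=e, i_g=g,
                        h_a=h_a, h_c=h_c, h_e=h_e, h_g=h_g)
    return Beat(r_index=r, landmarks=lm, cycle=(b, cycle_end), rr_s=rr)


class TestComputePtt:
    def test_sample_arithmetic(self):
        pttb, ptta, pttc = compute_ptt(_beat(), fs=125.0)
        assert pttb == pytest.approx(0.200)
        assert ptta == pytest.approx(0.240)
        assert pttc == pytest.approx(0.320)

    def test_onset_at_r_peak_rejected(self):
        with pytest.raises(ValueError, match="non-causal"):
            compute_ptt(_beat(r=25), fs=125.0)

    def test_matches_configured_delay_on_simulated_beats(self, clean_subject):
        cfg, record, _ = clean_subject
        beats = annotate_beats(record)
        for b in beats[:10]:
            pttb, _, _ = compute_ptt(b, record.fs)
            assert pttb == pytest.approx(cfg.ptt_s, abs=1.0 / record.fs)


class TestComputeK:
    def test_linear_ramp_gives_half(self):
        assert compute_k(np.linspace(0, 1, 101)) == pytest.approx(0.5)

    def test_half_sine_arch_gives_2_over_pi(self):
        n = 500
        cycle = np.sin(np.pi * np.arange(n) / n)
        assert compute_k(cycle) == pytest.approx(2 / np.pi, abs=1.0 / n)

    def test_flat_cycle_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            compute_k(np.full(50, 3.0))


class TestComputeHr:
    @pytest.mark.parametrize("rr,bpm", [(0.8, 75.0), (1.0, 60.0), (0.5, 120.0)])
    def test_inverse_of_rr(self, rr, bpm):
        assert compute_hr(rr) == pytest.approx(bpm)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            compute_hr(0.0)


class TestComputeMorphology:
    def test_definitional_sums(self, clean_subject):
        _, record, _ = clean_subject
        beats = annotate_beats(record)
        for b in beats:
            tupr, tdownr, _, _, _, _, s1, s2, ratio = compute_morphology(
                b, record.ppg, record.fs
            )
            assert tupr + tdownr == pytest.approx(1.0)
            assert s1 + s2 == pytest.approx(1.0)
            assert ratio == pytest.approx(s1 / s2)

    def test_symmetric_triangle_timing_and_slope(self):
        # triangle rising half the cycle: Tupr = 0.5, Cslope = Hc / (T/2)
        n = 100
        tri = np.concatenate([np.linspace(0, 1, n // 2 + 1)[:-1],
                              np.linspace(1, 0, n // 2 + 1)[:-1]])
        ppg = np.tile(tri, 3)
        beat = _beat(b=n, a=n + 25, c=n + n // 2, e=n + 75, g=n + 80,
                     cycle_end=2 * n, h_a=0.5, h_c=1.0, h_e=0.5, h_g=0.25)
        tupr, _, cslope, *_ = compute_morphology(beat, ppg, 125.0)
        assert tupr == pytest.approx(0.5)
        assert cslope == pytest.approx(1.0 / (n / 2 / 125.0))

    def test_dicrotic_height_by_construction(self, clean_subject):
        cfg, record, _ = clean_subject
        beats = annotate_beats(record)
        hgrs = [compute_morphology(b, record.ppg, record.fs)[5] for b in beats]
        assert np.allclose(hgrs, cfg.dicrotic_rel_height, atol=0.02)


class TestExtractFeatures:
    def test_emitted_rows_satisfy_invariants(self, clean_subject):
        _, record, _ = clean_subject
        beats = annotate_beats(record)
        ds = extract_features(beats, record.ppg, record.fs)
        f = ds.features
        assert list(f.columns) == FEATURE_NAMES
        assert np.all(f["PTTb"] < f["PTTa"])
        assert np.all(f["PTTa"] <= f["PTTc"])
        assert np.all((f["K"] > 0) & (f["K"] < 1))
        assert np.allclose(f["Tupr"] + f["Tdownr"], 1.0)
        assert np.allclose(f["S1"] + f["S2"], 1.0)
        assert np.all(np.isfinite(f.to_numpy()))

    def test_csv_round_trip(self, tmp_path, small_feature_ds):
        path = small_feature_ds.to_csv(tmp_path / "features.csv")
        back = FeatureDataset.from_csv(path)
        pd.testing.assert_frame_equal(back.features, small_feature_ds.features)
        pd.testing.assert_frame_equal(back.labels, small_feature_ds.labels)


class TestMinmaxNormalize:
    def test_three_point_column(self, small_feature_ds):
        ds = small_feature_ds.subset(np.arange(3))
        ds.features.loc[:, "K"] = [2.0, 4.0, 6.0]
        norm, _ = minmax_normalize(ds)
        assert np.allclose(norm.features["K"], [0.0, 0.5, 1.0])

    def test_endpoints_map_to_unit_interval(self, small_feature_ds):
        norm, _ = minmax_normalize(small_feature_ds)
        f = norm.features
        assert np.allclose(f.min(), 0.0)
        assert np.allclose(f.max(), 1.0)

    def test_round_trip_through_scaler(self, small_feature_ds):
        norm, scaler = minmax_normalize(small_feature_ds)
        back = scaler.inverse(norm.features)
        assert np.allclose(back.to_numpy(), small_feature_ds.features.to_numpy())

    def test_paper_and_leakfree_differ_when_test_exceeds_train_range(
        self, small_feature_ds
    ):
        n = len(small_feature_ds)
        train_idx = np.arange(n - 20)
        # force a test-only extreme in one feature
        ds = small_feature_ds.subset(np.arange(n))
        ds.features.loc[n - 1, "HR"] = ds.features["HR"].max() + 30
        pooled, _ = minmax_normalize(ds, mode="paper")
        leakfree, _ = minmax_normalize(ds, mode="leakfree", train_idx=train_idx)
        assert not np.allclose(pooled.features["HR"], leakfree.features["HR"])
        assert leakfree.features["HR"].max() <= 1.0

    def test_constant_feature_named_in_error(self, small_feature_ds):
        ds = small_feature_ds.subset(np.arange(50))
        ds.features.loc[:, "Hgr"] = 0.3
        with pytest.raises(ValueError, match="Hgr"):
            minmax_normalize(ds)
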