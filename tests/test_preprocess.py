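"""Segmentation, median smoothing, feature extraction and labeling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spikegp as sg
from spikegp.preprocess import (
    AnnotationError,
    EmptyInputError,
    Recording,
    channel_features,
    features_matrix,
    read_annotations,
    read_recording,
    window_starts,
    write_annotations,
    write_recording,
)

from conftest import brute_force_windows, oracle_features


class TestSegmentation:
    def test_1000_samples_gives_19_half_overlapping_windows(self, seg_cfg):
        segs = sg.segment_channel(np.arange(1000.0), seg_cfg, fs=1000.0)
        assert len(segs) == 19
        assert [s.start_sample for s in segs] == list(range(0, 901, 50))
        # consecutive windows share exactly N/2 samples
        assert np.array_equal(segs[0].values[50:], segs[1].values[:50])

    @pytest.mark.parametrize("length,expected", [
        (100, 1), (149, 1), (150, 2), (199, 2), (200, 3),
    ])
    def test_trailing_partial_window_discarded(self, seg_cfg, length, expected):
        segs = sg.segment_channel(np.zeros(length), seg_cfg, fs=1000.0)
        assert len(segs) == expected

    def test_count_formula_matches_enumeration(self, seg_cfg):
        for length in range(100, 1001):
            starts = window_starts(length, 100, 50)
            assert starts.tolist() == brute_force_windows(length, 100, 50)

    def test_short_signal_raises(self, seg_cfg):
        with pytest.raises(EmptyInputError):
            sg.segment_channel(np.zeros(99), seg_cfg, fs=1000.0)

    def test_window_scales_with_sampling_rate(self):
        cfg = sg.SegmentationConfig(window_ms=100.0)
        assert cfg.window_samples(1000.0) == 100
        assert cfg.window_samples(500.0) == 50


class TestMedianSmooth:
    def test_impulse_removed_with_edge_replication(self):
        out = sg.median_smooth(np.array([1.0, 9.0, 1.0, 1.0, 1.0]), 3)
        assert out.tolist() == [1.0, 1.0, 1.0, 1.0, 1.0]

    def test_constant_vector_unchanged(self):
        out = sg.median_smooth(np.full(20, 3.5), 5)
        assert np.array_equal(out, np.full(20, 3.5))

    def test_order_one_is_identity(self, rng):
        x = rng.standard_normal(50)
        assert np.array_equal(sg.median_smooth(x, 1), x)

    def test_even_order_rejected(self):
        with pytest.raises(ValueError):
            sg.median_smooth(np.zeros(10), 4)

    def test_output_length_preserved(self, rng):
        x = rng.standard_normal(100)
        assert sg.median_smooth(x, 5).shape == x.shape


class TestFeatures:
    def test_hand_computed_three_point_segment(self):
        f = sg.extract_features(np.array([1.0, 2.0, 3.0]))
        # mu=2, sigma=1 (1/(N-1)), kurtosis=(1+0+1)/(2*1)=1, skewness=0
        assert f[2] == pytest.approx(2.0)
        assert f[3] == pytest.approx(1.0)
        assert f[6] == pytest.approx(1.0)
        assert f[7] == pytest.approx(0.0)

    def test_exclusive_halves_iqr(self):
        f = sg.extract_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f[5] == pytest.approx(2.0)  # Q1=1.5, Q3=3.5
        # odd length: overall median excluded from both halves
        f5 = sg.extract_features(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert f5[5] == pytest.approx(4.5 - 1.5)

    def test_matches_direct_summation_oracle(self, rng):
        windows = rng.standard_normal((200, 100)) * 10 + 3
        got = features_matrix(windows)
        for row, window in zip(got, windows):
            assert row == pytest.approx(oracle_features(window), rel=1e-9)

    def test_zero_variance_degenerate_segment(self):
        f = sg.extract_features(np.full(100, 7.0))
        assert f[3] == 0.0 and f[6] == 0.0
        assert f[6] == 0.0
        assert f[7] == 0.0 and f[6] == 0.0
        assert np.all(np.isfinite(f))

    @given(shift=st.floats(-50, 50), scale=st.floats(0.01, 50))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_equivariance(self, shift, scale):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(100)
        base = sg.extract_features(x)
        shifted = sg.extract_features(x + shift)
        # max/min/mean/median shift by c; dispersion and shape invariant
        for i in (0, 1, 2, 4):
            assert shifted[i] == pytest.approx(base[i] + shift, rel=1e-9,
                                               abs=1e-9)
        for i in (3, 5, 6, 7):
            assert shifted[i] == pytest.approx(base[i], rel=1e-7, abs=1e-7)
        scaled = sg.extract_features(x * scale)
        for i in range(6):
            assert scaled[i] == pytest.approx(base[i] * scale, rel=1e-9)
        for i in (6, 7):
            assert scaled[i] == pytest.approx(base[i], rel=1e-7, abs=1e-9)


class TestLabeling:
    @pytest.mark.parametrize("interval,expected", [
        ((25, 90), sg.SPIKE),    # overlap 65 >= 50
        ((90, 140), sg.NONSPIKE),  # overlap 10 < 50
        ((50, 100), sg.SPIKE),   # overlap exactly half the window
        ((51, 100), sg.NONSPIKE),
    ])
    def test_half_window_overlap_rule(self, interval, expected):
        assert sg.label_segment(0, 100, [interval]) == expected

    def test_no_annotations_is_nonspike(self):
        assert sg.label_segment(0, 100, []) == sg.NONSPIKE

    def test_malformed_interval_raises(self):
        with pytest.raises(AnnotationError):
            sg.label_segment(0, 100, [(90, 90)])

    def test_spike_of_half_window_length_labels_some_window(self):
        # 50 ms spike anywhere always covers >= half of some 50%-overlap window
        for start in range(0, 900):
            labels = [
                sg.label_segment(w, 100, [(start, start + 50)])
                for w in range(0, 901, 50)
            ]
            assert sg.SPIKE in labels


class TestRecordingIO:
    def test_recording_roundtrip(self, tmp_path, rng):
        rec = Recording(rng.standard_normal((26, 500)), fs=1000.0,
                        region="right_parietal")
        path = tmp_path / "rec.csv"
        write_recording(path, rec)
        back = read_recording(path)
        assert back.fs == 1000.0
        assert back.region == "right_parietal"
        assert np.allclose(back.data, rec.data, atol=1e-4)

    def test_annotation_roundtrip(self, tmp_path):
        events = [(10, 80), (200, 290)]
        path = tmp_path / "ann.tsv"
        write_annotations(path, events)
        assert read_annotations(path) == events

    def test_invalid_channel_count_rejected(self, rng):
        with pytest.raises(ValueError):
            Recording(rng.standard_normal((5, 100)), fs=1000.0)

    def test_feature_table_layout(self, rng):
        rec = Recording(rng.standard_normal((24, 400)), fs=1000.0)
        table = sg.feature_table(rec, sg.SegmentationConfig(), [(100, 170)])
        assert len(table) == 24 * 7
        assert set(table.columns) >= {"channel", "start_sample", "X1", "X8",
                                      "label"}
        labeled = table[table.start_sample == 100]
        assert (labeled.label == sg.SPIKE).all()

    def test_channel_features_matches_segmentwise_path(self, rng, seg_cfg):
        signal = rng.standard_normal(500)
        starts, feats = channel_features(signal, seg_cfg, fs=1000.0)
        segs = sg.segment_channel(signal, seg_cfg, fs=1000.0)
        for i, seg in enumerate(segs):
            smoothed = sg.median_smooth(seg.values,
                                        seg_cfg.median_filter_order)
            assert feats[i] == pytest.approx(
                sg.extract_features(smoothed).tolist(), rel=1e-12)
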