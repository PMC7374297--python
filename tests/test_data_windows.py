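"""Windowing, frame labels, record splits, noise injection, and IO."""

import numpy as np
import pytest

from octaveqrs.data_windows import (
    PHYSIONET_EXCLUDED,
    Recording,
    add_gaussian_noise,
    add_motion_artifact,
    extract_windows,
    motion_artifact_trace,
    read_csv_recording,
    read_wfdb_record,
    split_records,
    standardize_windows,
    windows_from_hdf5,
    windows_to_hdf5,
)


def make_recording(n=60_000, ann=(350, 1400, 5000), seed=0, rid="r0", clip_ann=False):
    rng = np.random.default_rng(seed)
    ann = np.array(ann, dtype=np.int64)
    if clip_ann:
        ann = ann[ann < n]
    return Recording(
        signals=rng.standard_normal((4, n)) * 10,
        fqrs_annotations=ann,
        record_id=rid,
    )


class TestRecording:
    def test_annotation_order_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            make_recording(ann=(10, 10))

    def test_annotation_range_enforced(self):
        with pytest.raises(ValueError, match="within"):
            make_recording(n=100, ann=(350,))


class TestExtractWindows:
    def test_non_overlapping_count(self):
        assert len(extract_windows(make_recording(60_000), stride=1000)) == 60

    def test_annotation_labels_containing_frame(self):
        windows = extract_windows(make_recording(ann=(350,)))
        np.testing.assert_array_equal(
            windows[0].frame_labels, [0, 0, 0, 1, 0, 0, 0, 0, 0, 0]
        )

    def test_frame_boundary_is_half_open(self):
        windows = extract_windows(make_recording(ann=(400,)))
        assert windows[0].frame_labels[3] == 0
        assert windows[0].frame_labels[4] == 1

    def test_short_recording_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert extract_windows(make_recording(n=500, ann=(350,))) == []

    def test_every_annotation_labels_exactly_one_frame(self):
        rng = np.random.default_rng(3)
        ann = np.sort(rng.choice(60_000, size=120, replace=False))
        rec = make_recording(ann=tuple(int(a) for a in ann))
        windows = extract_windows(rec, stride=1000)
        total_pos = sum(int(w.frame_labels.sum()) for w in windows)
        # non-overlapping full cover: distinct labeled frames == distinct
        # (window, frame) cells hit; two annotations may share a frame
        cells = {(a // 1000, (a % 1000) // 100) for a in ann}
        assert total_pos == len(cells)

    def test_overlapping_stride(self):
        assert len(extract_windows(make_recording(3000, clip_ann=True), stride=500)) == 5


class TestSplitRecords:
    def test_full_set_partition_sizes(self):
        ids = [f"a{i:02d}" for i in range(1, 76)]
        train, val, test = split_records(ids)
        assert (len(train), len(val), len(test)) == (55, 6, 7)
        assert set(test) == {f"a{i:02d}" for i in range(1, 8)}
        assert set(val) == {f"a{i:02d}" for i in range(8, 14)}
        assert not (set(train) & set(val) or set(val) & set(test) or set(train) & set(test))

    def test_excluded_records_absent_everywhere(self):
        train, val, test = split_records([f"a{i:02d}" for i in range(1, 76)])
        for rid in PHYSIONET_EXCLUDED:
            assert rid not in train + val + test

    def test_empty_input(self):
        assert split_records([]) == ([], [], [])

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="a01..a75"):
            split_records(["b01"])
        with pytest.raises(ValueError):
            split_records(["a76"])


class TestGaussianNoise:
    def test_deterministic_per_seed(self):
        rec = make_recording()
        a = add_gaussian_noise(rec, 3.0, seed=5)
        b = add_gaussian_noise(rec, 3.0, seed=5)
        np.testing.assert_array_equal(a.signals, b.signals)

    def test_small_level_converges_to_input(self):
        rec = make_recording()
        noisy = add_gaussian_noise(rec, 1e-9, seed=0)
        np.testing.assert_allclose(noisy.signals, rec.signals, atol=1e-7)

    def test_base_noise_bounded_at_4uV(self):
        rec = make_recording()
        noisy = add_gaussian_noise(rec, 1.0, seed=1)
        assert np.max(np.abs(noisy.signals - rec.signals)) == pytest.approx(4.0)

    def test_snr_decreases_with_level(self):
        rec = make_recording()
        snrs = []
        for level in (3, 6, 9):
            noisy = add_gaussian_noise(rec, level, seed=2)
            noise = noisy.signals - rec.signals
            snrs.append(10 * np.log10((rec.signals**2).mean() / (noise**2).mean()))
        assert snrs[0] > snrs[1] > snrs[2]

    def test_annotations_and_length_untouched(self):
        rec = make_recording()
        noisy = add_gaussian_noise(rec, 6.0, seed=3)
        np.testing.assert_array_equal(noisy.fqrs_annotations, rec.fqrs_annotations)
        assert noisy.num_samples == rec.num_samples


class TestMotionArtifact:
    def test_severity_zero_only_normalizes(self):
        rec = make_recording()
        out = add_motion_artifact(rec, 0.0, seed=0)
        assert out.signals.min() == pytest.approx(-1.0)
        assert out.signals.max() == pytest.approx(1.0)

    def test_deterministic_per_seed(self):
        rec = make_recording()
        a = add_motion_artifact(rec, 0.5, seed=9)
        b = add_motion_artifact(rec, 0.5, seed=9)
        np.testing.assert_array_equal(a.signals, b.signals)

    def test_constant_channel_rejected(self):
        rec = make_recording()
        rec.signals[2] = 0.0
        with pytest.raises(ValueError, match="constant"):
            add_motion_artifact(rec, 0.5, seed=0)

    def test_artifact_power_concentrates_below_1hz(self):
        from scipy.signal import periodogram

        trace = motion_artifact_trace(60_000, 1.0, np.random.default_rng(4))
        freqs, psd = periodogram(trace, fs=1000)
        low = psd[freqs <= 1.0].sum()
        assert low / psd.sum() >= 0.9


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        rec = make_recording(n=2000, clip_ann=True)
        out = tmp_path / "rec0"
        from octaveqrs.data_windows import write_recording

        written = write_recording(rec, out, fmt="csv")
        back = read_csv_recording(written)
        np.testing.assert_allclose(back.signals, rec.signals, atol=1e-6)
        np.testing.assert_array_equal(back.fqrs_annotations, rec.fqrs_annotations)

    def test_wfdb_round_trip(self, tmp_path):
        from octaveqrs.data_windows import write_recording

        rec = make_recording(n=2000, clip_ann=True)
        write_recording(rec, tmp_path / "rec1", fmt="wfdb")
        back = read_wfdb_record(tmp_path / "rec1")
        # format-16 digitization at 100 adu/uV quantizes to 0.01 uV
        np.testing.assert_allclose(back.signals, rec.signals, atol=0.005 + 1e-9)
        np.testing.assert_array_equal(back.fqrs_annotations, rec.fqrs_annotations)

    def test_wfdb_wrong_channel_count_rejected(self, tmp_path):
        hea = tmp_path / "bad.hea"
        hea.write_text("bad 3 1000 100\nbad.dat 16 100(0)/uV 16 0 0 0 0 ch1\n")
        with pytest.raises(ValueError, match="4"):
            read_wfdb_record(tmp_path / "bad")

    def test_wfdb_wrong_rate_rejected(self, tmp_path):
        hea = tmp_path / "bad.hea"
        hea.write_text("bad 4 500 100\n" + "bad.dat 16 100(0)/uV 16 0 0 0 0 ch\n" * 4)
        with pytest.raises(ValueError, match="1000"):
            read_wfdb_record(tmp_path / "bad")

    def test_csv_line_count(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("ch1,ch2,ch3,ch4\n" + "\n".join("0.1,0.2,0.3,0.4" for _ in range(1500)))
        rec = read_csv_recording(p)
        assert rec.num_samples == 1500

    def test_hdf5_round_trip(self, tmp_path):
        windows = extract_windows(make_recording(6000))
        path = tmp_path / "w.h5"
        windows_to_hdf5(windows, path)
        back = windows_from_hdf5(path)
        assert len(back) == len(windows)
        np.testing.assert_array_equal(back[2].samples, windows[2].samples)
        np.testing.assert_array_equal(back[2].frame_labels, windows[2].frame_labels)
        assert back[2].start == windows[2].start


class TestStandardize:
    def test_zero_mean_unit_variance_per_channel(self):
        x = np.random.default_rng(0).standard_normal((3, 4, 1000)) * 7 + 2
        z = standardize_windows(x)
        np.testing.assert_allclose(z.mean(axis=-1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=-1), 1.0, atol=1e-3)
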