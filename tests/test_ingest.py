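"""Metadata/audio ingestion, clip segmentation and leakage-free splits."""
import numpy as np
import pandas as pd
import pytest
from scipy.io import wavfile

from copdscreen.ingest import (AudioRecording, assert_no_leakage,
                               kfold_patient_splits, load_metadata,
                               load_recording, normalize_clip,
                               oversample_minority, patient_split,
                               segment_clips, split_clips, split_manifest)


def _write_table(path, rows):
    pd.DataFrame(rows, columns=["patient_id", "diagnosis"]).to_csv(path, index=False)
    return str(path)


class TestLoadMetadata:
    def test_binary_filter(self, tmp_path):
        p = _write_table(tmp_path / "m.csv", [("p1", "COPD"), ("p2", "Healthy"),
                                              ("p3", "Asthma")])
        assert load_metadata(p) == {"p1": "COPD", "p2": "Healthy"}

    def test_empty_table(self, tmp_path):
        p = _write_table(tmp_path / "m.csv", [])
        assert load_metadata(p) == {}

    def test_unknown_label_warns_and_excludes(self, tmp_path):
        p = _write_table(tmp_path / "m.csv", [("p1", "COPD"), ("p2", "Zebra")])
        with pytest.warns(UserWarning, match="unknown diagnosis"):
            assert load_metadata(p) == {"p1": "COPD"}

    def test_conflicting_duplicate_is_hard_error(self, tmp_path):
        p = _write_table(tmp_path / "m.csv", [("p1", "COPD"), ("p1", "Healthy")])
        with pytest.raises(ValueError, match="conflicting"):
            load_metadata(p)

    def test_synthetic_table_roundtrip(self, tmp_path, tiny_cohort):
        path = tmp_path / "diag.csv"
        tiny_cohort["table"].to_csv(path, index=False)
        assert load_metadata(str(path)) == tiny_cohort["labels"]


class TestLoadRecording:
    def test_native_rate_unchanged(self, tmp_path):
        x = (np.sin(2 * np.pi * 100 * np.arange(80000) / 16000) * 20000).astype(np.int16)
        wavfile.write(tmp_path / "p1_0.wav", 16000, x)
        rec = load_recording(str(tmp_path / "p1_0.wav"))
        assert rec.sample_rate == 16000 and len(rec.waveform) == 80000
        assert rec.patient_id == "p1"

    def test_downsample_halves_length(self, tmp_path):
        x = np.zeros(32000, dtype=np.int16)
        wavfile.write(tmp_path / "a_0.wav", 32000, x)
        rec = load_recording(str(tmp_path / "a_0.wav"))
        assert len(rec.waveform) == 16000

    def test_tone_survives_44k_resample(self, tmp_path):
        sr = 44100
        x = (np.sin(2 * np.pi * 440 * np.arange(sr) / sr) * 20000).astype(np.int16)
        wavfile.write(tmp_path / "t_0.wav", sr, x)
        rec = load_recording(str(tmp_path / "t_0.wav"))
        freqs = np.fft.rfftfreq(len(rec.waveform), 1 / 16000)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(rec.waveform)))]
        assert abs(peak - 440.0) <= 5.0

    def test_stereo_collapsed_by_mean(self, tmp_path):
        left = np.full(16000, 10000, dtype=np.int16)
        right = np.full(16000, -10000, dtype=np.int16)
        wavfile.write(tmp_path / "s_0.wav", 16000, np.stack([left, right], 1))
        rec = load_recording(str(tmp_path / "s_0.wav"))
        assert np.allclose(rec.waveform, 0.0, atol=1e-6)

    def test_unreadable_file_raises_io_error_naming_path(self, tmp_path):
        bad = tmp_path / "nope.wav"
        with pytest.raises(IOError, match="nope.wav"):
            load_recording(str(bad))


class TestSegmentation:
    @pytest.mark.parametrize("dur_s,expected", [(20.0, 4), (4.9, 0), (23.0, 4)])
    def test_clip_counts(self, dur_s, expected):
        rec = AudioRecording("p", "COPD", np.zeros(int(dur_s * 16000)), 16000)
        clips = segment_clips(rec)
        assert len(clips) == expected
        for c in clips:
            assert c.end_s - c.start_s == pytest.approx(5.0)
            assert c.label == "COPD"

    def test_tiling_without_overlap(self):
        rec = AudioRecording("p", "COPD", np.arange(80000, dtype=float), 16000)
        clips = segment_clips(rec)
        joined = np.concatenate([c.waveform for c in clips])
        assert np.array_equal(joined, rec.waveform)

    def test_normalize_clip_zero_mean_peak_one(self):
        rec = AudioRecording("p", "COPD", np.random.default_rng(0).normal(1, 1, 80000), 16000)
        clip = normalize_clip(segment_clips(rec)[0])
        assert abs(clip.waveform.mean()) < 1e-9
        assert np.isclose(np.max(np.abs(clip.waveform)), 1.0)


class TestPatientSplit:
    def test_largest_remainder_sizes(self):
        labels = {f"p{i}": "COPD" for i in range(20)}
        labels.update({f"h{i}": "Healthy" for i in range(0)})
        # single class, 20 patients at 70/15/15 -> (14, 3, 3)
        sp = patient_split({f"p{i}": "COPD" for i in range(20)}, seed=0)
        sizes = [len(sp.patients(p)) for p in ("train", "val", "test")]
        assert sizes == [14, 3, 3]

    def test_stratified_two_class(self):
        labels = {f"c{i}": "COPD" for i in range(14)}
        labels.update({f"h{i}": "Healthy" for i in range(6)})
        sp = patient_split(labels, seed=1)
        sizes = [len(sp.patients(p)) for p in ("train", "val", "test")]
        assert sizes == [14, 3, 3]
        assert all(any(p.startswith("h") for p in sp.patients(part))
                   for part in ("train", "val", "test"))

    def test_deterministic_and_seed_sensitive(self):
        labels = {f"p{i}": ("COPD" if i % 2 else "Healthy") for i in range(12)}
        a = patient_split(labels, seed=5)
        b = patient_split(labels, seed=5)
        c = patient_split(labels, seed=6)
        assert a.assignment == b.assignment
        assert any(a.assignment[p] != c.assignment[p] for p in labels)

    def test_impossible_stratification_raises(self):
        labels = {"h1": "Healthy", "c1": "COPD", "c2": "COPD", "c3": "COPD"}
        with pytest.raises(ValueError, match="partition"):
            patient_split(labels, seed=0)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            patient_split({"a": "COPD"}, ratios=(0.5, 0.2, 0.2))


class TestKFold:
    def _labels(self, n_copd=7, n_healthy=5):
        d = {f"c{i}": "COPD" for i in range(n_copd)}
        d.update({f"h{i}": "Healthy" for i in range(n_healthy)})
        return d

    def test_each_patient_validated_exactly_once(self):
        labels = self._labels(5, 5)
        splits = kfold_patient_splits(labels, k=5, seed=0)
        val_sets = [set(sp.patients("val")) for sp in splits]
        assert all(len(v) == 2 for v in val_sets)
        union = set().union(*val_sets)
        assert union == set(labels)
        assert sum(len(v) for v in val_sets) == len(labels)

    def test_stratification_within_one_patient(self):
        labels = self._labels(12, 7)
        splits = kfold_patient_splits(labels, k=5, seed=2)
        for sp in splits:
            val = sp.patients("val")
            n_c = sum(1 for p in val if p.startswith("c"))
            n_h = sum(1 for p in val if p.startswith("h"))
            assert abs(n_c - 12 / 5) <= 1.0 and abs(n_h - 7 / 5) <= 1.0

    def test_small_class_raises_with_feasible_k(self):
        with pytest.raises(ValueError, match="max feasible k is 3"):
            kfold_patient_splits(self._labels(7, 3), k=5)

    def test_no_leakage_invariant(self, tiny_cohort):
        splits = kfold_patient_splits(tiny_cohort["labels"], k=3, seed=0)
        for sp in splits:
            assert_no_leakage(sp, tiny_cohort["clips"])
            parts = split_clips(tiny_cohort["clips"], sp)
            train_p = {c.patient_id for c in parts["train"]}
            val_p = {c.patient_id for c in parts["val"]}
            assert not train_p & val_p


class TestOversampling:
    def _clips(self, n_copd, n_healthy):
        from copdscreen.ingest import Clip
        mk = lambda i, lab: Clip(f"p{lab}{i}", lab, 0, 5, np.zeros(10), 16000)
        return ([mk(i, "COPD") for i in range(n_copd)]
                + [mk(i, "Healthy") for i in range(n_healthy)])

    def test_duplication_arithmetic(self):
        out = oversample_minority(self._clips(10, 2))
        labels = [c.label for c in out]
        assert labels.count("COPD") == 10 and labels.count("Healthy") == 10
        healthy_ids = [c.patient_id for c in out if c.label == "Healthy"]
        assert all(healthy_ids.count(pid) == 5 for pid in set(healthy_ids))

    def test_balanced_input_unchanged(self):
        clips = self._clips(4, 4)
        assert oversample_minority(clips) == clips

    def test_output_size_conservation(self):
        out = oversample_minority(self._clips(7, 3))
        assert len(out) == 14

    def test_single_class_warns_noop(self):
        clips = self._clips(3, 0)
        with pytest.warns(UserWarning, match="one class"):
            assert oversample_minority(clips) == clips


def test_split_manifest_columns(tiny_cohort):
    splits = kfold_patient_splits(tiny_cohort["labels"], k=3, seed=0)
    df = split_manifest(splits)
    assert list(df.columns) == ["patient_id", "partition", "fold"]
    assert set(df.fold) == {0, 1, 2}
    assert len(df) == 3 * len(tiny_cohort["labels"])
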