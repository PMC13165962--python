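"""Audio + metadata ingestion, clip segmentation, and leakage-free
patient-wise splitting.

All partitioning operates at the patient level: every clip of a patient lands
in exactly one of train/validation/test (or one CV fold), so no identity
leaks across evaluation boundaries. Minority-class oversampling is applied to
training clips only, after segmentation, by deterministic cycling.
"""
from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

from .synthetic import Diagnosis, SyntheticRecording

TARGET_RATE = 16000
CLIP_LEN_S = 5.0

#: diagnosis vocabulary of the public respiratory-sound corpus
KNOWN_LABELS = frozenset({
    "COPD", "Healthy", "Asthma", "URTI", "LRTI", "Bronchiectasis",
    "Bronchiolitis", "Pneumonia",
})


@dataclass
class AudioRecording:
    patient_id: str
    diagnosis: str
    waveform: np.ndarray
    sample_rate: int
    source_path: str = ""

    @property
    def duration_s(self) -> float:
        return len(self.waveform) / self.sample_rate


@dataclass
class Clip:
    patient_id: str
    label: str
    start_s: float
    end_s: float
    waveform: np.ndarray
    sample_rate: int
    source_path: str = ""

    @property
    def clip_id(self) -> str:
        return f"{self.patient_id}:{os.path.basename(self.source_path)}:{self.start_s:g}"


@dataclass
class SplitAssignment:
    assignment: Dict[str, str]          # patient_id -> partition name
    ratios: Tuple[float, float, float]
    seed: int

    def patients(self, partition: str) -> List[str]:
        return sorted(p for p, part in self.assignment.items() if part == partition)


# ---------------------------------------------------------------------------
# metadata and audio loading
# ---------------------------------------------------------------------------

def load_metadata(csv_path: str,
                  keep_labels: Sequence[str] = ("COPD", "Healthy")) -> Dict[str, str]:
    """Read the `patient_id,diagnosis` table, keeping only wanted labels.

    Labels outside the known vocabulary trigger a warning and are excluded;
    a patient listed twice with conflicting diagnoses is a hard error.
    """
    df = pd.read_csv(csv_path, dtype=str)
    if not {"patient_id", "diagnosis"} <= set(df.columns):
        raise ValueError(f"{csv_path}: expected columns patient_id,diagnosis")
    keep = set(keep_labels)
    out: Dict[str, str] = {}
    for pid, dx in zip(df["patient_id"], df["diagnosis"]):
        if dx not in KNOWN_LABELS and dx not in keep:
            warnings.warn(f"unknown diagnosis label {dx!r} for patient {pid}; excluded")
            continue
        if pid in out and out[pid] != dx and dx in keep:
            raise ValueError(f"patient {pid} has conflicting diagnoses "
                             f"{out[pid]!r} vs {dx!r}")
        if dx in keep:
            out[pid] = dx
    return out


def _to_float(data: np.ndarray) -> np.ndarray:
    if data.dtype == np.int16:
        return data / 32768.0
    if data.dtype == np.int32:
        return data / 2147483648.0
    if data.dtype == np.uint8:
        return (data.astype(np.float64) - 128.0) / 128.0
    return data.astype(np.float64)


def load_recording(path: str, target_rate: int = TARGET_RATE,
                   patient_id: str | None = None,
                   diagnosis: str = "") -> AudioRecording:
    """Read a RIFF/WAVE file, collapse to mono, and resample to 16 kHz.

    ``patient_id`` defaults to the token before the first underscore of the
    file name (the public corpus convention).
    """
    try:
        rate, data = wavfile.read(path)
    except (FileNotFoundError, ValueError) as exc:
        raise IOError(f"cannot read audio file {path!r}: {exc}") from exc
    x = _to_float(np.asarray(data))
    if x.ndim == 2:
        x = x.mean(axis=1)
    if rate != target_rate:
        g = math.gcd(int(rate), int(target_rate))
        x = sps.resample_poly(x, target_rate // g, rate // g)
    if not np.all(np.isfinite(x)):
        raise IOError(f"non-finite samples in {path!r}")
    if patient_id is None:
        patient_id = os.path.basename(path).split("_")[0]
    return AudioRecording(patient_id, diagnosis, x, target_rate, path)


def from_synthetic(rec: SyntheticRecording) -> AudioRecording:
    """Wrap an in-memory synthetic recording without a disk round-trip."""
    return AudioRecording(rec.patient_id, rec.diagnosis.value,
                          rec.waveform, rec.sample_rate,
                          source_path=rec.recording_id or "synthetic")


# ---------------------------------------------------------------------------
# segmentation and normalization
# ---------------------------------------------------------------------------

def segment_clips(rec: AudioRecording, clip_len_s: float = CLIP_LEN_S) -> List[Clip]:
    """Tile the recording with non-overlapping fixed-length clips; the
    trailing remainder shorter than one clip is dropped (not padded)."""
    if clip_len_s <= 0:
        raise ValueError("clip_len_s must be positive")
    n_clip = int(round(clip_len_s * rec.sample_rate))
    n = len(rec.waveform) // n_clip
    clips = []
    for i in range(n):
        seg = rec.waveform[i * n_clip:(i + 1) * n_clip]
        clips.append(Clip(rec.patient_id, rec.diagnosis,
                          i * clip_len_s, (i + 1) * clip_len_s,
                          np.asarray(seg, dtype=np.float64),
                          rec.sample_rate, rec.source_path))
    return clips


def normalize_clip(clip: Clip) -> Clip:
    """Zero-mean, peak-1 amplitude normalization (keeps SNR bookkeeping clean)."""
    x = clip.waveform - clip.waveform.mean()
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return Clip(clip.patient_id, clip.label, clip.start_s, clip.end_s,
                x, clip.sample_rate, clip.source_path)


# ---------------------------------------------------------------------------
# patient-wise splits
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, ratios: Sequence[float]) -> List[int]:
    quotas = [r * n for r in ratios]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: quotas[i] - counts[i],
                   reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def patient_split(patient_labels: Dict[str, str],
                  ratios: Tuple[float, float, float] = (0.7, 0.15, 0.15),
                  seed: int = 0,
                  partitions: Tuple[str, ...] = ("train", "val", "test"),
                  ) -> SplitAssignment:
    """Stratified patient-level split with largest-remainder rounding."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    assignment: Dict[str, str] = {}
    by_class: Dict[str, List[str]] = {}
    for pid in sorted(patient_labels):
        by_class.setdefault(patient_labels[pid], []).append(pid)
    for label, pids in sorted(by_class.items()):
        counts = _largest_remainder(len(pids), ratios)
        for part, ratio, cnt in zip(partitions, ratios, counts):
            if ratio > 0 and cnt == 0:
                raise ValueError(
                    f"cannot place >=1 {label!r} patient in partition {part!r} "
                    f"({len(pids)} patients, ratios {ratios}); use fewer "
                    "partitions or more patients")
        pids = list(pids)
        rng.shuffle(pids)
        pos = 0
        for part, cnt in zip(partitions, counts):
            for pid in pids[pos:pos + cnt]:
                assignment[pid] = part
            pos += cnt
    return SplitAssignment(assignment, tuple(ratios), seed)


def kfold_patient_splits(patient_labels: Dict[str, str], k: int = 5,
                         seed: int = 0) -> List[SplitAssignment]:
    """k patient-disjoint, class-stratified folds; every patient is held out
    exactly once. Each SplitAssignment maps patients to 'train'/'val'."""
    by_class: Dict[str, List[str]] = {}
    for pid in sorted(patient_labels):
        by_class.setdefault(patient_labels[pid], []).append(pid)
    for label, pids in by_class.items():
        if len(pids) < k:
            raise ValueError(
                f"class {label!r} has {len(pids)} patients < k={k}; "
                f"max feasible k is {len(pids)}")
    rng = np.random.default_rng(seed)
    fold_of: Dict[str, int] = {}
    for label, pids in sorted(by_class.items()):
        pids = list(pids)
        rng.shuffle(pids)
        for i, pid in enumerate(pids):  # round-robin deal keeps folds balanced
            fold_of[pid] = i % k
    splits = []
    for fold in range(k):
        assignment = {pid: ("val" if f == fold else "train")
                      for pid, f in fold_of.items()}
        splits.append(SplitAssignment(assignment, (0.0, 1.0 / k, 0.0), seed))
    return splits


def assert_no_leakage(split: SplitAssignment, clips: Sequence[Clip]) -> None:
    """Raise if any patient's clips would span two partitions."""
    parts: Dict[str, set] = {}
    for clip in clips:
        part = split.assignment.get(clip.patient_id)
        parts.setdefault(clip.patient_id, set()).add(part)
    bad = {p for p, s in parts.items() if len(s) > 1}
    if bad:
        raise AssertionError(f"patient leakage across partitions: {sorted(bad)}")


def split_clips(clips: Sequence[Clip],
                split: SplitAssignment) -> Dict[str, List[Clip]]:
    out: Dict[str, List[Clip]] = {}
    for clip in clips:
        part = split.assignment.get(clip.patient_id)
        if part is not None:
            out.setdefault(part, []).append(clip)
    return out


def oversample_minority(train_clips: Sequence[Clip]) -> List[Clip]:
    """Duplicate minority-class clips (cycling deterministically) until the
    class counts are equal. Training-set-only by contract."""
    by_label: Dict[str, List[Clip]] = {}
    for clip in train_clips:
        by_label.setdefault(clip.label, []).append(clip)
    if len(by_label) < 2:
        warnings.warn("oversample_minority: only one class present; no-op")
        return list(train_clips)
    n_max = max(len(v) for v in by_label.values())
    out = list(train_clips)
    for label, group in sorted(by_label.items()):
        need = n_max - len(group)
        for i in range(need):
            out.append(group[i % len(group)])
    return out


def split_manifest(splits: Sequence[SplitAssignment] | SplitAssignment) -> pd.DataFrame:
    """Split assignment(s) as a `patient_id,partition,fold` table."""
    if isinstance(splits, SplitAssignment):
        splits = [splits]
    rows = []
    for fold, sp in enumerate(splits):
        for pid in sorted(sp.assignment):
            rows.append({"patient_id": pid, "partition": sp.assignment[pid],
                         "fold": fold})
    return pd.DataFrame(rows, columns=["patient_id", "partition", "fold"])
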