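"""Seeded synthetic respiratory-sound cohorts.

Emulates the statistical structure of a clinical lung-sound corpus for a
COPD-vs-healthy screening task: several recordings per patient, durations
clustered near 20 s with a right-skewed tail for COPD, heavy class imbalance,
and class-dependent acoustics. Healthy recordings are smooth broadband breath
noise (band-limited white noise amplitude-modulated by the respiratory cycle);
COPD recordings band-limit the breath noise below ~800 Hz and add sustained
low-mid-frequency wheezes on expirations plus short crackle transients, giving
downstream models a known, separable ground-truth signature.

The generator is deterministic: a single cohort seed is expanded into one
counter-based substream per recording, so (spec, seed) fixes every sample.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile


class Diagnosis(str, Enum):
    COPD = "COPD"
    HEALTHY = "Healthy"


@dataclass
class ClassAcoustics:
    """Per-class event parameters for the generative model."""
    wheeze_freq_range: Tuple[float, float] = (150.0, 550.0)   # Hz
    wheeze_prob: float = 0.0          # per expiration
    crackle_rate: float = 0.0         # mean crackles per breath cycle
    breath_period_s: float = 4.0
    ie_ratio: float = 0.6             # inspiration/expiration duration ratio
    noise_band: Tuple[float, float] = (100.0, 1200.0)  # breath-noise band, Hz


@dataclass
class CohortSpec:
    """Cohort-level generative parameters.

    Defaults mirror the study conditions at desk scale: a 64:26 COPD:healthy
    patient imbalance (scaled proportionally when fewer patients are asked
    for), more recordings per COPD patient than per healthy patient, and
    durations near 20 s with a heavier right tail for COPD.
    """
    n_patients_copd: int = 64
    n_patients_healthy: int = 26
    recordings_per_patient: Tuple[int, int] = (2, 4)       # COPD inclusive range
    recordings_per_patient_healthy: Tuple[int, int] = (1, 2)
    duration_mean_s: float = 20.0
    duration_spread_s: float = 2.0
    copd_heavy_tail: bool = True
    sample_rate: int = 16000
    copd: ClassAcoustics = field(default_factory=lambda: ClassAcoustics(
        wheeze_prob=0.85, crackle_rate=1.5, noise_band=(100.0, 800.0)))
    healthy: ClassAcoustics = field(default_factory=ClassAcoustics)
    noise_floor_db: float = -30.0     # white noise floor relative to breath RMS
    seed: int = 0

    def __post_init__(self):
        if self.n_patients_copd < 0 or self.n_patients_healthy < 0:
            raise ValueError("patient counts must be nonnegative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for ac in (self.copd, self.healthy):
            if ac.wheeze_freq_range[1] >= self.sample_rate / 2:
                raise ValueError("wheeze frequencies must lie below Nyquist")


@dataclass
class SyntheticRecording:
    patient_id: str
    diagnosis: Diagnosis
    waveform: np.ndarray              # float in [-1, 1]
    sample_rate: int
    event_log: List[Tuple[str, float, float, float]]  # (type, onset s, dur s, Hz)
    recording_id: str = ""

    @property
    def duration_s(self) -> float:
        return len(self.waveform) / self.sample_rate


# ---------------------------------------------------------------------------
# acoustic primitives
# ---------------------------------------------------------------------------

def synth_breath_cycle(period_s: float, ie_ratio: float, sample_rate: int,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """One respiratory-cycle amplitude envelope.

    Two raised-cosine lobes, one inspiratory and one expiratory, with the
    inspiration/expiration duration split set by ``ie_ratio``
    (= inspiratory / expiratory duration). Peak normalized to 1.
    """
    if period_s <= 0 or sample_rate <= 0:
        raise ValueError("period_s and sample_rate must be positive")
    if ie_ratio <= 0:
        raise ValueError("ie_ratio must be positive")
    n = int(round(period_s * sample_rate))
    n_insp = int(round(n * ie_ratio / (1.0 + ie_ratio)))
    n_exp = n - n_insp
    env = np.zeros(n)
    # expiration is slightly stronger, as airflow noise tends to be
    env[:n_insp] = 0.95 * np.hanning(n_insp)
    env[n_insp:] = np.hanning(n_exp)
    peak = env.max()
    if peak > 0:
        env /= peak
    return env


def synth_wheeze(duration_s: float, center_hz: float, sample_rate: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Sustained narrowband (tonal) wheeze segment.

    A sinusoid at ``center_hz`` with slow random vibrato (<= 2% frequency
    deviation) and a Hann onset/offset envelope; by construction essentially
    all spectral power sits within +-15% of the center frequency.
    """
    if not 0 < center_hz < sample_rate / 2:
        raise ValueError("center_hz must be in (0, Nyquist)")
    n = int(round(duration_s * sample_rate))
    if n == 0:
        return np.zeros(0)
    t = np.arange(n) / sample_rate
    # slow vibrato: smoothed random walk of instantaneous frequency
    drift = rng.standard_normal(max(4, n // 800))
    drift = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, len(drift)), drift)
    inst_freq = center_hz * (1.0 + 0.02 * np.tanh(drift))
    phase = 2 * np.pi * np.cumsum(inst_freq) / sample_rate
    phase += rng.uniform(0, 2 * np.pi)
    return np.sin(phase) * np.hanning(n)


def synth_crackle(sample_rate: int, rng: np.random.Generator) -> np.ndarray:
    """Short (<= 20 ms) damped-oscillation crackle transient.

    Exponentially decaying sinusoid with a fast attack; the 1-ms smoothed
    energy envelope is non-increasing after its peak.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    dur_s = rng.uniform(0.008, 0.018)
    n = min(int(round(dur_s * sample_rate)), int(0.020 * sample_rate))
    t = np.arange(n) / sample_rate
    f = rng.uniform(800.0, min(2000.0, 0.45 * sample_rate))
    tau = rng.uniform(0.0015, 0.003)
    attack = 1.0 - np.exp(-t / 0.0004)
    return attack * np.exp(-t / tau) * np.sin(2 * np.pi * f * t)


# ---------------------------------------------------------------------------
# recording and cohort synthesis
# ---------------------------------------------------------------------------

def _bandpass(x: np.ndarray, band: Tuple[float, float], sample_rate: int) -> np.ndarray:
    nyq = sample_rate / 2
    lo = max(band[0] / nyq, 1e-4)
    hi = min(band[1] / nyq, 0.999)
    sos = sps.butter(4, [lo, hi], btype="bandpass", output="sos")
    return sps.sosfilt(sos, x)


def _synth_recording(patient_id: str, diagnosis: Diagnosis, duration_s: float,
                     spec: CohortSpec, rng: np.random.Generator) -> SyntheticRecording:
    sr = spec.sample_rate
    ac = spec.copd if diagnosis is Diagnosis.COPD else spec.healthy
    n = int(round(duration_s * sr))
    events: List[Tuple[str, float, float, float]] = []

    # breath-cycle envelope tiled over the recording (slight period jitter)
    env = np.zeros(n)
    cycle_bounds = []  # (start, n_insp, n_cycle)
    pos = 0
    while pos < n:
        period = ac.breath_period_s * rng.uniform(0.9, 1.1)
        cyc = synth_breath_cycle(period, ac.ie_ratio, sr)
        m = min(len(cyc), n - pos)
        env[pos:pos + m] = cyc[:m]
        n_insp = int(round(len(cyc) * ac.ie_ratio / (1 + ac.ie_ratio)))
        cycle_bounds.append((pos, n_insp, len(cyc)))
        pos += len(cyc)

    breath = _bandpass(rng.standard_normal(n), ac.noise_band, sr)
    breath /= max(np.sqrt(np.mean(breath**2)), 1e-12)
    x = breath * (0.12 + env)

    if diagnosis is Diagnosis.COPD:
        for start, n_insp, n_cyc in cycle_bounds:
            exp_start = start + n_insp
            exp_len = min(n_cyc - n_insp, n - exp_start)
            if exp_len <= int(0.45 * sr):  # too short for a >=250 ms wheeze
                continue
            if rng.random() < ac.wheeze_prob:
                dur = rng.uniform(0.3, min(0.8 * exp_len / sr, 1.2))
                onset = exp_start + int(rng.uniform(0, max(exp_len - dur * sr, 1)))
                f0 = rng.uniform(*ac.wheeze_freq_range)
                w = synth_wheeze(dur, f0, sr, rng)
                m = min(len(w), n - onset)
                amp = rng.uniform(0.8, 1.4)
                x[onset:onset + m] += amp * w[:m] * np.maximum(env[onset:onset + m], 0.3)
                events.append(("wheeze", onset / sr, dur, f0))
            k = rng.poisson(ac.crackle_rate)
            for _ in range(k):
                c = synth_crackle(sr, rng)
                onset = start + int(rng.uniform(0, max(n_cyc - len(c), 1)))
                if onset + len(c) > n:
                    continue
                amp = rng.uniform(0.5, 1.0)
                x[onset:onset + len(c)] += amp * c
                events.append(("crackle", onset / sr, len(c) / sr, 0.0))
        if not events:  # guarantee at least one adventitious event
            exp_start, n_insp, n_cyc = cycle_bounds[0]
            onset = exp_start + n_insp
            f0 = float(np.mean(ac.wheeze_freq_range))
            w = synth_wheeze(0.5, f0, sr, rng)
            m = min(len(w), n - onset)
            x[onset:onset + m] += w[:m]
            events.append(("wheeze", onset / sr, 0.5, f0))

    # recording-noise floor
    floor = 10 ** (spec.noise_floor_db / 20.0)
    x += floor * rng.standard_normal(n)

    x *= 0.9 / max(np.max(np.abs(x)), 1e-12)
    np.clip(x, -1.0, 1.0, out=x)
    return SyntheticRecording(patient_id, diagnosis, x.astype(np.float64), sr,
                              events)


def generate_cohort(spec: CohortSpec) -> Tuple[List[SyntheticRecording], pd.DataFrame]:
    """Generate all recordings plus the patient-level diagnosis table."""
    if spec.n_patients_copd == 0 and spec.n_patients_healthy == 0:
        raise ValueError("empty cohort: no patients in either class")
    recordings: List[SyntheticRecording] = []
    rows = []
    patients = ([(f"C{i:03d}", Diagnosis.COPD) for i in range(spec.n_patients_copd)]
                + [(f"H{i:03d}", Diagnosis.HEALTHY)
                   for i in range(spec.n_patients_healthy)])
    for p_idx, (pid, dx) in enumerate(patients):
        rows.append({"patient_id": pid, "diagnosis": dx.value})
        p_rng = np.random.default_rng([spec.seed, p_idx])
        lo, hi = (spec.recordings_per_patient if dx is Diagnosis.COPD
                  else spec.recordings_per_patient_healthy)
        n_rec = int(p_rng.integers(lo, hi + 1))
        for r_idx in range(n_rec):
            rng = np.random.default_rng([spec.seed, p_idx, r_idx])
            if dx is Diagnosis.COPD and spec.copd_heavy_tail:
                # right-skewed lognormal centered near the mean duration
                mu = np.log(spec.duration_mean_s) - 0.02
                dur = float(np.exp(rng.normal(mu, 0.2)))
            else:
                dur = float(rng.normal(spec.duration_mean_s, spec.duration_spread_s))
            dur = float(np.clip(dur, 6.0, 90.0))
            rec = _synth_recording(pid, dx, dur, spec, rng)
            rec.recording_id = f"{pid}_{r_idx}"
            recordings.append(rec)
    table = pd.DataFrame(rows, columns=["patient_id", "diagnosis"])
    return recordings, table


def write_cohort(recordings: List[SyntheticRecording], table: pd.DataFrame,
                 out_dir: str, icbhi_names: bool = False) -> pd.DataFrame:
    """Write PCM-16 WAVs plus the diagnosis CSV; returns a file manifest.

    Default names are ``<patientid>_<idx>.wav``; ``icbhi_names`` switches to
    the 5-token `<pid>_<rec>_<loc>_<mode>_<equip>.wav` convention used by the
    public respiratory-sound corpus.
    """
    os.makedirs(out_dir, exist_ok=True)
    counters: dict = {}
    rows = []
    for rec in recordings:
        idx = counters.get(rec.patient_id, 0)
        counters[rec.patient_id] = idx + 1
        if icbhi_names:
            name = f"{rec.patient_id}_{idx:02d}_Tc_sc_Meditron.wav"
        else:
            name = f"{rec.patient_id}_{idx}.wav"
        path = os.path.join(out_dir, name)
        pcm = np.round(rec.waveform * 32767.0).astype(np.int16)
        wavfile.write(path, rec.sample_rate, pcm)
        rows.append({"file": name, "patient_id": rec.patient_id,
                     "diagnosis": rec.diagnosis.value,
                     "duration_s": rec.duration_s})
    table.to_csv(os.path.join(out_dir, "diagnosis.csv"), index=False)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
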