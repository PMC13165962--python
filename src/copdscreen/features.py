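"""Log-Mel spectrogram extraction and augmentation.

The front-end follows the standard speech-processing configuration the
classifier family assumes: 25 ms Hann window, 10 ms hop, centered frames,
512-point FFT, 80 triangular mel filters spanning 0-8000 Hz, and natural-log
compression with a small floor. Gaussian noise injection is SNR-controlled:
for a target SNR (dB), the noise variance is

    P_noise = P_signal / 10**(SNR_dB / 10),

with P_signal the mean squared value of the input, so that
10*log10(P_signal / P_noise) recovers the target exactly. Noise can be added
either to the log-Mel representation (the robustness-evaluation default) or
to the raw waveform. SpecAugment masks random frequency bands / time spans
to the spectrogram mean.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .ingest import Clip

N_MELS = 80
WIN_S = 0.025
HOP_S = 0.010
N_FFT = 512
FMIN = 0.0
FMAX = 8000.0
LOG_FLOOR = 1e-6


@dataclass
class StftConfig:
    win_s: float = WIN_S
    hop_s: float = HOP_S
    n_fft: int = N_FFT
    n_mels: int = N_MELS
    fmin: float = FMIN
    fmax: float = FMAX
    log_floor: float = LOG_FLOOR


@dataclass
class LogMelSpec:
    values: np.ndarray          # (n_mels, T), log-energy
    frame_hop_s: float
    mel_freq_edges: np.ndarray  # (n_mels, 2) lower/upper band edge in Hz
    label: str = ""
    patient_id: str = ""
    clip_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class NoiseInjectionSpec:
    snr_db: float
    p_signal: float
    p_noise: float
    seed: int


@dataclass
class NoisySignalPair:
    clean: np.ndarray
    noise: np.ndarray
    noisy: np.ndarray
    spec: NoiseInjectionSpec


# ---------------------------------------------------------------------------
# mel filterbank (HTK mel scale, triangular filters)
# ---------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(sample_rate: int, n_fft: int, n_mels: int,
                   fmin: float, fmax: float) -> Tuple[np.ndarray, np.ndarray]:
    """Triangular mel filterbank. Returns (filters (n_mels, n_fft//2+1),
    band edges (n_mels, 2) in Hz)."""
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fft_freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    fb = np.zeros((n_mels, len(fft_freqs)))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-9)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-9)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    edges = np.stack([hz_pts[:-2], hz_pts[2:]], axis=1)
    return fb, edges


def _frame(x: np.ndarray, n_win: int, n_hop: int) -> np.ndarray:
    """Centered framing with zero padding; frame count 1 + floor(n/hop)."""
    pad = n_win // 2
    xp = np.pad(x, (pad, pad))
    n_frames = 1 + len(x) // n_hop
    idx = np.arange(n_win)[None, :] + n_hop * np.arange(n_frames)[:, None]
    return xp[idx]


def compute_logmel(clip: Clip, config: StftConfig | None = None) -> LogMelSpec:
    """Log-Mel spectrogram of a 16 kHz clip: (n_mels, 1 + floor(n/hop))."""
    config = config or StftConfig()
    x = np.asarray(clip.waveform, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty clip")
    sr = clip.sample_rate
    n_win = int(round(config.win_s * sr))
    n_hop = int(round(config.hop_s * sr))
    if n_win > x.size + n_win // 2:
        raise ValueError("stft window longer than clip")
    frames = _frame(x, n_win, n_hop) * np.hanning(n_win)
    spec = np.fft.rfft(frames, n=config.n_fft, axis=1)
    power = np.abs(spec) ** 2  # (T, n_fft//2+1)
    fb, edges = mel_filterbank(sr, config.n_fft, config.n_mels,
                               config.fmin, min(config.fmax, sr / 2))
    mel_power = power @ fb.T  # (T, n_mels)
    values = np.log(mel_power.T + config.log_floor)
    return LogMelSpec(values=values, frame_hop_s=config.hop_s,
                      mel_freq_edges=edges, label=clip.label,
                      patient_id=clip.patient_id, clip_id=clip.clip_id)


# ---------------------------------------------------------------------------
# augmentations
# ---------------------------------------------------------------------------

def inject_noise_snr(x: np.ndarray, snr_db: float,
                     seed: int = 0) -> NoisySignalPair:
    """Add zero-mean Gaussian noise at a controlled SNR.

    Works on any array (waveform or spectrogram). The realized spec records
    the signal power and the analytic noise power actually used.
    """
    x = np.asarray(x, dtype=np.float64)
    p_signal = float(np.mean(x ** 2))
    if p_signal == 0.0:
        raise ValueError("zero-power input: SNR undefined")
    p_noise = p_signal / 10.0 ** (snr_db / 10.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(p_noise), size=x.shape)
    return NoisySignalPair(clean=x, noise=noise, noisy=x + noise,
                           spec=NoiseInjectionSpec(snr_db, p_signal, p_noise, seed))


def noisy_logmel(spec: LogMelSpec, snr_db: float, seed: int = 0) -> LogMelSpec:
    """Spectrogram-domain noise injection used by the robustness sweep."""
    pair = inject_noise_snr(spec.values, snr_db, seed)
    return LogMelSpec(values=pair.noisy, frame_hop_s=spec.frame_hop_s,
                      mel_freq_edges=spec.mel_freq_edges, label=spec.label,
                      patient_id=spec.patient_id, clip_id=spec.clip_id)


def spec_augment(spec: LogMelSpec, n_freq_masks: int = 1, n_time_masks: int = 1,
                 max_freq_width: int = 10, max_time_width: int = 20,
                 seed: int = 0) -> LogMelSpec:
    """SpecAugment: mask random frequency bands and time spans with the
    spectrogram mean. Shape and label preserved; deterministic under seed."""
    F, T = spec.values.shape
    if max_freq_width >= F or max_time_width >= T:
        raise ValueError("mask widths must be smaller than the spectrogram")
    rng = np.random.default_rng(seed)
    out = spec.values.copy()
    fill = out.mean()
    for _ in range(n_freq_masks):
        w = int(rng.integers(1, max_freq_width + 1))
        f0 = int(rng.integers(0, F - w + 1))
        out[f0:f0 + w, :] = fill
    for _ in range(n_time_masks):
        w = int(rng.integers(1, max_time_width + 1))
        t0 = int(rng.integers(0, T - w + 1))
        out[:, t0:t0 + w] = fill
    return LogMelSpec(values=out, frame_hop_s=spec.frame_hop_s,
                      mel_freq_edges=spec.mel_freq_edges, label=spec.label,
                      patient_id=spec.patient_id, clip_id=spec.clip_id)


def standardize_spec(values: np.ndarray) -> np.ndarray:
    """Per-clip zero-mean/unit-variance standardization before the network."""
    mu = values.mean()
    sd = values.std()
    return (values - mu) / (sd if sd > 0 else 1.0)
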