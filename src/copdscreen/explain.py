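"""Grad-CAM interpretability for the classifier, with quantitative hot-zone
statistics.

The class-activation map is computed at the final convolutional stage (the
feature maps feeding the pooling layer): the target-class score is
backpropagated to those maps, the gradients are globally averaged over time
to give one weight per channel, and the rectified weighted channel sum yields
a one-dimensional (time-resolved) activation sequence. The map is linearly
upsampled to spectrogram-frame resolution; a min-max normalized copy supports
thresholded "hot-zone" statistics (fraction of frames >= 0.6 and the mean
length of contiguous hot runs), while max/mean summaries are reported on the
raw map. Frequency localization comes from the spectrogram overlay context:
the network collapses frequency into channels at its first convolution, so
the CAM itself is time-only.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import LogMelSpec
from .nn import ECAPAClassifier, Tensor

HOT_THRESHOLD = 0.6


@dataclass
class CAMMap:
    raw: np.ndarray          # (T',) nonnegative, feature-map resolution
    upsampled: np.ndarray    # (T,) aligned to spectrogram frames
    normalized: np.ndarray   # min-max rescale of upsampled to [0, 1]
    target_class: int
    sample_id: str = ""


@dataclass
class HotZoneStats:
    threshold: float
    hot_ratio: float         # percent of frames with normalized CAM >= threshold
    mean_run_length: float   # mean length of maximal contiguous hot segments
    n_runs: int


def grad_cam(model: ECAPAClassifier, spec_input: np.ndarray, target_class: int,
             n_frames: int | None = None, sample_id: str = "") -> CAMMap:
    """Grad-CAM at the final conv stage for a single (80, T) input."""
    x = np.asarray(spec_input, dtype=np.float32)
    if x.ndim != 2:
        raise ValueError("grad_cam expects a single (n_mel, T) sample")
    model.eval()
    out = model.forward(x[None])
    feats = out.frame_features          # (1, C, T')
    score = out.logits.narrow(1, target_class, 1).sum()
    model.zero_grad()
    score.backward()
    if feats.grad is None:
        raise RuntimeError("no gradient reached the final conv stage")
    grads = feats.grad[0]               # (C, T')
    acts = feats.data[0]
    weights = grads.mean(axis=1)        # temporal global average per channel
    cam = np.maximum(weights @ acts, 0.0)   # rectified weighted channel sum
    T = n_frames or x.shape[1]
    if len(cam) == T:
        up = cam.astype(np.float64)
    else:
        src = np.linspace(0.0, 1.0, len(cam))
        up = np.interp(np.linspace(0.0, 1.0, T), src, cam)
    lo, hi = up.min(), up.max()
    normalized = (up - lo) / (hi - lo) if hi > lo else np.zeros_like(up)
    return CAMMap(raw=cam.astype(np.float64), upsampled=up,
                  normalized=normalized, target_class=target_class,
                  sample_id=sample_id)


def hot_zone_stats(cam: CAMMap, threshold: float = HOT_THRESHOLD) -> HotZoneStats:
    """Threshold the normalized map and measure hot-frame coverage and the
    mean length of maximal contiguous hot runs."""
    hot = cam.normalized >= threshold
    T = len(hot)
    runs: List[int] = []
    count = 0
    for h in hot:
        if h:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    hot_ratio = 100.0 * hot.sum() / T if T else 0.0
    mean_run = float(np.mean(runs)) if runs else 0.0
    return HotZoneStats(threshold=threshold, hot_ratio=hot_ratio,
                        mean_run_length=mean_run, n_runs=len(runs))


def cam_summary(cam: CAMMap) -> Tuple[float, float]:
    """(max, mean) of the raw (unnormalized) upsampled map."""
    return float(cam.upsampled.max()), float(cam.upsampled.mean())


def cam_table(model: ECAPAClassifier, specs: Sequence[LogMelSpec],
              inputs: np.ndarray, threshold: float = HOT_THRESHOLD) -> pd.DataFrame:
    """Per-sample CAM statistics table: sample id, labels, raw max/mean,
    hot-zone ratio and mean run length."""
    rows = []
    for i, spec in enumerate(specs):
        probs = model.predict_proba(inputs[i][None])[0]
        pred = int(np.argmax(probs))
        cam = grad_cam(model, inputs[i], target_class=1,
                       sample_id=spec.clip_id or str(i))
        hz = hot_zone_stats(cam, threshold)
        cmax, cmean = cam_summary(cam)
        rows.append({"sample_id": cam.sample_id,
                     "true_label": spec.label,
                     "pred_label": "COPD" if pred == 1 else "Healthy",
                     "cam_max": cmax, "cam_mean": cmean,
                     "hot_ratio": hz.hot_ratio,
                     "mean_run_length": hz.mean_run_length})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def overlay_array(spec_values: np.ndarray, cam: CAMMap) -> np.ndarray:
    """CAM broadcast over frequency as an (n_mel, T) alpha layer aligned to
    the spectrogram frames (the array the renderer draws)."""
    if spec_values.shape[1] != len(cam.upsampled):
        raise ValueError("spectrogram frames and CAM length differ")
    return np.broadcast_to(cam.normalized, spec_values.shape).copy()


def render_overlay(spec: LogMelSpec, cam: CAMMap, out_path: str,
                   sample_rate: int = 16000) -> str:
    """Save a PNG of the log-Mel spectrogram with the CAM as a translucent
    heat overlay; axes in seconds and Hz."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    overlay = overlay_array(spec.values, cam)
    t_max = spec.n_frames * spec.frame_hop_s
    f_max = spec.mel_freq_edges[-1, 1]
    extent = (0.0, t_max, 0.0, f_max)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.imshow(spec.values, aspect="auto", origin="lower", extent=extent,
              cmap="magma")
    ax.imshow(overlay, aspect="auto", origin="lower", extent=extent,
              cmap="jet", alpha=0.35 * overlay, vmin=0.0, vmax=1.0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(f"Grad-CAM overlay ({spec.label or 'unlabeled'})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path
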