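"""End-to-end orchestration: synthetic cohort (or WAV directory) ->
preprocessing -> features -> lasso mask -> training -> evaluation ->
robustness sweep -> Grad-CAM export, with a run manifest for auditability."""
from __future__ import annotations

import glob
import hashlib
import json
import os
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .explain import cam_table, grad_cam, render_overlay
from .ingest import (Clip, load_metadata, load_recording, patient_split,
                     segment_clips, split_clips, split_manifest, from_synthetic)
from .metrics import round_half_up
from .synthetic import CohortSpec, generate_cohort, write_cohort
from .training import (PipelineConfig, clips_to_specs, cross_validate,
                       noise_robustness_curve, run_fold, specs_to_batch)


def synth_cohort(config: RunConfig, out_dir: str | None = None):
    """Generate the configured synthetic cohort; write WAVs if out_dir."""
    spec = CohortSpec(n_patients_copd=config.data.n_patients_copd,
                      n_patients_healthy=config.data.n_patients_healthy,
                      duration_mean_s=config.data.duration_mean_s,
                      sample_rate=config.data.sample_rate,
                      seed=config.subseed("cohort"))
    recordings, table = generate_cohort(spec)
    manifest = None
    if out_dir:
        manifest = write_cohort(recordings, table, out_dir)
    return recordings, table, manifest


def load_clips(config: RunConfig) -> Tuple[List[Clip], Dict[str, str]]:
    """Clips + patient->diagnosis map, from disk if data.input_dir is set,
    otherwise from an in-memory synthetic cohort."""
    if config.data.input_dir:
        labels = load_metadata(os.path.join(config.data.input_dir, "diagnosis.csv"))
        recs = []
        for path in sorted(glob.glob(os.path.join(config.data.input_dir, "*.wav"))):
            pid = os.path.basename(path).split("_")[0]
            if pid in labels:
                recs.append(load_recording(path, patient_id=pid,
                                           diagnosis=labels[pid]))
    else:
        srecs, table, _ = synth_cohort(config)
        labels = dict(zip(table.patient_id, table.diagnosis))
        recs = [from_synthetic(r) for r in srecs]
    clips: List[Clip] = []
    for rec in recs:
        clips.extend(segment_clips(rec, config.data.clip_len_s))
    return clips, labels


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Dict:
    """Full run; writes fold summary, robustness and CAM tables plus a
    manifest (config hash, seed, artifact checksums) under output_dir."""
    out = os.path.join(config.output_dir, config.run_id)
    os.makedirs(out, exist_ok=True)
    clips, labels = load_clips(config)
    pcfg = config.pipeline_config()

    # cross-validated metrics
    summary = cross_validate(clips, labels, k=config.train.k_folds, cfg=pcfg,
                             seed=config.subseed("cv"))
    fold_rows = [dict(fold=i, **fm.as_dict())
                 for i, fm in enumerate(summary.per_fold)]
    fold_df = pd.DataFrame(fold_rows)
    fold_df.to_csv(os.path.join(out, "fold_summary.csv"), index=False)
    ci_rows = [{"metric": k, "mean": round_half_up(summary.mean[k], 2),
                "std": round_half_up(summary.std[k], 2),
                "ci_lower": round_half_up(summary.ci95[k][0], 2),
                "ci_upper": round_half_up(summary.ci95[k][1], 2)}
               for k in summary.ci95]
    pd.DataFrame(ci_rows).to_csv(os.path.join(out, "ci_table.csv"), index=False)

    # single split for the robustness sweep + explanations
    split = patient_split(labels, config.data.split_ratios,
                          seed=config.subseed("split"))
    parts = split_clips(clips, split)
    model, selector, test_metrics, history = run_fold(
        parts.get("train", []), parts.get("val", []), pcfg,
        seed=config.subseed("final-train"))
    history.to_csv(os.path.join(out, "history.csv"), index=False)
    test_clips = parts.get("test", parts.get("val", []))
    test_specs = clips_to_specs(test_clips)
    rob = noise_robustness_curve(model, selector, test_specs,
                                 config.robustness.snr_db,
                                 seed=config.subseed("noise"))
    rob.to_csv(os.path.join(out, "robustness.csv"), index=False)

    X_test, _ = specs_to_batch(test_specs, selector)
    cams = cam_table(model, test_specs, X_test,
                     threshold=config.explain.hot_threshold)
    cams.to_csv(os.path.join(out, "cam_table.csv"), index=False)
    for i in range(min(config.explain.n_overlays, len(test_specs))):
        cam = grad_cam(model, X_test[i], target_class=1)
        render_overlay(test_specs[i], cam,
                       os.path.join(out, f"overlay_{i}.png"))

    artifacts = sorted(f for f in os.listdir(out)
                       if os.path.isfile(os.path.join(out, f))
                       and f != "manifest.json")
    manifest = {
        "run_id": config.run_id,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "config": config.to_dict(),
        "artifacts": {f: _sha256(os.path.join(out, f)) for f in artifacts},
        "cv_mean": {k: round_half_up(v, 2) for k, v in summary.mean.items()},
        "test_metrics": {k: round_half_up(v, 2)
                         for k, v in test_metrics.as_dict().items()},
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
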