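import numpy as np
import pytest

from copdscreen.ingest import from_synthetic, patient_split, segment_clips, split_clips
from copdscreen.nn import ModelConfig
from copdscreen.synthetic import CohortSpec, generate_cohort
from copdscreen.training import (PipelineConfig, TrainConfig, clips_to_specs,
                                 run_fold)

TINY_SEED = 1


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small synthetic cohort shared by unit tests: 6 COPD / 4 healthy."""
    spec = CohortSpec(n_patients_copd=6, n_patients_healthy=4, seed=TINY_SEED)
    recordings, table = generate_cohort(spec)
    labels = dict(zip(table.patient_id, table.diagnosis))
    clips = []
    for rec in recordings:
        clips.extend(segment_clips(from_synthetic(rec)))
    return {"spec": spec, "recordings": recordings, "table": table,
            "labels": labels, "clips": clips}


@pytest.fixture(scope="session")
def tiny_specs(tiny_cohort):
    return clips_to_specs(tiny_cohort["clips"])


@pytest.fixture(scope="session")
def trained_small(tiny_cohort):
    """A quickly trained small model + selector on a patient-wise split,
    shared by the explainability and robustness unit tests."""
    split = patient_split(tiny_cohort["labels"], (0.6, 0.2, 0.2), seed=3)
    parts = split_clips(tiny_cohort["clips"], split)
    cfg = PipelineConfig(
        model=ModelConfig(channels=16, embedding_dim=16, seed=0),
        train=TrainConfig(max_epochs=6, batch_size=16, seed=0),
        lasso_n_lambdas=10, lasso_cv_folds=2)
    model, selector, fm, history = run_fold(parts["train"], parts["val"],
                                            cfg, seed=42)
    eval_specs = clips_to_specs(parts["val"] + parts.get("test", []))
    return {"model": model, "selector": selector, "metrics": fm,
            "history": history, "eval_specs": eval_specs, "parts": parts,
            "cfg": cfg}
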