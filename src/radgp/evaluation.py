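"""Leave-one-patient-out cross-validation and performance metrics.

In LopoCV every patient in turn contributes all of their biopsy samples as
the test fold while the remaining patients train the model: the CNV
transform, the feature standardization and the GP hyperparameters are all
(re)fit on the training fold only, and — for the transductive model — each
test sample brings its own unlabeled neighbor set.  This mirrors clinical
use: the model meets a whole new patient, never a new sample of a known
patient.  A prediction is counted correct when the predictive mean and the
true CNV fall on the same side of the 3.5 amplification cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .cnv import CNV_THRESHOLD, CnvTransform
from .data import Cohort
from .gp import GPFitConfig, TrainingSet, fit_gp
from .transductive import build_context, predict_transductive_one
from .uncertainty import _confusion, assess


@dataclass(frozen=True)
class PredictionRecord:
    sample_id: str
    patient_id: str
    truth_class: str
    predicted_class: str
    mean: float
    sd: float
    p_value: float
    category: str


@dataclass(frozen=True)
class EvalConfig:
    """LopoCV options: model hyperparameters (or optimization settings) and
    the classification threshold on the transformed scale."""

    gp: GPFitConfig = field(default_factory=GPFitConfig)
    threshold: float = CNV_THRESHOLD


def run_lopocv(
    cohort: Cohort,
    model_kind: str = "standard",
    features: list | None = None,
    config: EvalConfig | None = None,
) -> list[PredictionRecord]:
    """One prediction record per sample, each from a fold excluding its patient."""
    if model_kind not in ("standard", "transductive"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    config = config or EvalConfig()
    features = list(features or cohort.feature_names)
    patients = sorted(map(str, cohort.patients))
    if len(patients) < 2:
        raise ValueError("LopoCV requires at least 2 patients")

    df = cohort.samples
    X_all = cohort.features(features)
    records: list[PredictionRecord] = []
    for test_patient in patients:
        test_mask = (df["patient_id"].astype(str) == test_patient).to_numpy()
        if not test_mask.any():
            warnings.warn(f"patient {test_patient} has no samples; fold skipped")
            continue
        train_mask = ~test_mask
        transform = CnvTransform.fit(df.loc[train_mask, "cnv_raw"].to_numpy(dtype=float))
        train = TrainingSet(
            X=X_all[train_mask],
            Y=transform(df.loc[train_mask, "cnv_raw"].to_numpy(dtype=float)),
            patient_ids=df.loc[train_mask, "patient_id"].to_numpy(),
        )
        # Structural no-leakage check: the held-out patient never trains.
        assert test_patient not in set(map(str, train.patient_ids))
        model = fit_gp(train, config.gp)
        threshold = transform.inverse_threshold() if config.threshold == CNV_THRESHOLD else config.threshold
        for idx in np.flatnonzero(test_mask):
            sid = str(df["sample_id"].iloc[idx])
            if model_kind == "transductive":
                context = build_context(model, cohort.neighbor_features(sid, features))
            else:
                context = None
            dist = predict_transductive_one(model, context, X_all[idx])
            ua = assess(dist, threshold)
            truth = "amplified" if float(df["cnv_raw"].iloc[idx]) > CNV_THRESHOLD else "wildtype"
            records.append(
                PredictionRecord(
                    sample_id=sid,
                    patient_id=test_patient,
                    truth_class=truth,
                    predicted_class=ua.predicted_class,
                    mean=dist.mean,
                    sd=ua.sd,
                    p_value=ua.p_value,
                    category=ua.category,
                )
            )
    return records


def confusion_metrics(records) -> dict:
    """Accuracy, sensitivity, specificity and n (amplified = positive class)."""
    records = list(records)
    if not records:
        raise ValueError("empty prediction set")
    return _confusion(records)


def roc_auc(records, score: str = "mean") -> float:
    """AUC with the transformed-scale predictive mean as the score.

    ``score="signed_z"`` uses the signed z-statistic instead.  Ties count
    half; both classes must be present.
    """
    records = list(records)
    y = np.array([r.truth_class == "amplified" for r in records], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC undefined with a single class present")
    if score == "mean":
        s = np.array([r.mean for r in records])
    elif score == "signed_z":
        s = np.array([(r.mean - CNV_THRESHOLD) / r.sd for r in records])
    else:
        raise ValueError(f"unknown score {score!r}")
    return float(roc_auc_score(y, s))


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
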