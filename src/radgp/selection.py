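"""Forward stepwise feature selection under two criteria.

Selection starts from an empty feature set.  At each step every remaining
candidate is scored by a full leave-one-patient-out cross-validation with
the current set plus that candidate, and the best candidate is added; the
procedure stops when the criterion no longer improves (beyond a small
tolerance) or a feature budget is reached.  Two criteria are supported:

* ``accuracy``    — maximize LopoCV classification accuracy (a match is
  counted when prediction and truth are on the same side of 3.5); the
  criterion paired with the standard GP.
* ``uncertainty`` — minimize the LopoCV sum of per-sample z-test p-values;
  the criterion paired with the transductive GP, which uses each test
  sample's own neighbor set.

Hyperparameters are refit within every training fold during selection (no
leakage).  That costs O(F^2 P) model fits; pass a fixed-hyperparameter
``GPFitConfig`` for the fast mode.

Step-0 baselines (the spec value the first step must beat): the accuracy of
the constant training-mean predictor for the accuracy criterion, and
p = 0.5 per sample (the one-sided cap) for the uncertainty criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cnv import CNV_THRESHOLD, CnvTransform
from .data import Cohort
from .evaluation import EvalConfig, run_lopocv


@dataclass(frozen=True)
class SelectionConfig:
    eval: EvalConfig = field(default_factory=EvalConfig)
    max_features: int = 20
    tolerance: float = 1e-6


@dataclass
class SelectionTrace:
    steps: list  # ordered (feature_id, criterion_value) pairs
    selected: list
    criterion_name: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"criterion": self.criterion_name, "selected": self.selected,
                 "steps": [{"feature": f, "value": v} for f, v in self.steps]},
                fh, indent=2,
            )


def criterion_value(records, criterion: str) -> float:
    """Score a set of LopoCV prediction records under one criterion."""
    records = list(records)
    if not records:
        raise ValueError("empty prediction set")
    if criterion == "accuracy":
        return float(np.mean([r.predicted_class == r.truth_class for r in records]))
    if criterion == "uncertainty":
        return float(np.sum([r.p_value for r in records]))
    raise ValueError(f"unknown criterion {criterion!r}")


def _baseline(cohort: Cohort, criterion: str) -> float:
    """Empty-feature-set reference value."""
    if criterion == "uncertainty":
        return 0.5 * len(cohort)
    # Constant training-mean predictor under LopoCV.
    df = cohort.samples
    correct = 0
    for patient in cohort.patients:
        mask = (df["patient_id"] == patient).to_numpy()
        raw_train = df.loc[~mask, "cnv_raw"].to_numpy(dtype=float)
        ybar = CnvTransform.fit(raw_train)(raw_train).mean()
        pred = "amplified" if ybar > CNV_THRESHOLD else "wildtype"
        truth = df.loc[mask, "cnv_raw"].to_numpy(dtype=float) > CNV_THRESHOLD
        correct += int(np.sum(truth == (pred == "amplified")))
    return correct / len(cohort)


def forward_select(
    cohort: Cohort,
    model_kind: str = "standard",
    criterion: str = "accuracy",
    config: SelectionConfig | None = None,
    candidates: list | None = None,
) -> SelectionTrace:
    """Greedy forward selection of features by LopoCV criterion.

    Ties between equally scoring candidates break toward the lowest feature
    index (candidate-list order), making the trace deterministic.
    """
    if criterion not in ("accuracy", "uncertainty"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if len(cohort.patients) < 2:
        raise ValueError("selection requires at least 2 patients (LopoCV undefined)")
    config = config or SelectionConfig()
    candidates = list(candidates or cohort.feature_names)
    if not candidates:
        raise ValueError("no candidate features")

    maximize = criterion == "accuracy"
    best_value = _baseline(cohort, criterion)
    selected: list = []
    steps: list = []
    remaining = list(candidates)
    while remaining and len(selected) < config.max_features:
        scores = []
        for f in remaining:
            records = run_lopocv(cohort, model_kind, selected + [f], config.eval)
            scores.append(criterion_value(records, criterion))
        scores = np.asarray(scores)
        idx = int(np.argmax(scores)) if maximize else int(np.argmin(scores))
        value = float(scores[idx])
        improvement = (value - best_value) if maximize else (best_value - value)
        if improvement < config.tolerance:
            break
        selected.append(remaining.pop(idx))
        steps.append((selected[-1], value))
        best_value = value
    return SelectionTrace(steps=steps, selected=selected, criterion_name=criterion)
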