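"""Predictive-uncertainty quantification via a one-sided z-test.

Each GP prediction is a Gaussian N(mu*, sigma*^2) on the transformed
copy-number scale.  The predicted class is read off the side of the 3.5
amplification cutoff the mean falls on, and the hypothesis "the sample
belongs to the class predicted by the mean" is tested with a one-sided
z-test: z = |mu* - 3.5| / sigma*, p = 1 - Phi(z).  Small p means the
predictive mass sits firmly on one side of the cutoff (a certain,
interpolated prediction); p is capped at 0.5 since the test is always
against the class the mean already favors.

Predictions are further categorized (scatter of SD vs p):

* ``interpolated``  — p < 0.05: the test point lies inside the effective
  training domain.
* ``extrapolated``  — p >= 0.05 and SD > 0.40: far from the training data,
  the prior dominates.
* ``border``        — p >= 0.05 and SD <= 0.40: confident distribution
  sitting close to the cutoff.

SD is the latent predictive SD on the transformed scale — the same quantity
as the z-test denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cnv import CNV_THRESHOLD
from .gp import PredictiveDistribution

#: Fig.-style category cutoffs.
P_CUTOFF = 0.05
SD_CUTOFF = 0.40


@dataclass(frozen=True)
class UncertaintyAssessment:
    p_value: float
    predicted_class: str
    sd: float
    category: str


def categorize(p: float, sd: float, *, p_cutoff: float = P_CUTOFF, sd_cutoff: float = SD_CUTOFF) -> str:
    """Assign the interpolated / extrapolated / border category.

    Boundary conventions: p == p_cutoff exactly is uncertain (the certain
    stratum is read strictly as p < cutoff); sd == sd_cutoff exactly is
    border.
    """
    if p < p_cutoff:
        return "interpolated"
    return "extrapolated" if sd > sd_cutoff else "border"


def assess(dist: PredictiveDistribution, threshold: float = CNV_THRESHOLD) -> UncertaintyAssessment:
    """One-sided z-test of a predictive distribution against the cutoff."""
    if dist.variance <= 0:
        raise ValueError("z-test undefined for zero predictive variance")
    sd = dist.sd
    z = abs(dist.mean - threshold) / sd
    p = float(norm.sf(z))
    predicted = "amplified" if dist.mean > threshold else "wildtype"
    return UncertaintyAssessment(
        p_value=p, predicted_class=predicted, sd=sd, category=categorize(p, sd)
    )


def _confusion(records) -> dict:
    """Accuracy / sensitivity / specificity with amplified as positive class."""
    tp = fn = tn = fp = 0
    for r in records:
        truth, pred = r.truth_class, r.predicted_class
        if truth == "amplified":
            tp += pred == "amplified"
            fn += pred != "amplified"
        else:
            tn += pred == "wildtype"
            fp += pred != "wildtype"
    n = tp + fn + tn + fp
    import warnings

    if tp + fn == 0:
        warnings.warn("no positive (amplified) samples: sensitivity undefined")
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative (wildtype) samples: specificity undefined")
        spec = float("nan")
    else:
        spec = tn / (tn + fp)
    return {
        "n": n,
        "accuracy": (tp + tn) / n if n else float("nan"),
        "sensitivity": sens,
        "specificity": spec,
    }


def stratify(records, p_cutoffs=(0.05, 0.10, 0.15)) -> pd.DataFrame:
    """Stratified performance report: pooled row plus certain/uncertain rows.

    For each cutoff c, the certain stratum is p < c and the uncertain stratum
    p >= c; their sizes always sum to the pooled n.  Columns: cutoff,
    stratum, n, accuracy, sensitivity, specificity.
    """
    records = list(records)
    if not records:
        raise ValueError("empty prediction set")
    rows = [{"cutoff": np.nan, "stratum": "pooled", **_confusion(records)}]
    for c in p_cutoffs:
        certain = [r for r in records if r.p_value < c]
        uncertain = [r for r in records if r.p_value >= c]
        for name, grp in (("certain", certain), ("uncertain", uncertain)):
            if grp:
                stats = _confusion(grp)
            else:
                stats = {"n": 0, "accuracy": np.nan, "sensitivity": np.nan, "specificity": np.nan}
            rows.append({"cutoff": c, "stratum": name, **stats})
    return pd.DataFrame(rows, columns=["cutoff", "stratum", "n", "accuracy", "sensitivity", "specificity"])
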