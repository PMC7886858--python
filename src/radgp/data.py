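"""Cohort container and CSV round-trip I/O.

A cohort is a table of biopsy samples (sample ID, patient ID, raw CNV
outcome, feature columns) plus an optional map from sample ID to the feature
vectors of its unlabeled image neighbors.  On disk a cohort is two CSVs and
a JSON sidecar:

* ``samples.csv``   — sample_id, patient_id, cnv_raw, <feature columns>
* ``neighbors.csv`` — sample_id, neighbor_idx, <feature columns>
* ``cohort.json``   — generating config (if any), truth classes, informative
  feature IDs.

Feature values are written with 17 significant digits and parsed back with
round-trip precision, so write -> read recovers tables exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Cohort:
    samples: pd.DataFrame
    feature_names: list
    neighbors: dict | None = None
    truth: dict | None = None
    informative_feature_ids: list = field(default_factory=list)
    config: dict | None = None

    def __post_init__(self):
        for col in ("sample_id", "patient_id", "cnv_raw"):
            if col not in self.samples.columns:
                raise ValueError(f"samples table missing required column {col!r}")
        missing = [f for f in self.feature_names if f not in self.samples.columns]
        if missing:
            raise ValueError(f"samples table missing feature columns: {missing[:5]}")

    @property
    def patients(self) -> np.ndarray:
        return np.unique(self.samples["patient_id"])

    def __len__(self) -> int:
        return len(self.samples)

    def features(self, names=None) -> np.ndarray:
        return self.samples[list(names or self.feature_names)].to_numpy(dtype=float)

    def neighbor_features(self, sample_id, names=None) -> np.ndarray | None:
        if not self.neighbors or sample_id not in self.neighbors:
            return None
        nbrs = self.neighbors[sample_id]
        if isinstance(nbrs, pd.DataFrame):
            return nbrs[list(names or self.feature_names)].to_numpy(dtype=float)
        idx = [self.feature_names.index(n) for n in (names or self.feature_names)]
        return np.asarray(nbrs, dtype=float)[:, idx]


def write_cohort(cohort: Cohort, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = ["sample_id", "patient_id", "cnv_raw", *cohort.feature_names]
    cohort.samples[cols].to_csv(outdir / "samples.csv", index=False, float_format="%.17g")
    if cohort.neighbors:
        rows = []
        for sid, nbrs in cohort.neighbors.items():
            arr = np.asarray(nbrs, dtype=float)
            for i, row in enumerate(arr):
                rows.append({"sample_id": sid, "neighbor_idx": i,
                             **dict(zip(cohort.feature_names, row))})
        pd.DataFrame(rows).to_csv(outdir / "neighbors.csv", index=False, float_format="%.17g")
    sidecar = {
        "feature_names": list(cohort.feature_names),
        "truth": cohort.truth,
        "informative_feature_ids": list(cohort.informative_feature_ids),
        "config": cohort.config,
    }
    with open(outdir / "cohort.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_cohort(indir) -> Cohort:
    indir = Path(indir)
    samples = pd.read_csv(indir / "samples.csv", float_precision="round_trip")
    sidecar = {}
    if (indir / "cohort.json").exists():
        with open(indir / "cohort.json") as fh:
            sidecar = json.load(fh)
    feature_names = sidecar.get("feature_names") or [
        c for c in samples.columns if c not in ("sample_id", "patient_id", "cnv_raw")
    ]
    neighbors = None
    if (indir / "neighbors.csv").exists():
        nbr_df = pd.read_csv(indir / "neighbors.csv", float_precision="round_trip")
        neighbors = {
            sid: grp.sort_values("neighbor_idx")[feature_names].to_numpy(dtype=float)
            for sid, grp in nbr_df.groupby("sample_id")
        }
    return Cohort(
        samples=samples,
        feature_names=feature_names,
        neighbors=neighbors,
        truth=sidecar.get("truth"),
        informative_feature_ids=sidecar.get("informative_feature_ids") or [],
        config=sidecar.get("config"),
    )
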