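"""Synthetic cohorts with the statistical structure of an image-localized
biopsy study.

The generator emulates a cohort of ~25 glioblastoma patients contributing
1-6 biopsies each.  Every biopsy carries a 336-dimensional texture-feature
vector; a small informative subset drives a smooth monotone nonlinear latent
score which is warped into a raw copy-number value on a right-skewed scale
(~[1.9, 82]) with a long amplified tail above the 3.5 cutoff.  Each biopsy
also has eight spatially correlated unlabeled neighbors (the feature vectors
a transductive model consumes).

Latent model, per sample i of patient p:

    u_i = (1/sqrt(m)) * sum of the m informative features   (unit variance)
    g(u) = u + 0.3 sin(2u) + 0.2 u |u|                      (strictly increasing)
    s_i = g(u_i) + a_p + eps_i,   a_p ~ N(0, (noise_sd/2)^2),
                                  eps_i ~ N(0, noise_sd^2)

The amplification boundary is set at the empirical (1 - amplified_fraction)
quantile t of s; scores at or below t map linearly onto
[cnv_min, 3.5] and scores above t map onto (3.5, cnv_max] through an
exponential warp exp m1(4w)/expm1(4), producing the long right tail.  Raw
CNV is therefore a strictly monotone function of the latent score, so with
zero noise and a single informative feature the raw CNV preserves that
feature's ranks exactly.

The patient-level intercept a_p makes samples within a patient more alike
than across patients, so leave-one-patient-out evaluation is strictly harder
than per-sample cross-validation.

All randomness flows from the config seed through named streams
(:mod:`radgp._seeds`), so every output is a pure function of the config.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._seeds import stream_rng
from .cnv import CNV_THRESHOLD
from .data import Cohort

#: The six MRI contrasts of the study, in canonical order.
CONTRASTS = ("T2", "SPGRC", "rCBV", "EPI", "FA", "MD")

#: Neighbors per interior biopsy sample.
N_NEIGHBORS = 8


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort-shape and effect parameters.

    Defaults are the study conditions: 25 patients with 1-6 biopsies each,
    336 texture features of which 4 are informative (matching the size of
    the uncertainty-selected feature set), raw CNV spanning 1.876-82.43 with
    ~40% amplified samples (amplification occurs in 30-45% of GBM tumors),
    and neighbors correlated at 0.9 with their parent sample.
    """

    n_patients: int = 25
    biopsies_per_patient_range: tuple = (1, 6)
    n_features: int = 336
    n_informative: int = 4
    amplified_fraction: float = 0.4
    cnv_range: tuple = (1.876, 82.43)
    noise_sd: float = 0.35
    neighbor_correlation: float = 0.9
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.biopsies_per_patient_range
        vals = [self.n_patients, lo, hi, self.n_features, self.n_informative,
                self.amplified_fraction, *self.cnv_range, self.noise_sd,
                self.neighbor_correlation]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite config value")
        if self.n_patients < 1 or self.n_features < 1:
            raise ValueError("n_patients and n_features must be positive")
        if not (1 <= lo <= hi):
            raise ValueError("biopsies_per_patient_range must satisfy 1 <= lo <= hi")
        if not (1 <= self.n_informative <= self.n_features):
            raise ValueError("n_informative must be in [1, n_features]")
        if not (0 < self.amplified_fraction < 1):
            raise ValueError("amplified_fraction must be in (0, 1)")
        if not (self.cnv_range[0] < CNV_THRESHOLD < self.cnv_range[1]):
            raise ValueError(f"cnv_range must straddle {CNV_THRESHOLD}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0 < self.neighbor_correlation <= 1):
            raise ValueError("neighbor_correlation must be in (0, 1]")

    @property
    def feature_names(self) -> list:
        width = max(4, len(str(self.n_features)))
        return [f"f_{i + 1:0{width}d}" for i in range(self.n_features)]


def _latent(u: np.ndarray) -> np.ndarray:
    # Strictly increasing: derivative >= 1 - 0.6 = 0.4 everywhere.
    return u + 0.3 * np.sin(2.0 * u) + 0.2 * u * np.abs(u)


def _skew_to_cnv(s: np.ndarray, threshold_score: float, cnv_range: tuple) -> np.ndarray:
    """Monotone warp of latent scores onto the raw CNV scale."""
    cmin, cmax = cnv_range
    raw = np.empty_like(s)
    wt = s <= threshold_score
    smin = float(s.min())
    span = max(threshold_score - smin, 1e-12)
    raw[wt] = cmin + (CNV_THRESHOLD - cmin) * (s[wt] - smin) / span
    amp = ~wt
    if np.any(amp):
        smax = float(s.max())
        wspan = max(smax - threshold_score, 1e-12)
        w = (s[amp] - threshold_score) / wspan
        k = 4.0  # exponential warp rate; larger -> heavier right tail
        raw[amp] = CNV_THRESHOLD + (cmax - CNV_THRESHOLD) * np.expm1(k * w) / np.expm1(k)
    return np.clip(raw, cmin, cmax)


def generate_neighbors(
    features: np.ndarray,
    config: SyntheticCohortConfig,
    *,
    count: int = N_NEIGHBORS,
    rng: np.random.Generator | None = None,
    key: object = "neighbors",
) -> np.ndarray:
    """Correlated unlabeled neighbors of one sample's feature vector.

    Each neighbor is ``rho * x + sqrt(1 - rho^2) * eps`` with standard-normal
    perturbations drawn once per neighbor, so the expected feature-wise
    correlation with the parent equals ``neighbor_correlation``.  In the
    rho = 1 limit neighbors equal the parent exactly.  Boundary samples may
    request fewer than 8 neighbors via ``count``.
    """
    x = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite sample features")
    rho = config.neighbor_correlation
    if rng is None:
        rng = stream_rng(config.seed, "neighbors", key)
    eps = rng.standard_normal((count, x.shape[0]))
    return rho * x + np.sqrt(max(1.0 - rho**2, 0.0)) * eps


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Generate a seeded synthetic cohort (samples, neighbors, truth)."""
    lo, hi = config.biopsies_per_patient_range
    counts = stream_rng(config.seed, "counts").integers(lo, hi + 1, size=config.n_patients)
    n = int(counts.sum())
    patient_ids = np.repeat([f"P{p + 1:03d}" for p in range(config.n_patients)], counts)
    sample_ids = []
    for p, c in enumerate(counts):
        sample_ids += [f"P{p + 1:03d}_B{b + 1}" for b in range(c)]

    X = stream_rng(config.seed, "features").standard_normal((n, config.n_features))
    m = config.n_informative
    u = X[:, :m].sum(axis=1) / np.sqrt(m)
    intercepts = stream_rng(config.seed, "patient_effects").normal(
        0.0, config.noise_sd / 2.0, size=config.n_patients
    )
    eps = stream_rng(config.seed, "noise").normal(0.0, config.noise_sd, size=n)
    s = _latent(u) + np.repeat(intercepts, counts) + eps

    t = float(np.quantile(s, 1.0 - config.amplified_fraction))
    raw = _skew_to_cnv(s, t, config.cnv_range)

    names = config.feature_names
    samples = pd.DataFrame(X, columns=names)
    samples.insert(0, "cnv_raw", raw)
    samples.insert(0, "patient_id", patient_ids)
    samples.insert(0, "sample_id", sample_ids)

    nbr_rng = stream_rng(config.seed, "neighbors")
    neighbors = {
        sid: generate_neighbors(X[i], config, rng=nbr_rng) for i, sid in enumerate(sample_ids)
    }
    truth = {sid: ("amplified" if r > CNV_THRESHOLD else "wildtype")
             for sid, r in zip(sample_ids, raw)}
    return Cohort(
        samples=samples,
        feature_names=names,
        neighbors=neighbors,
        truth=truth,
        informative_feature_ids=names[:m],
        config=asdict(config),
    )


def generate_roi_stack(class_label: str, seed: int, *, size: int = 8) -> dict:
    """Seeded 6-contrast stack of correlated random-field windows.

    Windows are smoothed Gaussian noise whose smoothness differs by class:
    wildtype textures are smooth (strong spatial correlation, low local
    contrast) and amplified textures are rough, so co-occurrence contrast
    separates the classes well above chance.  Statistical stand-ins only —
    no MRI physics is simulated.
    """
    if class_label not in ("amplified", "wildtype"):
        raise ValueError(f"unknown class label {class_label!r}")
    sigma = 0.45 if class_label == "amplified" else 1.3
    rng = stream_rng(seed, "roi", class_label)
    stack = {}
    for c in CONTRASTS:
        field = gaussian_filter(rng.standard_normal((size, size)), sigma=sigma, mode="reflect")
        stack[c] = field
    return stack
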