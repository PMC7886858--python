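"""Radiomic texture features for 8x8 ROI windows.

Each biopsy ROI is a single 8x8 window per MRI contrast (T2, SPGRC, rCBV,
EPI, FA, MD).  Per contrast the extractor emits exactly 56 features:

* 18 first-order statistics of the 0-255-mapped intensities,
* 14 direction-averaged Haralick statistics of the gray-level co-occurrence
  matrix at pixel distance 1,
* 14 at distance 3,
* 10 Gabor response statistics (mean and std for each of 5 frequency /
  bandwidth pairs, magnitude pooled over 4 orientations),

for a total of 6 x 56 = 336 features per stack.  Window intensities are
affinely mapped onto 0-255 first (min -> 0, max -> 255, round half up);
this standardizes intensities across scanners and contrasts.  Feature names
follow the "<Contrast>.<Feature>[_Avg_<d>]" convention, e.g.
"T2.Angular.Second.Moment_Avg_1", "rCBV.Kurtosis", "EPI.Gabor_Mean_0.4_0.1".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew
from skimage.feature import graycomatrix
from skimage.filters import gabor

from .synthetic import CONTRASTS

WINDOW_SIZE = 8

FIRST_ORDER_NAMES = (
    "Mean", "SD", "Energy", "TotalEnergy", "Entropy", "Minimum", "P10", "P90",
    "Maximum", "Median", "IQR", "Range", "MAD", "rMAD", "RMS", "Skewness",
    "Kurtosis", "Uniformity",
)

HARALICK_NAMES = (
    "Angular.Second.Moment", "Contrast", "Correlation", "Sum.of.Squares.Variance",
    "Inverse.Difference.Moment", "Sum.Average", "Sum.Variance", "Sum.Entropy",
    "Entropy", "Difference.Variance", "Difference.Entropy",
    "Information.Measure.of.Correlation.1", "Information.Measure.of.Correlation.2",
    "Maximal.Correlation.Coefficient",
)

#: Default Gabor bank: (frequency in cycles/pixel, envelope bandwidth).  The
#: bandwidth token is the frequency-domain std of the Gaussian envelope;
#: spatially sigma = 1 / (2 pi b).
DEFAULT_GABOR_BANK = ((0.1, 0.1), (0.2, 0.1), (0.3, 0.1), (0.4, 0.1), (0.5, 0.1))

_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass(frozen=True)
class TextureConfig:
    glcm_levels: int = 16
    glcm_distances: tuple = (1, 3)
    gabor_bank: tuple = DEFAULT_GABOR_BANK
    #: First-order stats computed after the 0-255 mapping (switchable).
    first_order_after_mapping: bool = True


@dataclass(frozen=True)
class ROIWindow:
    intensities: np.ndarray
    contrast_name: str

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.shape != (WINDOW_SIZE, WINDOW_SIZE):
            raise ValueError(f"window must be {WINDOW_SIZE}x{WINDOW_SIZE}, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite window intensities")
        if self.contrast_name not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast_name!r}")
        object.__setattr__(self, "intensities", arr)


@dataclass(frozen=True)
class FeatureVector:
    names: tuple
    values: tuple

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise ValueError("names and values lengths differ")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    def __len__(self) -> int:
        return len(self.names)

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


def normalize_window(window) -> np.ndarray:
    """Affine map of window intensities onto integers 0-255 (round half up).

    A constant window maps to all zeros (no division by zero), keeping every
    downstream feature finite.
    """
    arr = window.intensities if isinstance(window, ROIWindow) else np.asarray(window, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite window intensities")
    mn, mx = float(arr.min()), float(arr.max())
    if mx == mn:
        return np.zeros(arr.shape, dtype=np.int64)
    return np.floor((arr - mn) / (mx - mn) * 255.0 + 0.5).astype(np.int64)


# -- first-order --------------------------------------------------------------

def _histogram_probs(x: np.ndarray, levels: int = 16) -> np.ndarray:
    # 16 equal-width bins over the 0-255 range (bin width 16).
    counts, _ = np.histogram(x, bins=levels, range=(0, 256))
    p = counts / counts.sum()
    return p[p > 0]


def first_order_features(grid: np.ndarray) -> FeatureVector:
    """The 18 first-order statistics, in canonical order.

    Sample (ddof=1, bias-corrected) SD / skewness / excess kurtosis;
    skewness and kurtosis are 0 by convention for zero-variance windows.
    Entropy and uniformity use the 16-bin intensity histogram; percentiles
    use linear interpolation.  TotalEnergy equals Energy at unit voxel
    volume.
    """
    x = np.asarray(grid, dtype=float).ravel()
    p10, p25, med, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    probs = _histogram_probs(x)
    constant = x.max() == x.min()
    robust = x[(x >= p10) & (x <= p90)]
    vals = {
        "Mean": x.mean(),
        "SD": x.std(ddof=1),
        "Energy": np.sum(x**2),
        "TotalEnergy": np.sum(x**2),
        "Entropy": -np.sum(probs * np.log2(probs)),
        "Minimum": x.min(),
        "P10": p10,
        "P90": p90,
        "Maximum": x.max(),
        "Median": med,
        "IQR": p75 - p25,
        "Range": x.max() - x.min(),
        "MAD": np.mean(np.abs(x - x.mean())),
        "rMAD": np.mean(np.abs(robust - robust.mean())) if robust.size else 0.0,
        "RMS": np.sqrt(np.mean(x**2)),
        "Skewness": 0.0 if constant else _skew(x, bias=False),
        "Kurtosis": 0.0 if constant else _kurtosis(x, fisher=True, bias=False),
        "Uniformity": np.sum(probs**2),
    }
    return FeatureVector(FIRST_ORDER_NAMES, tuple(vals[n] for n in FIRST_ORDER_NAMES))


# -- GLCM / Haralick ----------------------------------------------------------

def glcm_matrix(grid: np.ndarray, distance: int, *, levels: int = 16) -> np.ndarray:
    """Direction-averaged symmetric normalized co-occurrence matrix.

    The 0-255 grid is quantized to ``levels`` gray levels (16 by default:
    finer quantization gives sparse matrices on a 64-pixel window), then the
    four in-plane directions (0, 45, 90, 135 degrees) at the given pixel
    distance are accumulated symmetrically, normalized, and averaged.
    """
    q = (np.asarray(grid, dtype=np.int64) * levels // 256).astype(np.uint8)
    P = graycomatrix(q, distances=[distance], angles=list(_ANGLES), levels=levels,
                     symmetric=True, normed=True)
    return P[:, :, 0, :].mean(axis=-1)


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def haralick_from_matrix(P: np.ndarray) -> dict:
    """The classic 14 Haralick statistics of one normalized GLCM.

    Degenerate conventions (single occupied gray level): Correlation, IMC1
    and MCC are 0.  Sum Variance uses Sum Average as its center (the common
    correction of the original definition).
    """
    levels = P.shape[0]
    i = np.arange(levels)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mx = float(np.sum(i * px))
    my = float(np.sum(i * py))
    sx = float(np.sqrt(np.sum((i - mx) ** 2 * px)))
    sy = float(np.sqrt(np.sum((i - my) ** 2 * py)))

    p_sum = np.zeros(2 * levels - 1)  # p_{x+y}, k = i+j in [0, 2L-2]
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    p_diff = np.zeros(levels)  # p_{|x-y|}
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())

    ksum = np.arange(2 * levels - 1)
    kdiff = np.arange(levels)
    sum_avg = float(np.sum(ksum * p_sum))
    diff_avg = float(np.sum(kdiff * p_diff))

    HXY = _entropy2(P.ravel())
    HX, HY = _entropy2(px), _entropy2(py)
    pxy = np.outer(px, py)
    mask = (P > 0) & (pxy > 0)
    HXY1 = float(-np.sum(P[mask] * np.log2(pxy[mask])))
    mask2 = pxy > 0
    HXY2 = float(-np.sum(pxy[mask2] * np.log2(pxy[mask2])))

    # Maximal correlation coefficient: sqrt of 2nd-largest eigenvalue of Q.
    active = px > 0
    if active.sum() < 2:
        mcc = 0.0
    else:
        Pa = P[np.ix_(active, active)]
        qx = px[active]
        qy = py[active]
        # Q(i, j) = sum_k P(i, k) P(j, k) / (px(i) py(k))
        Q = (Pa / qx[:, None]) @ (Pa.T / qy[:, None])
        ev = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(ev[-2], 0.0)))

    corr = 0.0 if sx * sy == 0 else float((np.sum(ii * jj * P) - mx * my) / (sx * sy))
    imc1 = 0.0 if max(HX, HY) == 0 else (HXY - HXY1) / max(HX, HY)
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (HXY2 - HXY)), 0.0)))

    return {
        "Angular.Second.Moment": float(np.sum(P**2)),
        "Contrast": float(np.sum((ii - jj) ** 2 * P)),
        "Correlation": corr,
        "Sum.of.Squares.Variance": float(np.sum((ii - mx) ** 2 * P)),
        "Inverse.Difference.Moment": float(np.sum(P / (1.0 + (ii - jj) ** 2))),
        "Sum.Average": sum_avg,
        "Sum.Variance": float(np.sum((ksum - sum_avg) ** 2 * p_sum)),
        "Sum.Entropy": _entropy2(p_sum),
        "Entropy": HXY,
        "Difference.Variance": float(np.sum((kdiff - diff_avg) ** 2 * p_diff)),
        "Difference.Entropy": _entropy2(p_diff),
        "Information.Measure.of.Correlation.1": float(imc1),
        "Information.Measure.of.Correlation.2": imc2,
        "Maximal.Correlation.Coefficient": mcc,
    }


def glcm_features(grid: np.ndarray, distance: int, *, levels: int = 16) -> FeatureVector:
    """Direction-averaged Haralick features at one pixel distance."""
    stats = haralick_from_matrix(glcm_matrix(grid, distance, levels=levels))
    names = tuple(f"{n}_Avg_{distance}" for n in HARALICK_NAMES)
    return FeatureVector(names, tuple(stats[n] for n in HARALICK_NAMES))


# -- Gabor --------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:g}"


def gabor_features(grid: np.ndarray, bank=DEFAULT_GABOR_BANK) -> FeatureVector:
    """Mean and std of Gabor magnitude responses for each (f, b) pair.

    For each pair the complex response is computed at 4 orientations, the
    magnitude images are averaged across orientations, and the mean and
    (population) std of the pooled image are emitted.  A constant window has
    a constant response, hence Std = 0.
    """
    bank = tuple(bank)
    if not bank:
        raise ValueError("empty Gabor bank")
    img = np.asarray(grid, dtype=float)
    names, values = [], []
    for f, b in bank:
        sigma = 1.0 / (2.0 * np.pi * b)
        mags = []
        for theta in _ANGLES:
            re, im = gabor(img, frequency=f, theta=theta, sigma_x=sigma, sigma_y=sigma)
            mags.append(np.hypot(re, im))
        pooled = np.mean(mags, axis=0)
        names += [f"Gabor_Mean_{_fmt(f)}_{_fmt(b)}", f"Gabor_Std_{_fmt(f)}_{_fmt(b)}"]
        values += [pooled.mean(), pooled.std(ddof=0)]
    return FeatureVector(tuple(names), tuple(values))


# -- full stack ---------------------------------------------------------------

def contrast_features(grid_raw: np.ndarray, config: TextureConfig | None = None) -> FeatureVector:
    """All 56 features of one contrast window (raw intensities in)."""
    config = config or TextureConfig()
    norm = normalize_window(grid_raw)
    fo_input = norm if config.first_order_after_mapping else np.asarray(grid_raw, dtype=float)
    parts = [first_order_features(fo_input)]
    for d in config.glcm_distances:
        parts.append(glcm_features(norm, d, levels=config.glcm_levels))
    parts.append(gabor_features(norm, config.gabor_bank))
    names = tuple(n for p in parts for n in p.names)
    values = tuple(v for p in parts for v in p.values)
    return FeatureVector(names, values)


def extract_all(stack: dict, config: TextureConfig | None = None) -> FeatureVector:
    """336-feature vector of a 6-contrast ROI stack.

    ``stack`` maps contrast name to an 8x8 intensity array (raw scale).
    Per contrast: 18 first-order + 14 GLCM@d=1 + 14 GLCM@d=3 + 10 Gabor = 56.
    """
    config = config or TextureConfig()
    missing = [c for c in CONTRASTS if c not in stack]
    if missing:
        raise ValueError(f"missing contrast(s): {', '.join(missing)}")
    names, values = [], []
    for c in CONTRASTS:
        arr = stack[c].intensities if isinstance(stack[c], ROIWindow) else stack[c]
        fv = contrast_features(arr, config)
        names += [f"{c}.{n}" for n in fv.names]
        values += list(fv.values)
    n_per = len(names) // len(CONTRASTS)
    assert len(names) == n_per * len(CONTRASTS), "uneven per-contrast feature counts"
    out = FeatureVector(tuple(names), tuple(values))
    if not all(np.isfinite(v) for v in out.values):
        raise AssertionError("non-finite texture feature")
    return out
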