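"""EGFR copy-number classification and the tail-condensing target transform.

Raw EGFR copy-number scores (log-scale) are heavily right-skewed: wildtype
samples sit in a narrow band below the amplification cutoff of 3.5 while
amplified samples stretch out to values above 80.  Regressing directly on the
raw scale lets a handful of extreme samples dominate the fit, so the
regression target is an order-preserving transform that compresses the
amplified tail until its width roughly matches the wildtype side, while
leaving everything at or below 3.5 untouched.  The cutoff 3.5 is a fixed
point of the transform, so classification thresholds are identical on both
scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Amplification cutoff on the raw (and transformed) copy-number scale.
CNV_THRESHOLD = 3.5

#: Shift inside the log so the transform is finite and increasing just above
#: the cutoff: t(v) = T + w * log(v - (T - 1)) / log(vmax - (T - 1)).
_LOG_SHIFT = CNV_THRESHOLD - 1.0


def classify_cnv(raw: float) -> str:
    """Classify a raw copy-number score as ``"amplified"`` or ``"wildtype"``.

    Amplified iff raw > 3.5; the boundary value 3.5 itself is wildtype.
    """
    raw = float(raw)
    if not np.isfinite(raw):
        raise ValueError(f"non-finite CNV value: {raw!r}")
    return "amplified" if raw > CNV_THRESHOLD else "wildtype"


@dataclass(frozen=True)
class CnvTransform:
    """Fitted order-preserving compression of the amplified tail.

    ``t(v) = v`` for ``v <= 3.5`` and
    ``t(v) = 3.5 + w * log(v - 2.5) / log(vmax - 2.5)`` for ``v > 3.5``,
    where ``w = 3.5 - min(train)`` (the wildtype-side width) and ``vmax`` is
    the training maximum.  At ``v = vmax`` the transformed value is
    ``3.5 + w``, so the amplified group occupies the same width as the
    wildtype group.  Values above the fitted ``vmax`` extrapolate through the
    same formula (no clipping), keeping the map strictly increasing
    everywhere.  The transform degenerates to the identity when the training
    data lack one of the two classes.
    """

    width: float
    vmax: float
    identity: bool = False

    @classmethod
    def fit(cls, values: np.ndarray) -> "CnvTransform":
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("cannot fit CNV transform on empty input")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite CNV values")
        vmin = float(values.min())
        vmax = float(values.max())
        has_wt = bool(np.any(values <= CNV_THRESHOLD))
        has_amp = bool(np.any(values > CNV_THRESHOLD))
        if not (has_wt and has_amp):
            return cls(width=0.0, vmax=vmax, identity=True)
        width = CNV_THRESHOLD - vmin
        if width <= 0:
            # Degenerate wildtype side (single value at the cutoff): fall back
            # to unit width so the map stays strictly increasing.
            width = 1.0
        return cls(width=width, vmax=vmax, identity=False)

    def __call__(self, values) -> np.ndarray:
        values = np.atleast_1d(np.asarray(values, dtype=float))
        if self.identity:
            return values.copy()
        out = values.copy()
        amp = values > CNV_THRESHOLD
        denom = np.log(self.vmax - _LOG_SHIFT)
        # vmax <= 3.5 cannot reach here (identity branch); denom > 0.
        out[amp] = CNV_THRESHOLD + self.width * np.log(values[amp] - _LOG_SHIFT) / denom
        return out

    def inverse_threshold(self) -> float:
        """Transformed-scale location of the 3.5 cutoff.

        3.5 is a fixed point of the transform (log term vanishes there), so
        this always returns 3.5; kept explicit so downstream code never
        hard-codes a second constant.
        """
        return CNV_THRESHOLD

    def to_dict(self) -> dict:
        return {"width": self.width, "vmax": self.vmax, "identity": self.identity}

    @classmethod
    def from_dict(cls, d: dict) -> "CnvTransform":
        return cls(width=float(d["width"]), vmax=float(d["vmax"]), identity=bool(d["identity"]))


def transform_cnv(values) -> np.ndarray:
    """Fit the tail-condensing transform on ``values`` and apply it."""
    values = np.asarray(values, dtype=float)
    return CnvTransform.fit(values)(values)
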