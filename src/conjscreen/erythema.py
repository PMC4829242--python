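"""Erythema index on the 8-bit scaled-log scale.

The erythema index of a pixel is

    EI = log(S_red) - log(S_green)

with both logarithms taken on the classic 8-bit image scale: the log of
a channel is multiplied by ``c = 255 / ln(255) ~ 46.0184`` so that an
input of 255 maps back to 255. On this scale EI = c * ln(R/G), a pure
function of the red/green ratio: redder (better perfused) tissue scores
higher, pallor scores lower. Published anaemia cut-offs (e.g. an EI
below 18.14 for a compact camera, 30.49 for a phone camera) live on
this scale, which is why the constant is fixed here rather than left as
an option.

Zero channels cannot be logged; such pixels (specular burnout or deep
shadow) take the conventional value 0 in the map and are flagged, and
ROI means exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import PolygonROI, RGBImage, SceneAnnotation
from .errors import GeometryError, ValidationError

__all__ = [
    "SCALE_CONSTANT",
    "EIMap",
    "EIMeasurement",
    "scaled_log",
    "ei_map",
    "roi_mean_ei",
    "measure_annotation",
    "classify_anaemia",
    "measurements_to_dataframe",
]

#: c = 255 / ln(255): the 8-bit log rescaling factor.
SCALE_CONSTANT = 255.0 / np.log(255.0)


def _round_half_up(a: np.ndarray) -> np.ndarray:
    return np.floor(a + 0.5)


def scaled_log(plane: np.ndarray, mode: str = "real") -> np.ndarray:
    """Scaled logarithm ``v -> c * ln(v)`` with ``v = 0 -> 0``.

    In ``real`` mode values in (0, 1) map to negative outputs; in
    ``imagej8`` mode the result is clamped to [0, 255] and rounded
    half-up, emulating an 8-bit intermediate.
    """
    v = np.asarray(plane, dtype=float)
    if v.min() < 0 or v.max() > 255:
        raise ValidationError("plane values must lie in [0, 255]")
    out = np.zeros_like(v)
    pos = v > 0
    out[pos] = SCALE_CONSTANT * np.log(v[pos])
    if mode == "imagej8":
        out = _round_half_up(np.clip(out, 0.0, 255.0))
    elif mode != "real":
        raise ValidationError(f"unknown mode {mode!r}")
    return out


@dataclass
class EIMap:
    """Plane of per-pixel erythema-index values plus a mask of pixels
    whose red or green channel was zero (excluded from ROI means)."""

    values: np.ndarray
    flagged: np.ndarray
    mode: str = "real"
    scale_constant: float = SCALE_CONSTANT

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def ei_map(image: RGBImage, mode: str = "real") -> EIMap:
    """Per-pixel EI = scaled_log(red) - scaled_log(green).

    ``imagej8`` mode additionally clamps negative differences at 0, as
    an 8-bit image subtraction does — this silently censors EI < 0 and
    exists only for regression against legacy 8-bit workflows.
    """
    flagged = (image.red == 0) | (image.green == 0)
    values = scaled_log(image.red, mode) - scaled_log(image.green, mode)
    if mode == "imagej8":
        values = np.clip(values, 0.0, 255.0)
    values = np.where(flagged, 0.0, values)
    return EIMap(values=values, flagged=flagged, mode=mode)


def roi_mean_ei(eimap: EIMap, roi: PolygonROI) -> tuple[float, int]:
    """Arithmetic mean EI over the polygon interior (pixel centres,
    even-odd fill), excluding flagged pixels; returns ``(mean, n)``."""
    mask = roi.mask(eimap.shape) & ~eimap.flagged
    n = int(mask.sum())
    if n == 0:
        raise GeometryError(
            f"ROI {roi.label!r} covers no usable pixels of the EI map"
        )
    return float(eimap.values[mask].mean()), n


@dataclass
class EIMeasurement:
    image_id: str
    palpebral_ei: float | None = None
    palpebral_n: int = 0
    forniceal_ei: float | None = None
    forniceal_n: int = 0
    mode: str = "real"


def measure_annotation(
    eimap: EIMap, annotation: SceneAnnotation
) -> EIMeasurement:
    """Mean EI over the palpebral and forniceal ROIs of one scene."""
    m = EIMeasurement(image_id=annotation.image_id, mode=eimap.mode)
    for label in ("palpebral", "forniceal"):
        roi = annotation.get(label)
        if roi is None:
            continue
        mean, n = roi_mean_ei(eimap, roi)
        setattr(m, f"{label}_ei", mean)
        setattr(m, f"{label}_n", n)
    return m


def classify_anaemia(ei, threshold: float):
    """Predict anaemia for EI strictly below the cut-off.

    Accepts a scalar or an array; returns a bool or boolean array.
    """
    arr = np.asarray(ei, dtype=float)
    if not np.all(np.isfinite(arr)) or not np.isfinite(threshold):
        raise ValidationError("EI values and threshold must be finite")
    result = arr < threshold
    return bool(result) if np.isscalar(ei) else result


def measurements_to_dataframe(measurements: list[EIMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "image_id": [m.image_id for m in measurements],
            "palpebral_ei": [m.palpebral_ei for m in measurements],
            "palpebral_n": [m.palpebral_n for m in measurements],
            "forniceal_ei": [m.forniceal_ei for m in measurements],
            "forniceal_n": [m.forniceal_n for m in measurements],
            "mode": [m.mode for m in measurements],
        }
    )
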