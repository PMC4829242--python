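"""Core data types: images, polygon ROIs, scene annotations, cohorts.

An :class:`RGBImage` keeps each channel as a real-valued plane in
[0, 255] so that calibration gains can be applied without premature
8-bit quantisation; file I/O (see :mod:`conjscreen.io`) quantises on
write. Anaemia is defined throughout as haemoglobin < 110 g/L (strict),
and a participant is eligible when photography and venous sampling are
at most 36 hours apart (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError
from .geometry import check_simple_polygon, polygon_mask

__all__ = [
    "ANAEMIA_CUTOFF_G_PER_L",
    "ELIGIBILITY_WINDOW_HOURS",
    "ROI_LABELS",
    "RGBImage",
    "PolygonROI",
    "SceneAnnotation",
    "ParticipantRecord",
    "CohortTable",
]

ANAEMIA_CUTOFF_G_PER_L = 110.0
ELIGIBILITY_WINDOW_HOURS = 36.0
ROI_LABELS = ("white_patch", "palpebral", "forniceal", "other")


@dataclass
class RGBImage:
    """Three equal-shape brightness planes with values in [0, 255]."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        planes = []
        for name in ("red", "green", "blue"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.ndim != 2:
                raise ValidationError(f"{name} plane must be 2-D")
            planes.append(p)
            setattr(self, name, p)
        if not (planes[0].shape == planes[1].shape == planes[2].shape):
            raise ValidationError("channel planes must share dimensions")
        h, w = planes[0].shape
        if h < 1 or w < 1:
            raise ValidationError("image must be at least 1x1")
        stacked = np.stack(planes)
        if not np.all(np.isfinite(stacked)):
            raise ValidationError("pixel values must be finite")
        if stacked.min() < 0 or stacked.max() > 255:
            raise ValidationError("pixel values must lie in [0, 255]")

    @property
    def height(self) -> int:
        return self.red.shape[0]

    @property
    def width(self) -> int:
        return self.red.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    def stack(self) -> np.ndarray:
        """Return an ``(h, w, 3)`` array (R, G, B last axis)."""
        return np.stack([self.red, self.green, self.blue], axis=-1)

    @classmethod
    def from_array(cls, arr: np.ndarray, id: str = "") -> "RGBImage":
        a = np.asarray(arr, dtype=float)
        if a.ndim != 3 or a.shape[2] != 3:
            raise ValidationError("expected an (h, w, 3) array")
        return cls(a[..., 0], a[..., 1], a[..., 2], id=id)


@dataclass
class PolygonROI:
    """A labelled simple polygon in pixel coordinates (x = column,
    y = row, 0-based)."""

    label: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise ValidationError(
                f"unknown ROI label {self.label!r}; expected one of {ROI_LABELS}"
            )
        v = np.asarray(self.vertices, dtype=float)
        check_simple_polygon(v)
        self.vertices = v

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        return polygon_mask(self.vertices, shape)

    def pixel_count(self, shape: tuple[int, int]) -> int:
        return int(self.mask(shape).sum())

    def check_within(self, height: int, width: int) -> None:
        """Raise :class:`GeometryError` if any vertex falls outside the
        image bounds."""
        v = self.vertices
        if (v[:, 0] < 0).any() or (v[:, 0] > width - 1).any() or \
                (v[:, 1] < 0).any() or (v[:, 1] > height - 1).any():
            raise GeometryError(
                f"ROI {self.label!r} has vertices outside the {height}x{width} image"
            )


@dataclass
class SceneAnnotation:
    """All ROIs for one image: exactly one white patch, at most one
    palpebral and one forniceal conjunctiva."""

    image_id: str
    rois: list[PolygonROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for roi in self.rois:
            counts[roi.label] = counts.get(roi.label, 0) + 1
        if counts.get("white_patch", 0) != 1:
            raise ValidationError(
                f"annotation {self.image_id!r}: exactly one white_patch ROI required"
            )
        for label in ("palpebral", "forniceal"):
            if counts.get(label, 0) > 1:
                raise ValidationError(
                    f"annotation {self.image_id!r}: duplicate {label!r} ROI"
                )

    def get(self, label: str) -> PolygonROI | None:
        for roi in self.rois:
            if roi.label == label:
                return roi
        return None

    @property
    def white_patch(self) -> PolygonROI:
        roi = self.get("white_patch")
        assert roi is not None  # guaranteed by __post_init__
        return roi

    @property
    def palpebral(self) -> PolygonROI | None:
        return self.get("palpebral")

    @property
    def forniceal(self) -> PolygonROI | None:
        return self.get("forniceal")


@dataclass
class ParticipantRecord:
    """One study participant: laboratory haemoglobin plus the timestamps
    used for the 36-hour eligibility window."""

    id: str
    haemoglobin: float
    photo_time: datetime
    blood_time: datetime

    def __post_init__(self) -> None:
        self.haemoglobin = float(self.haemoglobin)
        if not np.isfinite(self.haemoglobin) or self.haemoglobin <= 0:
            raise ValidationError(
                f"participant {self.id!r}: haemoglobin must be a positive number"
            )
        for name in ("photo_time", "blood_time"):
            t = getattr(self, name)
            if isinstance(t, str):
                setattr(self, name, datetime.fromisoformat(t))
            elif isinstance(t, pd.Timestamp):
                setattr(self, name, t.to_pydatetime())
            elif not isinstance(t, datetime):
                raise ValidationError(
                    f"participant {self.id!r}: {name} must be a timestamp"
                )

    @property
    def delay_hours(self) -> float:
        """Absolute photo-to-blood delay in hours."""
        return abs((self.photo_time - self.blood_time).total_seconds()) / 3600.0

    @property
    def anaemic(self) -> bool:
        """Haemoglobin strictly below 110 g/L."""
        return self.is_anaemic()

    def is_anaemic(self, cutoff: float = ANAEMIA_CUTOFF_G_PER_L) -> bool:
        return self.haemoglobin < cutoff

    @property
    def eligible(self) -> bool:
        """Photography within 36 hours (inclusive) of blood sampling."""
        return self.delay_hours <= ELIGIBILITY_WINDOW_HOURS


@dataclass
class CohortTable:
    records: list[ParticipantRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("cohort table must be non-empty")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate participant ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self) -> dict[str, ParticipantRecord]:
        return {r.id: r for r in self.records}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "haemoglobin_g_per_L": [r.haemoglobin for r in self.records],
                "photo_time": [r.photo_time for r in self.records],
                "blood_time": [r.blood_time for r in self.records],
                "anaemic": [r.anaemic for r in self.records],
                "eligible": [r.eligible for r in self.records],
                "delay_hours": [r.delay_hours for r in self.records],
            }
        )
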