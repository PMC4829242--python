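"""Readers and writers: 8-bit RGB images, ROI JSON, cohort CSV.

Images are accepted as already-demosaiced 8-bit rasters (PNG/TIFF
lossless, JPEG accepted since phone cameras emit it); camera raw decode
is out of scope. The ROI dialect is a single JSON document::

    {"images": [{"image_id": "...",
                 "rois": [{"label": "white_patch",
                           "vertices": [[x, y], ...]}, ...]}]}

Cohort CSVs carry ``id, haemoglobin_g_per_L, photo_time, blood_time``
with ISO-8601 timestamps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .data_model import CohortTable, ParticipantRecord, PolygonROI, RGBImage, SceneAnnotation
from .errors import FormatError, RangeError, UnsupportedDepthError, ValidationError

__all__ = [
    "read_image",
    "write_image",
    "read_annotations",
    "write_annotations",
    "read_cohort",
    "write_cohort",
]

COHORT_COLUMNS = ("id", "haemoglobin_g_per_L", "photo_time", "blood_time")


def read_image(path: str | Path) -> RGBImage:
    """Load an 8-bit RGB raster; alpha is discarded, anything deeper or
    grayscale raises :class:`UnsupportedDepthError`."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            mode = im.mode
            if mode in ("RGB", "RGBA"):
                arr = np.asarray(im.convert("RGB"), dtype=float)
            elif mode == "P":
                arr = np.asarray(im.convert("RGB"), dtype=float)
            else:
                raise UnsupportedDepthError(
                    f"{path.name}: mode {mode!r} is not 8-bit RGB"
                )
    except UnidentifiedImageError as exc:
        raise FormatError(f"{path.name}: not a decodable image") from exc
    return RGBImage(arr[..., 0], arr[..., 1], arr[..., 2], id=path.stem)


def _round_half_up(a: np.ndarray) -> np.ndarray:
    return np.floor(a + 0.5)


def write_image(
    image: RGBImage,
    path: str | Path,
    quantise: bool = True,
    allow_lossy: bool = False,
) -> None:
    """Write an image as 8-bit PNG/TIFF (lossless) or JPEG.

    With ``quantise`` values are rounded half-up to integers first;
    otherwise the planes must already be integral. JPEG requires
    ``allow_lossy=True`` since it does not round-trip.
    """
    path = Path(path)
    arr = image.stack()
    if quantise:
        arr = _round_half_up(arr)
    elif not np.array_equal(arr, np.round(arr)):
        raise ValidationError(
            "non-integer pixel values: pass quantise=True to round on write"
        )
    if arr.min() < 0 or arr.max() > 255:
        raise RangeError("pixel values outside [0, 255] after rounding")
    suffix = path.suffix.lower()
    if suffix in (".jpg", ".jpeg") and not allow_lossy:
        raise ValidationError(
            "JPEG is lossy; pass allow_lossy=True to write it anyway"
        )
    Image.fromarray(arr.astype(np.uint8), mode="RGB").save(path)


def read_annotations(path: str | Path) -> list[SceneAnnotation]:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path.name}: invalid JSON") from exc
    if not isinstance(doc, dict) or "images" not in doc:
        raise FormatError(f"{path.name}: expected a top-level 'images' list")
    annotations = []
    for entry in doc["images"]:
        image_id = entry.get("image_id", "")
        rois = [
            PolygonROI(label=r["label"], vertices=np.asarray(r["vertices"], dtype=float))
            for r in entry.get("rois", [])
        ]
        annotations.append(SceneAnnotation(image_id=image_id, rois=rois))
    return annotations


def write_annotations(annotations: list[SceneAnnotation], path: str | Path) -> None:
    doc = {
        "images": [
            {
                "image_id": a.image_id,
                "rois": [
                    {"label": r.label, "vertices": np.asarray(r.vertices).tolist()}
                    for r in a.rois
                ],
            }
            for a in annotations
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_cohort(path: str | Path) -> CohortTable:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    hb = pd.to_numeric(df["haemoglobin_g_per_L"], errors="coerce")
    if hb.isna().any():
        bad = df.loc[hb.isna(), "id"].tolist()
        raise FormatError(f"{path.name}: non-numeric haemoglobin for ids {bad}")
    records = []
    for _, row in df.iterrows():
        try:
            photo = pd.Timestamp(row["photo_time"]).to_pydatetime()
            blood = pd.Timestamp(row["blood_time"]).to_pydatetime()
        except (ValueError, TypeError) as exc:
            raise FormatError(
                f"{path.name}: bad timestamp for id {row['id']!r}"
            ) from exc
        records.append(
            ParticipantRecord(
                id=str(row["id"]),
                haemoglobin=float(row["haemoglobin_g_per_L"]),
                photo_time=photo,
                blood_time=blood,
            )
        )
    return CohortTable(records)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in cohort],
            "haemoglobin_g_per_L": [r.haemoglobin for r in cohort],
            "photo_time": [r.photo_time.isoformat() for r in cohort],
            "blood_time": [r.blood_time.isoformat() for r in cohort],
        }
    )
    df.to_csv(path, index=False)
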