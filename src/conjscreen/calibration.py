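"""White-balance standardisation against the in-frame card, plus
automated image quality control.

Standardisation scales each channel by ``200 / M_B``, where ``M_B`` is
the mean brightness of the calibration card's white square in that
channel, so that after scaling the white square averages 200 brightness
units regardless of the lighting cast. Per-channel gains (true white
balance) are the default; a ``global`` mode with a single scalar ``M_B``
averaged over channels is provided for comparison, but a single scalar
cannot remove a colour cast.

Two numeric modes run through the whole pipeline:

``real``
    keep full floating precision after scaling (default);
``imagej8``
    round half-up to integers after scaling, emulating an 8-bit
    intermediate as produced by classic 8-bit image-calculator
    workflows. Published erythema-index cut-offs were derived under
    8-bit intermediates, so both behaviours are exposed and labelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data_model import PolygonROI, RGBImage, SceneAnnotation
from .errors import DegenerateCardError, GeometryError, ValidationError

__all__ = [
    "TARGET_WHITE",
    "MIN_WHITE_PIXELS",
    "CalibrationResult",
    "QCConfig",
    "QCReport",
    "white_patch_means",
    "standardise",
    "calibrate",
    "qc_assess",
]

#: Post-standardisation brightness of the card's white square.
TARGET_WHITE = 200.0
#: Minimum pixel support required for a trustworthy white-patch mean.
MIN_WHITE_PIXELS = 25


@dataclass
class CalibrationResult:
    """Per-channel white means ``M_B``, the gains ``200/M_B`` and the
    fraction of pixels clamped at 255 after scaling."""

    white_means: np.ndarray
    gains: np.ndarray
    clipped_fraction: float


def white_patch_means(
    image: RGBImage,
    white_roi: PolygonROI,
    channel_mode: str = "per_channel",
) -> np.ndarray:
    """Mean brightness of the white square per channel (length-3 array).

    ``channel_mode='global'`` replaces all three means with their common
    average (a single scalar ``M_B``).
    """
    mask = white_roi.mask(image.shape)
    n = int(mask.sum())
    if n == 0:
        raise GeometryError("white patch ROI covers no pixels of the image")
    if n < MIN_WHITE_PIXELS:
        raise GeometryError(
            f"white patch ROI covers only {n} pixels (< {MIN_WHITE_PIXELS})"
        )
    means = np.array(
        [image.red[mask].mean(), image.green[mask].mean(), image.blue[mask].mean()]
    )
    if channel_mode == "global":
        means = np.full(3, means.mean())
    elif channel_mode != "per_channel":
        raise ValidationError(f"unknown channel_mode {channel_mode!r}")
    if np.any(means <= 0):
        raise DegenerateCardError("white patch has a zero channel mean")
    return means


def _round_half_up(a: np.ndarray) -> np.ndarray:
    return np.floor(a + 0.5)


def standardise(
    image: RGBImage, means: np.ndarray, mode: str = "real"
) -> RGBImage:
    """Scale each channel by ``200/means[c]`` and clamp to [0, 255]."""
    out, _ = _standardise_planes(image, means, mode)
    return out


def calibrate(
    image: RGBImage,
    white_roi: PolygonROI,
    mode: str = "real",
    channel_mode: str = "per_channel",
) -> tuple[RGBImage, CalibrationResult]:
    """``white_patch_means`` + ``standardise`` in one step, reporting
    the gains and the clipped pixel fraction."""
    means = white_patch_means(image, white_roi, channel_mode=channel_mode)
    out, clipped = _standardise_planes(image, means, mode)
    return out, CalibrationResult(
        white_means=means, gains=TARGET_WHITE / means, clipped_fraction=clipped
    )


def _standardise_planes(
    image: RGBImage, means: np.ndarray, mode: str
) -> tuple[RGBImage, float]:
    means = np.asarray(means, dtype=float)
    if means.shape != (3,):
        raise ValidationError("means must be a length-3 per-channel array")
    if np.any(means <= 0):
        raise DegenerateCardError("channel means must be positive")
    if mode not in ("real", "imagej8"):
        raise ValidationError(f"unknown mode {mode!r}")
    gains = TARGET_WHITE / means
    planes = []
    n_clipped = 0
    for plane, gain in zip((image.red, image.green, image.blue), gains):
        scaled = plane * gain
        n_clipped += int((scaled > 255).sum())
        scaled = np.clip(scaled, 0.0, 255.0)
        if mode == "imagej8":
            scaled = _round_half_up(scaled)
        planes.append(scaled)
    clipped = n_clipped / (3 * image.height * image.width)
    return RGBImage(*planes, id=image.id), clipped


# ---------------------------------------------------------------------------
# Quality control

@dataclass
class QCConfig:
    """Thresholds operationalising the visual image-selection criteria:
    both card and conjunctiva in focus, adequate conjunctiva exposed,
    no bright specular reflections, no lighting difference between card
    and conjunctiva."""

    #: minimum variance of the Laplacian of the green channel (focus proxy)
    focus_min: float = 10.0
    #: max tolerated fraction of near-saturated conjunctival pixels
    specular_max: float = 0.01
    #: acceptable card-ring / conjunctiva-ring brightness ratio
    ratio_lo: float = 0.8
    ratio_hi: float = 1.25
    #: minimum conjunctival ROI area in pixels
    min_area: int = 200
    #: width (in dilation steps) of the sampling rings
    ring_width: int = 4


@dataclass
class QCReport:
    focus_ok: bool
    conjunctiva_exposed_ok: bool
    no_specular_ok: bool
    lighting_uniform_ok: bool
    metrics: dict[str, float] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return (
            self.focus_ok
            and self.conjunctiva_exposed_ok
            and self.no_specular_ok
            and self.lighting_uniform_ok
        )

    def failing_flags(self) -> list[str]:
        return [
            name
            for name, ok in [
                ("focus", self.focus_ok),
                ("conjunctiva_exposed", self.conjunctiva_exposed_ok),
                ("specular", self.no_specular_ok),
                ("lighting_uniform", self.lighting_uniform_ok),
            ]
            if not ok
        ]


def _ring(mask: np.ndarray, width: int) -> np.ndarray:
    dilated = ndimage.binary_dilation(mask, iterations=width)
    return dilated & ~mask


def qc_assess(
    image: RGBImage,
    annotation: SceneAnnotation,
    config: QCConfig | None = None,
) -> QCReport:
    """Automated stand-in for the visual pre-analysis checks.

    Degenerate inputs produce failing flags, never exceptions, so a bad
    image is excluded rather than aborting a batch run.
    """
    cfg = config or QCConfig()
    shape = image.shape

    lap = ndimage.laplace(image.green)
    focus_metric = float(lap.var())
    focus_ok = focus_metric >= cfg.focus_min

    conj_masks = []
    areas = {}
    for label in ("palpebral", "forniceal"):
        roi = annotation.get(label)
        if roi is not None:
            m = roi.mask(shape)
            conj_masks.append(m)
            areas[label] = int(m.sum())
        else:
            areas[label] = 0
    conjunctiva_exposed_ok = (
        areas["palpebral"] >= cfg.min_area and areas["forniceal"] >= cfg.min_area
    )

    if conj_masks:
        union = np.logical_or.reduce(conj_masks)
    else:
        union = np.zeros(shape, dtype=bool)
    if union.any():
        saturated = (
            (image.red >= 250) & (image.green >= 250) & (image.blue >= 250)
        )
        specular_fraction = float(saturated[union].mean())
    else:
        specular_fraction = 0.0
    no_specular_ok = specular_fraction <= cfg.specular_max

    brightness = (image.red + image.green + image.blue) / 3.0
    card_ring = _ring(annotation.white_patch.mask(shape), cfg.ring_width)
    lighting_ratio = float("nan")
    lighting_uniform_ok = False
    if union.any() and card_ring.any():
        conj_ring = _ring(union, cfg.ring_width)
        if conj_ring.any():
            conj_mean = float(brightness[conj_ring].mean())
            card_mean = float(brightness[card_ring].mean())
            if conj_mean > 0:
                lighting_ratio = card_mean / conj_mean
                lighting_uniform_ok = cfg.ratio_lo <= lighting_ratio <= cfg.ratio_hi

    return QCReport(
        focus_ok=focus_ok,
        conjunctiva_exposed_ok=conjunctiva_exposed_ok,
        no_specular_ok=no_specular_ok,
        lighting_uniform_ok=lighting_uniform_ok,
        metrics={
            "focus_variance_of_laplacian": focus_metric,
            "specular_fraction": specular_fraction,
            "lighting_ratio": lighting_ratio,
            "palpebral_area": float(areas["palpebral"]),
            "forniceal_area": float(areas["forniceal"]),
        },
    )
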