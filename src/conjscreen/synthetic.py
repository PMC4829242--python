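"""Synthetic conjunctival scenes and cohorts.

The generator produces the statistical structure the analysis assumes
rather than photorealistic eyes: a scene is a flat canvas holding a
calibration card (grey border + white square at reflectance 200) and
two conjunctival patches whose red/green ratio encodes a target
erythema index. Conjunctival colour is specified directly in EI space —
``red = green_base * exp(EI*/c)`` — so the ground truth is exact by
construction, and the palpebral EI target is a linear function of
haemoglobin::

    EI*(Hb) = alpha + beta * Hb            (palpebral)
    EI*(Hb) = alpha + beta * Hb + offset   (forniceal, offset < 0)

Default slope beta = 0.092 EI units per g/L (the regression slope
observed on real compact-camera photographs) and alpha = 8.02, chosen
so that EI*(110 g/L) = 18.14 — the published screening cut-off sits
exactly at the anaemia boundary. The forniceal offset (-6 EI) encodes
that the fornix is paler than the palpebral surface; its magnitude is
a plausible invention, as only the direction is established.

On top of the clean colour model the generator applies, in order:
per-channel multiplicative lighting gains (colour casts), additive
Gaussian sensor noise, clamping to [0, 255] and 8-bit quantisation.
Cohort simulation draws haemoglobin from a truncated normal
(113 +/- 21 g/L by default, matching the study cohort; about 44% fall
below 110 g/L) and adds a per-participant EI scatter representing
everything the Hb -> colour model does not capture (default sd 3.2 EI,
calibrated analytically so a regression of measured EI on Hb explains
roughly 27% of the variance, as on real photographs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
from scipy import ndimage, stats

from .data_model import CohortTable, ParticipantRecord, PolygonROI, RGBImage, SceneAnnotation
from .erythema import SCALE_CONSTANT
from .errors import GeometryError, RangeError, ValidationError

__all__ = [
    "LIGHTING_PRESETS",
    "ColourModel",
    "SceneLayout",
    "SceneParams",
    "CohortSimConfig",
    "SimulatedScene",
    "CohortSim",
    "hb_to_true_ei",
    "render_scene",
    "simulate_cohort",
    "simulate_repeatability",
    "add_specular",
    "add_shadow",
    "blur_image",
]

#: Per-channel (R, G, B) gain presets for the three ambient conditions.
LIGHTING_PRESETS: dict[str, tuple[float, float, float]] = {
    "fluorescent": (0.95, 1.05, 1.10),
    "incandescent": (1.25, 1.00, 0.75),
    "daylight": (1.00, 1.00, 1.00),
}


@dataclass
class ColourModel:
    """Linear haemoglobin -> erythema-index colour model."""

    alpha: float = 8.02          # EI units; EI*(110) = 18.14 by construction
    beta: float = 0.092          # EI units per g/L
    forniceal_offset: float = -6.0
    green_base: float = 110.0    # green reflectance of conjunctiva (8-bit units)
    hb_range: tuple[float, float] = (50.0, 180.0)

    def __post_init__(self) -> None:
        if self.beta <= 0 and self.beta != 0.0:
            raise ValidationError("beta must be non-negative")
        if self.forniceal_offset > 0:
            raise ValidationError("forniceal_offset must be <= 0")


def hb_to_true_ei(hb: float, model: ColourModel, portion: str = "palpebral") -> float:
    """Deterministic EI target for a haemoglobin value."""
    lo, hi = model.hb_range
    if not lo <= hb <= hi:
        raise RangeError(f"haemoglobin {hb} g/L outside model range [{lo}, {hi}]")
    ei = model.alpha + model.beta * hb
    if portion == "forniceal":
        ei += model.forniceal_offset
    elif portion != "palpebral":
        raise ValidationError(f"unknown portion {portion!r}")
    return float(ei)


def _rect(x0: float, y0: float, x1: float, y1: float) -> np.ndarray:
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


@dataclass
class SceneLayout:
    """Polygon geometry of a synthetic scene on an h x w canvas.

    The card border reflectance (155) is matched to the mean skin
    reflectance so the QC lighting-uniformity ratio sits near 1 under
    uniform lighting.
    """

    height: int = 80
    width: int = 120
    card: np.ndarray = field(default_factory=lambda: _rect(8, 8, 40, 40))
    white_patch: np.ndarray = field(default_factory=lambda: _rect(14, 14, 32, 32))
    palpebral: np.ndarray = field(
        default_factory=lambda: np.array(
            [[60, 20], [100, 20], [104, 27], [100, 35], [60, 35]], dtype=float
        )
    )
    forniceal: np.ndarray = field(default_factory=lambda: _rect(60, 44, 100, 56))
    skin_reflectance: tuple[float, float, float] = (185.0, 150.0, 135.0)
    card_reflectance: tuple[float, float, float] = (155.0, 155.0, 155.0)
    white_reflectance: tuple[float, float, float] = (200.0, 200.0, 200.0)

    def validate(self) -> None:
        h, w = self.height, self.width
        for name in ("card", "white_patch", "palpebral", "forniceal"):
            v = getattr(self, name)
            if (v[:, 0] < 0).any() or (v[:, 0] > w - 1).any() or \
                    (v[:, 1] < 0).any() or (v[:, 1] > h - 1).any():
                raise GeometryError(f"layout polygon {name!r} outside the canvas")


@dataclass
class SceneParams:
    """Everything needed to render one photograph deterministically."""

    haemoglobin: float
    lighting_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 2.0
    seed: int = 0
    ei_offset: float = 0.0   # per-image/participant EI deviation from the model
    layout: SceneLayout = field(default_factory=SceneLayout)
    image_id: str = "scene"

    def __post_init__(self) -> None:
        if min(self.lighting_gains) <= 0:
            raise ValidationError("lighting gains must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def _round_half_up(a: np.ndarray) -> np.ndarray:
    return np.floor(a + 0.5)


def render_scene(
    params: SceneParams, model: ColourModel | None = None
) -> tuple[RGBImage, SceneAnnotation]:
    """Render one scene; identical (params, model) gives identical output."""
    model = model or ColourModel()
    layout = params.layout
    layout.validate()
    h, w = layout.height, layout.width
    shape = (h, w)

    planes = [np.full(shape, r) for r in layout.skin_reflectance]
    masks = {
        name: PolygonROI(label="other", vertices=getattr(layout, name)).mask(shape)
        for name in ("card", "white_patch", "palpebral", "forniceal")
    }
    for c in range(3):
        planes[c][masks["card"]] = layout.card_reflectance[c]
        planes[c][masks["white_patch"]] = layout.white_reflectance[c]

    for portion in ("palpebral", "forniceal"):
        ei = hb_to_true_ei(params.haemoglobin, model, portion) + params.ei_offset
        green = model.green_base
        red = green * np.exp(ei / SCALE_CONSTANT)
        blue = 0.75 * green
        if red > 255 or red < 0:
            raise RangeError(
                f"{portion} red reflectance {red:.1f} outside [0, 255]; "
                "lower green_base or restrict the Hb range"
            )
        planes[0][masks[portion]] = red
        planes[1][masks[portion]] = green
        planes[2][masks[portion]] = blue

    rng = np.random.default_rng(params.seed)
    out = []
    for c in range(3):
        p = planes[c] * params.lighting_gains[c]
        if params.noise_sd > 0:
            p = p + rng.normal(0.0, params.noise_sd, size=shape)
        out.append(_round_half_up(np.clip(p, 0.0, 255.0)))

    image = RGBImage(*out, id=params.image_id)
    annotation = SceneAnnotation(
        image_id=params.image_id,
        rois=[
            PolygonROI("white_patch", layout.white_patch),
            PolygonROI("palpebral", layout.palpebral),
            PolygonROI("forniceal", layout.forniceal),
        ],
    )
    return image, annotation


# ---------------------------------------------------------------------------
# Artefact injectors (used by QC tests and the exclusion pathway)

def add_specular(
    image: RGBImage, roi: PolygonROI, fraction: float, seed: int = 0
) -> RGBImage:
    """Paint saturated (255,255,255) glints over a fraction of an ROI."""
    mask = roi.mask(image.shape)
    idx = np.flatnonzero(mask.ravel())
    rng = np.random.default_rng(seed)
    n = int(round(fraction * idx.size))
    chosen = rng.choice(idx, size=n, replace=False)
    planes = []
    for plane in (image.red, image.green, image.blue):
        p = plane.copy().ravel()
        p[chosen] = 255.0
        planes.append(p.reshape(image.shape))
    return RGBImage(*planes, id=image.id)


def add_shadow(image: RGBImage, factor: float = 0.6, x_split: int | None = None) -> RGBImage:
    """Darken the left part of the frame (covering the card) by a
    multiplicative factor, emulating uneven lighting."""
    split = x_split if x_split is not None else image.width // 2
    planes = []
    for plane in (image.red, image.green, image.blue):
        p = plane.copy()
        p[:, :split] *= factor
        planes.append(p)
    return RGBImage(*planes, id=image.id)


def blur_image(image: RGBImage, sigma: float = 2.0) -> RGBImage:
    """Gaussian blur, emulating an out-of-focus photograph."""
    planes = [
        ndimage.gaussian_filter(p, sigma=sigma)
        for p in (image.red, image.green, image.blue)
    ]
    return RGBImage(*planes, id=image.id)


# ---------------------------------------------------------------------------
# Cohort simulation

@dataclass
class CohortSimConfig:
    n: int = 94
    hb_mean: float = 113.0
    hb_sd: float = 21.0
    hb_range: tuple[float, float] = (50.0, 180.0)
    lighting_mix: dict[str, float] | None = None   # None = uniform over presets
    noise_sd: float = 2.0
    ei_scatter_sd: float = 3.2
    match_prevalence: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.hb_sd <= 0:
            raise ValidationError("hb_sd must be > 0")


@dataclass
class SimulatedScene:
    participant_id: str
    image: RGBImage | None
    annotation: SceneAnnotation | None
    true_ei_palpebral: float
    true_ei_forniceal: float
    lighting: str


@dataclass
class CohortSim:
    cohort: CohortTable
    scenes: list[SimulatedScene]
    model: ColourModel
    config: CohortSimConfig


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_delays(rng, n):
    """Photo-to-blood delay (hours): mixture matching the study's
    subgroup sizes (~44% within 4 h, ~43% beyond 12 h, rest between)."""
    kind = rng.choice(3, size=n, p=[0.436, 0.138, 0.426])
    delay = np.empty(n)
    delay[kind == 0] = rng.uniform(0.0, 4.0, size=(kind == 0).sum())
    delay[kind == 1] = rng.uniform(4.0, 12.0, size=(kind == 1).sum())
    delay[kind == 2] = rng.uniform(12.0, 31.0, size=(kind == 2).sum())
    return delay


def simulate_cohort(
    config: CohortSimConfig | None = None,
    model: ColourModel | None = None,
    render_scenes: bool = True,
) -> CohortSim:
    """Draw a cohort and (optionally) render one scene per participant.

    With ``match_prevalence`` set, exactly ``round(p * n)`` participants
    are drawn from the anaemic side of the truncated normal, pinning the
    anaemic fraction (e.g. the study's 40%) instead of leaving it to the
    distribution (~44% below 110 g/L under the defaults).
    """
    config = config or CohortSimConfig()
    model = model or ColourModel()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.hb_range

    if config.match_prevalence is None:
        hbs = _truncnorm(rng, config.hb_mean, config.hb_sd, lo, hi, config.n)
    else:
        n_anaemic = int(round(config.match_prevalence * config.n))
        hbs = np.concatenate(
            [
                _truncnorm(rng, config.hb_mean, config.hb_sd, lo, 110.0 - 1e-9, n_anaemic),
                _truncnorm(rng, config.hb_mean, config.hb_sd, 110.0, hi, config.n - n_anaemic),
            ]
        )
        rng.shuffle(hbs)

    preset_names = sorted(LIGHTING_PRESETS)
    if config.lighting_mix is None:
        probs = np.full(len(preset_names), 1.0 / len(preset_names))
    else:
        probs = np.array([config.lighting_mix.get(k, 0.0) for k in preset_names])
        probs = probs / probs.sum()

    base_time = datetime(2026, 1, 5, 9, 0)
    delays = _draw_delays(rng, config.n)
    signs = rng.choice([-1.0, 1.0], size=config.n)

    records, scenes = [], []
    for i in range(config.n):
        pid = f"P{i + 1:04d}"
        hb = float(hbs[i])
        offset = float(rng.normal(0.0, config.ei_scatter_sd)) if config.ei_scatter_sd > 0 else 0.0
        lighting = preset_names[int(rng.choice(len(preset_names), p=probs))]
        scene_seed = int(rng.integers(0, 2**31 - 1))
        photo = base_time + timedelta(minutes=17 * i)
        blood = photo + timedelta(hours=float(signs[i] * delays[i]))
        records.append(
            ParticipantRecord(id=pid, haemoglobin=hb, photo_time=photo, blood_time=blood)
        )
        image = annotation = None
        if render_scenes:
            params = SceneParams(
                haemoglobin=hb,
                lighting_gains=LIGHTING_PRESETS[lighting],
                noise_sd=config.noise_sd,
                seed=scene_seed,
                ei_offset=offset,
                image_id=f"{pid}_1",
            )
            image, annotation = render_scene(params, model)
        scenes.append(
            SimulatedScene(
                participant_id=pid,
                image=image,
                annotation=annotation,
                true_ei_palpebral=hb_to_true_ei(hb, model, "palpebral") + offset,
                true_ei_forniceal=hb_to_true_ei(hb, model, "forniceal") + offset,
                lighting=lighting,
            )
        )
    return CohortSim(
        cohort=CohortTable(records), scenes=scenes, model=model, config=config
    )


def simulate_repeatability(
    n_subjects: int = 3,
    n_images_per_condition: int = 5,
    conditions: tuple[str, ...] = ("fluorescent", "incandescent", "daylight"),
    noise_sd: float = 2.0,
    ei_jitter_sd: float = 0.5,
    seed: int = 0,
    model: ColourModel | None = None,
    subject_hbs: tuple[float, ...] | None = None,
):
    """Repeat-photography experiment: n healthy subjects, several images
    each under each lighting condition.

    ``ei_jitter_sd`` is a per-image EI deviation capturing pose and
    exposure variation between repeat photographs — the dominant source
    of photo-to-photo variability; pixel noise alone averages away over
    the ROI. Returns a DataFrame with per-image mean palpebral EI both
    before (``ei_raw``) and after (``ei_std``) standardisation.
    """
    import pandas as pd

    from .calibration import calibrate
    from .erythema import ei_map, roi_mean_ei

    model = model or ColourModel()
    if subject_hbs is None:
        subject_hbs = tuple(125.0 + 10.0 * i for i in range(n_subjects))
    if len(subject_hbs) != n_subjects:
        raise ValidationError("need one haemoglobin value per subject")
    for c in conditions:
        if c not in LIGHTING_PRESETS:
            raise ValidationError(f"unknown lighting condition {c!r}")
    if n_subjects < 1 or n_images_per_condition < 1 or not conditions:
        raise ValidationError("all counts must be >= 1")

    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for cond in conditions:
            for rep in range(n_images_per_condition):
                jitter = float(rng.normal(0.0, ei_jitter_sd)) if ei_jitter_sd > 0 else 0.0
                params = SceneParams(
                    haemoglobin=subject_hbs[s],
                    lighting_gains=LIGHTING_PRESETS[cond],
                    noise_sd=noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    ei_offset=jitter,
                    image_id=f"S{s + 1}_{cond}_{rep + 1}",
                )
                image, annotation = render_scene(params, model)
                raw_ei, _ = roi_mean_ei(ei_map(image), annotation.palpebral)
                std_image, _ = calibrate(image, annotation.white_patch)
                std_ei, _ = roi_mean_ei(ei_map(std_image), annotation.palpebral)
                rows.append(
                    {
                        "subject": f"S{s + 1}",
                        "condition": cond,
                        "replicate": rep + 1,
                        "ei_raw": raw_ei,
                        "ei_std": std_ei,
                    }
                )
    return pd.DataFrame(rows)
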