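"""Synthetic colony images and fermentation time courses with known truth.

Every downstream stage — binarization, core extraction, kinetic fitting —
is validated against data whose ground truth is known by construction:

* colony images rendered as a bright central disk (the pellet core) plus
  thin radial filaments on a dark background, with the exact pixel-count
  areas returned alongside the image;
* time courses sampled from the closed-form logistic and Luedeking-Piret
  solutions with additive Gaussian observation noise.

The three rendered macro-morphologies mirror what M. alpina shows in
submerged culture: hollow pellets (a large surface-compacted core, drawn
as a filled disk with a brighter rim — a 2-D projection cannot depict
interior hollowness, so "hollow" is a class label here, not a geometry),
fluffy pellets (core plus radial filaments), and dispersed mycelia
(filaments only, no core).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import draw, morphology

from .kinetics import (
    LogisticParams,
    LuedekingPiretParams,
    TimeCourse,
    biomass,
    lipid,
)
from .morphometrics import ColonyImage

__all__ = [
    "ImageSpec",
    "GroundTruth",
    "TimeCourseSpec",
    "make_colony_image",
    "make_timecourse",
    "default_image_spec",
]

MORPHOLOGY_LABELS = ("hollow_pellet", "fluffy_pellet", "dispersed")


@dataclass(frozen=True)
class ImageSpec:
    """Recipe for one synthetic colony image.

    Geometry is given in physical units (mm) and rendered at ``scale``
    mm per pixel on a square-ish canvas. ``core_radius = 0`` renders a
    dispersed colony (filaments only). Filament angles are jittered
    deterministically from ``seed``; ``noise_sd`` is the SD of additive
    Gaussian intensity noise on a 0-1 intensity scale.
    """

    canvas_size: tuple[int, int] = (384, 384)
    scale: float = 0.02
    core_radius: float = 1.455
    n_filaments: int = 24
    filament_length: float = 1.2
    filament_width: float = 0.06
    morphology_label: str = "fluffy_pellet"
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0 mm/px, got {self.scale}")
        if self.core_radius < 0:
            raise ValueError(f"core_radius must be >= 0, got {self.core_radius}")
        if self.n_filaments < 0:
            raise ValueError(f"n_filaments must be >= 0, got {self.n_filaments}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.morphology_label not in MORPHOLOGY_LABELS:
            raise ValueError(f"unknown morphology_label {self.morphology_label!r}")
        half_mm = (min(self.canvas_size) / 2.0 - 4.0) * self.scale
        if self.core_radius > half_mm:
            raise ValueError(
                f"core_radius {self.core_radius} mm does not fit the canvas "
                f"(max {half_mm:.3f} mm at {self.scale} mm/px)"
            )
        reach = self.core_radius + (self.filament_length if self.n_filaments else 0.0)
        if reach > half_mm:
            raise ValueError(
                f"filament_length {self.filament_length} mm reaches {reach:.3f} mm "
                f"from center and does not fit the canvas (max {half_mm:.3f} mm)"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Exact pixel-count areas of the rendered colony, in mm^2."""

    core_area: float
    total_area: float


def default_image_spec(morphology: str, seed: int = 0, noise_sd: float = 0.02) -> ImageSpec:
    """Canonical spec for each of the three macro-morphologies.

    Core radii follow the published core diameters (hollow 3.88 mm,
    fluffy 2.91 mm — radii 1.94 and 1.455 mm); the dispersed form has
    no core and many scattered filaments.
    """
    if morphology == "hollow_pellet":
        return ImageSpec(core_radius=1.94, n_filaments=6, filament_length=0.8,
                         morphology_label="hollow_pellet", noise_sd=noise_sd, seed=seed)
    if morphology == "fluffy_pellet":
        return ImageSpec(core_radius=1.455, n_filaments=24, filament_length=1.2,
                         morphology_label="fluffy_pellet", noise_sd=noise_sd, seed=seed)
    if morphology == "dispersed":
        return ImageSpec(core_radius=0.0, n_filaments=40, filament_length=1.2,
                         morphology_label="dispersed", noise_sd=noise_sd, seed=seed)
    raise ValueError(f"unknown morphology {morphology!r}")


def _filament_mask(spec: ImageSpec, rng: np.random.Generator) -> np.ndarray:
    """Thin straight filaments as dilated line segments.

    Radial from the core rim when a core exists; scattered at random
    radial offsets (so no artificial dense center forms) when it does not.
    Drawing a 1-px line and dilating with a radius-1 disk yields width-3
    strokes that a radius-1 opening preserves exactly and a radius-2
    opening removes cleanly.
    """
    h, w = spec.canvas_size
    mask = np.zeros((h, w), dtype=bool)
    if spec.n_filaments == 0:
        return mask
    cy, cx = h / 2.0, w / 2.0
    length_px = spec.filament_length / spec.scale
    core_px = spec.core_radius / spec.scale
    half = min(h, w) / 2.0 - 4.0
    base_angles = np.linspace(0, 2 * np.pi, spec.n_filaments, endpoint=False)
    jitter = rng.uniform(-0.5, 0.5, size=spec.n_filaments) * (2 * np.pi / max(spec.n_filaments, 1))
    for ang in base_angles + jitter:
        if core_px > 0:
            r0 = core_px - 1.0  # start just inside the rim so core and filament connect
        else:
            r0 = rng.uniform(0.3, 0.6) * half
        r1 = min(r0 + length_px, half)
        y0, x0 = cy + r0 * np.sin(ang), cx + r0 * np.cos(ang)
        y1, x1 = cy + r1 * np.sin(ang), cx + r1 * np.cos(ang)
        rr, cc = draw.line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        mask[rr[keep], cc[keep]] = True
    width_px = max(2, int(round(spec.filament_width / spec.scale)))
    return morphology.dilation(mask, morphology.disk(width_px // 2))


def make_colony_image(spec: ImageSpec) -> tuple[ColonyImage, GroundTruth]:
    """Render a colony image and return it with exact ground-truth areas.

    Intensities on a 0-1 scale: background 0, filaments 0.75, core 0.9,
    and for hollow pellets a brighter rim at 1.0 (projection of the
    surface-compacted shell). Ground-truth areas are foreground pixel
    counts times scale^2 — the independent oracle every morphometric
    result is checked against. Identical spec (including seed) gives a
    bit-identical image.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas_size
    img = np.zeros((h, w), dtype=float)

    core_mask = np.zeros((h, w), dtype=bool)
    if spec.core_radius > 0:
        rr, cc = draw.disk((h / 2.0, w / 2.0), spec.core_radius / spec.scale, shape=(h, w))
        core_mask[rr, cc] = True

    fil_mask = _filament_mask(spec, rng)
    img[fil_mask] = 0.75
    img[core_mask] = 0.9
    if spec.morphology_label == "hollow_pellet" and core_mask.any():
        rim_w = max(2, int(round(0.08 * spec.core_radius / spec.scale)))
        interior = morphology.erosion(core_mask, morphology.disk(rim_w))
        img[core_mask & ~interior] = 1.0

    fg = core_mask | fil_mask
    gt = GroundTruth(
        core_area=float(core_mask.sum()) * spec.scale**2,
        total_area=float(fg.sum()) * spec.scale**2,
    )
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return ColonyImage(img, spec.scale), gt


@dataclass(frozen=True)
class TimeCourseSpec:
    """Recipe for one simulated fermentation time course.

    Biomass and lipid are sampled from the closed-form logistic /
    Luedeking-Piret solutions at ``sample_times`` (days) and perturbed by
    additive zero-mean Gaussian noise (``noise_sd_x``, ``noise_sd_p``,
    g/L), floored at 0. Residual glucose, when requested, follows a
    constant-yield bookkeeping model S(t) = s0 - yield*(X(t) - x_0),
    floored at 0 — a simulation convenience, not a fitted model.
    """

    logistic: LogisticParams = LogisticParams(mu_max=0.6584, x_m=28.44, x_0=4.0)
    lp: LuedekingPiretParams = LuedekingPiretParams(alpha=0.3531, beta=0.0204, p_0=0.0)
    sample_times: tuple[float, ...] = tuple(float(d) for d in range(9))
    noise_sd_x: float = 0.5
    noise_sd_p: float = 0.2
    glucose_s0: float | None = None
    glucose_yield: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        if t.size == 0 or t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("sample_times must be strictly increasing with first >= 0")
        if self.noise_sd_x < 0 or self.noise_sd_p < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.glucose_s0 is not None and self.glucose_s0 < 0:
            raise ValueError("glucose_s0 must be >= 0")


def make_timecourse(spec: TimeCourseSpec) -> TimeCourse:
    """Sample a noisy trajectory from the closed-form model."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.sample_times, dtype=float)
    x = biomass(t, spec.logistic)
    p = lipid(t, spec.logistic, spec.lp)
    if spec.noise_sd_x > 0:
        x = np.clip(x + rng.normal(0.0, spec.noise_sd_x, size=t.shape), 0.0, None)
    if spec.noise_sd_p > 0:
        p = np.clip(p + rng.normal(0.0, spec.noise_sd_p, size=t.shape), 0.0, None)
    s = None
    if spec.glucose_s0 is not None:
        clean_x = biomass(t, spec.logistic)
        s = np.clip(spec.glucose_s0 - spec.glucose_yield * (clean_x - spec.logistic.x_0), 0.0, None)
    return TimeCourse(t=t, x=x, p=p, s=s)
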