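"""Macro-morphometrics of fungal colonies from grayscale images.

The quantification follows the granulometric recipe used for pelleted
filamentous fungi: threshold the image, clean it with a small opening,
then open with disks of increasing radius until the retained area
plateaus — thin radial filaments vanish early, the compact pellet core
survives. Subtracting the core from the whole colony gives the
filamentous fraction. From the two masks come the projected areas
(A_m, A_pc), equivalent circular diameters (D_m, D_pc), the fluffy
degree A_pc/A_m, and — given a dry-mass measurement for a counted set
of colonies — the compactness (dry mass per idealized spherical colony
volume, mg/cm^3).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, morphology

__all__ = [
    "ColonyImage",
    "BinaryMask",
    "MorphometricRecord",
    "CompactnessInput",
    "ClassThresholds",
    "binarize",
    "extract_core",
    "measure",
    "compactness",
    "classify_morphology",
    "aggregate",
]

CLASSES = ("hollow_pellet", "fluffy_pellet", "dispersed")
# deterministic tie-break order for majority voting
_CLASS_RANK = {"hollow_pellet": 0, "fluffy_pellet": 1, "dispersed": 2}


@dataclass
class ColonyImage:
    """2-D grayscale colony image with a physical pixel scale (mm/px)."""

    pixels: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0 mm/px, got {self.scale}")


@dataclass
class BinaryMask:
    """Boolean foreground mask sharing the source image's scale."""

    pixels: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0 mm/px, got {self.scale}")

    @property
    def area_mm2(self) -> float:
        return float(self.pixels.sum()) * self.scale**2


@dataclass
class MorphometricRecord:
    """Per-colony morphometric parameters.

    a_m / a_pc : projected area of the whole mycelium / of the pellet core (mm^2)
    d_m / d_pc : equivalent circular diameters (mm)
    fluffy_degree : a_pc / a_m in [0, 1] (0 when a_m = 0)
    compactness : optional, mg dry mass per cm^3 of idealized sphere
    morphology_class : optional, one of hollow_pellet / fluffy_pellet / dispersed
    """

    a_m: float
    a_pc: float
    d_m: float
    d_pc: float
    fluffy_degree: float
    compactness: float | None = None
    morphology_class: str | None = None
    warnings: list[str] = field(default_factory=list)
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.a_pc <= self.a_m + 1e-12:
            raise ValueError(f"need 0 <= a_pc <= a_m, got a_pc={self.a_pc}, a_m={self.a_m}")
        if not 0 <= self.fluffy_degree <= 1 + 1e-12:
            raise ValueError(f"fluffy_degree outside [0,1]: {self.fluffy_degree}")
        if self.d_pc > self.d_m + 1e-12:
            raise ValueError(f"d_pc={self.d_pc} exceeds d_m={self.d_m}")
        if self.compactness is not None and self.compactness < 0:
            raise ValueError("compactness must be >= 0")


@dataclass(frozen=True)
class CompactnessInput:
    """Dry mass (mg) of a counted set of colonies plus their mean diameter."""

    dcw_total: float
    n_elements: int
    d_m: float

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")
        if self.dcw_total < 0:
            raise ValueError("dcw_total must be >= 0")
        if not self.d_m > 0:
            raise ValueError("d_m must be > 0")


@dataclass(frozen=True)
class ClassThresholds:
    """Decision thresholds for the three macro-morphology classes.

    fd_dispersed : fluffy degree at or below which a colony is dispersed
    fd_hollow    : fluffy degree at or above which a large-cored colony is
                   a hollow (surface-compacted) pellet
    core_diam_hollow : minimum core diameter (mm) for the hollow class
    """

    fd_dispersed: float = 0.05
    fd_hollow: float = 0.7
    core_diam_hollow: float = 3.0


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the given area: 2*sqrt(A/pi)."""
    return 2.0 * float(np.sqrt(area / np.pi))


def binarize(
    image: ColonyImage,
    method: str = "otsu",
    min_object_area: float = 0.0,
    cleanup_radius: int = 1,
) -> BinaryMask:
    """Threshold a colony image to a foreground mask and clean it up.

    Foreground = pixels above the threshold (Otsu by default, or a numeric
    value). A single small-radius opening removes speckle, then connected
    components below ``min_object_area`` (mm^2) are dropped. A uniform
    image has no separating threshold and raises.
    """
    px = np.asarray(image.pixels, dtype=float)
    if np.ptp(px) == 0:
        raise ValueError("no threshold separates foreground: image is uniform")
    if method == "otsu":
        thr = filters.threshold_otsu(px)
    else:
        thr = float(method)
    mask = px > thr
    if cleanup_radius > 0:
        mask = morphology.opening(mask, morphology.disk(cleanup_radius))
    if min_object_area > 0:
        min_px = int(np.ceil(min_object_area / image.scale**2))
        lab, n = ndimage.label(mask)
        if n:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
            keep = np.concatenate([[False], sizes >= min_px])
            mask = keep[lab]
    return BinaryMask(mask, image.scale)


def extract_core(
    mask: BinaryMask,
    max_radius: int = 30,
    stop_tol: float = 0.02,
    min_radius: int = 2,
    fill_holes: bool = True,
) -> tuple[BinaryMask, BinaryMask, list[tuple[int, float]]]:
    """Separate the pellet core from the filaments by granulometry.

    Opens the (optionally hole-filled) mask with disk structuring elements
    of radius r = 1, 2, ... and watches the retained area. Thin filaments
    disappear as soon as the disk outgrows their width; the compact core
    barely changes. The loop stops at the first r >= ``min_radius`` where
    the relative area change from r-1 to r falls below ``stop_tol`` — the
    plateau that marks "filaments gone, core reached". The opened mask at
    that radius is the core; mask AND NOT core is the filamentous part.

    Returns (core, filaments, radius_profile) where radius_profile is the
    granulometry curve [(radius, area_mm2), ...] starting at r = 0.
    ``min_radius`` >= 2 keeps the near-zero r=0 -> r=1 change (the mask was
    already cleaned with a radius-1 opening) from stopping the loop before
    any filament has been removed. If no plateau appears by ``max_radius``
    the core at ``max_radius`` is returned and the condition is reported in
    the profile's final entry (callers flag it via the returned radius).
    """
    base = mask.pixels
    if fill_holes and base.any():
        base = ndimage.binary_fill_holes(base)
    profile: list[tuple[int, float]] = [(0, float(base.sum()) * mask.scale**2)]
    if not base.any():
        empty = BinaryMask(np.zeros_like(base, dtype=bool), mask.scale)
        return empty, BinaryMask(mask.pixels.copy(), mask.scale), profile

    prev_area = float(base.sum())
    opened = base
    for r in range(1, max_radius + 1):
        opened = morphology.opening(base, morphology.disk(r))
        area = float(opened.sum())
        profile.append((r, area * mask.scale**2))
        rel_change = (prev_area - area) / prev_area if prev_area > 0 else 0.0
        if r >= min_radius and rel_change < stop_tol:
            break
        prev_area = area

    core = BinaryMask(opened, mask.scale)
    filaments = BinaryMask(mask.pixels & ~opened, mask.scale)
    return core, filaments, profile


def measure(mask: BinaryMask, core: BinaryMask, sample_id: str | None = None) -> MorphometricRecord:
    """Areas, equivalent diameters and fluffy degree from the two masks.

    A = pixel count * scale^2; D = 2*sqrt(A/pi); fluffy degree = A_pc/A_m,
    defined as 0 for an empty colony. The core must be a subset of the
    whole-colony mask (after hole filling the core can cover interior
    holes of the raw mask, so subset is checked against the filled mask).
    """
    whole = ndimage.binary_fill_holes(mask.pixels) if mask.pixels.any() else mask.pixels
    if np.any(core.pixels & ~whole):
        raise ValueError("core mask is not a subset of the colony mask")
    a_m = float(whole.sum()) * mask.scale**2
    a_pc = core.area_mm2
    fd = a_pc / a_m if a_m > 0 else 0.0
    return MorphometricRecord(
        a_m=a_m,
        a_pc=a_pc,
        d_m=equivalent_diameter(a_m),
        d_pc=equivalent_diameter(a_pc),
        fluffy_degree=fd,
        sample_id=sample_id,
    )


def compactness(inp: CompactnessInput) -> float:
    """Dry mass per idealized spherical colony volume, mg/cm^3.

    The counted colonies are idealized as spheres of diameter d_m:
    compactness = dcw_total / (n_elements * (4/3)*pi*(d_m/2)^3),
    with d_m converted from mm to cm.
    """
    r_cm = (inp.d_m / 10.0) / 2.0
    vol = (4.0 / 3.0) * np.pi * r_cm**3
    return float(inp.dcw_total / (inp.n_elements * vol))


def classify_morphology(
    rec: MorphometricRecord, thresholds: ClassThresholds = ClassThresholds()
) -> str:
    """Assign hollow_pellet / fluffy_pellet / dispersed from the record.

    Dispersed mycelia have essentially no core (fluffy degree at or below
    fd_dispersed). A colony whose core dominates the projection (fluffy
    degree >= fd_hollow) *and* whose core diameter exceeds
    core_diam_hollow is a hollow, surface-compacted pellet. Everything in
    between — a clear core surrounded by substantial radial filaments —
    is a fluffy pellet.
    """
    if rec.fluffy_degree <= thresholds.fd_dispersed:
        return "dispersed"
    if rec.fluffy_degree >= thresholds.fd_hollow and rec.d_pc > thresholds.core_diam_hollow:
        return "hollow_pellet"
    return "fluffy_pellet"


_NUMERIC_FIELDS = ("a_m", "a_pc", "d_m", "d_pc", "fluffy_degree", "compactness")


def aggregate(records: list[MorphometricRecord], min_n: int = 20) -> dict:
    """Per-metric mean and SD over colonies, plus the majority class.

    Colony-level morphometrics are averaged over a sample of colonies.
    Ties in the class vote break deterministically toward the more
    compact class (hollow > fluffy > dispersed). A sample smaller than
    ``min_n`` colonies is flagged.
    """
    if not records:
        raise ValueError("cannot aggregate an empty record list")
    rows = []
    for r in records:
        rows.append({f: getattr(r, f) for f in _NUMERIC_FIELDS})
    df = pd.DataFrame(rows)
    summary: dict = {"n": len(records), "warnings": []}
    for f in _NUMERIC_FIELDS:
        col = df[f].dropna()
        if len(col):
            summary[f] = {"mean": float(col.mean()), "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0}
    votes = Counter(r.morphology_class for r in records if r.morphology_class)
    if votes:
        best = max(votes.items(), key=lambda kv: (kv[1], -_CLASS_RANK[kv[0]]))
        summary["majority_class"] = best[0]
    if len(records) < min_n:
        summary["warnings"].append(f"only {len(records)} colonies (< {min_n})")
    return summary
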