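"""Reading and writing the package's file formats.

Time courses travel as CSV with the header
``time_d,dcw_g_l,lipid_g_l,glucose_g_l`` (lipid and glucose optional);
colony images as 8-bit grayscale PNG/TIFF with an optional JSON sidecar
holding the generating spec and ground truth; morphometric records as a
flat CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .kinetics import TimeCourse
from .morphometrics import ColonyImage, MorphometricRecord

__all__ = [
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_colony_image",
    "write_colony_image",
    "write_records_csv",
]

TIMECOURSE_COLUMNS = {"time_d", "dcw_g_l"}


def read_timecourse_csv(path: str | Path) -> TimeCourse:
    """Load a time course; raises with the file name on malformed input."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValueError(f"cannot parse time-course CSV {path}: {exc}") from exc
    missing = TIMECOURSE_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    return TimeCourse(
        t=df["time_d"].to_numpy(float),
        x=df["dcw_g_l"].to_numpy(float),
        p=df["lipid_g_l"].to_numpy(float) if "lipid_g_l" in df else None,
        s=df["glucose_g_l"].to_numpy(float) if "glucose_g_l" in df else None,
    )


def write_timecourse_csv(tc: TimeCourse, path: str | Path) -> None:
    tc.to_frame().to_csv(path, index=False)


def write_colony_image(image: ColonyImage, path: str | Path, sidecar: dict | None = None) -> None:
    """Write as 8-bit grayscale; intensities clipped to [0, 1] then scaled.

    ``sidecar`` (e.g. the generating spec and ground truth) is written to
    ``<path>.json``.
    """
    path = Path(path)
    px = np.clip(np.asarray(image.pixels, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (px * 255).round().astype(np.uint8))
    meta = {"scale_mm_per_px": image.scale}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_colony_image(path: str | Path, scale: float | None = None) -> ColonyImage:
    """Read a grayscale image; the mm/px scale comes from the argument or
    the JSON sidecar written by :func:`write_colony_image`."""
    path = Path(path)
    if scale is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(f"{path}: no scale given and no sidecar {sidecar.name}")
        scale = json.loads(sidecar.read_text())["scale_mm_per_px"]
    px = np.asarray(iio.imread(path), dtype=float)
    if px.ndim == 3:  # collapse any color channels
        px = px.mean(axis=-1)
    if px.max() > 1:
        px = px / 255.0
    return ColonyImage(px, float(scale))


def write_records_csv(records: list[MorphometricRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = asdict(r)
        rows.append({
            "sample_id": d["sample_id"],
            "A_m_mm2": d["a_m"],
            "A_pc_mm2": d["a_pc"],
            "D_m_mm": d["d_m"],
            "D_pc_mm": d["d_pc"],
            "fluffy_degree": d["fluffy_degree"],
            "compactness_mg_cm3": d["compactness"],
            "class": d["morphology_class"],
            "warning": ";".join(d["warnings"]),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
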