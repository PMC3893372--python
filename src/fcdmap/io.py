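"""File formats: contour CSV + JSON sidecar, profile CSV, TIFF rasters.

Contours travel as a CSV with columns (contour_id in {outer, inner},
vertex_index, x_px, y_px) plus a JSON sidecar holding pixel_size_um,
slide_id and, when known, the stereotaxic y. Midline profiles are CSV;
potentials and label masks are single-channel TIFFs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ribbon import ContourPair, MidlineProfile


def write_contours(cp: ContourPair, csv_path, y_mm: float | None = None) -> Path:
    """Write a contour pair as CSV + ``.json`` sidecar; returns the CSV path."""
    csv_path = Path(csv_path)
    rows = []
    for cid, pts in (("outer", cp.outer), ("inner", cp.inner)):
        for i, (x, y) in enumerate(pts):
            rows.append({"contour_id": cid, "vertex_index": i, "x_px": x, "y_px": y})
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    side = {
        "pixel_size_um": cp.pixel_size,
        "slide_id": cp.slide_id,
        "closed": bool(cp.closed),
    }
    if y_mm is not None:
        side["y_mm"] = float(y_mm)
    csv_path.with_suffix(".json").write_text(json.dumps(side, indent=1))
    return csv_path


def read_contours(csv_path) -> tuple[ContourPair, dict]:
    """Read a contour CSV (+ sidecar); returns (ContourPair, sidecar dict)."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    need = {"contour_id", "vertex_index", "x_px", "y_px"}
    if not need.issubset(df.columns):
        raise ValueError(f"contour file {csv_path} lacks columns {need - set(df.columns)}")
    side_path = csv_path.with_suffix(".json")
    side = json.loads(side_path.read_text()) if side_path.exists() else {}

    def pts(cid):
        sub = df[df.contour_id == cid].sort_values("vertex_index")
        if sub.empty:
            raise ValueError(f"contour file {csv_path} has no '{cid}' contour")
        return sub[["x_px", "y_px"]].to_numpy(dtype=float)

    cp = ContourPair(
        pts("outer"),
        pts("inner"),
        float(side.get("pixel_size_um", 1.0)),
        str(side.get("slide_id", csv_path.stem)),
        closed=side.get("closed"),
    )
    return cp, side


def write_profile(profile: MidlineProfile, path) -> Path:
    path = Path(path)
    profile.to_frame().to_csv(path, index=False)
    return path


def read_profile(path) -> MidlineProfile:
    df = pd.read_csv(path)
    return MidlineProfile(
        slide_id=str(df["slide_id"].iloc[0]) if len(df) else Path(path).stem,
        points=df[["x_px", "y_px"]].to_numpy(dtype=float),
        arc_s=df["arc_s_um"].to_numpy(dtype=float),
        t=df["t_um"].to_numpy(dtype=float),
        kappa=df["kappa_per_mm"].to_numpy(dtype=float),
    )


def write_phi(phi: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, phi.astype(np.float32))
    return path


def write_image(img: np.ndarray, path) -> Path:
    """Grayscale image as 8- or 16-bit TIFF (clipped/rounded)."""
    path = Path(path)
    a = np.asarray(img)
    if a.dtype in (np.uint8, np.uint16):
        tifffile.imwrite(path, a)
    else:
        a = np.clip(np.rint(a), 0, 65535)
        dt = np.uint8 if a.max() <= 255 else np.uint16
        tifffile.imwrite(path, a.astype(dt))
    return path


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=float)
    from PIL import Image

    return np.asarray(Image.open(path).convert("I"), dtype=float)


def write_labels(labels: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels).astype(np.uint16))
    return path


def read_labels(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path)).astype(np.int32)
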