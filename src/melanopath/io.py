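"""File formats: indexed-PNG masks, RGB images, viewport CSV, ROI JSON.

Masks are stored as paletted PNG.  On read, labels are resolved through the
registered palette *colors*, not raw indices, so a file whose palette lists
the same colors in a different order still round-trips correctly; colors
outside the registered palette are rejected.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from . import palette as P
from .viewbehave import Viewport, ViewportLog

__all__ = ["write_mask", "read_mask", "write_image", "read_image",
           "write_viewport_csv", "read_viewport_csv", "write_rois",
           "read_rois", "write_manifest"]

VIEWPORT_COLUMNS = ["interpretation_id", "pathologist_id", "case_id",
                    "x", "y", "width", "height", "zoom", "timestamp_s"]


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a label grid as an indexed PNG with the registered palette."""
    mask = np.asarray(mask)
    bad = set(np.unique(mask)) - set(P.MASK_PALETTE)
    if bad:
        raise ValueError(f"mask contains unregistered class codes {sorted(bad)}")
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    flat = []
    for code in range(P.N_CLASSES):
        flat.extend(P.MASK_PALETTE[code])
    img.putpalette(flat)
    img.save(path, format="PNG")


def read_mask(path: str | Path) -> np.ndarray:
    """Read an indexed PNG mask, resolving labels via palette colors."""
    img = Image.open(path)
    if img.mode != "P":
        raise ValueError(
            f"{path}: expected an indexed (palette) PNG, got mode {img.mode!r};"
            " convert with Image.convert('P') using the registered palette")
    raw = np.asarray(img)
    pal = img.getpalette()
    color_to_code = {color: code for code, color in P.MASK_PALETTE.items()}
    used = np.unique(raw)
    lut = np.zeros(int(used.max()) + 1, dtype=np.uint8)
    for idx in used:
        color = tuple(pal[3 * idx:3 * idx + 3])
        if color not in color_to_code:
            raise ValueError(
                f"{path}: palette index {idx} has color {color}, which is not"
                " a registered class color")
        lut[idx] = color_to_code[color]
    return lut[raw]


def write_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(
        path, format="PNG")


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_viewport_csv(logs: list[ViewportLog], path: str | Path) -> None:
    rows = []
    for log in logs:
        for v in log.viewports:
            rows.append({"interpretation_id": log.interpretation_id,
                         "pathologist_id": log.pathologist_id,
                         "case_id": log.case_id, "x": v.x, "y": v.y,
                         "width": v.width, "height": v.height,
                         "zoom": v.zoom, "timestamp_s": v.timestamp_s})
    pd.DataFrame(rows, columns=VIEWPORT_COLUMNS).to_csv(path, index=False)


def read_viewport_csv(path: str | Path) -> list[ViewportLog]:
    """Parse a viewport CSV into per-interpretation logs, time-sorted."""
    df = pd.read_csv(path)
    missing = [c for c in VIEWPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    logs = []
    for interp_id, group in df.groupby("interpretation_id", sort=False):
        group = group.sort_values("timestamp_s", kind="stable")
        dup = group["timestamp_s"].duplicated()
        if dup.any():
            rows = (group.index[dup] + 2).tolist()  # header + 0-based
            raise ValueError(
                f"{path}: duplicate timestamps in interpretation"
                f" {interp_id!r} at file rows {rows}")
        viewports = [Viewport(x=r.x, y=r.y, width=r.width, height=r.height,
                              zoom=r.zoom, timestamp_s=r.timestamp_s)
                     for r in group.itertuples()]
        logs.append(ViewportLog(
            interpretation_id=str(interp_id),
            pathologist_id=str(group["pathologist_id"].iloc[0]),
            case_id=str(group["case_id"].iloc[0]),
            viewports=viewports))
    return logs


def write_rois(rois_by_case: dict[str, list], path: str | Path) -> None:
    """ROI polygons per case as JSON lists of [x, y] vertex pairs."""
    payload = {}
    for case, polys in rois_by_case.items():
        out = []
        for poly in polys:
            coords = (list(poly.exterior.coords) if hasattr(poly, "exterior")
                      else list(poly))
            out.append([[float(x), float(y)] for x, y in coords])
        payload[case] = out
    Path(path).write_text(json.dumps(payload, indent=1))


def read_rois(path: str | Path) -> dict[str, list]:
    from shapely.geometry import Polygon

    payload = json.loads(Path(path).read_text())
    return {case: [Polygon(p) for p in polys]
            for case, polys in payload.items()}


def write_manifest(out_dir: str | Path, command: str, seed: int,
                   inputs: dict, config: dict | None = None) -> Path:
    """Record inputs, config hash, seed and versions for reproducibility."""
    config = config or {}
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]
    manifest = {
        "command": command,
        "seed": seed,
        "inputs": inputs,
        "config": config,
        "config_sha256": cfg_hash,
        "versions": {
            "melanopath": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
        },
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
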