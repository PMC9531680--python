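"""Layered synthetic skin tissue: image, per-pixel mask, nucleus instances.

The renderer lays out horizontal bands (background, stratum corneum,
epidermis, dermis) top to bottom, embeds elliptical melanocytic nests in the
epidermis and dermis, scatters melanocyte and mitotic nuclei, and finishes
with Gaussian pixel noise.  Everything is a pure function of the parameter
set, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import ellipse

from .. import palette as P
from ..instances import Box, InstanceSet

__all__ = ["TissueParams", "gen_tissue_image", "gen_virtual_stain_pair",
           "coarse_labels", "sparsify_mask"]


@dataclass(frozen=True)
class TissueParams:
    """Layout parameters for one synthetic tissue tile.

    band_fractions are the height fractions of the BG, COR, EP and DE bands
    from the top; any remainder is background at the bottom.
    """

    image_height: int = 128
    image_width: int = 128
    band_fractions: tuple[float, float, float, float] = (0.15, 0.10, 0.30, 0.45)
    n_epidermal_nests: int = 2
    n_dermal_nests: int = 3
    nest_radius_range: tuple[int, int] = (5, 9)
    n_melanocytes: int = 10
    n_mitoses: int = 0
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if any(f < 0 for f in self.band_fractions):
            raise ValueError("band fractions must be non-negative")
        if sum(self.band_fractions) > 1.0 + 1e-9:
            raise ValueError("band fractions must sum to at most 1")
        for name in ("n_epidermal_nests", "n_dermal_nests", "n_melanocytes",
                     "n_mitoses"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.nest_radius_range[0] > self.nest_radius_range[1]:
            raise ValueError("nest_radius_range must be (min, max)")


def _band_rows(params: TissueParams) -> dict[int, tuple[int, int]]:
    """Half-open row spans of the BG/COR/EP/DE bands (top remainder joins BG)."""
    h = params.image_height
    edges = np.cumsum([0.0, *params.band_fractions])
    rows = (edges * h).round().astype(int)
    return {P.BG: (rows[0], rows[1]), P.COR: (rows[1], rows[2]),
            P.EP: (rows[2], rows[3]), P.DE: (rows[3], rows[4])}


def _place_ellipses(rng, n, row_span, width, radius_range, occupied,
                    min_gap=3, max_tries=2000):
    """Rejection-sample non-touching ellipses inside a band."""
    placed = []
    r_lo, r_hi = radius_range
    for _ in range(n):
        for attempt in range(max_tries):
            ry = int(rng.integers(r_lo, r_hi + 1))
            rx = int(rng.integers(r_lo, r_hi + 1))
            top, bot = row_span
            if bot - top < 2 * ry + 2:
                raise ValueError(
                    f"nest radius {ry} does not fit band of height {bot - top}")
            cy = int(rng.integers(top + ry + 1, bot - ry))
            cx = int(rng.integers(rx + 1, width - rx - 1))
            ok = all(abs(cy - py) > ry + pry + min_gap or
                     abs(cx - px) > rx + prx + min_gap
                     for (py, px, pry, prx) in occupied)
            if ok:
                occupied.append((cy, cx, ry, rx))
                placed.append((cy, cx, ry, rx))
                break
        else:
            raise RuntimeError("could not place all ellipses without contact")
    return placed


def gen_tissue_image(params: TissueParams) -> tuple[np.ndarray, np.ndarray, InstanceSet]:
    """Render one tissue tile.

    Returns (RGB uint8 image of shape (H, W, 3), label mask of shape (H, W)
    over the class palette, melanocyte bounding boxes).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height, params.image_width
    bands = _band_rows(params)

    mask = np.full((h, w), P.BG, dtype=np.uint8)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = P.TISSUE_COLORS[P.BG]
    for code in (P.COR, P.EP, P.DE):
        top, bot = bands[code]
        mask[top:bot] = code
        img[top:bot] = P.TISSUE_COLORS[code]

    r_hi = params.nest_radius_range[1]
    for code, band_code, n in ((P.EPN, P.EP, params.n_epidermal_nests),
                               (P.DMN, P.DE, params.n_dermal_nests)):
        top, bot = bands[band_code]
        if n > 0 and bot - top < 2 * r_hi + 2:
            raise ValueError(
                f"nest radius {r_hi} larger than {P.CLASS_NAMES[band_code]} "
                f"band height {bot - top}")
        occupied: list = []
        for (cy, cx, ry, rx) in _place_ellipses(
                rng, n, (top, bot), w, params.nest_radius_range, occupied):
            rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w))
            mask[rr, cc] = code
            img[rr, cc] = P.TISSUE_COLORS[code]

    # melanocyte nuclei: small ellipses in EP or DE, kept outside nests and
    # apart from each other so instance boxes are unambiguous
    cell_occupied: list = []
    boxes: list[Box] = []
    ep_top, de_bot = bands[P.EP][0], bands[P.DE][1]
    for _ in range(params.n_melanocytes):
        for attempt in range(4000):
            ry = int(rng.integers(2, 4))
            rx = int(rng.integers(2, 4))
            cy = int(rng.integers(ep_top + ry + 1, de_bot - ry - 1))
            cx = int(rng.integers(rx + 1, w - rx - 1))
            rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w))
            on_nest = np.isin(mask[rr, cc], (P.DMN, P.EPN)).any()
            clear = all(abs(cy - py) > ry + pry + 2 or abs(cx - px) > rx + prx + 2
                        for (py, px, pry, prx) in cell_occupied)
            if clear and not on_nest:
                break
        else:
            raise RuntimeError("could not place melanocytes without contact")
        cell_occupied.append((cy, cx, ry, rx))
        img[rr, cc] = P.MELANOCYTE_COLOR
        boxes.append(Box(int(cc.min()), int(rr.min()),
                         int(cc.max()) + 1, int(rr.max()) + 1))

    # mitotic nuclei: dark, speckled texture; not part of the instance set
    for _ in range(params.n_mitoses):
        for attempt in range(4000):
            ry, rx = int(rng.integers(3, 5)), int(rng.integers(3, 5))
            cy = int(rng.integers(ep_top + ry + 1, de_bot - ry - 1))
            cx = int(rng.integers(rx + 1, w - rx - 1))
            clear = all(abs(cy - py) > ry + pry + 2 or abs(cx - px) > rx + prx + 2
                        for (py, px, pry, prx) in cell_occupied)
            if clear:
                break
        else:
            raise RuntimeError("could not place mitoses without contact")
        cell_occupied.append((cy, cx, ry, rx))
        rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w))
        img[rr, cc] = P.MITOSIS_COLOR
        img[rr, cc] += rng.normal(0, 25, size=(rr.size, 1))

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    labels = ["melanocyte"] * len(boxes)
    return img, mask, InstanceSet(boxes=boxes, labels=labels)


def gen_virtual_stain_pair(image: np.ndarray, instances: InstanceSet) -> np.ndarray:
    """Deterministic SOX10-like recoloring of an H&E-like image.

    All pixels are desaturated to their channel mean; pixels inside melanocyte
    boxes are set to the fixed red-brown SOX10 color.
    """
    h, w = image.shape[:2]
    for b in instances.boxes:
        if not (0 <= b.x0 and b.x1 <= w and 0 <= b.y0 and b.y1 <= h):
            raise ValueError(f"instance box {b} outside image bounds {w}x{h}")
    gray = np.rint(image.astype(np.float64).mean(axis=2)).astype(np.uint8)
    out = np.stack([gray, gray, gray], axis=2)
    for b in instances.boxes:
        out[b.y0:b.y1, b.x0:b.x1] = P.SOX10_COLOR
    return out


def coarse_labels(mask: np.ndarray) -> np.ndarray:
    """Collapse nest classes onto their parent bands (stage-1 ground truth)."""
    out = mask.copy()
    out[mask == P.DMN] = P.DE
    out[mask == P.EPN] = P.EP
    return out


def sparsify_mask(mask: np.ndarray, keep_fraction: float, seed: int) -> np.ndarray:
    """Set a random subset of pixels to UL, emulating sparse annotation."""
    if not 0.0 <= keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = mask.copy()
    drop = rng.random(mask.shape) >= keep_fraction
    out[drop] = P.UL
    return out
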