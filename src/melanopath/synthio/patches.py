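"""Synthetic 101x101 nucleus patches: mitotic vs normal.

Mitotic-class patches hold a dark, condensed, speckle-textured nucleus;
normal-class patches a lighter, smoothly shaded one.  The darker mean color
of the mitotic class makes the two classes separable by simple features,
which is the point of the fixture: recovery tests need a learnable signal.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import ellipse

from .. import palette as P

__all__ = ["PATCH_SIZE", "gen_patch_dataset"]

PATCH_SIZE = 101


def _stroma_background(rng) -> np.ndarray:
    img = np.empty((PATCH_SIZE, PATCH_SIZE, 3), dtype=np.float64)
    img[:] = P.TISSUE_COLORS[P.DE]
    return img


def _draw_nucleus(img, rng, mitotic: bool) -> None:
    cy = PATCH_SIZE // 2 + int(rng.integers(-3, 4))
    cx = PATCH_SIZE // 2 + int(rng.integers(-3, 4))
    ry = int(rng.integers(8, 14))
    rx = int(rng.integers(8, 14))
    rr, cc = ellipse(cy, cx, ry, rx, shape=(PATCH_SIZE, PATCH_SIZE))
    if mitotic:
        img[rr, cc] = P.MITOSIS_COLOR
        # condensed-chromatin speckle
        img[rr, cc] += rng.normal(0, 30, size=(rr.size, 1))
    else:
        color = np.asarray(P.NORMAL_NUCLEUS_COLOR, dtype=np.float64)
        # smooth radial shading toward the rim
        d = np.sqrt(((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2)
        img[rr, cc] = color + (20.0 * d)[:, None]


def gen_patch_dataset(n_mitosis: int, class_ratio: float, seed: int,
                      noise_sd: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Generate a labeled patch collection.

    Returns (patches, labels): patches of shape (N, 101, 101, 3) uint8 and
    integer labels with 1 = mitosis, 0 = normal.  The normal-class count is
    ``floor(n_mitosis * class_ratio)``.  Identical arguments reproduce the
    dataset exactly, including ordering.
    """
    if n_mitosis < 1:
        raise ValueError("n_mitosis must be >= 1")
    if class_ratio < 0:
        raise ValueError("class_ratio must be >= 0")
    rng = np.random.default_rng(seed)
    n_normal = int(n_mitosis * class_ratio)
    patches = np.empty((n_mitosis + n_normal, PATCH_SIZE, PATCH_SIZE, 3),
                       dtype=np.uint8)
    labels = np.concatenate([np.ones(n_mitosis, dtype=int),
                             np.zeros(n_normal, dtype=int)])
    for i, lab in enumerate(labels):
        img = _stroma_background(rng)
        _draw_nucleus(img, rng, mitotic=bool(lab))
        img += rng.normal(0.0, noise_sd, size=img.shape)
        patches[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return patches, labels
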