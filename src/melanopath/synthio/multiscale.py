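"""Co-registered multi-magnification renderings and diagnosis cohorts.

Magnification tags 7.5x / 10x / 12.5x are realized as resampled renderings of
one tissue tile at relative factors 0.6 / 0.8 / 1.0.  Two cohort generators
feed the scale-aware classifier:

* :func:`gen_multiscale_cohort` — classes differ in dermal nest density, a
  cue visible at every magnification (the separable-recovery fixture);
* :func:`gen_crossscale_cohort` — class identity is the combination of a
  coarse cue rendered only at 7.5x (a global stain cast) and a fine cue
  rendered only at 12.5x (fine pigment speckle), so no single magnification
  determines the class.  This emulates diagnoses that require integrating
  structure seen at low power with cytology seen at high power.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import resize

from .tissue import TissueParams, gen_tissue_image

__all__ = ["SCALE_FACTORS", "MultiScaleCase", "render_multiscale",
           "gen_multiscale_cohort", "gen_crossscale_cohort"]

SCALE_FACTORS: dict[str, float] = {"7.5x": 0.6, "10x": 0.8, "12.5x": 1.0}


@dataclass
class MultiScaleCase:
    case_id: str
    images: dict[str, np.ndarray]  # scale tag -> (H, W, 3) uint8
    label: int


def _resample(image: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return image.copy()
    h, w = image.shape[:2]
    out = resize(image, (max(1, round(h * factor)), max(1, round(w * factor))),
                 anti_aliasing=True, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def render_multiscale(image: np.ndarray,
                      scales=tuple(SCALE_FACTORS)) -> dict[str, np.ndarray]:
    return {sc: _resample(image, SCALE_FACTORS[sc]) for sc in scales}


def gen_multiscale_cohort(n_per_class: int, seed: int,
                          nest_counts: tuple[int, ...] = (0, 3, 7),
                          base_size: int = 96) -> list[MultiScaleCase]:
    """Cohort whose class label is the dermal nest density.

    The narrow nest-radius band keeps total nest area roughly proportional
    to nest count, so density is the dominant class cue.
    """
    rng = np.random.default_rng(seed)
    cases = []
    for label, n_nests in enumerate(nest_counts):
        for i in range(n_per_class):
            params = TissueParams(
                image_height=base_size, image_width=base_size,
                n_dermal_nests=n_nests, n_epidermal_nests=0,
                nest_radius_range=(4, 5), n_melanocytes=4,
                seed=int(rng.integers(2 ** 31)))
            img, _, _ = gen_tissue_image(params)
            cases.append(MultiScaleCase(
                case_id=f"ms-{label}-{i}", images=render_multiscale(img),
                label=label))
    rng.shuffle(cases)
    return cases


def _apply_coarse_cue(image: np.ndarray) -> np.ndarray:
    """Global stain cast: the kind of cue read at low power."""
    shifted = image.astype(np.int16) + np.array([18, -12, -18])
    return np.clip(shifted, 0, 255).astype(np.uint8)


def _apply_fine_cue(image: np.ndarray, rng) -> np.ndarray:
    """Fine dark speckle: the kind of cue read at high power."""
    out = image.copy()
    h, w = out.shape[:2]
    n_dots = (h * w) // 100
    ys = rng.integers(0, h - 1, size=n_dots)
    xs = rng.integers(0, w - 1, size=n_dots)
    for dy in (0, 1):
        for dx in (0, 1):
            out[np.clip(ys + dy, 0, h - 1), np.clip(xs + dx, 0, w - 1)] = (45, 30, 50)
    return out


# class label <- (coarse cue, fine cue); neither cue alone resolves the label
CROSS_SCALE_CLASSES: dict[tuple[int, int], int] = {
    (0, 0): 0, (0, 1): 1, (1, 1): 2,
}


def gen_crossscale_cohort(n_per_class: int, seed: int,
                          base_size: int = 96) -> list[MultiScaleCase]:
    """Cohort separable only by combining cues planted at different scales.

    The coarse cue appears only in the 7.5x rendering and the fine cue only in
    the 12.5x rendering, so the best achievable single-scale accuracy is 2/3
    with balanced classes while all three scales together determine the label.
    """
    rng = np.random.default_rng(seed)
    cases = []
    for (cue_a, cue_b), label in CROSS_SCALE_CLASSES.items():
        for i in range(n_per_class):
            params = TissueParams(
                image_height=base_size, image_width=base_size,
                n_dermal_nests=2, n_epidermal_nests=1,
                nest_radius_range=(4, 7), n_melanocytes=4,
                seed=int(rng.integers(2 ** 31)))
            img, _, _ = gen_tissue_image(params)
            views = render_multiscale(img)
            if cue_a:
                views["7.5x"] = _apply_coarse_cue(views["7.5x"])
            if cue_b:
                views["12.5x"] = _apply_fine_cue(views["12.5x"], rng)
            cases.append(MultiScaleCase(
                case_id=f"xs-{label}-{i}", images=views, label=label))
    rng.shuffle(cases)
    return cases
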