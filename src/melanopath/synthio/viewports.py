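"""Synthetic viewport logs with controllable zoom/pan/ROI-dwell behavior.

The zoom trajectory is a random walk on a fixed ladder of zoom levels with
reflecting boundaries: a zoom-in drawn at the top level is realized as a
zoom-out and vice versa at the bottom.  On a bounded ladder every ascent is
eventually matched by a descent, so when the drawn zoom-in and zoom-out
probabilities are equal, the realized fraction of zoom-in transitions
converges to the drawn probability.  The viewport rectangle is the slide
extent divided by the zoom, and panning re-centers it — near an ROI with
probability ``roi_dwell_target``, uniformly otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from ..viewbehave import Viewport, ViewportLog

__all__ = ["BehaviorParams", "gen_viewport_log"]


@dataclass(frozen=True)
class BehaviorParams:
    zoom_levels: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    p_zoom_in: float = 0.3
    p_zoom_out: float = 0.3
    p_pan: float = 0.4
    roi_dwell_target: float = 0.4
    mean_step_seconds: float = 2.0
    n_viewports: int = 50
    seed: int = 0

    def __post_init__(self):
        probs = (self.p_zoom_in, self.p_zoom_out, self.p_pan)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("transition probabilities must sum to 1")
        if self.n_viewports < 1:
            raise ValueError("n_viewports must be >= 1")
        if not 0.0 <= self.roi_dwell_target <= 1.0:
            raise ValueError("roi_dwell_target must lie in [0, 1]")
        if list(self.zoom_levels) != sorted(self.zoom_levels) or \
                len(set(self.zoom_levels)) != len(self.zoom_levels):
            raise ValueError("zoom_levels must be strictly increasing")


def _roi_anchor(rng, rois) -> tuple[float, float] | None:
    if not rois:
        return None
    poly = rois[int(rng.integers(len(rois)))]
    poly = poly if isinstance(poly, Polygon) else Polygon(poly)
    cx, cy = poly.centroid.x, poly.centroid.y
    return cx, cy


def gen_viewport_log(params: BehaviorParams, rois, slide_extent,
                     interpretation_id: str = "interp-0",
                     pathologist_id: str = "path-0",
                     case_id: str = "case-0") -> ViewportLog:
    """Simulate one interpretation's viewport sequence.

    ``slide_extent`` is (width, height) in slide pixels; ROI polygons must lie
    inside it.
    """
    sw, sh = float(slide_extent[0]), float(slide_extent[1])
    for roi in rois:
        poly = roi if isinstance(roi, Polygon) else Polygon(roi)
        minx, miny, maxx, maxy = poly.bounds
        if minx < 0 or miny < 0 or maxx > sw or maxy > sh:
            raise ValueError("ROI polygon outside slide extent")
    rng = np.random.default_rng(params.seed)
    levels = params.zoom_levels
    zi = 0  # start fully zoomed out
    cx, cy = sw / 2.0, sh / 2.0
    t = 0.0
    viewports: list[Viewport] = []

    def make_viewport(zidx: int, cx: float, cy: float, t: float) -> Viewport:
        z = levels[zidx]
        w, h = sw / z, sh / z
        x = float(np.clip(cx - w / 2.0, 0.0, sw - w))
        y = float(np.clip(cy - h / 2.0, 0.0, sh - h))
        return Viewport(x=x, y=y, width=w, height=h, zoom=z, timestamp_s=t)

    viewports.append(make_viewport(zi, cx, cy, t))
    for _ in range(params.n_viewports - 1):
        t += max(float(rng.exponential(params.mean_step_seconds)), 1e-3)
        u = rng.random()
        if u < params.p_zoom_in:
            action = "in"
        elif u < params.p_zoom_in + params.p_zoom_out:
            action = "out"
        else:
            action = "pan"
        # reflecting boundaries on the zoom ladder
        if action == "in" and zi == len(levels) - 1:
            action = "out"
        elif action == "out" and zi == 0:
            action = "in" if len(levels) > 1 else "pan"
        if action == "in":
            zi += 1
        elif action == "out":
            zi -= 1
        else:
            anchor = _roi_anchor(rng, rois) if rng.random() < params.roi_dwell_target else None
            if anchor is not None:
                jitter = rng.normal(0.0, 0.05 * min(sw, sh), size=2)
                cx = float(np.clip(anchor[0] + jitter[0], 0, sw))
                cy = float(np.clip(anchor[1] + jitter[1], 0, sh))
            else:
                cx, cy = float(rng.uniform(0, sw)), float(rng.uniform(0, sh))
        viewports.append(make_viewport(zi, cx, cy, t))
    return ViewportLog(interpretation_id=interpretation_id,
                       pathologist_id=pathologist_id, case_id=case_id,
                       viewports=viewports)
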