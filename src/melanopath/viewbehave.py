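"""Pathologist viewport-tracking analytics.

A viewing session is an ordered sequence of viewports (visible rectangle,
zoom multiplier, timestamp).  Seven summary variables describe one
interpretation: total interpretation time, average/maximum/variance of zoom,
magnification percentage (share of transitions that zoom in), scanning
percentage (share of transitions that pan at fixed zoom), and the percentage
of time spent on viewports intersecting expert consensus ROIs.  Their
association with diagnostic accuracy is estimated with a logistic
mixed-effects model (random intercept per pathologist), adjusting for
experience covariates; the behavior variable is z-scored so the odds ratio
is per standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Polygon

__all__ = [
    "Viewport", "ViewportLog", "BehaviorSummary", "AssociationResult",
    "viewport_durations", "total_time", "zoom_stats", "magnification_pct",
    "scanning_pct", "roi_time_pct", "summarize", "fit_association",
    "accuracy_outcome", "DIAGNOSTIC_CLASSES",
]

DIAGNOSTIC_CLASSES = (
    "mildly atypical nevus",
    "advanced atypical precursor",
    "melanoma in situ",
    "invasive melanoma",
)


@dataclass(frozen=True)
class Viewport:
    """One visible slide rectangle [x, x+width) x [y, y+height)."""

    x: float
    y: float
    width: float
    height: float
    zoom: float
    timestamp_s: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("viewport must have positive width and height")
        if self.zoom <= 0:
            raise ValueError("zoom must be positive")

    @property
    def rect(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.x + self.width, self.y + self.height)


@dataclass
class ViewportLog:
    interpretation_id: str
    pathologist_id: str
    case_id: str
    viewports: list[Viewport]

    def __post_init__(self):
        if not self.viewports:
            raise ValueError("a viewport log needs at least one viewport")
        ts = [v.timestamp_s for v in self.viewports]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("timestamps must be strictly increasing")


@dataclass(frozen=True)
class BehaviorSummary:
    total_time: float
    avg_zoom: float
    max_zoom: float
    zoom_variance: float
    magnification_pct: float
    scanning_pct: float
    roi_time_pct: float

    def __post_init__(self):
        if self.max_zoom < self.avg_zoom:
            raise ValueError("max zoom below average zoom")
        for name in ("magnification_pct", "scanning_pct", "roi_time_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 100]")

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


@dataclass(frozen=True)
class AssociationResult:
    variable: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self):
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("odds ratio outside its confidence interval")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")


# -- per-log summaries --------------------------------------------------------

def viewport_durations(log: ViewportLog) -> np.ndarray:
    """Seconds each viewport stayed on screen; the final viewport gets 0."""
    ts = np.array([v.timestamp_s for v in log.viewports])
    return np.append(np.diff(ts), 0.0)


def total_time(log: ViewportLog) -> float:
    ts = [v.timestamp_s for v in log.viewports]
    return float(ts[-1] - ts[0])


def zoom_stats(log: ViewportLog) -> tuple[float, float, float]:
    """(mean, max, population variance) of per-viewport zoom levels."""
    z = np.array([v.zoom for v in log.viewports])
    return float(z.mean()), float(z.max()), float(z.var())


def _transitions(log: ViewportLog):
    return list(zip(log.viewports, log.viewports[1:]))


def magnification_pct(log: ViewportLog) -> float:
    """Percent of transitions whose zoom strictly increases."""
    trans = _transitions(log)
    if not trans:
        return 0.0
    n_in = sum(b.zoom > a.zoom for a, b in trans)
    return 100.0 * n_in / len(trans)


def scanning_pct(log: ViewportLog) -> float:
    """Percent of transitions that pan (move) at an unchanged zoom level."""
    trans = _transitions(log)
    if not trans:
        return 0.0
    n_scan = sum(b.zoom == a.zoom and
                 (b.x, b.y, b.width, b.height) != (a.x, a.y, a.width, a.height)
                 for a, b in trans)
    return 100.0 * n_scan / len(trans)


def _as_polygon(roi) -> Polygon:
    poly = roi if isinstance(roi, Polygon) else Polygon(roi)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("malformed ROI polygon")
    return poly


def roi_time_pct(log: ViewportLog, rois) -> float:
    """Percent of interpretation time on viewports overlapping any ROI.

    Overlap means positive intersection area between the viewport rectangle
    and an ROI polygon.
    """
    polys = [_as_polygon(r) for r in rois]
    tt = total_time(log)
    if tt == 0:
        return 0.0
    durations = viewport_durations(log)
    xs = np.array([v.x for v in log.viewports])
    ys = np.array([v.y for v in log.viewports])
    ws = np.array([v.width for v in log.viewports])
    hs = np.array([v.height for v in log.viewports])
    rects = shapely.box(xs, ys, xs + ws, ys + hs)
    overlaps = np.zeros(len(rects), dtype=bool)
    for poly in polys:
        overlaps |= shapely.area(shapely.intersection(rects, poly)) > 0
    return 100.0 * float(durations[overlaps].sum()) / tt


def summarize(log: ViewportLog, rois) -> BehaviorSummary:
    avg_z, max_z, var_z = zoom_stats(log)
    return BehaviorSummary(
        total_time=total_time(log),
        avg_zoom=avg_z,
        max_zoom=max_z,
        zoom_variance=var_z,
        magnification_pct=magnification_pct(log),
        scanning_pct=scanning_pct(log),
        roi_time_pct=roi_time_pct(log, rois),
    )


# -- accuracy outcome and mixed-model association -----------------------------

def accuracy_outcome(diagnosis: str, consensus: str,
                     categories=DIAGNOSTIC_CLASSES) -> int:
    """1 if the diagnosis agrees with the consensus reference, else 0."""
    for lab in (diagnosis, consensus):
        if lab not in categories:
            raise ValueError(f"unknown diagnostic label: {lab!r}")
    return int(diagnosis == consensus)


def fit_association(cohort: pd.DataFrame, variable: str,
                    covariates=("experience_years", "board_certified"),
                    group: str = "pathologist_id") -> AssociationResult:
    """Adjusted odds ratio of one behavior variable for diagnostic accuracy.

    Fits a logistic mixed model (variational Bayes):
    ``accuracy ~ z(variable) + covariates`` with a random intercept per
    pathologist.  The behavior variable is standardized, so the returned
    odds ratio is per one standard deviation of the predictor.
    """
    if variable not in cohort.columns:
        raise ValueError(f"variable {variable!r} not in cohort")
    x = cohort[variable].to_numpy(dtype=float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"predictor {variable!r} has zero variance")
    data = cohort.copy()
    data["_zvar"] = (x - x.mean()) / sd

    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    formula = "accuracy ~ _zvar + " + " + ".join(covariates)
    model = BinomialBayesMixedGLM.from_formula(
        formula, {"pathologist": f"0 + C({group})"}, data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit_vb()
    names = list(result.model.exog_names)
    idx = names.index("_zvar")
    beta = float(result.fe_mean[idx])
    se = float(result.fe_sd[idx])
    if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
        raise RuntimeError("mixed-model fit did not converge to finite estimates")
    z = beta / se
    return AssociationResult(
        variable=variable,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=float(2.0 * stats.norm.sf(abs(z))),
    )
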