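"""Simulated interpretation cohorts with a known accuracy-generating model.

Each row is one pathologist-case interpretation: the seven viewing-behavior
summaries of a freshly simulated viewport log, pathologist experience
covariates, and a binary accuracy outcome drawn from a logistic model

    logit P(correct) = intercept + beta * z(effect_variable) + u_pathologist

with a Gaussian random intercept per pathologist.  Because the true
coefficient is planted, the cohort is a ground-truth fixture for the
mixed-model association estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from shapely.geometry import box as shapely_box

from ..viewbehave import BehaviorSummary, summarize
from .viewports import BehaviorParams, gen_viewport_log

__all__ = ["CohortSpec", "gen_interpretation_cohort"]

SLIDE_EXTENT = (4096.0, 3072.0)


@dataclass(frozen=True)
class CohortSpec:
    n_pathologists: int = 10
    n_cases: int = 36
    effect_variable: str = "total_time"
    beta: float = 0.0
    intercept: float = 0.0
    pathologist_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_pathologists * self.n_cases < 1:
            raise ValueError("cohort must contain at least one interpretation")
        if self.pathologist_sd < 0:
            raise ValueError("pathologist_sd must be non-negative")
        if self.effect_variable not in BehaviorSummary.field_names():
            raise ValueError(f"unknown behavior variable {self.effect_variable!r}")


def _case_roi(rng) -> list:
    """One rectangular consensus ROI per case, placed at random."""
    sw, sh = SLIDE_EXTENT
    w = rng.uniform(0.1, 0.25) * sw
    h = rng.uniform(0.1, 0.25) * sh
    x = rng.uniform(0, sw - w)
    y = rng.uniform(0, sh - h)
    return [shapely_box(x, y, x + w, y + h)]


def _jittered(base: BehaviorParams, rng, seed: int) -> BehaviorParams:
    """Per-interpretation variation so behavior variables spread realistically."""
    probs = np.array([base.p_zoom_in, base.p_zoom_out, base.p_pan])
    probs = rng.dirichlet(probs * 30.0 + 0.5)
    return replace(
        base,
        p_zoom_in=float(probs[0]), p_zoom_out=float(probs[1]),
        p_pan=float(probs[2]),
        roi_dwell_target=float(np.clip(rng.normal(base.roi_dwell_target, 0.15), 0, 1)),
        mean_step_seconds=float(base.mean_step_seconds * rng.lognormal(0.0, 0.3)),
        n_viewports=max(2, int(rng.poisson(base.n_viewports))),
        seed=seed,
    )


def gen_interpretation_cohort(spec: CohortSpec,
                              params: BehaviorParams | None = None) -> pd.DataFrame:
    """Simulate ``n_pathologists * n_cases`` interpretations."""
    if params is None:
        params = BehaviorParams()
    rng = np.random.default_rng(spec.seed)
    u = rng.normal(0.0, spec.pathologist_sd, size=spec.n_pathologists)
    experience = rng.integers(1, 31, size=spec.n_pathologists)
    certified = rng.integers(0, 2, size=spec.n_pathologists)
    case_rois = [_case_roi(rng) for _ in range(spec.n_cases)]
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(
        spec.n_pathologists * spec.n_cases) % (2 ** 31)

    rows = []
    k = 0
    for p in range(spec.n_pathologists):
        for c in range(spec.n_cases):
            bp = _jittered(params, rng, int(child_seeds[k]))
            log = gen_viewport_log(
                bp, case_rois[c], SLIDE_EXTENT,
                interpretation_id=f"interp-{k}",
                pathologist_id=f"path-{p}", case_id=f"case-{c}")
            summ = summarize(log, case_rois[c])
            row = {"interpretation_id": f"interp-{k}",
                   "pathologist_id": f"path-{p}", "case_id": f"case-{c}"}
            for name in BehaviorSummary.field_names():
                row[name] = getattr(summ, name)
            row["experience_years"] = int(experience[p])
            row["board_certified"] = int(certified[p])
            row["_u"] = u[p]
            rows.append(row)
            k += 1
    df = pd.DataFrame(rows)
    x = df[spec.effect_variable].to_numpy(dtype=float)
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    logit = spec.intercept + spec.beta * z + df.pop("_u").to_numpy()
    prob = 1.0 / (1.0 + np.exp(-logit))
    df["accuracy"] = (rng.random(len(df)) < prob).astype(int)
    return df
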