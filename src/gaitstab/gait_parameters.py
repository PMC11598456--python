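"""Per-step spatiotemporal gait parameters and score correlations.

Definitions
-----------
* maximal CoM velocities: per-step maxima of the absolute mediolateral and
  anterior CoM velocity components;
* step width: mediolateral heel-to-heel distance at the first double-support
  frame of the step;
* step length: anterior heel-to-heel distance at the same frame;
* cadence: 60 / step duration, steps per minute;
* single-support %: fraction of the two-step cycle starting at the step with
  exactly one foot on the ground (requires toe offs);
* minimum foot clearance: lowest toe height above the standing baseline
  during the lead foot's preceding swing, restricted to frames where the
  foot is parallel to the ground (|toe_z - heel_z| below a tolerance).

Velocity, width and length are additionally reported normalised by subject
height when it is known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import GaitStabError
from .gait_geometry import GaitEvents, GaitFrame, differentiate, toe_centre
from .marker_io import MarkerTrialSet
from .pelvis_features import StepSegment, steps_from_events
from .stability import support_schedule

NORMALISED_BY_HEIGHT = ("max_ml_vel", "max_ant_vel", "step_width", "step_length")


def _interp3(times, arr, t):
    return np.array([np.interp(t, times, arr[:, j]) for j in range(3)])


def compute_parameters(trial: MarkerTrialSet, events: GaitEvents, frame: GaitFrame,
                       com: np.ndarray, steps: list[StepSegment] | None = None,
                       parallel_tol: float = 0.005) -> pd.DataFrame:
    """Per-step gait parameters as a data frame (one row per step).

    Single-support percentage and foot clearance need toe-off events; when
    these are missing the columns are reported as NaN and everything else is
    still computed.
    """
    if steps is None:
        steps = steps_from_events(events)
    if not steps:
        raise GaitStabError("no steps available; is the trial stationary?")
    times = trial.times
    vcom_xy = frame.to_xy(differentiate(np.asarray(com, dtype=float), trial.rate))
    heel = {s: trial.markers[f"{s}HEE"] for s in ("L", "R")}
    toe = {s: toe_centre(trial, s) for s in ("L", "R")}
    have_to = bool(events.toe_offs)
    flags = support_schedule(times, events) if have_to else None
    n_down = (flags["L"].astype(int) + flags["R"].astype(int)) if have_to else None
    baseline = {s: float(np.min(toe[s][:, 2])) for s in ("L", "R")}

    rows = []
    for i, step in enumerate(steps):
        lead, trail = step.lead_side, ("R" if step.lead_side == "L" else "L")
        in_step = (times >= step.t_start - 1e-12) & (times < step.t_end - 1e-12)
        if not in_step.any():
            continue
        vx = np.abs(vcom_xy[in_step, 0]).max()
        vy = np.abs(vcom_xy[in_step, 1]).max()
        # first double-support frame = the step-initiating heel contact
        hc = step.t_start
        lead_heel = _interp3(times, heel[lead], hc)
        trail_heel = _interp3(times, heel[trail], hc)
        width = abs((lead_heel - trail_heel) @ frame.mediolateral)
        length = abs((lead_heel - trail_heel) @ frame.anterior)
        cadence = 60.0 / step.duration

        single_pct = np.nan
        if have_to:
            cyc = (times >= step.t_start) & (times < step.t_start + 2.0 * step.duration)
            if cyc.any() and times[-1] >= step.t_start + 2.0 * step.duration - 1.0 / trial.rate:
                single_pct = 100.0 * np.mean(n_down[cyc] == 1)

        clearance = np.nan
        if have_to:
            prior_tos = [t for t, _ in events.toe_offs_for(lead) if t < hc - 1e-9]
            if prior_tos:
                # skip the first 5% of swing: the foot is still pushing off
                # there and both ends sit near the floor
                t_on = prior_tos[-1] + 0.05 * (hc - prior_tos[-1])
                swing = (times > t_on) & (times < hc)
                tz = toe[lead][swing, 2] - baseline[lead]
                hz = heel[lead][swing, 2] - float(np.min(heel[lead][:, 2]))
                par = np.abs(tz - hz) < parallel_tol
                if par.any():
                    clearance = float(np.min(tz[par]))

        rows.append({
            "step_id": step.step_id, "lead_side": lead,
            "t_start": step.t_start, "t_end": step.t_end,
            "max_ml_vel": float(vx), "max_ant_vel": float(vy),
            "step_width": float(width), "step_length": float(length),
            "cadence": float(cadence), "single_support_pct": float(single_pct),
            "min_foot_clearance": clearance,
        })
    df = pd.DataFrame(rows)
    if trial.subject_height:
        for col in NORMALISED_BY_HEIGHT:
            df[f"{col}_norm"] = df[col] / trial.subject_height
    return df


# ---------------------------------------------------------------------------
# score / parameter correlations


@dataclass
class CorrelationTable:
    """Pearson correlations between principal-motion scores and parameters."""

    r: pd.DataFrame         # full correlation coefficients
    p: pd.DataFrame         # two-sided p-values
    masked: pd.DataFrame    # r with entries at p >= alpha hidden (NaN)
    alpha: float


def correlate_scores(scores: np.ndarray, params: pd.DataFrame, alpha: float = 0.05,
                     height: np.ndarray | None = None,
                     columns: list[str] | None = None) -> CorrelationTable:
    """Correlate each score column against each gait parameter.

    When per-sample subject heights are supplied, velocity, width and length
    are divided by height before correlating.  Zero-variance pairs are masked
    with a warning rather than raising.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != len(params):
        raise GaitStabError("scores and parameter table have different lengths")
    if scores.shape[0] < 3:
        raise GaitStabError("need at least 3 paired observations")
    if columns is None:
        columns = [c for c in params.columns
                   if params[c].dtype.kind in "fi" and c not in
                   ("step_id", "t_start", "t_end", "subject_height")
                   and not c.endswith("_norm")]
    work = params[columns].astype(float).copy()
    if height is not None:
        h = np.asarray(height, dtype=float)
        for col in NORMALISED_BY_HEIGHT:
            if col in work.columns:
                work[col] = work[col] / h
    a = scores.shape[1]
    idx = [f"score_{n + 1}" for n in range(a)]
    r = pd.DataFrame(np.nan, index=idx, columns=columns)
    p = pd.DataFrame(np.nan, index=idx, columns=columns)
    for n in range(a):
        s = scores[:, n]
        for col in columns:
            v = work[col].to_numpy()
            ok = np.isfinite(v) & np.isfinite(s)
            if ok.sum() < 3:
                continue
            if np.std(s[ok]) < 1e-15 or np.std(v[ok]) < 1e-15:
                warnings.warn(f"zero-variance pair (score_{n + 1}, {col}); masked", stacklevel=2)
                continue
            rr, pp = sps.pearsonr(s[ok], v[ok])
            r.loc[idx[n], col] = rr
            p.loc[idx[n], col] = pp
    masked = r.where(p < alpha)
    return CorrelationTable(r=r, p=p, masked=masked, alpha=alpha)
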