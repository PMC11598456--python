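"""Extrapolated centre of mass and margin of stability.

The extrapolated centre of mass (XCoM) advances the CoM by its horizontal
velocity divided by the natural frequency ``omega = sqrt(g / l)`` of an
inverted pendulum of length ``l`` (the CoM height above the floor).  The
mediolateral margin is the absolute mediolateral XCoM-to-support-toe
distance; the anterior margin is the signed anterior distance (positive when
the XCoM trails the base of support).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GaitStabError
from .gait_geometry import GaitEvents, GaitFrame, differentiate

#: Standard gravity (m/s^2); configurable in every entry point.
G_DEFAULT = 9.80665


def pendulum_omega(l: float, g: float = G_DEFAULT) -> float:
    """Natural frequency of an inverted pendulum of length ``l``."""
    if l <= 0 or g <= 0:
        raise GaitStabError(f"pendulum length and gravity must be positive (l={l}, g={g})")
    return np.sqrt(g / l)


def xcom(com_xy: np.ndarray, vcom_xy: np.ndarray, l: float, g: float = G_DEFAULT) -> np.ndarray:
    """Extrapolated CoM on the horizontal plane: ``com + vcom / omega``.

    Accepts single 2-vectors or ``(T, 2)`` arrays.
    """
    omega = pendulum_omega(l, g)
    return np.asarray(com_xy, dtype=float) + np.asarray(vcom_xy, dtype=float) / omega


@dataclass
class MoSeries:
    """Per-frame margin-of-stability series in gait-frame coordinates.

    ``bos_xy[:, 0]`` is the mediolateral coordinate of the foot governing the
    mediolateral margin and ``bos_xy[:, 1]`` the anterior coordinate of the
    foot governing the anterior margin (during double support the two rules
    may pick different feet).
    """

    times: np.ndarray
    xcom_xy: np.ndarray     # (T, 2) mediolateral, anterior
    bos_xy: np.ndarray      # (T, 2) composite, see above
    mos_ml: np.ndarray      # (T,)  >= 0
    mos_ap: np.ndarray      # (T,)  signed
    support_phase: np.ndarray   # (T,) of {"L", "R", "double"}
    support_ml: np.ndarray      # (T,) foot used for the mediolateral margin
    support_ap: np.ndarray      # (T,) foot used for the anterior margin
    l: float = np.nan
    g: float = G_DEFAULT


@dataclass
class CriticalMoS:
    """Per-step scalar stability targets."""

    step_id: int
    lead_side: str
    mos_ml_min: float       # minimum mediolateral margin over the step (m)
    mos_ap_hc: float        # anterior margin at the step-initiating heel contact (m)
    t_ml_min_pct: float     # location of the minimum, % of the step
    t_hc: float             # heel-contact time (s)


def support_schedule(times: np.ndarray, events: GaitEvents) -> dict:
    """Boolean on-ground flags per side.

    A foot is on the ground from each of its heel contacts to its next toe
    off.  Before its first event it is treated as grounded iff that first
    event is a toe off; after its last event iff that event is a heel contact.
    """
    flags = {}
    for side in ("L", "R"):
        ev = [(t, "HC") for t, _ in events.contacts(side)]
        ev += [(t, "TO") for t, _ in events.toe_offs_for(side)]
        ev.sort()
        on = np.zeros(times.shape[0], dtype=bool)
        if not ev:
            flags[side] = on
            continue
        if ev[0][1] == "TO":
            on[times < ev[0][0]] = True
        for (t0, kind0), nxt in zip(ev, ev[1:] + [(np.inf, None)]):
            if kind0 == "HC":
                on[(times >= t0) & (times < nxt[0])] = True
        flags[side] = on
    return flags


def mos_series(times: np.ndarray, com: np.ndarray, toes: dict, events: GaitEvents,
               frame: GaitFrame, g: float = G_DEFAULT, l: float | None = None) -> MoSeries:
    """Compute the per-frame margins of stability.

    Parameters
    ----------
    com : (T, 3) filtered CoM positions (metres, ground frame).
    toes : dict with "L" and "R" mapping to (T, 3) toe-centre positions.
    l : float, optional
        Pendulum length; defaults to the trial-mean vertical CoM height.

    Support rules: single support uses the stance foot for both margins;
    during double support the mediolateral margin uses the foot on the side
    of the mediolateral CoM velocity and the anterior margin the leading
    (most anterior) foot.
    """
    times = np.asarray(times, dtype=float)
    com = np.asarray(com, dtype=float)
    if com.shape[0] != times.shape[0]:
        raise GaitStabError("times/com length mismatch")
    rate = 1.0 / np.median(np.diff(times))
    if l is None:
        l = float(np.mean(com[:, 2]))
    omega = pendulum_omega(l, g)

    com_xy = frame.to_xy(com)
    vcom_xy = frame.to_xy(differentiate(com, rate))
    xcom_xy = com_xy + vcom_xy / omega
    toe_xy = {s: frame.to_xy(np.asarray(toes[s], dtype=float)) for s in ("L", "R")}

    flags = support_schedule(times, events)
    n = times.shape[0]
    phase = np.empty(n, dtype=object)
    foot_ml = np.empty(n, dtype=object)
    foot_ap = np.empty(n, dtype=object)
    prev_ml = None
    for i in range(n):
        down = [s for s in ("L", "R") if flags[s][i]]
        if not down:
            raise GaitStabError(f"no support foot derivable at t={times[i]:.3f} s")
        if len(down) == 1:
            phase[i] = down[0]
            foot_ml[i] = foot_ap[i] = down[0]
            prev_ml = down[0]
            continue
        phase[i] = "double"
        vx = vcom_xy[i, 0]
        if vx > 0:
            foot_ml[i] = "L" if toe_xy["L"][i, 0] > toe_xy["R"][i, 0] else "R"
        elif vx < 0:
            foot_ml[i] = "L" if toe_xy["L"][i, 0] < toe_xy["R"][i, 0] else "R"
        else:
            foot_ml[i] = prev_ml or "L"
        foot_ap[i] = "L" if toe_xy["L"][i, 1] > toe_xy["R"][i, 1] else "R"
        prev_ml = foot_ml[i]

    bos_x = np.array([toe_xy[foot_ml[i]][i, 0] for i in range(n)])
    bos_y = np.array([toe_xy[foot_ap[i]][i, 1] for i in range(n)])
    mos_ml = np.abs(bos_x - xcom_xy[:, 0])
    mos_ap = bos_y - xcom_xy[:, 1]
    return MoSeries(times=times, xcom_xy=xcom_xy,
                    bos_xy=np.stack([bos_x, bos_y], axis=-1),
                    mos_ml=mos_ml, mos_ap=mos_ap,
                    support_phase=phase, support_ml=foot_ml, support_ap=foot_ap,
                    l=l, g=g)


def critical_mos(series: MoSeries, steps) -> list[CriticalMoS]:
    """Per-step critical values: the minimum mediolateral margin over the
    step (argmin ties broken to the earliest frame) and the anterior margin
    at the step-initiating heel-contact frame."""
    out = []
    t = series.times
    for step in steps:
        if step.t_start < t[0] - 1e-9 or step.t_end > t[-1] + 1e-9:
            raise GaitStabError(
                f"step [{step.t_start:.3f}, {step.t_end:.3f}] not covered by the series")
        in_step = (t >= step.t_start - 1e-12) & (t < step.t_end - 1e-12)
        if not in_step.any():
            raise GaitStabError("step contains no frames")
        idx = np.flatnonzero(in_step)
        k = idx[np.argmin(series.mos_ml[idx])]
        # anterior margin at the first frame with the lead foot on the
        # ground, i.e. at/after the step-initiating contact
        hc_frame = int(np.searchsorted(t, step.t_start - 1e-9))
        duration = step.t_end - step.t_start
        out.append(CriticalMoS(
            step_id=step.step_id,
            lead_side=step.lead_side,
            mos_ml_min=float(series.mos_ml[k]),
            mos_ap_hc=float(series.mos_ap[hc_frame]),
            t_ml_min_pct=float(100.0 * (t[k] - step.t_start) / duration),
            t_hc=float(step.t_start),
        ))
    return out


def critical_table(criticals: list[CriticalMoS]) -> pd.DataFrame:
    """Tabulate critical values; metres for analysis plus centimetre columns
    for reporting."""
    df = pd.DataFrame([vars(c) for c in criticals])
    if not df.empty:
        df["mos_ml_min_cm"] = 100.0 * df["mos_ml_min"]
        df["mos_ap_hc_cm"] = 100.0 * df["mos_ap_hc"]
    return df
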