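"""Filtering, CoM approximation, pelvis pose, gait frame and event detection.

Conventions
-----------
* The ground-fixed frame is right-handed with +z up (gravity along -z).
* The trial-local *gait frame* is a constant orthonormal triad
  ``(mediolateral, anterior, vertical)`` with ``vertical = +z``,
  ``anterior`` the horizontal walking direction, and
  ``mediolateral = anterior x vertical`` (pointing to the walker's right, so
  that stacking the axes as matrix columns gives determinant +1).
* The pelvis anatomical frame has x to the subject's right (RASIS direction),
  y anterior and z up; its rotation matrix maps pelvis coordinates to the
  ground frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import (
    DegeneratePoseError,
    EventDetectionError,
    GaitStabError,
    SignalLengthError,
)
from .marker_io import MarkerTrialSet, with_sacral_crest

UP = np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# filtering and differentiation


def lowpass(series: np.ndarray, cutoff: float, rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter (forward-backward).

    Parameters
    ----------
    series : (T,) or (T, k) array
    cutoff : float
        Cut-off frequency in Hz; must satisfy ``rate > 2 * cutoff``.
    """
    if rate <= 2 * cutoff:
        raise GaitStabError(f"rate {rate} Hz must exceed twice the cutoff {cutoff} Hz")
    x = np.asarray(series, dtype=float)
    sos = signal.butter(order, cutoff, fs=rate, output="sos")
    padlen = 3 * (2 * order + 1)
    if x.shape[0] <= padlen:
        raise SignalLengthError(
            f"series of length {x.shape[0]} too short for filter warm-up ({padlen + 1} needed)")
    return signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)


def filter_trial(trial: MarkerTrialSet, cutoff: float = 6.0, order: int = 4) -> MarkerTrialSet:
    """Return a copy of ``trial`` with every marker low-pass filtered."""
    out = trial.copy()
    for name, arr in out.markers.items():
        out.markers[name] = lowpass(arr, cutoff, trial.rate, order)
    return out


def differentiate(series: np.ndarray, rate: float) -> np.ndarray:
    """Velocity by central differences (one-sided at the ends)."""
    return np.gradient(np.asarray(series, dtype=float), 1.0 / rate, axis=0)


# ---------------------------------------------------------------------------
# CoM and pelvis pose


def compute_com(trial: MarkerTrialSet) -> np.ndarray:
    """Approximate the body CoM as the centroid of LASIS, RASIS and the
    sacral crest (derived from the PSIS pair when absent)."""
    trial = with_sacral_crest(trial)
    trial.require("LASIS", "RASIS", "SACR")
    m = trial.markers
    return (m["LASIS"] + m["RASIS"] + m["SACR"]) / 3.0


@dataclass
class PelvisPose:
    """Pelvis rigid-body pose per frame.

    ``origin`` is the three-marker centroid; ``rotation[t]`` maps pelvis
    coordinates (x right, y anterior, z up) to the ground frame.
    """

    origin: np.ndarray      # (T, 3)
    rotation: np.ndarray    # (T, 3, 3)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if self.rotation.shape != (self.origin.shape[0], 3, 3):
            raise GaitStabError("pose origin/rotation shape mismatch")


def _unit(v: np.ndarray, axis=-1) -> np.ndarray:
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    return v / n


def pelvis_pose(trial: MarkerTrialSet, min_area: float = 1e-6) -> PelvisPose:
    """Pelvis rigid-body pose from the LASIS/RASIS/SACR triplet.

    The lateral axis (RASIS - LASIS) is kept exact; the vertical axis is
    ``lateral x provisional_anterior`` and the anterior axis closes the
    right-handed triad.
    """
    trial = with_sacral_crest(trial)
    trial.require("LASIS", "RASIS", "SACR")
    la, ra, sa = (trial.markers[k] for k in ("LASIS", "RASIS", "SACR"))
    lateral = ra - la                       # to the subject's right
    mid_asis = 0.5 * (la + ra)
    ant_prov = mid_asis - sa
    cross = np.cross(lateral, ant_prov)
    area = 0.5 * np.linalg.norm(cross, axis=1)
    bad = np.flatnonzero(area <= min_area)
    if bad.size:
        raise DegeneratePoseError(int(bad[0]))
    x = _unit(lateral)
    z = _unit(cross)
    y = np.cross(z, x)
    rotation = np.stack([x, y, z], axis=-1)
    origin = (la + ra + sa) / 3.0
    return PelvisPose(origin=origin, rotation=rotation)


# ---------------------------------------------------------------------------
# gait frame


@dataclass(frozen=True)
class GaitFrame:
    """Constant per-trial gait coordinate triad."""

    anterior: np.ndarray
    mediolateral: np.ndarray
    vertical: np.ndarray

    def as_matrix(self) -> np.ndarray:
        """Axes stacked as columns ``[mediolateral, anterior, vertical]``."""
        return np.stack([self.mediolateral, self.anterior, self.vertical], axis=-1)

    def to_xy(self, points: np.ndarray) -> np.ndarray:
        """Project world points/vectors onto (mediolateral, anterior)."""
        p = np.asarray(points, dtype=float)
        return np.stack([p @ self.mediolateral, p @ self.anterior], axis=-1)


def _frame_from_anterior(direction: np.ndarray) -> GaitFrame:
    horiz = np.asarray(direction, dtype=float).copy()
    horiz[2] = 0.0
    n = np.linalg.norm(horiz)
    if n == 0:
        raise GaitStabError("anterior direction has no horizontal component")
    anterior = horiz / n
    mediolateral = np.cross(anterior, UP)
    return GaitFrame(anterior=anterior, mediolateral=mediolateral, vertical=UP.copy())


def provisional_frame(com: np.ndarray) -> GaitFrame:
    """Gait frame from the net horizontal CoM displacement of the trial.

    Used to bootstrap event detection before heel contacts are known.
    """
    com = np.asarray(com, dtype=float)
    return _frame_from_anterior(com[-1] - com[0])


@dataclass
class GaitEvents:
    """Heel-contact and toe-off times, each a list of ``(time_s, side)``."""

    heel_contacts: list = field(default_factory=list)
    toe_offs: list = field(default_factory=list)

    def __post_init__(self):
        self.heel_contacts = sorted(self.heel_contacts)
        self.toe_offs = sorted(self.toe_offs)
        sides = [s for _, s in self.heel_contacts]
        if any(a == b for a, b in zip(sides, sides[1:])):
            warnings.warn("heel contacts do not alternate sides", stacklevel=2)

    def contacts(self, side: str | None = None) -> list:
        if side is None:
            return list(self.heel_contacts)
        return [(t, s) for t, s in self.heel_contacts if s == side]

    def toe_offs_for(self, side: str) -> list:
        return [(t, s) for t, s in self.toe_offs if s == side]


def gait_frame(times: np.ndarray, com: np.ndarray, events: GaitEvents) -> GaitFrame:
    """Gait frame whose anterior axis joins the CoM positions at the first
    two left heel contacts (horizontal projection, normalised)."""
    lefts = events.contacts("L")
    if len(lefts) < 2:
        raise GaitStabError("need at least two left heel contacts to orient the gait frame")
    com = np.asarray(com, dtype=float)
    t0, t1 = lefts[0][0], lefts[1][0]
    p0 = np.array([np.interp(t0, times, com[:, j]) for j in range(3)])
    p1 = np.array([np.interp(t1, times, com[:, j]) for j in range(3)])
    return _frame_from_anterior(p1 - p0)


# ---------------------------------------------------------------------------
# event detection


def toe_centre(trial: MarkerTrialSet, side: str) -> np.ndarray:
    """Toe point = centre of the 2nd and 3rd metatarsal markers."""
    m2, m3 = f"{side}TOE2", f"{side}TOE3"
    if trial.has(m2, m3):
        return 0.5 * (trial.markers[m2] + trial.markers[m3])
    if trial.has(m2):
        return trial.markers[m2]
    trial.require(m2, m3)
    raise AssertionError("unreachable")


def _detect_relative_position(trial, frame, side, min_step_time, min_excursion):
    """Coordinate-based detection: heel contact at the peak anterior heel
    excursion relative to the pelvis centroid, toe off at the trough of the
    toe excursion.  Run on unfiltered markers; accurate to about one frame on
    smooth data."""
    com = compute_com(trial)
    heel = trial.markers[f"{side}HEE"]
    toe = toe_centre(trial, side)
    rel_heel = (heel - com) @ frame.anterior
    rel_toe = (toe - com) @ frame.anterior
    distance = max(2, int(1.2 * min_step_time * trial.rate))
    if np.ptp(rel_heel) < min_excursion:
        return [], []
    hc_idx, _ = signal.find_peaks(rel_heel, distance=distance,
                                  prominence=0.25 * np.ptp(rel_heel))
    to_idx, _ = signal.find_peaks(-rel_toe, distance=distance,
                                  prominence=0.25 * np.ptp(rel_toe))
    t = trial.times
    return list(t[hc_idx]), list(t[to_idx])


def _detect_height_velocity(trial, frame, side, min_step_time,
                            hc_vel_threshold, to_vel_threshold, height_tol=0.001):
    """Threshold detection: heel contact where the heel height settles onto
    its floor level (within ``height_tol``) while the heel's anterior
    velocity is below ``hc_vel_threshold``; toe off where the toe vertical
    velocity rises through ``to_vel_threshold``.  Less precise than the
    coordinate-based method but robust to missing pelvis markers."""
    heel = trial.markers[f"{side}HEE"]
    toe = toe_centre(trial, side)
    rate = trial.rate
    distance = max(2, int(1.2 * min_step_time * rate))
    heel_z = heel[:, 2]
    heel_v_ant = differentiate(heel, rate) @ frame.anterior
    if np.ptp(heel_z) <= 4.0 * height_tol:
        return [], []
    floor = np.percentile(heel_z, 5)
    below = heel_z <= floor + height_tol
    down = np.flatnonzero(~below[:-1] & below[1:]) + 1
    hc_idx, last = [], -distance
    for i in down:
        if i - last >= distance and heel_v_ant[i] < hc_vel_threshold:
            hc_idx.append(i)
            last = i
    toe_vz = differentiate(toe, rate)[:, 2]
    crossings = np.flatnonzero((toe_vz[:-1] < to_vel_threshold) & (toe_vz[1:] >= to_vel_threshold))
    to_idx, last = [], -distance
    for i in crossings:
        if i - last >= distance:
            to_idx.append(i)
            last = i
    t = trial.times
    return list(t[hc_idx]), list(t[to_idx])


def detect_events(trial: MarkerTrialSet, frame: GaitFrame, *,
                  method: str = "relative_position",
                  sidecar: GaitEvents | None = None,
                  min_step_time: float = 0.35,
                  min_excursion: float = 0.15,
                  hc_vel_threshold: float = 0.2,
                  to_vel_threshold: float = 0.1) -> GaitEvents:
    """Detect heel contacts and toe offs from heel/toe markers.

    ``sidecar`` events, when given, are returned verbatim and detection is
    skipped entirely.
    """
    if sidecar is not None:
        return sidecar
    trial.require("LHEE", "RHEE")
    hcs, tos = [], []
    for side in ("L", "R"):
        if method == "relative_position":
            h, t = _detect_relative_position(trial, frame, side, min_step_time, min_excursion)
        elif method == "height_velocity":
            h, t = _detect_height_velocity(trial, frame, side, min_step_time,
                                           hc_vel_threshold, to_vel_threshold)
        else:
            raise GaitStabError(f"unknown event detection method {method!r}")
        hcs += [(ti, side) for ti in h]
        tos += [(ti, side) for ti in t]
    if not hcs:
        raise EventDetectionError(f"no heel contacts found in trial {trial.trial_id!r}")
    return GaitEvents(heel_contacts=hcs, toe_offs=tos)


# ---------------------------------------------------------------------------
# event sidecar files


def read_events_csv(path) -> GaitEvents:
    """Read an events sidecar CSV with columns ``time_s,side,event``
    (event in {HC, TO})."""
    import pandas as pd

    df = pd.read_csv(path)
    hcs = [(float(r.time_s), str(r.side)) for r in df.itertuples() if r.event == "HC"]
    tos = [(float(r.time_s), str(r.side)) for r in df.itertuples() if r.event == "TO"]
    return GaitEvents(heel_contacts=hcs, toe_offs=tos)


def write_events_csv(events: GaitEvents, path) -> None:
    import pandas as pd

    rows = [{"time_s": t, "side": s, "event": "HC"} for t, s in events.heel_contacts]
    rows += [{"time_s": t, "side": s, "event": "TO"} for t, s in events.toe_offs]
    pd.DataFrame(rows).sort_values("time_s").to_csv(path, index=False, float_format="%.9g")
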