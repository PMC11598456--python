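"""Ground-truth-bearing synthetic inputs.

Two generators:

* :func:`make_walker` -- an analytic periodic walker emitting pelvis, heel
  and toe marker trajectories together with exact event times, the CoM path
  and independently evaluated per-step critical stability margins.  The
  margins are computed here directly from the commanded closed-form
  trajectories (dense grid, analytic velocities), completely bypassing the
  pipeline modules, so they can serve as an oracle for them.
* :func:`make_latent_dataset` -- feature/target pairs with a shared mean
  waveform plus a few orthonormal smooth latent "motions" whose scores
  linearly determine the target; exactly the structure the supervised
  principal-motion regression assumes.

Default walker magnitudes sit near typical comfortable-pace elderly gait
(step length 0.63 m, width 0.15 m, cadence 118 steps/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GaitStabError
from .gait_geometry import GaitEvents
from .marker_io import MarkerTrialSet
from .stability import G_DEFAULT

# pelvis marker positions in the body frame (x right, y anterior, z up);
# the ASIS pair and the PSIS midpoint sum to zero so the marker centroid
# coincides with the commanded CoM path exactly.
_R_LASIS = np.array([-0.12, 0.05, 0.0])
_R_RASIS = np.array([0.12, 0.05, 0.0])
_R_LPSIS = np.array([-0.06, -0.10, 0.0])
_R_RPSIS = np.array([0.06, -0.10, 0.0])


@dataclass
class WalkerSpec:
    """Commanded kinematics of the analytic walker."""

    step_length: float = 0.63       # m, anterior distance per step
    step_width: float = 0.15        # m, lateral heel-to-heel distance
    cadence: float = 118.0          # steps/min
    com_height: float = 0.90        # m, mean CoM height above the floor
    lateral_sway_amp: float = 0.02  # m
    vertical_bounce_amp: float = 0.015  # m
    pelvis_yaw_amp: float = 0.10    # rad
    pelvis_roll_amp: float = 0.06   # rad
    pelvis_pitch_amp: float = 0.04  # rad
    heading: float = 0.0            # rad, walking direction in the world frame
    n_steps: int = 10
    rate: float = 200.0             # Hz
    seed: int = 0
    # secondary geometry
    double_support_frac: float = 0.15   # of one step duration
    heel_lead: float = 0.19         # m, heel ahead of the CoM at contact
    foot_length: float = 0.15       # m, heel-to-toe anterior offset
    heel_lift: float = 0.05         # m, peak heel rise during swing
    toe_lift: float = 0.05          # m, toe swing hump scale
    toe_dip: float = 0.6            # mid-swing dip factor of the toe hump
    toe_land: float = 0.02          # m, toe height at heel contact
    marker_noise_sd: float = 0.0    # m, optional white marker noise

    def validate(self):
        if min(self.step_length, self.step_width, self.cadence, self.com_height,
               self.rate, self.foot_length) <= 0:
            raise GaitStabError("walker lengths, cadence and rate must be positive")
        if self.n_steps < 2:
            raise GaitStabError("need at least 2 steps")
        if not 0.0 < self.double_support_frac < 0.5:
            raise GaitStabError("double_support_frac must lie in (0, 0.5)")
        if self.heel_lead <= 0 or self.heel_lead + self.foot_length >= self.step_length + 0.3:
            raise GaitStabError("foot placement overlaps the next step")


@dataclass
class WalkerTruth:
    """Everything the generator knows exactly."""

    events: GaitEvents
    com: np.ndarray             # (T, 3) world CoM path on the frame grid
    vcom: np.ndarray            # (T, 3) analytic CoM velocity
    six_axis: np.ndarray        # (T, 6) pelvic velocities on the gait axes
    critical: pd.DataFrame      # per-step mos_ml_min / mos_ap_hc / timing
    anterior: np.ndarray        # world anterior unit vector
    l: float                    # pendulum length used for the margins
    omega: float
    params: dict                # commanded per-step parameter values
    spec: WalkerSpec = field(repr=False, default=None)


def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_series(psi, theta, rho):
    """Stacked Rz(psi) @ Rx(theta) @ Ry(rho)."""
    cz, sz = np.cos(psi), np.sin(psi)
    cx, sx = np.cos(theta), np.sin(theta)
    cy, sy = np.cos(rho), np.sin(rho)
    n = psi.shape[0]
    rz = np.zeros((n, 3, 3))
    rz[:, 0, 0], rz[:, 0, 1] = cz, -sz
    rz[:, 1, 0], rz[:, 1, 1] = sz, cz
    rz[:, 2, 2] = 1.0
    rx = np.zeros((n, 3, 3))
    rx[:, 0, 0] = 1.0
    rx[:, 1, 1], rx[:, 1, 2] = cx, -sx
    rx[:, 2, 1], rx[:, 2, 2] = sx, cx
    ry = np.zeros((n, 3, 3))
    ry[:, 0, 0], ry[:, 0, 2] = cy, sy
    ry[:, 1, 1] = 1.0
    ry[:, 2, 0], ry[:, 2, 2] = -sy, cy
    return rz @ rx @ ry


class _Schedule:
    """Contact / toe-off timing and closed-form trajectories."""

    def __init__(self, spec: WalkerSpec):
        self.spec = spec
        self.t_step = 60.0 / spec.cadence
        self.stride = 2.0 * self.t_step
        self.speed = spec.step_length / self.t_step
        self.ds = spec.double_support_frac * self.t_step
        self.stance = self.t_step + self.ds
        self.t_swing = self.t_step - self.ds
        if self.t_swing <= 0:
            raise GaitStabError("double support leaves no swing time")
        self.t_l0 = 1.5 * self.t_step                  # first left heel contact
        self.t_total = self.t_l0 + (spec.n_steps + 1.5) * self.t_step
        # generous contact schedule so feet are defined over the whole window
        ks = np.arange(-3, spec.n_steps + 4)
        self.contacts = {
            "L": self.t_l0 + 2.0 * ks * self.t_step,
            "R": self.t_l0 + (2.0 * ks + 1.0) * self.t_step,
        }
        self.lat = {"L": -spec.step_width / 2.0, "R": spec.step_width / 2.0}
        # constant fraction of swing velocity above the CoM speed, chosen so
        # the heel's anterior velocity meets the CoM speed exactly at contact
        self.b_swing = 2.0 * self.speed * self.stance / self.t_swing

    def tau(self, t):
        return np.asarray(t, dtype=float) - self.t_l0

    # CoM path (local coordinates: x right, y anterior, z up) --------------
    def com_local(self, t):
        sp = self.spec
        tau = self.tau(t)
        ph = 2.0 * np.pi * tau / self.stride
        x = -sp.lateral_sway_amp * np.sin(ph)
        y = self.speed * tau
        z = sp.com_height - sp.vertical_bounce_amp * np.cos(2.0 * ph)
        return np.stack([x, y, z], axis=-1)

    def vcom_local(self, t):
        sp = self.spec
        tau = self.tau(t)
        ph = 2.0 * np.pi * tau / self.stride
        dph = 2.0 * np.pi / self.stride
        vx = -sp.lateral_sway_amp * dph * np.cos(ph)
        vy = np.full_like(tau, self.speed)
        vz = 2.0 * sp.vertical_bounce_amp * dph * np.sin(2.0 * ph)
        return np.stack([vx, vy, vz], axis=-1)

    # pelvis orientation ---------------------------------------------------
    def angles(self, t):
        sp = self.spec
        ph = 2.0 * np.pi * self.tau(t) / self.stride
        psi = sp.pelvis_yaw_amp * np.sin(ph)
        theta = sp.pelvis_pitch_amp * np.sin(2.0 * ph + 0.3)
        rho = sp.pelvis_roll_amp * np.sin(ph + 0.5 * np.pi)
        return psi, theta, rho

    def angle_rates(self, t):
        sp = self.spec
        ph = 2.0 * np.pi * self.tau(t) / self.stride
        dph = 2.0 * np.pi / self.stride
        dpsi = sp.pelvis_yaw_amp * dph * np.cos(ph)
        dtheta = 2.0 * sp.pelvis_pitch_amp * dph * np.cos(2.0 * ph + 0.3)
        drho = sp.pelvis_roll_amp * dph * np.cos(ph + 0.5 * np.pi)
        return dpsi, dtheta, drho

    def omega_local(self, t):
        """Analytic pelvis angular velocity in local coordinates."""
        psi, theta, _ = self.angles(t)
        dpsi, dtheta, drho = self.angle_rates(t)
        cz, sz = np.cos(psi), np.sin(psi)
        cx, sx = np.cos(theta), np.sin(theta)
        # w = dpsi*z + Rz(psi)(dtheta*x) + Rz(psi)Rx(theta)(drho*y)
        wx = dtheta * cz - drho * sz * cx
        wy = dtheta * sz + drho * cz * cx
        wz = dpsi + drho * sx
        return np.stack([wx, wy, wz], axis=-1)

    # feet -----------------------------------------------------------------
    def placement_y(self, contact_time):
        return self.speed * (contact_time - self.t_l0) + self.spec.heel_lead

    def foot_local(self, side, t):
        """Heel and toe-centre trajectories of one foot (local coords)."""
        sp = self.spec
        t = np.asarray(t, dtype=float)
        cs = self.contacts[side]
        i = np.clip(np.searchsorted(cs, t, side="right") - 1, 0, cs.size - 2)
        c = cs[i]
        off = c + self.stance                        # toe-off time
        swing = t >= off
        u = np.clip((t - off) / self.t_swing, 0.0, 1.0)
        y0 = self.placement_y(c)
        # anterior: placement during stance, commanded profile during swing
        y = np.where(swing,
                     y0 + self.speed * (t - off)
                     + self.b_swing * self.t_swing * (u / 2.0 - np.sin(2.0 * np.pi * u) / (4.0 * np.pi)),
                     y0)
        heel_z = np.where(swing, sp.heel_lift * np.sin(np.pi * np.sqrt(u)) ** 2, 0.0)
        s_u = np.sin(np.pi * u) ** 2
        smooth = u * u * (3.0 - 2.0 * u)
        toe_z_sw = sp.toe_lift * s_u * (1.0 - sp.toe_dip * s_u) + sp.toe_land * smooth
        # early stance: lower the toe from its landing height to the floor
        ts = np.clip((t - c) / self.ds, 0.0, 1.0)
        toe_z_st = sp.toe_land * (1.0 - ts * ts * (3.0 - 2.0 * ts))
        toe_z = np.where(swing, toe_z_sw, toe_z_st)
        x = np.full_like(t, self.lat[side])
        heel = np.stack([x, y, heel_z], axis=-1)
        toe = np.stack([x, y + sp.foot_length, toe_z], axis=-1)
        return heel, toe


def make_walker(spec: WalkerSpec | None = None, g: float = G_DEFAULT):
    """Generate a marker trial and its ground truth.

    Returns ``(MarkerTrialSet, WalkerTruth)``.
    """
    spec = spec or WalkerSpec()
    spec.validate()
    sch = _Schedule(spec)
    n_frames = int(np.floor(sch.t_total * spec.rate)) + 1
    t = np.arange(n_frames) / spec.rate
    rz_head = _rz(spec.heading)

    com_loc = sch.com_local(t)
    vcom_loc = sch.vcom_local(t)
    psi, theta, rho = sch.angles(t)
    r_loc = _rot_series(psi, theta, rho)
    r_world = rz_head[None] @ r_loc
    com_w = com_loc @ rz_head.T
    vcom_w = vcom_loc @ rz_head.T

    markers = {}
    for name, rvec in (("LASIS", _R_LASIS), ("RASIS", _R_RASIS),
                       ("LPSIS", _R_LPSIS), ("RPSIS", _R_RPSIS)):
        markers[name] = com_w + np.einsum("tij,j->ti", r_world, rvec)
    for side in ("L", "R"):
        heel, toe = sch.foot_local(side, t)
        lat_off = np.array([0.012 if side == "R" else -0.012, 0.0, 0.0])
        markers[f"{side}HEE"] = heel @ rz_head.T
        markers[f"{side}TOE2"] = (toe + lat_off) @ rz_head.T
        markers[f"{side}TOE3"] = (toe - lat_off) @ rz_head.T
    if spec.marker_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        for name in markers:
            markers[name] = markers[name] + rng.normal(0.0, spec.marker_noise_sd,
                                                       markers[name].shape)
    trial = MarkerTrialSet(markers=markers, rate=spec.rate,
                           trial_id=f"walker_seed{spec.seed}",
                           subject_height=spec.com_height / 0.56,
                           subject_meta={"generator": "walker", "seed": spec.seed})

    # ---- ground truth ----------------------------------------------------
    hcs, tos = [], []
    for side in ("L", "R"):
        for c in sch.contacts[side]:
            if 0.0 < c < sch.t_total:
                hcs.append((float(c), side))
            if 0.0 < c + sch.stance < sch.t_total:
                tos.append((float(c + sch.stance), side))
    events = GaitEvents(heel_contacts=hcs, toe_offs=tos)

    l = float(np.mean(com_loc[:, 2]))
    omega = np.sqrt(g / l)
    # independent margin evaluation on a dense analytic grid
    rows = []
    for i in range(spec.n_steps):
        c0 = sch.t_l0 + i * sch.t_step
        lead = "L" if i % 2 == 0 else "R"
        dense = np.linspace(c0, c0 + sch.t_step, 2001, endpoint=False)
        xcom_x = sch.com_local(dense)[:, 0] + sch.vcom_local(dense)[:, 0] / omega
        bos_x = sch.lat[lead]
        mos_ml = np.abs(bos_x - xcom_x)
        k = int(np.argmin(mos_ml))
        mos_ap_hc = spec.heel_lead + spec.foot_length - sch.speed / omega
        rows.append({
            "step_id": i, "lead_side": lead,
            "t_start": c0, "t_end": c0 + sch.t_step,
            "mos_ml_min": float(mos_ml[k]),
            "t_ml_min_pct": 100.0 * k / dense.size,
            "mos_ap_hc": float(mos_ap_hc),
        })
    critical = pd.DataFrame(rows)

    w_loc = sch.omega_local(t)
    # channel order: roll = about anterior (local y), pitch = about
    # mediolateral (local x), yaw = about vertical
    six = np.column_stack([vcom_loc, w_loc[:, 1], w_loc[:, 0], w_loc[:, 2]])
    params = {
        "step_length": spec.step_length,
        "step_width": spec.step_width,
        "cadence": spec.cadence,
        "speed": sch.speed,
        "single_support_pct": 100.0 * (1.0 - sch.ds / sch.t_step),
        "step_duration": sch.t_step,
        "max_ml_vel": spec.lateral_sway_amp * 2.0 * np.pi / sch.stride,
        "max_ant_vel": sch.speed,
        "t_first_left_hc": sch.t_l0,
    }
    anterior = rz_head @ np.array([0.0, 1.0, 0.0])
    truth = WalkerTruth(events=events, com=com_w, vcom=vcom_w, six_axis=six,
                        critical=critical, anterior=anterior, l=l, omega=float(omega),
                        params=params, spec=spec)
    return trial, truth


# ---------------------------------------------------------------------------
# latent-factor feature/target generator


def default_mean_profile(n_pct: int = 51) -> np.ndarray:
    """A smooth 6 x n_pct mean waveform (low-order Fourier shapes; the
    anterior velocity carries two maxima per cycle)."""
    x = np.linspace(0.0, 1.0, n_pct)
    two_pi = 2.0 * np.pi
    return np.stack([
        0.08 * np.sin(two_pi * x),                                   # vx
        1.30 + 0.12 * np.cos(2.0 * two_pi * x) + 0.05 * np.sin(two_pi * x),  # vy
        0.10 * np.sin(2.0 * two_pi * x + 0.8),                       # vz
        0.25 * np.sin(two_pi * x + 1.1),                             # roll
        0.20 * np.sin(2.0 * two_pi * x + 0.4),                       # pitch
        0.45 * np.sin(two_pi * x - 0.6),                             # yaw
    ])


@dataclass
class LatentSpec:
    """Latent-factor dataset: X = mean + scores @ loadings + noise,
    y = scores @ coeffs + eps."""

    n_samples: int = 600
    n_features: int = 306
    n_factors: int = 3
    # the dominant motion carries the least target weight per unit score, so
    # the supervised decomposition genuinely needs all three components
    factor_score_sd: tuple = (3.0, 1.5, 0.75)
    coeffs: tuple = (0.03, 0.06, 0.12)
    x_noise_sd: float = 0.1
    y_noise_sd: float | None = None     # None -> equal to the signal SD (SNR 1)
    n_harmonics: int = 3
    seed: int = 0
    mean_profile: np.ndarray | None = None

    def validate(self):
        if self.n_factors > self.n_features:
            raise GaitStabError("more factors than features")
        if len(self.factor_score_sd) != self.n_factors or len(self.coeffs) != self.n_factors:
            raise GaitStabError("factor_score_sd and coeffs must have n_factors entries")
        if self.x_noise_sd < 0 or (self.y_noise_sd is not None and self.y_noise_sd < 0):
            raise GaitStabError("noise SDs must be non-negative")


@dataclass
class LatentTruth:
    scores: np.ndarray          # (n, f)
    loadings: np.ndarray        # (f, m) orthonormal rows
    beta: np.ndarray            # (f,)
    mean: np.ndarray            # (m,)
    y_noise: np.ndarray         # (n,)
    y_noise_sd: float
    spec: LatentSpec = field(repr=False, default=None)


def _smooth_loadings(rng, n_factors, n_features, n_harmonics):
    """Orthonormal smooth waveforms: random low-order Fourier series per
    channel, orthonormalised by QR (linear combinations stay smooth)."""
    n_pct = 51
    n_channels = max(1, n_features // n_pct)
    x = np.linspace(0.0, 1.0, n_pct)
    raw = np.zeros((n_factors, n_features))
    for f in range(n_factors):
        pieces = []
        for _ in range(n_channels):
            wave = np.zeros(n_pct)
            for h in range(1, n_harmonics + 1):
                wave += rng.normal() * np.cos(2 * np.pi * h * x) + rng.normal() * np.sin(2 * np.pi * h * x)
            pieces.append(wave)
        vec = np.concatenate(pieces)[:n_features]
        if vec.size < n_features:
            vec = np.pad(vec, (0, n_features - vec.size))
        raw[f] = vec
    q, _ = np.linalg.qr(raw.T)
    return q.T[:n_factors]


def make_latent_dataset(spec: LatentSpec | None = None):
    """Generate ``(X_raw, y, LatentTruth)``; seeded and reproducible."""
    spec = spec or LatentSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sds = np.asarray(spec.factor_score_sd, dtype=float)
    beta = np.asarray(spec.coeffs, dtype=float)
    loadings = _smooth_loadings(rng, spec.n_factors, spec.n_features, spec.n_harmonics)
    mean = spec.mean_profile
    if mean is None:
        mean = default_mean_profile()
    mean = np.asarray(mean, dtype=float).ravel()[: spec.n_features]
    if mean.size < spec.n_features:
        mean = np.pad(mean, (0, spec.n_features - mean.size))

    scores = rng.normal(0.0, 1.0, (spec.n_samples, spec.n_factors)) * sds
    X = mean + scores @ loadings
    if spec.x_noise_sd > 0:
        X = X + rng.normal(0.0, spec.x_noise_sd, X.shape)
    signal_sd = float(np.sqrt(np.sum((beta * sds) ** 2)))
    y_noise_sd = signal_sd if spec.y_noise_sd is None else float(spec.y_noise_sd)
    eps = rng.normal(0.0, y_noise_sd, spec.n_samples) if y_noise_sd > 0 else np.zeros(spec.n_samples)
    y = scores @ beta + eps
    truth = LatentTruth(scores=scores, loadings=loadings, beta=beta, mean=mean,
                        y_noise=eps, y_noise_sd=y_noise_sd, spec=spec)
    return X, y, truth
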