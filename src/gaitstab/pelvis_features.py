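"""Six-axis pelvic velocity features, one 306-vector per step.

A step runs between successive contralateral heel contacts.  Its six pelvic
velocity channels (three translational, three angular, expressed on the
constant gait-frame axes) are linearly resampled onto the 51 integer
percentages 0..50 of the gait cycle and concatenated channel-wise::

    [vx_0..vx_50, vy_0..vy_50, vz_0..vz_50,
     wroll_0..wroll_50, wpitch_0..wpitch_50, wyaw_0..wyaw_50]

For right-lead steps (the 50-100% half of the cycle under a left-first
convention) the mediolateral velocity, roll rate and yaw rate change sign so
that left- and right-lead steps share one model.  Columns are finally
z-scored; test data reuses training statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import GaitStabError, SignalLengthError, ZeroVarianceError
from .gait_geometry import GaitEvents, GaitFrame, PelvisPose, differentiate

CHANNELS = ("vx", "vy", "vz", "wroll", "wpitch", "wyaw")
N_PCT = 51
N_FEATURES = N_PCT * len(CHANNELS)   # 306

#: Column ranges of the translational / angular channel subsets.
CHANNEL_SUBSETS = {
    "six_axis": slice(0, N_FEATURES),
    "translational": slice(0, 3 * N_PCT),
    "angular": slice(3 * N_PCT, N_FEATURES),
}

#: Channels negated by the laterality flip.
FLIP_CHANNELS = ("vx", "wroll", "wyaw")


def feature_index() -> list[str]:
    """Ordered column labels, e.g. ``vx_00 ... wyaw_50``."""
    return [f"{ch}_{p:02d}" for ch in CHANNELS for p in range(N_PCT)]


# ---------------------------------------------------------------------------
# step segmentation


@dataclass(frozen=True)
class StepSegment:
    """One step: the interval between successive contralateral heel contacts."""

    step_id: int
    t_start: float
    t_end: float
    lead_side: str          # side of the initiating heel contact
    cycle_half: str         # "first" (left lead) or "second" (right lead)

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise GaitStabError("step must have t_end > t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def steps_from_events(events: GaitEvents) -> list[StepSegment]:
    """Build steps from consecutive alternating heel contacts.

    Consecutive same-side contacts (a missed detection) break the chain with
    a warning; the following contact starts a fresh step.
    """
    contacts = events.contacts()
    steps = []
    for i, ((t0, s0), (t1, s1)) in enumerate(zip(contacts, contacts[1:])):
        if s1 == s0:
            warnings.warn(f"skipping non-alternating contact pair at t={t0:.3f}s", stacklevel=2)
            continue
        steps.append(StepSegment(
            step_id=len(steps), t_start=t0, t_end=t1, lead_side=s0,
            cycle_half="first" if s0 == "L" else "second"))
    return steps


# ---------------------------------------------------------------------------
# six-axis velocities


def _vee(mat: np.ndarray) -> np.ndarray:
    """Axial vector of the antisymmetric part of a stack of 3x3 matrices."""
    a = 0.5 * (mat - mat.transpose(0, 2, 1))
    return np.stack([a[:, 2, 1], a[:, 0, 2], a[:, 1, 0]], axis=-1)


def six_axis_velocity(pose: PelvisPose, frame: GaitFrame, rate: float) -> np.ndarray:
    """Translational and angular pelvis velocities on the gait-frame axes.

    Returns a ``(T, 6)`` array ordered as :data:`CHANNELS`.  The angular
    velocity is the axial vector of ``dR/dt R^T`` (a world-frame vector),
    re-expressed as roll (about anterior), pitch (about mediolateral) and yaw
    (about vertical) rates.
    """
    if pose.origin.shape[0] < 3:
        raise SignalLengthError("need at least 3 frames to differentiate the pose")
    v = differentiate(pose.origin, rate)
    rdot = np.gradient(pose.rotation, 1.0 / rate, axis=0)
    w_world = _vee(rdot @ pose.rotation.transpose(0, 2, 1))
    return np.stack([
        v @ frame.mediolateral,
        v @ frame.anterior,
        v @ frame.vertical,
        w_world @ frame.anterior,      # roll
        w_world @ frame.mediolateral,  # pitch
        w_world @ frame.vertical,      # yaw
    ], axis=-1)


# ---------------------------------------------------------------------------
# per-step profiles


@dataclass
class SixAxisProfile:
    """Six velocity channels sampled at 0,1,...,50% of the step."""

    v: np.ndarray           # (3, 51) translational, gait-frame x/y/z
    w: np.ndarray           # (3, 51) roll/pitch/yaw rates
    lead_side: str = "L"
    step_id: int = -1

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.v.shape != (3, N_PCT) or self.w.shape != (3, N_PCT):
            raise GaitStabError(f"profile channels must be 3 x {N_PCT}")
        if not (np.isfinite(self.v).all() and np.isfinite(self.w).all()):
            raise GaitStabError("profile contains non-finite values")

    def vector(self) -> np.ndarray:
        """Concatenate channels into the 306-element feature vector."""
        return np.concatenate([self.v.ravel(), self.w.ravel()])


def resample_step(series: np.ndarray, step: StepSegment, rate: float,
                  t0: float = 0.0) -> SixAxisProfile:
    """Linearly interpolate a ``(T, 6)`` velocity series onto 51 equally
    spaced instants spanning the step (both endpoints included)."""
    series = np.asarray(series, dtype=float)
    times = t0 + np.arange(series.shape[0]) / rate
    if step.t_start < times[0] - 1e-9 or step.t_end > times[-1] + 1e-9:
        raise GaitStabError(
            f"step [{step.t_start:.3f}, {step.t_end:.3f}] outside series span "
            f"[{times[0]:.3f}, {times[-1]:.3f}]")
    grid = np.linspace(step.t_start, step.t_end, N_PCT)
    sampled = np.stack([np.interp(grid, times, series[:, c]) for c in range(6)])
    return SixAxisProfile(v=sampled[:3], w=sampled[3:],
                          lead_side=step.lead_side, step_id=step.step_id)


def laterality_flip(profile: SixAxisProfile, step: StepSegment | None = None) -> SixAxisProfile:
    """Cancel laterality: negate vx, roll and yaw for second-half
    (right-lead) steps.  First-half steps pass through unchanged; applying
    the flip twice restores the original profile."""
    half = step.cycle_half if step is not None else ("second" if profile.lead_side == "R" else "first")
    if half != "second":
        return replace(profile, v=profile.v.copy(), w=profile.w.copy())
    v = profile.v.copy()
    w = profile.w.copy()
    v[0] = -v[0]    # vx
    w[0] = -w[0]    # roll
    w[2] = -w[2]    # yaw
    return replace(profile, v=v, w=w)


# ---------------------------------------------------------------------------
# feature matrix assembly


def stack_profiles(profiles) -> np.ndarray:
    """Stack profile vectors into a raw (unstandardized) ``(k, 306)`` matrix."""
    if not profiles:
        raise GaitStabError("no profiles to stack")
    return np.stack([p.vector() for p in profiles])


@dataclass
class FeatureStats:
    """Per-column standardization statistics (sample SD, ddof=1)."""

    mean: np.ndarray
    sd: np.ndarray


def fit_stats(X: np.ndarray, labels=None) -> FeatureStats:
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise GaitStabError("need at least 2 samples to fit standardization statistics")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd < 1e-12)
    if zero.size:
        labels = labels or feature_index()
        raise ZeroVarianceError(labels[zero[0]] if zero[0] < len(labels) else str(zero[0]))
    return FeatureStats(mean=mean, sd=sd)


def apply_stats(X: np.ndarray, stats: FeatureStats) -> np.ndarray:
    return (np.asarray(X, dtype=float) - stats.mean) / stats.sd


@dataclass
class FeatureMatrix:
    """Standardized per-step feature matrix with its column labels and the
    statistics used for z-scoring."""

    X: np.ndarray
    feature_labels: list
    stats: FeatureStats

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


def assemble_features(profiles, stats: FeatureStats | None = None) -> FeatureMatrix:
    """Stack profiles and z-score columns.

    When ``stats`` is None the statistics are fitted on the given profiles
    (training); otherwise the supplied training statistics are applied
    (test fold).
    """
    labels = feature_index()
    raw = stack_profiles(profiles)
    if stats is None:
        stats = fit_stats(raw, labels)
    elif raw.shape[1] != stats.mean.shape[0]:
        raise GaitStabError("feature count does not match the supplied statistics")
    return FeatureMatrix(X=apply_stats(raw, stats), feature_labels=labels, stats=stats)
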