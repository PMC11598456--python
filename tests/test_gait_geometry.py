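import numpy as np
import pytest

from gaitstab.errors import (
    DegeneratePoseError,
    EventDetectionError,
    GaitStabError,
    SignalLengthError,
)
from gaitstab.gait_geometry import (
    GaitEvents,
    compute_com,
    detect_events,
    gait_frame,
    lowpass,
    pelvis_pose,
    provisional_frame,
    read_events_csv,
    write_events_csv,
)
from gaitstab.marker_io import MarkerTrialSet
from gaitstab.synthetic_data import WalkerSpec, make_walker
from oracles import butterworth_filtfilt_gain


def _sine_amplitude(x):
    return 0.5 * np.ptp(x[len(x) // 4: -len(x) // 4])


class TestLowpass:
    def test_dc_passes(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(lowpass(x, 6.0, 200.0), x, atol=1e-9)

    def test_passband_sine_preserved(self):
        t = np.arange(4000) / 200.0
        x = np.sin(2 * np.pi * 1.0 * t)
        out = lowpass(x, 6.0, 200.0)
        amp = _sine_amplitude(out)
        assert abs(amp - 1.0) < 0.01
        expected = butterworth_filtfilt_gain(1.0, 6.0, 4)
        assert abs(amp - expected) < 0.01

    def test_stopband_sine_attenuated(self):
        t = np.arange(4000) / 200.0
        x = np.sin(2 * np.pi * 50.0 * t)
        out = lowpass(x, 6.0, 200.0)
        assert np.abs(out[200:-200]).max() < 0.01
        assert butterworth_filtfilt_gain(50.0, 6.0, 4) < 1e-7

    def test_too_short_errors(self):
        with pytest.raises(SignalLengthError):
            lowpass(np.zeros(10), 6.0, 200.0)

    def test_rate_vs_cutoff_guard(self):
        with pytest.raises(GaitStabError):
            lowpass(np.zeros(100), 60.0, 100.0)


class TestComputeCom:
    def test_coincident_points(self):
        p = np.tile([1.0, 2.0, 3.0], (5, 1))
        trial = MarkerTrialSet(markers={"LASIS": p, "RASIS": p, "SACR": p}, rate=100.0)
        np.testing.assert_allclose(compute_com(trial), p)

    def test_centroid_arithmetic(self):
        a = np.tile([0.0, 0.0, 0.0], (2, 1))
        b = np.tile([2.0, 0.0, 0.0], (2, 1))
        c = np.tile([1.0, 3.0, 0.0], (2, 1))
        trial = MarkerTrialSet(markers={"LASIS": a, "RASIS": b, "SACR": c}, rate=100.0)
        np.testing.assert_allclose(compute_com(trial), np.tile([1.0, 1.0, 0.0], (2, 1)))

    def test_walker_matches_generator(self, walker):
        trial, truth = walker
        np.testing.assert_allclose(compute_com(trial), truth.com, atol=1e-12)


def _neutral_pelvis(n=4):
    # body frame: x right, y anterior, z up -> rotation should be identity
    la = np.tile([-0.12, 0.05, 1.0], (n, 1))
    ra = np.tile([0.12, 0.05, 1.0], (n, 1))
    sa = np.tile([0.0, -0.10, 1.0], (n, 1))
    return MarkerTrialSet(markers={"LASIS": la, "RASIS": ra, "SACR": sa}, rate=100.0)


class TestPelvisPose:
    def test_neutral_pose_identity(self):
        pose = pelvis_pose(_neutral_pelvis())
        np.testing.assert_allclose(pose.rotation, np.tile(np.eye(3), (4, 1, 1)), atol=1e-12)

    def test_known_rotation_recovered(self):
        from scipy.spatial.transform import Rotation

        r0 = Rotation.from_euler("zxy", [0.4, -0.2, 0.1]).as_matrix()
        trial = _neutral_pelvis()
        rotated = {k: v @ r0.T for k, v in trial.markers.items()}
        pose = pelvis_pose(MarkerTrialSet(markers=rotated, rate=100.0))
        np.testing.assert_allclose(pose.rotation[0], r0, atol=1e-9)

    def test_degenerate_markers_error(self):
        trial = _neutral_pelvis()
        trial.markers["LASIS"] = trial.markers["RASIS"].copy()
        with pytest.raises(DegeneratePoseError):
            pelvis_pose(trial)

    def test_orthonormal_and_continuous_on_walker(self, walker_processed):
        rot = walker_processed["pose"].rotation
        eye = np.einsum("tij,tkj->tik", rot, rot)
        assert np.abs(eye - np.eye(3)).max() < 1e-8
        np.testing.assert_allclose(np.linalg.det(rot), 1.0, atol=1e-8)
        # frame-to-frame geodesic angle stays well below 10 deg at 200 Hz
        rel = np.einsum("tij,tkj->tik", rot[1:], rot[:-1])
        tr = np.einsum("tii->t", rel)
        ang = np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))
        assert np.degrees(ang).max() < 10.0

    def test_origin_is_centroid(self, walker_processed):
        trial = walker_processed["filtered"]
        pose = walker_processed["pose"]
        np.testing.assert_allclose(pose.origin, compute_com(trial), atol=1e-12)


class TestGaitFrame:
    def _events(self, t0=0.0, t1=1.0):
        return GaitEvents(heel_contacts=[(t0, "L"), (t0 + 0.5, "R"), (t1, "L")])

    def test_advance_along_x(self):
        times = np.linspace(0, 1, 11)
        com = np.stack([times, np.zeros(11), np.ones(11)], axis=-1)
        frame = gait_frame(times, com, self._events())
        np.testing.assert_allclose(frame.anterior, [1, 0, 0], atol=1e-12)

    def test_diagonal_normalised(self):
        times = np.linspace(0, 1, 11)
        com = np.stack([times, times, np.ones(11)], axis=-1)
        frame = gait_frame(times, com, self._events())
        np.testing.assert_allclose(frame.anterior, [0.7071, 0.7071, 0], atol=1e-4)

    def test_right_handed_triad(self):
        times = np.linspace(0, 1, 11)
        com = np.stack([times, 0.3 * times, np.ones(11)], axis=-1)
        frame = gait_frame(times, com, self._events())
        assert abs(np.linalg.det(frame.as_matrix()) - 1.0) < 1e-9
        assert abs(frame.anterior @ frame.mediolateral) < 1e-12
        np.testing.assert_allclose(frame.vertical, [0, 0, 1])

    def test_walker_heading_recovered(self):
        spec = WalkerSpec(cadence=120.0, n_steps=4, heading=np.radians(30.0))
        trial, truth = make_walker(spec)
        frame = gait_frame(trial.times, compute_com(trial), truth.events)
        np.testing.assert_allclose(frame.anterior, truth.anterior, atol=1e-9)

    def test_too_few_left_contacts(self):
        times = np.linspace(0, 1, 11)
        com = np.stack([times, np.zeros(11), np.ones(11)], axis=-1)
        with pytest.raises(GaitStabError):
            gait_frame(times, com, GaitEvents(heel_contacts=[(0.0, "L"), (0.5, "R")]))


class TestDetectEvents:
    def _match_errors(self, detected, truth_events, rate):
        errs = []
        for t, s in detected:
            cand = [abs(t - tt) for tt, ss in truth_events if ss == s]
            errs.append(min(cand) * rate)
        return errs

    def test_walker_contacts_within_one_frame(self, walker):
        trial, truth = walker
        frame = provisional_frame(compute_com(trial))
        events = detect_events(trial, frame)
        errs = self._match_errors(events.heel_contacts, truth.events.heel_contacts, trial.rate)
        assert len(events.heel_contacts) >= len(truth.events.heel_contacts) - 2
        assert max(errs) <= 1.0

    def test_standing_trial_errors(self):
        n = 600
        markers = {}
        for name, pos in (("LASIS", [-0.12, 0.05, 1.0]), ("RASIS", [0.12, 0.05, 1.0]),
                          ("SACR", [0.0, -0.1, 1.0]), ("LHEE", [-0.1, 0.0, 0.0]),
                          ("RHEE", [0.1, 0.0, 0.0]), ("LTOE2", [-0.1, 0.2, 0.0]),
                          ("RTOE2", [0.1, 0.2, 0.0])):
            markers[name] = np.tile(pos, (n, 1))
        trial = MarkerTrialSet(markers=markers, rate=200.0)
        frame = gait_frame(np.arange(n) / 200.0,
                           np.tile([0, 0.001, 1.0], (n, 1)) * np.arange(n)[:, None],
                           GaitEvents(heel_contacts=[(0.1, "L"), (0.6, "R"), (1.1, "L")]))
        with pytest.raises(EventDetectionError):
            detect_events(trial, frame)

    def test_sidecar_override_verbatim(self, walker):
        trial, truth = walker
        frame = provisional_frame(compute_com(trial))
        override = GaitEvents(heel_contacts=[(0.123, "L"), (0.456, "R")])
        out = detect_events(trial, frame, sidecar=override)
        assert out is override

    def test_rotation_invariance(self):
        base = WalkerSpec(cadence=120.0, n_steps=4, heading=0.0)
        rot = WalkerSpec(cadence=120.0, n_steps=4, heading=1.1)
        ev = []
        for spec in (base, rot):
            trial, _ = make_walker(spec)
            frame = provisional_frame(compute_com(trial))
            ev.append(detect_events(trial, frame))
        t0 = sorted(ev[0].heel_contacts)
        t1 = sorted(ev[1].heel_contacts)
        assert len(t0) == len(t1)
        for (a, sa), (b, sb) in zip(t0, t1):
            assert sa == sb and abs(a - b) < 1e-9

    def test_height_velocity_method_close(self, walker):
        trial, truth = walker
        frame = provisional_frame(compute_com(trial))
        # the walker's heel translates anteriorly right up to touchdown, so
        # the velocity gate needs a generous threshold here
        events = detect_events(trial, frame, method="height_velocity",
                               hc_vel_threshold=2.0)
        errs = self._match_errors(events.heel_contacts, truth.events.heel_contacts, trial.rate)
        assert len(events.heel_contacts) >= len(truth.events.heel_contacts) - 2
        assert max(errs) <= 10.0  # looser threshold-based variant


def test_events_csv_round_trip(tmp_path):
    events = GaitEvents(heel_contacts=[(0.5, "L"), (1.0, "R")],
                        toe_offs=[(0.65, "R"), (1.15, "L")])
    path = tmp_path / "events.csv"
    write_events_csv(events, path)
    back = read_events_csv(path)
    assert back.heel_contacts == events.heel_contacts
    assert back.toe_offs == events.toe_offs


def test_non_alternating_contacts_warn():
    with pytest.warns(UserWarning, match="alternate"):
        GaitEvents(heel_contacts=[(0.0, "L"), (0.5, "L")])
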