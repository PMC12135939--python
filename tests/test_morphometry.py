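"""Tests for landmark alignment and heart-loop metrics."""

import numpy as np
import pytest

from asymscreen.morphometry import (HEART_LANDMARKS, LandmarkSet, QCError,
                                    align_to_embryo_frame,
                                    direction_frequency_test, loop_metrics,
                                    looping_direction, rvlv_axis_angle,
                                    tube_length, venous_pole_displacement)
from asymscreen.synthetic import LandmarkSimParams, simulate_landmarks


def canonical_set(**overrides) -> LandmarkSet:
    """A landmark set already expressed in the embryo frame."""
    landmarks = {
        "outflow_exit": (0.5, 0.2, 30.0),
        "OFT": (1.0, -0.5, 22.0),
        "RV": (0.3, -5.0, 15.0),
        "interventricular_sulcus": (0.5, 0.0, 15.0),
        "LV": (0.3, 5.0, 15.0),
        "AVC_LA": (0.2, 1.0, 8.0),
        "RA": (0.1, -1.0, 4.0),
        "venous_pole": (0.0, 2.0, 0.0),
    }
    kwargs = dict(
        landmarks=landmarks,
        notochord_points=np.array([[0, 0, -10.0], [0, 0, 10.0], [0, 0, 30.0]]),
        dorsoventral_ref=np.array([50.0, 0.0, 0.0]),
        somite_count=25,
    )
    kwargs.update(overrides)
    return LandmarkSet(**kwargs)


def random_rigid(rng):
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-500, 500, size=3)


def transform_set(lm: LandmarkSet, rot, shift) -> LandmarkSet:
    return LandmarkSet(
        landmarks={k: rot @ v + shift for k, v in lm.landmarks.items()},
        notochord_points=lm.notochord_points @ rot.T + shift,
        dorsoventral_ref=rot @ lm.dorsoventral_ref + shift,
        somite_count=lm.somite_count,
    )


class TestAlignment:
    def test_identity_on_canonical_frame(self):
        lm = canonical_set()
        aligned = align_to_embryo_frame(lm)
        # frame fixed up to a translation along Z (origin at notochord centroid)
        for name in HEART_LANDMARKS:
            assert aligned.point(name)[:2] == pytest.approx(
                np.asarray(lm.point(name)[:2]), abs=1e-9)

    def test_rigid_jitter_matches_unjittered(self, rng):
        lm = canonical_set()
        ref = align_to_embryo_frame(lm)
        for _ in range(10):
            rot, shift = random_rigid(rng)
            aligned = align_to_embryo_frame(transform_set(lm, rot, shift))
            for name in HEART_LANDMARKS:
                assert aligned.point(name) == pytest.approx(
                    ref.point(name), abs=1e-6)

    def test_notochord_order_reversed_same_axis(self):
        lm = canonical_set()
        rev = canonical_set(
            notochord_points=lm.notochord_points[::-1].copy())
        a1, a2 = align_to_embryo_frame(lm), align_to_embryo_frame(rev)
        assert a1.point("RV") == pytest.approx(a2.point("RV"), abs=1e-9)

    def test_somite_qc(self):
        with pytest.raises(QCError, match="17"):
            align_to_embryo_frame(canonical_set(somite_count=17))
        with pytest.raises(QCError, match="somite_count unknown"):
            align_to_embryo_frame(canonical_set(somite_count=None))
        align_to_embryo_frame(canonical_set(somite_count=18))  # boundary passes

    def test_missing_landmark(self):
        lm = canonical_set()
        bad = dict(lm.landmarks)
        del bad["venous_pole"]
        with pytest.raises(ValueError, match="venous_pole"):
            LandmarkSet(landmarks=bad, notochord_points=lm.notochord_points,
                        dorsoventral_ref=lm.dorsoventral_ref)


class TestAngle:
    def test_convention_anchor(self):
        lm = canonical_set()
        aligned = align_to_embryo_frame(lm)
        # RV right of LV (RV y<0, LV y>0) -> 0 degrees
        assert rvlv_axis_angle(aligned) == pytest.approx(0.0, abs=1e-9)

    def test_mirror_is_180(self):
        lm = canonical_set()
        mirrored = canonical_set(landmarks={
            k: (v[0], -v[1], v[2]) for k, v in lm.landmarks.items()})
        aligned = align_to_embryo_frame(mirrored)
        assert abs(rvlv_axis_angle(aligned)) == pytest.approx(180.0, abs=1e-9)

    def test_rotation_about_z_shifts_angle(self, rng):
        lm = canonical_set()
        base = rvlv_axis_angle(align_to_embryo_frame(lm))
        for theta in (30.0, -75.0, 120.0):
            t = np.radians(theta)
            rot = np.array([[np.cos(t), -np.sin(t), 0],
                            [np.sin(t), np.cos(t), 0], [0, 0, 1]])
            # rotate landmarks and notochord but keep the DV reference, so
            # the aligned frame is unchanged and the angle shifts linearly
            rotated = LandmarkSet(
                landmarks={k: rot @ v for k, v in lm.landmarks.items()},
                notochord_points=lm.notochord_points @ rot.T,
                dorsoventral_ref=lm.dorsoventral_ref,
                somite_count=lm.somite_count)
            angle = rvlv_axis_angle(align_to_embryo_frame(rotated))
            expected = (base + theta + 180) % 360 - 180
            assert angle == pytest.approx(expected, abs=1e-8)

    def test_coincident_projection_indeterminate(self):
        lm = canonical_set()
        marks = dict(lm.landmarks)
        marks["LV"] = np.array(marks["RV"]) + np.array([0, 0, 2.0])
        aligned = align_to_embryo_frame(canonical_set(landmarks=marks))
        with pytest.raises(ValueError, match="indeterminate"):
            rvlv_axis_angle(aligned)


class TestLengthAndDisplacement:
    def test_collinear_chain(self):
        marks = {name: (0.0, 0.0, 7.0 - i)
                 for i, name in enumerate(HEART_LANDMARKS)}
        marks["RV"] = (0.0, -1e-9, 5.0)  # keep RV/LV projections distinct
        lm = canonical_set(landmarks=marks)
        aligned = align_to_embryo_frame(lm)
        assert tube_length(aligned) == pytest.approx(7.0, rel=1e-6)

    def test_brute_force_segment_sum(self, rng):
        lm = canonical_set()
        aligned = align_to_embryo_frame(lm)
        pts = [aligned.point(n) for n in HEART_LANDMARKS]
        ref = sum(np.linalg.norm(b - a) for a, b in zip(pts, pts[1:]))
        assert tube_length(aligned) == pytest.approx(ref)

    def test_displacement_closed_form(self):
        aligned = align_to_embryo_frame(canonical_set())
        ref = aligned.point("venous_pole")[1] / tube_length(aligned)
        assert venous_pole_displacement(aligned) == pytest.approx(ref)
        assert venous_pole_displacement(aligned) > 0  # leftward positive

    def test_mirror_negates_displacement(self):
        lm = canonical_set()
        aligned = align_to_embryo_frame(lm)
        mirrored = align_to_embryo_frame(canonical_set(landmarks={
            k: (v[0], -v[1], v[2]) for k, v in lm.landmarks.items()}))
        assert venous_pole_displacement(mirrored) == pytest.approx(
            -venous_pole_displacement(aligned))


class TestDirection:
    def test_anchor_rightward(self):
        aligned = align_to_embryo_frame(canonical_set())
        assert looping_direction(aligned) == "rightward"

    def test_mirrored_leftward(self):
        lm = canonical_set()
        mirrored = align_to_embryo_frame(canonical_set(landmarks={
            k: (v[0], -v[1], v[2]) for k, v in lm.landmarks.items()}))
        assert looping_direction(mirrored) == "leftward"

    def test_indeterminate_below_tolerance(self):
        lm = canonical_set()
        marks = dict(lm.landmarks)
        marks["RV"] = (0.3, 0.2, 15.0)
        marks["LV"] = (0.1, 0.6, 15.0)
        aligned = align_to_embryo_frame(canonical_set(landmarks=marks))
        assert looping_direction(aligned) == "indeterminate"


class TestDirectionFrequencyTest:
    def test_balanced_is_null(self):
        res = direction_frequency_test(38, 76)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_yates_closed_form(self):
        res = direction_frequency_test(30, 76)
        assert res.statistic == pytest.approx(2 * 7.5**2 / 38)

    def test_zero_expected_guard(self):
        with pytest.raises(ValueError):
            direction_frequency_test(70, 76, expected_prop=1.0)

    def test_count_bounds(self):
        with pytest.raises(ValueError):
            direction_frequency_test(10, 5)


class TestRecoveryPipeline:
    @pytest.mark.parametrize("theta,frac", [
        (0.0, 0.0), (25.0, 0.1), (-60.0, -0.25), (150.0, 0.3)])
    def test_exact_recovery_zero_noise(self, theta, frac):
        lm, _ = simulate_landmarks(LandmarkSimParams(
            rvlv_angle_deg=theta, venous_offset_frac=frac))
        m = loop_metrics(lm)
        assert m.rvlv_angle_deg == pytest.approx(theta, abs=1e-8)
        assert m.venous_displacement_norm == pytest.approx(frac, abs=1e-10)

    def test_rigid_invariance_sweep(self, rng):
        lm, _ = simulate_landmarks(LandmarkSimParams(
            rvlv_angle_deg=40.0, venous_offset_frac=0.12))
        ref = loop_metrics(lm)
        for _ in range(100):
            rot, shift = random_rigid(rng)
            moved = transform_set(lm, rot, shift)
            m = loop_metrics(moved)
            assert m.rvlv_angle_deg == pytest.approx(ref.rvlv_angle_deg,
                                                     rel=1e-6, abs=1e-6)
            assert m.venous_displacement_norm == pytest.approx(
                ref.venous_displacement_norm, rel=1e-6)
            assert m.tube_length == pytest.approx(ref.tube_length, rel=1e-6)
            assert m.direction == ref.direction
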