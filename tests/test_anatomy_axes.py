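import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from afogen.anatomy_axes import (
    compute_axes,
    coronal_eversion_angle,
    sagittal_ankle_angle,
)
from afogen.errors import DegenerateLandmarkError, DegeneratePlaneError
from afogen.geometry_io import LandmarkSet

FOOT = ("heel", "mh1", "mh2", "mh5")


def rotate_foot(lm_set: LandmarkSet, rotvec_deg: np.ndarray, center: np.ndarray):
    """Rigidly rotate only the foot landmarks about a point (exact oracle)."""
    rot = Rotation.from_rotvec(np.radians(rotvec_deg))
    moved = {n: center + rot.apply(getattr(lm_set, n) - center) for n in FOOT}
    return lm_set.replace(**moved)


class TestAxisConstruction:
    def test_midpoints_and_leg_axis(self):
        # malleoli/condyles symmetric about the z-axis; mh2/heel anterior/posterior
        lm_set = LandmarkSet(
            heel=[-60, 0, -60], mh1=[150, -35, -60], mh2=[180, 0, -60],
            mh5=[150, 35, -60], lm=[0, 45, 0], mm=[0, -45, 0],
            lt=[0, 40, 380], mt=[0, -40, 380],
        )
        axes = compute_axes(lm_set)
        assert np.allclose(axes.c_t, [0, 0, 0])
        assert np.allclose(axes.c_k, [0, 0, 380])
        assert np.allclose(axes.leg_axis, [0, 0, 1])
        assert abs(np.linalg.norm(axes.foot_axis) - 1) < 1e-9
        assert abs(np.linalg.norm(axes.leg_axis) - 1) < 1e-9

    def test_neutral_fixture_measures_90_and_0(self, perpendicular_landmarks):
        axes = compute_axes(perpendicular_landmarks)
        assert axes.sagittal_angle_deg == pytest.approx(90.0, abs=1e-9)
        assert axes.eversion_angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_translation_invariance(self, perpendicular_landmarks):
        shifted = perpendicular_landmarks.transformed(np.eye(3), np.array([10.0, 20, 30]))
        a0 = compute_axes(perpendicular_landmarks)
        a1 = compute_axes(shifted)
        assert np.allclose(a0.foot_axis, a1.foot_axis)
        assert np.allclose(a0.leg_axis, a1.leg_axis)

    def test_coincident_malleoli_rejected_at_construction(self):
        from afogen.errors import LandmarkError

        with pytest.raises(LandmarkError):
            LandmarkSet(
                heel=[0, 0, 0], mh1=[1, 0, 0], mh2=[2, 0, 0], mh5=[1, 1, 0],
                lm=[0, 0, 5], mm=[0, 0, 5], lt=[0, 1, 10], mt=[0, -1, 10],
            )

    def test_mh2_at_malleolar_midpoint_is_degenerate(self, perpendicular_landmarks):
        bad = perpendicular_landmarks.replace(mh2=np.zeros(3))
        with pytest.raises(DegenerateLandmarkError):
            compute_axes(bad)


class TestSagittalAngle:
    @pytest.mark.parametrize("delta", [-20.0, -5.0, 0.0, 5.0, 20.0, 30.0])
    def test_plantarflexion_rotation_recovers_90_plus_delta(
        self, perpendicular_landmarks, delta
    ):
        # plantarflexion = rotation of the foot about the malleolar axis
        # (toes drop for positive delta)
        lm_set = rotate_foot(
            perpendicular_landmarks, np.array([0.0, delta, 0.0]), np.zeros(3)
        )
        axes = compute_axes(lm_set)
        assert axes.sagittal_angle_deg == pytest.approx(90.0 + delta, abs=1e-6)

    def test_foot_axis_parallel_to_leg_axis_reads_zero(self, perpendicular_landmarks):
        # rotate the whole foot 90 deg toes-up: foot axis parallel to leg axis
        lm_set = rotate_foot(
            perpendicular_landmarks, np.array([0.0, -90.0, 0.0]), np.zeros(3)
        )
        axes = compute_axes(lm_set)
        assert sagittal_ankle_angle(axes) == pytest.approx(0.0, abs=1e-9)


class TestEversionAngle:
    @pytest.mark.parametrize("eps", [-15.0, -10.0, 0.0, 10.0, 15.0])
    def test_roll_about_anterior_axis_recovers_eps(self, perpendicular_landmarks, eps):
        lm_set = rotate_foot(
            perpendicular_landmarks, np.array([eps, 0.0, 0.0]), np.zeros(3)
        )
        axes = compute_axes(lm_set)
        assert axes.eversion_angle_deg == pytest.approx(eps, abs=1e-6)

    def test_sign_antisymmetry(self, perpendicular_landmarks):
        plus = rotate_foot(perpendicular_landmarks, np.array([10.0, 0, 0]), np.zeros(3))
        minus = rotate_foot(perpendicular_landmarks, np.array([-10.0, 0, 0]), np.zeros(3))
        a_plus = compute_axes(plus)
        a_minus = compute_axes(minus)
        assert a_plus.eversion_angle_deg == pytest.approx(
            -a_minus.eversion_angle_deg, abs=1e-9
        )

    def test_collinear_plantar_landmarks_rejected(self, perpendicular_landmarks):
        bad = perpendicular_landmarks.replace(
            mh1=np.array([100.0, 0.0, -50.0]),
            mh5=np.array([140.0, 0.0, -50.0]),
            heel=np.array([-60.0, 0.0, -50.0]),
        )
        with pytest.raises(DegeneratePlaneError):
            compute_axes(bad)

    def test_combined_deformity_decomposes_exactly(self, perpendicular_landmarks):
        # plantarflexion about the malleolar axis applied after eversion
        # about the anterior axis: both angles recovered exactly
        center = np.zeros(3)
        step1 = rotate_foot(perpendicular_landmarks, np.array([12.0, 0, 0]), center)
        lm_set = rotate_foot(step1, np.array([0.0, 25.0, 0.0]), center)
        axes = compute_axes(lm_set)
        assert axes.sagittal_angle_deg == pytest.approx(115.0, abs=1e-6)
        assert coronal_eversion_angle(lm_set, axes) == pytest.approx(12.0, abs=1e-6)


class TestMarkingErrorRobustness:
    def test_angles_degrade_gracefully_under_landmark_jitter(self):
        """Manual marking error propagates predictably.

        With sigma = 1 mm isotropic jitter on every landmark, first-order
        propagation gives sigma ~ 1.0 deg for eversion (sqrt(2) x 1 mm over
        the 80 mm mh1-mh5 baseline) and ~ 0.3 deg for the sagittal angle
        (1 mm over the ~220 mm foot-axis lever).  Errors are checked against
        4-sigma bounds of those analytic rates.
        """
        from afogen.synthetic_leg import SyntheticLegSpec, generate_leg

        sag_bound = 4 * np.degrees(np.sqrt(1.0**2 + 0.5) / 220.0)
        ev_bound = 4 * np.degrees(np.sqrt(2.0) * 1.0 / 80.0)
        for seed in range(1, 6):
            for delta in (0.0, 10.0, 30.0):
                for eps in (-15.0, 0.0, 15.0):
                    _, lm_set = generate_leg(SyntheticLegSpec(
                        plantarflexion_deg=delta, eversion_deg=eps,
                        landmark_jitter_sigma_mm=1.0, seed=seed,
                        circumferential_resolution=8, axial_resolution=8))
                    axes = compute_axes(lm_set)
                    assert abs(axes.sagittal_angle_deg - (90 + delta)) <= sag_bound
                    assert abs(axes.eversion_angle_deg - eps) <= ev_bound


class TestRigidEquivariance:
    @given(seed=st.integers(0, 10_000))
    def test_angles_invariant_under_rigid_transforms(self, seed):
        from afogen.synthetic_leg import SyntheticLegSpec, generate_leg

        rng = np.random.default_rng(seed)
        delta = float(rng.uniform(-20, 30))
        eps = float(rng.uniform(-15, 15))
        _, lm_set = generate_leg(
            SyntheticLegSpec(plantarflexion_deg=delta, eversion_deg=eps,
                             circumferential_resolution=8, axial_resolution=8)
        )
        a0 = compute_axes(lm_set)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-100, 100, 3)
        a1 = compute_axes(lm_set.transformed(R, t))
        assert a1.sagittal_angle_deg == pytest.approx(a0.sagittal_angle_deg, abs=1e-6)
        assert a1.eversion_angle_deg == pytest.approx(a0.eversion_angle_deg, abs=1e-6)
        # axes transform with the landmarks
        assert np.allclose(a1.foot_axis, R @ a0.foot_axis, atol=1e-9)
        assert np.allclose(a1.c_t, R @ a0.c_t + t, atol=1e-9)

    @given(k=st.floats(0.25, 4.0))
    def test_scale_invariance_of_angles(self, k):
        base = LandmarkSet(
            heel=[-60, 0, -50], mh1=[150, -40, -50], mh2=[180, 0, 0],
            mh5=[150, 40, -50], lm=[0, 45, 0], mm=[0, -45, 0],
            lt=[0, 40, 380], mt=[0, -40, 380],
        )
        lm_set = rotate_foot(base, np.array([8.0, 15.0, 0]), np.zeros(3))
        a0 = compute_axes(lm_set)
        scaled = lm_set.transformed(k * np.eye(3), np.zeros(3))
        a1 = compute_axes(scaled)
        assert a1.sagittal_angle_deg == pytest.approx(a0.sagittal_angle_deg, abs=1e-6)
        assert a1.eversion_angle_deg == pytest.approx(a0.eversion_angle_deg, abs=1e-6)
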