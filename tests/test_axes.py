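"""Axis measurements: sphere fit, Moreland axis, mechanical axis, TEA,
posterior condylar angle and coronal deviation, with their invariances."""

import numpy as np
import pytest

from kneeplan.axes import (
    AxisLine,
    coronal_deviation,
    fit_femoral_head_center,
    measure_axes,
    mechanical_axis,
    moreland_anatomical_axis,
    posterior_condylar_angle,
    probe_condyles,
    surgical_tea,
)
from kneeplan.errors import ExtentError, GeometryError, ValidationError
from kneeplan.femur import FemurSpec, LandmarkSet, generate_femur


def synthetic_landmarks(**overrides) -> LandmarkSet:
    base = dict(
        femoral_head_center=[0, 0, 400],
        adductor_tubercle=[-37, -5, 42.5],
        lateral_epicondyle_prominence=[37.5, 0, 25],
        medial_epicondyle_sulcus=[-37.5, 0, 25],
        trochlear_notch_center=[0, 0, 15],
        distal_condyle_medial=[-22.5, 0, 0],
        distal_condyle_lateral=[22.5, 0, 0],
        posterior_condyle_medial=[-25, -30, 20],
        posterior_condyle_lateral=[25, -30, 20],
    )
    base.update(overrides)
    return LandmarkSet(**{k: np.asarray(v, float) for k, v in base.items()})


class TestSphereFit:
    def test_noiseless_recovery_is_exact(self, rng):
        true_c, true_r = np.array([10.0, 20.0, 30.0]), 24.0
        pts = rng.normal(size=(200, 3))
        pts = true_c + true_r * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        c, r, rms = fit_femoral_head_center(pts)
        assert np.allclose(c, true_c, atol=1e-9)
        assert r == pytest.approx(true_r, abs=1e-9)
        assert rms < 1e-9

    def test_regular_tetrahedron_plus_cage_on_unit_sphere(self):
        # tetrahedron vertices alone are < 10 points; replicate the
        # symmetric configuration to satisfy the count without breaking it
        tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
        pts = np.vstack([tet, -tet, tet[[0, 1, 2]] @ _rot_z(0.4)])
        c, r, rms = fit_femoral_head_center(pts)
        assert np.allclose(c, 0, atol=1e-9)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_noisy_monte_carlo_center_error_below_resolution(self, rng):
        true_c, true_r = np.array([10.0, 20.0, 30.0]), 24.0
        pts = rng.normal(size=(500, 3))
        pts = true_c + true_r * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        noisy = pts + rng.normal(scale=0.5, size=pts.shape)
        c, r, rms = fit_femoral_head_center(noisy)
        assert np.linalg.norm(c - true_c) < 0.2
        assert rms == pytest.approx(0.5, rel=0.2)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValidationError):
            fit_femoral_head_center(rng.normal(size=(5, 3)))
        planar = np.column_stack([rng.normal(size=(50, 2)), np.zeros(50)])
        with pytest.raises(GeometryError):
            fit_femoral_head_center(planar)

    def test_fixture_head_vertices_recover_generator_center(self, intact):
        mesh, lm = intact
        r_true = FemurSpec().head_radius
        d = np.linalg.norm(mesh.vertices - lm.femoral_head_center, axis=1)
        head_pts = mesh.vertices[np.abs(d - r_true) < 1e-6]
        c, r, rms = fit_femoral_head_center(head_pts)
        assert np.linalg.norm(c - lm.femoral_head_center) < 1e-6
        assert r == pytest.approx(r_true, abs=1e-6)


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


class TestMechanicalAndTea:
    def test_two_point_lines(self):
        ax = mechanical_axis([0, 0, 400], [0, 0, 0])
        assert np.allclose(ax.direction, [0, 0, 1])
        ax2 = mechanical_axis([20, 0, 400], [0, 0, 0])
        assert np.allclose(ax2.direction, np.array([20, 0, 400]) / np.linalg.norm([20, 0, 400]))
        with pytest.raises(GeometryError):
            mechanical_axis([0, 0, 10], [0, 0, 0])

    def test_surgical_tea_oriented_medial_to_lateral(self):
        lm = synthetic_landmarks()
        tea = surgical_tea(lm)
        assert np.allclose(tea.direction, [1, 0, 0])

    def test_fixture_mechanical_axis_matches_ground_truth(self, intact):
        _, lm = intact
        ax = mechanical_axis(lm.femoral_head_center, lm.trochlear_notch_center)
        assert ax.angle_to(AxisLine(point=[0, 0, 0], direction=[0, 0, 1])) < 0.2


class TestMoreland:
    def test_second_point_is_100mm_above_the_joint_surface(self, intact):
        mesh, lm = intact
        u = lm.femoral_head_center - lm.distal_condyle_medial
        u = u / np.linalg.norm(u)
        ax = moreland_anatomical_axis(mesh, lm)
        height = ax.point @ u - (mesh.vertices @ u).min()
        assert height == pytest.approx(100.0, abs=1e-6)

    def test_straight_shaft_yields_vertical_axis(self):
        mesh, lm = generate_femur(FemurSpec(anatomical_mechanical_angle=0.0, mesh_resolution=8))
        ax = moreland_anatomical_axis(mesh, lm)
        assert ax.angle_to(AxisLine(point=[0, 0, 0], direction=[0, 0, 1])) < 0.1

    def test_fixture_recovers_anatomical_mechanical_angle(self, intact):
        mesh, lm = intact
        anat = moreland_anatomical_axis(mesh, lm)
        mech = mechanical_axis(lm.femoral_head_center, lm.trochlear_notch_center)
        assert anat.angle_to(mech) == pytest.approx(6.0, abs=0.5)

    def test_short_mesh_raises_extent_error(self, intact):
        mesh, lm = intact
        # a stub spanning well under 100 mm proximal of the joint surface
        import trimesh

        short = trimesh.Trimesh(
            vertices=mesh.vertices[mesh.vertices[:, 2] < 60].copy(),
            faces=[[0, 1, 2]],
            process=False,
        )
        with pytest.raises(ExtentError):
            moreland_anatomical_axis(short, lm)


class TestPcaAndCoronal:
    def test_pca_magnitude_matches_atan2_oracle(self):
        # TEA with slope 3/60 against a straight posterior line
        lm = synthetic_landmarks(
            medial_epicondyle_sulcus=[-30, -1.5, 25],
            lateral_epicondyle_prominence=[30, 1.5, 25],
        )
        expected = np.degrees(np.arctan2(3.0, 60.0))
        assert abs(posterior_condylar_angle(lm)) == pytest.approx(expected, abs=1e-9)

    def test_parallel_lines_give_zero(self):
        lm = synthetic_landmarks()
        assert posterior_condylar_angle(lm) == pytest.approx(0.0, abs=1e-12)

    def test_fixture_native_pca_sign_is_positive(self, intact):
        _, lm = intact
        assert posterior_condylar_angle(lm) == pytest.approx(3.0, abs=0.05)

    def test_posterior_lateral_defect_shifts_pca_by_trig_oracle(self, intact, case3):
        _, lm = intact
        mesh, _, defect = case3
        native = posterior_condylar_angle(lm)
        shifted = posterior_condylar_angle(probe_condyles(mesh, lm))
        span = np.linalg.norm(
            (lm.posterior_condyle_lateral - lm.posterior_condyle_medial)[:2]
        )
        expected = np.degrees(np.arctan(defect.depth / span))
        assert shifted - native == pytest.approx(expected, abs=0.15)

    def test_perpendicular_joint_line_reads_zero(self):
        mech = AxisLine(point=[0, 0, 0], direction=[0, 0, 1])
        joint = AxisLine(point=[0, 0, 0], direction=[1, 0, 0])
        assert coronal_deviation(mech, joint) == 0.0

    def test_medial_defect_reads_varus_by_trig_oracle(self, intact, case2):
        _, lm = intact
        mesh, _, defect = case2
        probed = probe_condyles(mesh, lm)
        joint = AxisLine(
            point=probed.distal_condyle_medial,
            direction=probed.distal_condyle_lateral - probed.distal_condyle_medial,
        )
        mech = mechanical_axis(lm.femoral_head_center, lm.trochlear_notch_center)
        expected = np.degrees(np.arctan(7.0 / 45.0))
        assert coronal_deviation(mech, joint) == pytest.approx(expected, abs=0.1)

    def test_mirrored_lateral_defect_flips_the_sign(self, intact):
        from kneeplan.femur import DefectSpec, apply_defect

        mesh0, lm = intact
        mesh = apply_defect(mesh0, lm, DefectSpec("distal_lateral", 7.0))
        probed = probe_condyles(mesh, lm)
        joint = AxisLine(
            point=probed.distal_condyle_medial,
            direction=probed.distal_condyle_lateral - probed.distal_condyle_medial,
        )
        mech = mechanical_axis(lm.femoral_head_center, lm.trochlear_notch_center)
        assert coronal_deviation(mech, joint) == pytest.approx(
            -np.degrees(np.arctan(7.0 / 45.0)), abs=0.1
        )

    def test_parallel_inputs_rejected(self):
        mech = AxisLine(point=[0, 0, 0], direction=[0, 0, 1])
        with pytest.raises(GeometryError):
            coronal_deviation(mech, AxisLine(point=[0, 0, 0], direction=[0, 0.01, 1]))


class TestInvariances:
    def test_pca_and_coronal_invariant_under_rigid_motion(self, intact, case2, rng):
        mesh, _, _ = case2
        _, lm = intact
        pca0 = posterior_condylar_angle(lm)
        rep0 = measure_axes(mesh, lm)

        # random proper rotation + translation
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        t = rng.uniform(-100, 100, size=3)

        import trimesh

        mesh_t = trimesh.Trimesh(vertices=mesh.vertices @ R.T + t, faces=mesh.faces, process=False)
        lm_t = LandmarkSet(**{name: R @ p + t for name, p in lm.items()})

        assert posterior_condylar_angle(lm_t) == pytest.approx(pca0, abs=1e-9)
        rep_t = measure_axes(mesh_t, lm_t)
        assert rep_t.pca == pytest.approx(rep0.pca, abs=1e-6)
        assert rep_t.coronal_deviation == pytest.approx(rep0.coronal_deviation, abs=1e-6)

    def test_left_right_mirroring_flips_signs(self):
        _, lm_r = generate_femur(FemurSpec(side="right", mesh_resolution=8))
        _, lm_l = generate_femur(FemurSpec(side="left", mesh_resolution=8))
        assert posterior_condylar_angle(lm_l) == pytest.approx(
            -posterior_condylar_angle(lm_r), abs=1e-9
        )

    def test_full_report_on_intact_fixture_matches_ground_truth(self, intact):
        mesh, lm = intact
        rep = measure_axes(mesh, lm)
        assert rep.pca == pytest.approx(3.0, abs=0.3)
        assert rep.coronal_deviation == pytest.approx(0.0, abs=0.2)
        assert rep.anatomical_axis.angle_to(rep.mechanical_axis_FMA) == pytest.approx(6.0, abs=0.5)
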