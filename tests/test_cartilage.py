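"""Cartilage layer construction and the three thickness predictors."""

import numpy as np
import pytest

from hipdea.cartilage import (
    apply_thickness_map,
    build_thickness_map,
    loo_validate,
    predict_constant,
    predict_spherical,
    project_cartilage,
    thickness_error,
)
from hipdea.errors import CorrespondenceError, DegenerateGeometryError
from hipdea.mesh import SurfaceMesh, make_ball_socket, make_spherical_cap
from hipdea.synthetic import synth_population


def _radii(mesh):
    return np.linalg.norm(mesh.vertices, axis=1)


@pytest.fixture(scope="module")
def bones():
    """Concentric spherical bones: femoral r=24, acetabular r=27."""
    fem, acet = make_ball_socket(24.0, 27.0, target_edge=1.5)
    return acet, fem


class TestProjectCartilage:
    def test_outward_extrusion(self):
        sphere = make_spherical_cap(20.0, 1.5, 90.0)
        layer = project_cartilage(sphere, 1.5, "femoral")
        assert np.allclose(_radii(layer.articular_surface), 21.5, atol=1e-9)
        assert layer.articular_surface.faces is not sphere.faces
        assert np.array_equal(layer.articular_surface.faces, sphere.faces)

    def test_zero_thickness_identity(self):
        sphere = make_spherical_cap(20.0, 1.5, 60.0)
        layer = project_cartilage(sphere, 0.0, "femoral")
        assert np.array_equal(layer.articular_surface.vertices, sphere.vertices)

    def test_inward_extrusion(self):
        shell = make_spherical_cap(24.0, 1.5, 90.0, inward=True)
        layer = project_cartilage(shell, 2.0, "acetabular")
        assert np.allclose(_radii(layer.articular_surface), 22.0, atol=1e-9)

    def test_negative_thickness_rejected(self):
        sphere = make_spherical_cap(20.0, 1.5, 60.0)
        with pytest.raises(ValueError):
            project_cartilage(sphere, -0.1, "femoral")

    def test_extrusion_invariant(self):
        sphere = make_spherical_cap(20.0, 2.0, 60.0)
        t = np.linspace(0.5, 2.5, sphere.n_vertices)
        layer = project_cartilage(sphere, t, "femoral")
        recon = layer.bone_surface.vertices + t[:, None] * layer.bone_surface.normals
        assert np.allclose(layer.articular_surface.vertices, recon, atol=1e-9)


class TestSphericalPrediction:
    def test_perfect_spheres_split_evenly(self, bones):
        acet_bone, fem_bone = bones
        acet, fem = predict_spherical(acet_bone, fem_bone)
        assert np.allclose(acet.thickness, 1.5, atol=1e-6)
        assert np.allclose(fem.thickness, 1.5, atol=1e-6)
        # congruent interfaces on the joint sphere of radius 25.5
        assert np.allclose(_radii(acet.articular_surface), 25.5, atol=1e-6)
        assert np.allclose(_radii(fem.articular_surface), 25.5, atol=1e-6)

    def test_second_radius_pair(self):
        fem_bone, acet_bone = make_ball_socket(20.0, 24.0, target_edge=1.5)
        acet, fem = predict_spherical(acet_bone, fem_bone)
        assert np.allclose(acet.thickness, 2.0, atol=1e-6)
        assert np.allclose(fem.thickness, 2.0, atol=1e-6)

    def test_aspherical_bump_thins_locally(self):
        fem_bone, acet_bone = make_ball_socket(20.0, 24.0, target_edge=1.5)
        # push a small patch of the femoral head 0.5 mm outward
        direction = np.array([np.sin(0.5), 0.0, -np.cos(0.5)])
        cosang = (fem_bone.vertices / 20.0) @ direction
        bump = cosang > np.cos(np.deg2rad(6.0))
        verts = fem_bone.vertices.copy()
        verts[bump] *= (20.5 / 20.0)
        bumped = SurfaceMesh(verts, fem_bone.faces.copy(), fem_bone.normals.copy(), validate=False)
        _, fem = predict_spherical(acet_bone, bumped)
        assert np.allclose(fem.thickness[bump], 1.5, atol=0.05)
        far = cosang < np.cos(np.deg2rad(20.0))
        assert np.allclose(fem.thickness[far], 2.0, atol=0.05)

    def test_no_joint_space_rejected(self, bones):
        acet_bone, fem_bone = bones
        with pytest.raises(DegenerateGeometryError):
            predict_spherical(fem_bone.flipped(), acet_bone.flipped())


class TestConstantPrediction:
    def test_uniform_thickness(self, bones):
        acet_bone, fem_bone = bones
        acet, fem = predict_constant(acet_bone, fem_bone)
        assert np.allclose(acet.thickness, 1.5, atol=1e-6)
        assert np.allclose(fem.thickness, 1.5, atol=1e-6)

    def test_degenerate_with_spherical_on_spheres(self, bones):
        acet_bone, fem_bone = bones
        acet_c, fem_c = predict_constant(acet_bone, fem_bone)
        acet_s, fem_s = predict_spherical(acet_bone, fem_bone)
        for a, b in ((acet_c, acet_s), (fem_c, fem_s)):
            assert np.allclose(a.thickness, b.thickness, atol=1e-6)
            assert np.allclose(
                a.articular_surface.vertices, b.articular_surface.vertices, atol=1e-6
            )


class TestThicknessMap:
    def _flat_layer(self, thickness, n=5):
        x, y = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
        v = np.column_stack([x.ravel(), y.ravel(), np.zeros(n * n)])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + 1, a + n])
                faces.append([a + 1, a + n + 1, a + n])
        mesh = SurfaceMesh(v, np.array(faces))
        return project_cartilage(mesh, thickness, "femoral")

    def test_hand_arithmetic_scaling(self):
        la = self._flat_layer(np.full(25, 2.0))
        lb = self._flat_layer(np.full(25, 1.6))
        tmap = build_thickness_map([la, lb], [25.0, 20.0])
        assert np.allclose(tmap.normalized_thickness, 0.08)
        applied = apply_thickness_map(tmap, la.bone_surface, 20.0)
        assert np.allclose(applied.thickness, 1.6)

    def test_single_subject_round_trip(self):
        rng = np.random.default_rng(7)
        layer = self._flat_layer(1.0 + 0.5 * rng.random(25))
        tmap = build_thickness_map([layer], [22.0])
        applied = apply_thickness_map(tmap, layer.bone_surface, 22.0)
        assert np.allclose(applied.thickness, layer.thickness, atol=1e-12)

    def test_scale_invariance_of_normalization(self):
        rng = np.random.default_rng(8)
        t = 1.0 + 0.5 * rng.random(25)
        layer = self._flat_layer(t)
        c = 1.37
        scaled_bone = SurfaceMesh(
            layer.bone_surface.vertices * c,
            layer.bone_surface.faces.copy(),
            layer.bone_surface.normals.copy(),
            validate=False,
        )
        scaled = project_cartilage(scaled_bone, t * c, "femoral")
        m1 = build_thickness_map([layer], [20.0])
        m2 = build_thickness_map([scaled], [20.0 * c])
        assert np.allclose(m1.normalized_thickness, m2.normalized_thickness, atol=1e-12)

    def test_mismatched_inputs_rejected(self):
        la = self._flat_layer(np.full(25, 2.0))
        lb = self._flat_layer(np.full(16, 2.0), n=4)
        with pytest.raises(CorrespondenceError):
            build_thickness_map([la, lb], [25.0, 25.0])
        with pytest.raises(ValueError):
            build_thickness_map([la], [-1.0])
        tmap = build_thickness_map([la], [25.0])
        with pytest.raises(CorrespondenceError):
            apply_thickness_map(tmap, lb.bone_surface, 25.0)


class TestThicknessError:
    def test_identical_layers_zero(self):
        subs = synth_population(n=1, seed=0)
        layer = subs[0].femoral_layer()
        assert thickness_error(layer, layer) == (0.0, 0.0)

    def test_constant_offset(self):
        sphere = make_spherical_cap(20.0, 2.0, 60.0)
        ref = project_cartilage(sphere, 2.0, "femoral")
        pred = project_cartilage(sphere, 1.5, "femoral")
        rmse, mx = thickness_error(pred, ref)
        assert rmse == pytest.approx(0.5, abs=1e-9)
        assert mx == pytest.approx(0.5, abs=1e-9)

    def test_known_noise_values(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        f = np.array([[0, 1, 2], [0, 2, 3]])
        bone = SurfaceMesh(v, f)
        ref = project_cartilage(bone, np.full(4, 1.0), "femoral")
        noise = np.array([0.1, -0.3, 0.2, 0.0])
        pred = project_cartilage(bone, 1.0 + noise, "femoral")
        rmse, mx = thickness_error(pred, ref)
        assert rmse == pytest.approx(np.sqrt(0.14 / 4), abs=1e-12)
        assert mx == pytest.approx(0.3, abs=1e-12)


class TestLeaveOneOut:
    def test_homogeneous_population_scores_zero(self):
        subs = synth_population(n=4, seed=2, perturbation_sd=0.0, radius_sd=1.0)
        layers = [s.femoral_layer() for s in subs]
        radii = [s.head_radius for s in subs]
        for rmse, mx in loo_validate(layers, radii):
            assert rmse < 1e-9 and mx < 1e-9

    def test_perturbation_recovery_scale(self, population):
        layers = [s.femoral_layer() for s in population]
        radii = [s.head_radius for s in population]
        scores = loo_validate(layers, radii)
        mean_rmse = np.mean([r for r, _ in scores])
        # per-subject smooth perturbations have RMS 0.1 mm; leave-one-out
        # errors should recover that scale (within a factor of two)
        assert 0.05 < mean_rmse < 0.2

    def test_needs_two_subjects(self, population):
        with pytest.raises(ValueError):
            loo_validate([population[0].femoral_layer()], [25.0])
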