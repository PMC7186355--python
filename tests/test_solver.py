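"""Translational equilibrium: convergence, symmetry, contact physics."""

import numpy as np
import pytest

from hipdea.cartilage import project_cartilage
from hipdea.errors import ConvergenceError, DislocationError
from hipdea.mesh import make_ball_socket
from hipdea.solver import SolverConfig, solve_equilibrium
from hipdea.springs import LinearMaterial, NonlinearMaterial, build_springs
from hipdea.synthetic import synth_edge_case, synth_population

LOAD = np.array([0.0, 0.0, 2000.0])  # joint reaction on the femur; pole at -z


@pytest.fixture(scope="module")
def conformal_springs():
    ball, shell = make_ball_socket(20.0, 24.0, target_edge=1.5)
    acet = project_cartilage(shell, 2.0, "acetabular")
    fem = project_cartilage(ball, 2.0, "femoral")
    return build_springs(acet, fem)


class TestVerificationTranslation:
    def test_one_layer_approach_matches_foundation_oracle(self, verification_1mm):
        # closed form: delta0 = h p0 / k with p0 = 3W/(2 pi R^2)
        sol = verification_1mm.solution_1layer
        delta0 = verification_1mm.analytic_1layer.delta0
        assert abs(sol.translation[2]) == pytest.approx(delta0, rel=5e-3)
        assert sol.translation[2] < 0  # femur moves toward the -z pole

    def test_symmetric_load_gives_axial_translation(self, verification_1mm):
        for sol in (verification_1mm.solution_1layer, verification_1mm.solution_2layer):
            assert np.abs(sol.translation[:2]).max() < 1e-3

    def test_peak_at_pole(self, verification_1mm):
        assert int(np.argmax(verification_1mm.stress_1layer)) == 0
        assert int(np.argmax(verification_1mm.stress_2layer)) == 0


class TestForceConservation:
    def test_linear_conformal(self, conformal_springs):
        sol = solve_equilibrium(conformal_springs, LOAD, LinearMaterial())
        assert sol.residual / np.linalg.norm(LOAD) < 1e-3

    def test_nonlinear_conformal(self, conformal_springs):
        load = np.array([0.0, 0.0, 500.0])
        sol = solve_equilibrium(conformal_springs, load, NonlinearMaterial(), law="nonlinear")
        assert sol.residual / 500.0 < 1e-3
        assert sol.stress.max() > 0

    def test_oblique_load(self, conformal_springs):
        load = 2000.0 * np.array([np.sin(0.3), 0.0, np.cos(0.3)])
        sol = solve_equilibrium(conformal_springs, load, LinearMaterial())
        assert sol.residual / 2000.0 < 1e-3
        total = sol.forces.sum(axis=0)
        assert np.allclose(total, load, atol=1e-3 * 2000.0)


class TestContactPhysics:
    def test_compression_only(self, conformal_springs):
        sol = solve_equilibrium(conformal_springs, LOAD, LinearMaterial())
        assert np.all(sol.stress >= 0.0)
        assert np.all(sol.stress[~sol.contact] == 0.0)
        # every spring force points along its own direction (no tension)
        along = np.einsum("ij,ij->i", sol.forces, conformal_springs.dirs)
        assert np.all(along >= -1e-12)

    def test_noncontact_springs_are_irrelevant(self, conformal_springs):
        sol = solve_equilibrium(conformal_springs, LOAD, LinearMaterial())
        open_gaps = conformal_springs.gaps(sol.translation) > 0
        assert np.all(sol.stress[open_gaps] == 0.0)

    def test_stress_equals_force_over_area(self, conformal_springs):
        sol = solve_equilibrium(conformal_springs, LOAD, LinearMaterial())
        mags = np.linalg.norm(sol.forces, axis=1)
        mask = sol.contact
        assert np.allclose(mags[mask] / conformal_springs.areas[mask], sol.stress[mask])


class TestEdgeLoading:
    def test_peak_moves_to_rim_under_tilt(self):
        subject = synth_edge_case(coverage_angle=50.0, tilt=20.0, target_edge=1.0)
        springs = build_springs(
            subject.acetabular_layer(),
            subject.femoral_layer(),
            correspondence=subject.correspondence,
        )
        load = 1500.0 * subject.provenance["load_direction"]
        sol = solve_equilibrium(springs, load, LinearMaterial())
        anchors = springs.anchors
        theta = np.degrees(np.arccos(np.clip(-anchors[:, 2] / np.linalg.norm(anchors, axis=1), -1, 1)))
        rim = theta.max()
        peak_theta = theta[np.argmax(sol.stress)]
        # peak sits on the outermost retained ring of the truncated socket
        assert peak_theta > rim - 3.0

    def test_full_coverage_matches_symmetric_fixture(self, conformal_springs):
        subject = synth_edge_case(coverage_angle=90.0, tilt=0.0, target_edge=1.5)
        springs = build_springs(
            subject.acetabular_layer(),
            subject.femoral_layer(),
            correspondence=subject.correspondence,
        )
        load = 2000.0 * subject.provenance["load_direction"]
        sol = solve_equilibrium(springs, load, LinearMaterial())
        ref = solve_equilibrium(conformal_springs, LOAD, LinearMaterial())
        assert np.allclose(np.abs(sol.translation[2]), np.abs(ref.translation[2]), rtol=1e-3)
        assert sol.stress.max() == pytest.approx(ref.stress.max(), rel=1e-3)


class TestLawComparison:
    def test_small_load_agreement_with_matched_origin_stiffness(self, conformal_springs):
        nl = NonlinearMaterial()
        lin = LinearMaterial(e=nl.h_a0, v=0.0)  # k = H_A0: matched at zero strain
        load = np.array([0.0, 0.0, 5.0])
        a = solve_equilibrium(conformal_springs, load, lin)
        b = solve_equilibrium(conformal_springs, load, nl)
        assert b.strains.max() < 0.02
        m = a.contact & b.contact
        corr = np.corrcoef(a.stress[m], b.stress[m])[0, 1]
        assert corr > 0.999

    def test_stiffening_raises_peak_on_edge_fixture(self):
        subject = synth_edge_case(coverage_angle=50.0, tilt=20.0, target_edge=1.5)
        springs = build_springs(
            subject.acetabular_layer(),
            subject.femoral_layer(),
            correspondence=subject.correspondence,
        )
        nl = NonlinearMaterial()
        lin = LinearMaterial(e=nl.h_a0, v=0.0)
        load = 100.0 * subject.provenance["load_direction"]
        peak_lin = solve_equilibrium(springs, load, lin).stress.max()
        peak_nl = solve_equilibrium(springs, load, nl).stress.max()
        assert peak_nl >= peak_lin


class TestFailureModes:
    def test_tensile_load_dislocates(self, conformal_springs):
        with pytest.raises(DislocationError):
            solve_equilibrium(conformal_springs, -LOAD, LinearMaterial())

    def test_zero_load_rejected(self, conformal_springs):
        with pytest.raises(ValueError):
            solve_equilibrium(conformal_springs, [0.0, 0.0, 0.0], LinearMaterial())

    def test_infeasible_load_raises_convergence_error(self):
        subject = synth_edge_case(coverage_angle=50.0, tilt=20.0, target_edge=1.5)
        springs = build_springs(
            subject.acetabular_layer(),
            subject.femoral_layer(),
            correspondence=subject.correspondence,
        )
        soft = LinearMaterial(e=0.4, v=0.0)
        with pytest.raises(ConvergenceError) as exc:
            solve_equilibrium(springs, 1500.0 * subject.provenance["load_direction"], soft)
        assert exc.value.residual is not None

    def test_law_material_mismatch_rejected(self, conformal_springs):
        with pytest.raises(ValueError):
            solve_equilibrium(conformal_springs, LOAD, LinearMaterial(), law="nonlinear")


class TestSolverOnPredictedGeometry:
    def test_constant_method_subject_converges(self):
        from hipdea.cartilage import predict_constant

        subject = synth_population(n=1, seed=3, perturbation_sd=0.05)[0]
        acet, fem = predict_constant(subject.acet_bone, subject.fem_bone)
        springs = build_springs(acet, fem)
        sol = solve_equilibrium(springs, LOAD, LinearMaterial())
        assert sol.residual / 2000.0 < 1e-3
        assert sol.n_contact > 0

    def test_tighter_tolerance_is_respected(self, conformal_springs):
        cfg = SolverConfig(rel_tol=1e-6)
        sol = solve_equilibrium(conformal_springs, LOAD, LinearMaterial(), config=cfg)
        assert sol.residual / 2000.0 < 1e-6
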