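"""Axisymmetric FE engine: patch test, closed-form oracle, and contact
mechanics properties."""

import numpy as np
import pytest
from scipy.optimize import brentq

import staplecomp as sc
from staplecomp.geometry_mesh import AxisymMesh


def _penalty_uniaxial_oracle(mat, lam_z):
    """Independent 1-D solve of the penalty-compressible uniaxial problem.

    Finds the lateral stretch with zero lateral Cauchy stress for the
    isochoric-split Ogden law plus volumetric penalty, then returns the
    axial stress.  Uses only scalar arithmetic and brentq.
    """
    K = mat.penalty_bulk

    def stresses(lr):
        J = lam_z * lr * lr
        lb = [l * J ** (-1.0 / 3.0) for l in (lr, lam_z, lr)]
        mean = lambda a: (lb[0] ** a + lb[1] ** a + lb[2] ** a) / 3.0
        dev = [
            sum(mu * (lb[i] ** a - mean(a)) for mu, a in mat.terms) / J
            for i in range(3)
        ]
        return [d + K * (J - 1.0) for d in dev]

    lr = brentq(lambda x: stresses(x)[0], 0.5, 4.0, xtol=1e-14)
    return stresses(lr)[1]


def _single_element_mesh(stack):
    nodes = np.array(
        [
            [stack.r_inner, 0.0],
            [stack.r_outer, 0.0],
            [stack.r_outer, stack.total_thickness],
            [stack.r_inner, stack.total_thickness],
        ]
    )
    r_bar = nodes[:, 0].mean()
    vol = 2.0 * np.pi * r_bar * (stack.r_outer - stack.r_inner) * stack.total_thickness
    return AxisymMesh(
        nodes=nodes,
        elements=np.array([[0, 1, 2, 3]]),
        layer_tag=np.array(["lower"]),
        ref_volume=np.array([vol]),
        stack=stack,
        element_size=stack.total_thickness,
    )


class TestPatchAndOracle:
    def test_single_element_patch_reproduces_closed_form(self, tissue_material):
        """One ring element under uniform axial displacement matches the 1-D
        penalty-compressible solution to 1e-4 relative."""
        stack = sc.TissueStack(0.5, 0.5, 12.0, 14.0)
        mesh = _single_element_mesh(stack)
        program = sc.LoadProgram(total_travel=0.6, step_size=0.1)
        options = sc.SolverOptions(mode="frictionless")
        results = sc.run_fem(tissue_material, stack, None, program, mesh, options)
        for step in results[1:]:
            lam_z = 1.0 - step.d / stack.total_thickness
            expected = abs(_penalty_uniaxial_oracle(tissue_material, lam_z))
            assert step.von_mises[0] == pytest.approx(expected, rel=1e-4)

    def test_frictionless_matches_uniform_engine_within_2pct(
        self, tissue_material, stack_2_2, fem_frictionless
    ):
        """The engine's analytically solvable limit: every element's von
        Mises stress tracks the incompressible closed form at every step."""
        _, program, fem = fem_frictionless
        uniform = sc.run_uniform(tissue_material, stack_2_2, program)
        for fs, us in zip(fem, uniform):
            ref = us.von_mises[0]
            if ref < 1e-9:
                assert np.all(fs.von_mises < 1e-9)
                continue
            assert np.abs(fs.von_mises - ref).max() / ref < 0.02

    def test_frictionless_reaction_force_matches_deformed_area_closed_form(
        self, tissue_material, stack_2_2, fem_frictionless
    ):
        """The platen force is the Cauchy stress times the *deformed*
        contact area; for the laterally free column that area grows as
        1/lambda_z relative to the reference annulus."""
        _, program, fem = fem_frictionless
        uniform = sc.run_uniform(tissue_material, stack_2_2, program)
        for fs, us in zip(fem[1:], uniform[1:]):
            lam_z = 1.0 - us.d / stack_2_2.total_thickness
            assert fs.reaction_force == pytest.approx(
                us.reaction_force / lam_z, rel=0.02
            )

    def test_zero_displacement_is_stress_free(self, fem_frictionless):
        _, _, fem = fem_frictionless
        assert np.all(fem[0].von_mises == 0.0)
        assert fem[0].reaction_force == pytest.approx(0.0, abs=1e-6)


class TestConservationAndMonotonicity:
    @pytest.mark.parametrize("fixture", ["fem_frictionless", "fem_bonded"])
    def test_global_volume_conserved_within_2pct(self, fixture, request):
        _, _, results = request.getfixturevalue(fixture)
        for s in results:
            drift = abs(s.current_volume.sum() - s.ref_volume.sum()) / s.ref_volume.sum()
            assert drift <= 0.02

    @pytest.mark.parametrize("fixture", ["fem_frictionless", "fem_bonded"])
    def test_force_displacement_monotone(self, fixture, request):
        _, _, results = request.getfixturevalue(fixture)
        forces = [s.reaction_force for s in results]
        assert all(b >= a - 1e-6 for a, b in zip(forces, forces[1:]))

    def test_element_volumes_positive(self, fem_bonded):
        _, _, results = fem_bonded
        for s in results:
            assert np.all(s.current_volume > 0.0)


class TestLayerAsymmetry:
    """The contact mechanism: the cartridge presents less effective area
    than the anvil, so the lower layer sees the harsher stress state."""

    def test_lower_layer_max_stress_dominates(self, fem_bonded):
        _, _, results = fem_bonded
        checked = 0
        for s in results:
            if s.ratio >= 0.2:
                assert s.layer_stats["lower"].max_vm >= s.layer_stats["upper"].max_vm
                checked += 1
        assert checked >= 5

    def test_layer_mean_stresses_track(self, fem_bonded):
        _, _, results = fem_bonded
        for s in results:
            if s.ratio >= 0.2:
                lo = s.layer_stats["lower"].mean_vm
                up = s.layer_stats["upper"].mean_vm
                assert abs(lo - up) / max(lo, up) <= 0.2


class TestErrors:
    def test_mesh_stack_mismatch_rejected(self, tissue_material):
        stack = sc.TissueStack(2.0, 2.0)
        other = sc.TissueStack(1.5, 1.5)
        mesh = sc.build_mesh(other, 0.5)
        with pytest.raises(ValueError, match="different tissue stack"):
            sc.run_fem(tissue_material, stack, None, sc.LoadProgram(1.0), mesh)

    def test_bonded_mode_needs_footprints(self, tissue_material, stack_2_2):
        mesh = sc.build_mesh(stack_2_2, 0.8)
        with pytest.raises(ValueError, match="footprints"):
            sc.run_fem(tissue_material, stack_2_2, None, sc.LoadProgram(1.0), mesh)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            sc.SolverOptions(mode="sliding")

    def test_structured_failure_names_the_step(self, tissue_material):
        """Crushing far past the representable regime raises a failure that
        carries the offending step."""
        stack = sc.TissueStack(2.0, 2.0)
        mesh = sc.build_mesh(stack, 0.8)
        fps = sc.default_footprints(stack)
        program = sc.LoadProgram(total_travel=3.2, step_size=0.8)
        options = sc.SolverOptions(bisection_levels=1, max_iterations=10)
        with pytest.raises(sc.NonConvergenceError) as err:
            sc.run_fem(tissue_material, stack, fps, program, mesh, options)
        assert err.value.step_index >= 1
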