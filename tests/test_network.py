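import dataclasses

import numpy as np
import pytest

from ffrct.calibration import OutletBC
from ffrct.config import SolverConfig, paper_defaults
from ffrct.experiments import solve_case
from ffrct.geometry import (EmulatorConfig, build_porcine_lad_emulator,
                            spec_at_location)
from ffrct.network import (NetworkError, build_problem, pressure_pullback,
                           solve_network, trunk_pressure_profile)
from ffrct.segment_models import SegmentLaw
from ffrct.units import mmhg_to_pa


def single_tube_problem(a_v=2e7, R=1e9, p0=0.0, p_in=9270.0, omega=0.5):
    """Series-resistance oracle: Q = P_in / (a_v + R) when P0 = 0."""
    tree = build_porcine_lad_emulator(EmulatorConfig(
        branch_positions_mm=(), branch_diameters_mm=(), locations_mm={"A": 50.0}))
    problem = build_problem(
        tree, paper_defaults().fluid, p_in, {"trunk": OutletBC("trunk", R, p0)},
        numerics=SolverConfig(omega=omega, total_pressure_inlet=False, tol_pa=1e-6))
    # pin the viscous coefficient to the oracle's value
    problem.trunk_pieces[0] = dataclasses.replace(
        problem.trunk_pieces[0], law=SegmentLaw(a_v=a_v, a_t=0.0, provenance="poiseuille"))
    return problem


class TestSingleTubeOracle:
    def test_series_resistance_closed_form(self):
        problem = single_tube_problem()
        sol = solve_network(problem)
        assert sol.converged
        q_exact = 9270.0 / (2e7 + 1e9)
        assert sol.inlet_flow_m3s == pytest.approx(q_exact, rel=1e-9)
        assert sol.outlet_pressures_pa["trunk"] == pytest.approx(1e9 * q_exact, rel=1e-9)
        assert sol.outlet_pressures_pa["trunk"] == pytest.approx(9088.0, abs=1.0)

    def test_fixed_point_initialization_converges_immediately(self):
        problem = single_tube_problem()
        sol = solve_network(problem)
        # re-solve with tightened tolerance starting from scratch: the
        # first outer iteration already lands on the Eq.-(4) fixed point
        assert sol.trace[-1] < problem.numerics.tol_pa
        sol2 = solve_network(problem)
        assert sol2.outlet_pressures_pa["trunk"] == pytest.approx(
            sol.outlet_pressures_pa["trunk"], abs=1e-6)

    @pytest.mark.parametrize("omega", [0.1, 0.5, 1.0])
    def test_omega_independence(self, omega):
        sol = solve_network(single_tube_problem(omega=omega))
        assert sol.converged
        q_exact = 9270.0 / (2e7 + 1e9)
        assert sol.inlet_flow_m3s == pytest.approx(q_exact, rel=1e-8)


class TestEmulatorNetwork:
    def test_junction_mass_conservation(self, study):
        sol, _ = solve_case(study, None)
        q = sol.inlet_flow_m3s
        running = q
        for j in study.tree.children_of("trunk"):
            running -= sol.outlet_flows_m3s[j.child]
        running -= sol.outlet_flows_m3s["trunk"]
        assert abs(running) / q < 1e-10

    def test_outlet_bc_residuals_below_tolerance(self, study):
        sol, _ = solve_case(study, None)
        for bc in study.hyperemic_bcs:
            resid = abs(sol.outlet_pressures_pa[bc.outlet]
                        - (bc.resistance_pa_s_m3 * sol.outlet_flows_m3s[bc.outlet]
                           + bc.back_pressure_pa))
            assert resid < study.config.solver.tol_pa

    def test_omega_independent_outlet_pressures(self, study):
        sols = {}
        for omega in (0.1, 0.5, 1.0):
            cfg = dataclasses.replace(study.config,
                                      solver=dataclasses.replace(study.config.solver,
                                                                 omega=omega))
            ctx = dataclasses.replace(study, config=cfg)
            sols[omega], _ = solve_case(ctx, None)
        tol = 10 * study.config.solver.tol_pa
        for oid in study.tree.outlets:
            p = [sols[w].outlet_pressures_pa[oid] for w in (0.1, 0.5, 1.0)]
            assert max(p) - min(p) < tol

    def test_nonconvergence_flagged_not_silent(self, study):
        cfg = dataclasses.replace(
            study.config, solver=dataclasses.replace(study.config.solver,
                                                     max_iters=2, omega=0.1))
        ctx = dataclasses.replace(study, config=cfg)
        from ffrct.experiments import ExperimentError
        with pytest.raises(ExperimentError, match="converge"):
            solve_case(ctx, None)


class TestFFRAndPullback:
    def test_baseline_ffr_near_unity_at_any_position_pair(self, study):
        sol, _ = solve_case(study, None, bcs=study.resting_bcs,
                            inlet_pressure_mmhg=69.54)
        s, p = trunk_pressure_profile(sol)
        assert p.min() / p.max() >= 0.95  # worst-case pair on the trunk

    def test_baseline_hyperemic_ffr_high(self, study):
        spec = spec_at_location(study.tree, 0.0, 4.0, "A")
        _sol, ffr = solve_case(study, spec)
        assert ffr >= 0.95

    def test_ratio_arithmetic(self):
        assert 55.6 / 69.5 == pytest.approx(0.8, abs=2e-3)

    def test_pullback_monotone_and_additive(self, study):
        spec = spec_at_location(study.tree, 0.55, 4.0, "A")
        sol, _ = solve_case(study, spec)
        pull = pressure_pullback(sol, 150)
        assert pull.shape == (150, 3)
        assert np.all(np.diff(pull[:, 1]) <= 1e-9)  # nonincreasing
        s, p = trunk_pressure_profile(sol)
        assert pull[0, 1] == pytest.approx(p[0] * 7.5006e-3, rel=1e-3)
        assert pull[-1, 1] == pytest.approx(p[-1] * 7.5006e-3, rel=1e-3)

    def test_steepest_gradient_inside_stenotic_extent(self, study):
        spec = spec_at_location(study.tree, 0.65, 4.0, "B")
        sol, _ = solve_case(study, spec)
        s, p = trunk_pressure_profile(sol)
        grad = -np.diff(p) / np.diff(s)
        s_mid = 0.5 * (s[:-1] + s[1:])
        steepest = s_mid[np.argmax(grad)]
        assert spec.s_start <= steepest <= spec.s_end

    def test_pullback_needs_two_points(self, study):
        sol, _ = solve_case(study, None)
        with pytest.raises(NetworkError):
            pressure_pullback(sol, 1)

    def test_ffr_sampling_clips_to_adjacent_junctions(self, study):
        # location D sits 6 mm proximal of branch "g": the distal sample
        # must clip to the junction, not cross it
        spec = spec_at_location(study.tree, 0.55, 4.0, "D")
        sol, ffr = solve_case(study, spec)
        assert 0 < ffr <= 1

    def test_missing_bc_rejected(self, study):
        with pytest.raises(NetworkError, match="without boundary"):
            build_problem(study.tree, study.config.fluid, mmhg_to_pa(69.87),
                          {"a": OutletBC("a", 1e9, 0.0)})
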