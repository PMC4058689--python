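import math

import numpy as np
import pytest

from ffrct.axisym import (AxisymError, AxisymNumerics, export_vtk,
                          export_wall_shear_csv, recirculation_metrics,
                          solve_axisym, wall_shear_profile)
from ffrct.geometry import VesselSegment, make_stenosed_tube
from ffrct.segment_models import stenosis_law, tabulate_from_axisym

Q_REF = 1e-6  # m^3/s (60 mL/min); throat Re 182 at ds=0.45, d=3 mm


@pytest.fixture(scope="module")
def straight_field(fluid):
    seg = VesselSegment.tapered("tube", 20.0, 3.0, 3.0)
    return solve_axisym(seg, Q_REF, fluid, AxisymNumerics(nz=80, nr=12, max_iters=4000))


@pytest.fixture(scope="module")
def field_ds045(fluid):
    seg, _ = make_stenosed_tube(3.0, 0.45, 4.0)
    return solve_axisym(seg, Q_REF, fluid, AxisymNumerics(nz=120, nr=14, max_iters=8000))


@pytest.fixture(scope="module")
def field_ds060(fluid):
    seg, _ = make_stenosed_tube(3.0, 0.60, 4.0)
    return solve_axisym(seg, Q_REF, fluid, AxisymNumerics(nz=120, nr=14, max_iters=8000))


class TestPoiseuilleVerification:
    def test_converged(self, straight_field):
        assert straight_field.converged

    def test_centerline_to_mean_velocity_ratio(self, straight_field):
        f = straight_field
        v_mean = Q_REF / (math.pi * (1.5e-3) ** 2)
        mid = f.grid.nz // 2
        assert f.u_z[mid, 0] / v_mean == pytest.approx(2.0, rel=0.01)

    def test_pressure_drop_matches_closed_form(self, straight_field, fluid):
        dp_exact = (128 * fluid.viscosity_pa_s * 0.02 * Q_REF
                    / (math.pi * (3e-3) ** 4))
        assert straight_field.pressure_drop_pa == pytest.approx(dp_exact, rel=0.02)

    def test_mass_conserved_through_every_section(self, straight_field):
        f = straight_field
        for i in range(f.grid.nz + 1):
            assert f.face_flow(i) == pytest.approx(Q_REF, rel=1e-3)
        # interior cell-velocity integral agrees too
        assert f.section_flow(f.grid.nz // 2) == pytest.approx(Q_REF, rel=1e-3)

    def test_no_recirculation_in_straight_tube(self, straight_field):
        assert recirculation_metrics(straight_field) == (0.0, 0.0)
        _z, tau = wall_shear_profile(straight_field)
        assert np.all(tau > 0)


class TestStenosedFlow:
    def test_recirculation_exists_downstream_of_throat(self, field_ds045):
        assert field_ds045.converged
        reattach, area = recirculation_metrics(field_ds045)
        assert reattach > 0
        assert area > 0

    def test_recirculation_monotone_in_ds(self, field_ds045, field_ds060):
        assert field_ds060.converged
        r45 = recirculation_metrics(field_ds045)
        r60 = recirculation_metrics(field_ds060)
        assert r60[0] > r45[0]
        assert r60[1] > r45[1]

    def test_recirculation_monotone_in_reynolds(self, fluid):
        seg, _ = make_stenosed_tube(3.0, 0.5, 4.0)
        num = AxisymNumerics(nz=120, nr=14, max_iters=8000)
        f_lo = solve_axisym(seg, 0.5 * Q_REF, fluid, num)   # throat Re 100
        f_hi = solve_axisym(seg, 1.0 * Q_REF, fluid, num)   # throat Re 200
        r_lo = recirculation_metrics(f_lo)
        r_hi = recirculation_metrics(f_hi)
        assert r_hi[0] > r_lo[0]

    def test_mass_conserved_across_stenosis(self, field_ds045):
        f = field_ds045
        for i in range(f.grid.nz + 1):
            assert f.face_flow(i) == pytest.approx(Q_REF, rel=1e-3)

    def test_algebraic_law_within_surrogate_band(self, field_ds045, fluid):
        """The viscous+expansion-loss law must sit within 30% of the
        Navier-Stokes pressure drop for moderate stenoses at Re <= 200."""
        seg, spec = make_stenosed_tube(3.0, 0.45, 4.0)
        dp_alg = stenosis_law(seg, spec, fluid).dp(Q_REF)
        assert abs(dp_alg / field_ds045.pressure_drop_pa - 1.0) < 0.30

    def test_algebraic_law_band_holds_at_ds055(self, fluid):
        q = 0.9e-6  # throat Re ~200
        seg, spec = make_stenosed_tube(3.0, 0.55, 4.0)
        field = solve_axisym(seg, q, fluid,
                             AxisymNumerics(nz=120, nr=14, max_iters=8000))
        assert field.converged
        dp_alg = stenosis_law(seg, spec, fluid).dp(q)
        assert abs(dp_alg / field.pressure_drop_pa - 1.0) < 0.30


class TestGridConvergence:
    """Pressure drop must change < 2% under simultaneous (2nz, 2nr)
    refinement once the base grid resolves the flow."""

    def test_straight_tube(self, fluid):
        seg = VesselSegment.tapered("tube", 30.0, 3.0, 3.0)
        dp = [solve_axisym(seg, Q_REF, fluid,
                           AxisymNumerics(nz=nz, nr=nr, max_iters=8000)).pressure_drop_pa
              for nz, nr in ((80, 10), (160, 20))]
        assert abs(dp[1] / dp[0] - 1.0) < 0.02

    @pytest.mark.parametrize("ds", [0.45, 0.55])
    def test_stenosed_tube(self, fluid, ds):
        seg, _ = make_stenosed_tube(3.0, ds, 4.0)
        fields = [solve_axisym(seg, Q_REF, fluid,
                               AxisymNumerics(nz=nz, nr=nr, max_iters=5000))
                  for nz, nr in ((160, 20), (320, 40))]
        assert all(f.converged for f in fields)
        assert abs(fields[1].pressure_drop_pa / fields[0].pressure_drop_pa - 1.0) < 0.02


class TestTabulation:
    def test_straight_tube_fit_recovers_poiseuille(self, fluid):
        from ffrct.segment_models import poiseuille_law
        seg = VesselSegment.tapered("tube", 20.0, 3.0, 3.0)
        law = tabulate_from_axisym(seg, fluid, np.array([5e-7, 1e-6, 2e-6]),
                                   numerics=AxisymNumerics(nz=60, nr=10, max_iters=4000))
        a_v_exact = poiseuille_law(seg, fluid).a_v
        assert law.a_v == pytest.approx(a_v_exact, rel=0.02)
        # quadratic part negligible against the viscous drop
        assert law.a_t * (2e-6) ** 2 < 0.05 * a_v_exact * 2e-6

    def test_stenosed_fit_residual_small(self, fluid):
        seg, _ = make_stenosed_tube(3.0, 0.45, 4.0)
        law = tabulate_from_axisym(seg, fluid, np.array([4e-7, 8e-7, 1.2e-6]),
                                   numerics=AxisymNumerics(nz=100, nr=12, max_iters=8000))
        dp_max = law.dp(1.2e-6)
        assert law.fit_residual < 0.05 * dp_max
        assert law.a_t > 0


class TestGuards:
    def test_turbulent_flow_rejected(self, fluid):
        seg, _ = make_stenosed_tube(3.0, 0.75, 4.0)
        with pytest.raises(AxisymError, match="Reynolds"):
            solve_axisym(seg, 2e-5, fluid)  # throat Re ~ 10^4

    def test_nonconvergence_flagged(self, fluid):
        seg, _ = make_stenosed_tube(3.0, 0.45, 4.0)
        f = solve_axisym(seg, Q_REF, fluid,
                         AxisymNumerics(nz=32, nr=8, max_iters=3))
        assert not f.converged
        with pytest.raises(AxisymError, match="converged"):
            recirculation_metrics(f)

    def test_bad_grid_rejected(self):
        with pytest.raises(AxisymError):
            AxisymNumerics(nz=4, nr=4)


def test_field_exports_are_loadable_text(straight_field, tmp_path):
    vtk = tmp_path / "f.vtk"
    export_vtk(straight_field, vtk)
    text = vtk.read_text()
    assert text.startswith("# vtk DataFile")
    assert "SCALARS u_z" in text
    csv = tmp_path / "tau.csv"
    export_wall_shear_csv(straight_field, csv)
    assert csv.read_text().startswith("z_mm,tau_wall_pa")
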