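"""Outlet resistance calibration and hyperemic scaling.

Each coronary outlet is closed by a resistance boundary condition
P_i = R_i Q_i + P_{0,i} representing its downstream vascular bed. The pair
(R_i, P_{0,i}) is identified from two steady solves of the healthy
(stenosis-free) tree — one at the peak-systolic inlet pressure, one at the
peak-diastolic — with outlet flows prescribed by the generalized Murray
law. The two (Q_i, P_i) samples determine the line exactly:

    R_i = (P_i^sys - P_i^dia) / (Q_i^sys - Q_i^dia)
    P_{0,i} = P_i^sys - R_i Q_i^sys

A single-point mode with a fixed back pressure is available as an
alternative. Maximal hyperemia is modeled by scaling every R_i by a fixed
factor (default 0.21, i.e. the bed resistance falls to 21% of rest) while
back pressures are left unchanged. Because the microvascular bed is
assumed insensitive to the epicardial stenosis, calibrated BCs transfer
unchanged from the baseline tree to any stenosed variant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .config import Fluid
from .flow_split import FlowSplit, assign_baseline_flows
from .geometry import CoronaryTree
from .segment_models import poiseuille_law
from .units import MM_TO_M, mlmin_to_m3s, mmhg_to_pa, pa_to_mmhg


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class OutletBC:
    outlet: str
    resistance_pa_s_m3: float
    back_pressure_pa: float

    def __post_init__(self) -> None:
        if self.resistance_pa_s_m3 <= 0:
            raise CalibrationError(
                f"outlet {self.outlet!r}: resistance must be positive, "
                f"got {self.resistance_pa_s_m3:.3e}")
        if self.back_pressure_pa < 0:
            raise CalibrationError(
                f"outlet {self.outlet!r}: back pressure must be >= 0, "
                f"got {self.back_pressure_pa:.1f} Pa")


@dataclass(frozen=True)
class CalibrationState:
    """One steady baseline operating point."""

    label: str  # systole | diastole
    inlet_pressure_mmhg: float
    total_inflow_ml_min: float

    def __post_init__(self) -> None:
        if self.inlet_pressure_mmhg <= 0 or self.total_inflow_ml_min <= 0:
            raise CalibrationError(f"state {self.label!r}: pressure and inflow must be positive")


def prescribed_flow_solve(tree: CoronaryTree, fluid: Fluid, split: FlowSplit,
                          inlet_pressure_pa: float, total_inflow_m3s: float,
                          total_pressure_inlet: bool = True) -> dict:
    """March pressures down the baseline tree with prescribed outlet flows.

    Returns outlet id -> (Q_i [m^3/s], P_i [Pa]). With flows prescribed the
    network is linear in pressure and solves in one pass.
    """
    flows_ml = assign_baseline_flows(tree, split, 1.0)  # fractions
    q_out = {oid: f * total_inflow_m3s for oid, f in flows_ml.items()}
    trunk = tree.trunk
    p_in = inlet_pressure_pa
    if total_pressure_inlet:
        d_in = float(trunk.samples_d[0]) * MM_TO_M
        v = total_inflow_m3s / (np.pi / 4.0 * d_in ** 2)
        p_in = inlet_pressure_pa - 0.5 * fluid.density_kg_m3 * v ** 2

    from .network import _extract_piece  # shared trunk-cutting helper

    junctions = tree.children_of(tree.inlet)
    cuts = [0.0] + [j.s for j in junctions] + [trunk.length]
    q = total_inflow_m3s
    p = p_in
    result = {}
    for k, (s0, s1) in enumerate(zip(cuts[:-1], cuts[1:])):
        piece = _extract_piece(trunk, s0, s1)
        p = p - poiseuille_law(piece, fluid).dp(q)
        if k < len(junctions):
            j = junctions[k]
            branch_drop = poiseuille_law(tree.segment(j.child), fluid).dp(q_out[j.child])
            result[j.child] = (q_out[j.child], p - branch_drop)
            q -= q_out[j.child]
    result[tree.inlet] = (q, p)
    return result


def calibrate_two_point(tree: CoronaryTree, fluid: Fluid, split: FlowSplit,
                        state_sys: CalibrationState, state_dia: CalibrationState,
                        total_pressure_inlet: bool = True) -> list[OutletBC]:
    """Fit (R_i, P_0i) per outlet from the two baseline operating points."""
    if abs(state_sys.total_inflow_ml_min - state_dia.total_inflow_ml_min) < 1e-12:
        raise CalibrationError("calibration states have identical flows; the fit is degenerate")
    samples = {}
    for state in (state_sys, state_dia):
        samples[state.label] = prescribed_flow_solve(
            tree, fluid, split,
            mmhg_to_pa(state.inlet_pressure_mmhg),
            mlmin_to_m3s(state.total_inflow_ml_min),
            total_pressure_inlet=total_pressure_inlet)
    bcs = []
    for oid in tree.outlets:
        q_s, p_s = samples[state_sys.label][oid]
        q_d, p_d = samples[state_dia.label][oid]
        r = (p_s - p_d) / (q_s - q_d)
        p0 = p_s - r * q_s
        if r <= 0:
            raise CalibrationError(
                f"outlet {oid!r}: nonpositive fitted resistance ({r:.3e}); "
                "the calibration states are inconsistent")
        if p0 >= min(p_s, p_d):
            raise CalibrationError(
                f"outlet {oid!r}: back pressure {pa_to_mmhg(p0):.1f} mmHg is not "
                "below both calibration pressures; states are inconsistent")
        bcs.append(OutletBC(outlet=oid, resistance_pa_s_m3=r, back_pressure_pa=p0))
    return bcs


def calibrate_single_point(tree: CoronaryTree, fluid: Fluid, split: FlowSplit,
                           state: CalibrationState, back_pressure_mmhg: float = 0.0,
                           total_pressure_inlet: bool = True) -> list[OutletBC]:
    """R_i = (P_i - P_0) / Q_i at one operating point with P_0 fixed."""
    p0 = mmhg_to_pa(back_pressure_mmhg)
    samples = prescribed_flow_solve(
        tree, fluid, split, mmhg_to_pa(state.inlet_pressure_mmhg),
        mlmin_to_m3s(state.total_inflow_ml_min),
        total_pressure_inlet=total_pressure_inlet)
    bcs = []
    for oid in tree.outlets:
        q_i, p_i = samples[oid]
        if p_i <= p0:
            raise CalibrationError(
                f"outlet {oid!r}: outlet pressure below the fixed back pressure")
        bcs.append(OutletBC(outlet=oid, resistance_pa_s_m3=(p_i - p0) / q_i,
                            back_pressure_pa=p0))
    return bcs


def apply_hyperemia(bcs: list[OutletBC], factor: float = 0.21) -> list[OutletBC]:
    """Scale every outlet resistance by ``factor``; back pressures unchanged."""
    if not 0 < factor <= 1:
        raise CalibrationError(f"hyperemia factor must be in (0, 1], got {factor}")
    return [replace(bc, resistance_pa_s_m3=bc.resistance_pa_s_m3 * factor)
            for bc in bcs]


def scale_resistances(bcs: list[OutletBC], factor: float) -> list[OutletBC]:
    """Uniformly rescale resistances (sensitivity studies); factor > 0."""
    if factor <= 0:
        raise CalibrationError(f"resistance scale factor must be positive, got {factor}")
    return [replace(bc, resistance_pa_s_m3=bc.resistance_pa_s_m3 * factor)
            for bc in bcs]


def bcs_to_dict(bcs: list[OutletBC]) -> list[dict]:
    return [{"outlet": bc.outlet,
             "R_pa_s_per_m3": bc.resistance_pa_s_m3,
             "p0_mmHg": pa_to_mmhg(bc.back_pressure_pa)} for bc in bcs]


def write_bcs(bcs: list[OutletBC], path: str | Path) -> None:
    Path(path).write_text(json.dumps(bcs_to_dict(bcs), indent=1))


def read_bcs(path: str | Path) -> list[OutletBC]:
    data = json.loads(Path(path).read_text())
    out = []
    for row in data:
        for key in ("outlet", "R_pa_s_per_m3", "p0_mmHg"):
            if key not in row:
                raise CalibrationError(f"BC record missing key {key!r}")
        out.append(OutletBC(outlet=row["outlet"],
                            resistance_pa_s_m3=float(row["R_pa_s_per_m3"]),
                            back_pressure_pa=mmhg_to_pa(float(row["p0_mmHg"]))))
    return out
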