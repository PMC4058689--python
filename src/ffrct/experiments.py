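"""Parametric studies: DS, location and length sweeps, and the
resistance-sensitivity analysis.

All studies share the same pipeline: build the emulated LAD, calibrate
outlet resistances on the healthy tree, apply hyperemic scaling, insert
one idealized stenosis, solve the coupled network at the hyperemic inlet
total pressure, and read FFR_CT off the trunk pressure profile. Every
stage is deterministic given the configuration; the configuration hash is
recorded in each result for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import (CalibrationState, apply_hyperemia,
                          calibrate_single_point, calibrate_two_point,
                          scale_resistances)
from .config import RunConfig, paper_defaults
from .flow_split import FlowSplit, tree_murray_split
from .geometry import (CoronaryTree, EmulatorConfig, StenosisSpec,
                       build_porcine_lad_emulator, insert_stenosis,
                       spec_at_location)
from .network import (NetworkSolution, build_problem, compute_ffr,
                      solve_network)
from .units import m3s_to_mlmin, mlmin_to_m3s, mmhg_to_pa


class ExperimentError(ValueError):
    pass


@dataclass
class StudyContext:
    """Shared pipeline state: geometry, split and calibrated BCs."""

    config: RunConfig
    tree: CoronaryTree
    split: FlowSplit
    resting_bcs: list
    hyperemic_bcs: list


@dataclass
class SweepResult:
    kind: str
    table: pd.DataFrame  # one row per sweep value, ordered
    config_hash: str


def setup_study(config: RunConfig | None = None) -> StudyContext:
    cfg = config or paper_defaults()
    tree = build_porcine_lad_emulator(EmulatorConfig(**cfg.geometry))
    split = tree_murray_split(tree, cfg.flow.murray_exponent)
    cal = cfg.calibration
    if cal.mode == "two_point":
        resting = calibrate_two_point(
            tree, cfg.fluid, split,
            CalibrationState("systole", cal.systole_pressure_mmhg, cal.systole_inflow_ml_min),
            CalibrationState("diastole", cal.diastole_pressure_mmhg, cal.diastole_inflow_ml_min),
            total_pressure_inlet=cfg.solver.total_pressure_inlet)
    else:
        resting = calibrate_single_point(
            tree, cfg.fluid, split,
            CalibrationState("mean", cfg.pressures.resting_inlet_mmhg,
                             cfg.flow.total_resting_inflow_ml_min),
            back_pressure_mmhg=cal.single_point_back_pressure_mmhg,
            total_pressure_inlet=cfg.solver.total_pressure_inlet)
    hyper = apply_hyperemia(resting, cal.hyperemia_factor)
    return StudyContext(config=cfg, tree=tree, split=split,
                        resting_bcs=resting, hyperemic_bcs=hyper)


def solve_case(ctx: StudyContext, spec: StenosisSpec | None,
               bcs: list | None = None,
               inlet_pressure_mmhg: float | None = None) -> tuple[NetworkSolution, float | None]:
    """Solve one (possibly stenosed) hyperemic case; returns (solution, FFR)."""
    cfg = ctx.config
    bcs = ctx.hyperemic_bcs if bcs is None else bcs
    p_in = cfg.pressures.hyperemic_inlet_mmhg if inlet_pressure_mmhg is None else inlet_pressure_mmhg
    tree = ctx.tree if spec is None or spec.ds == 0 else insert_stenosis(ctx.tree, spec)
    problem = build_problem(
        tree, cfg.fluid, mmhg_to_pa(p_in), {bc.outlet: bc for bc in bcs},
        stenosis=spec if spec is not None and spec.ds > 0 else None,
        Kt=cfg.stenosis_model.Kt, numerics=cfg.solver,
        law_backend=cfg.stenosis_model.segment_law_backend,
        axisym_flow_grid_m3s=tuple(mlmin_to_m3s(q) for q
                                   in cfg.stenosis_model.axisym_flow_grid_ml_min))
    solution = solve_network(problem)
    if not solution.converged:
        raise ExperimentError("network solve did not converge")
    ffr = None
    if spec is not None:
        ffr = compute_ffr(solution, spec, cfg.solver.pa_offset_mm, cfg.solver.pd_offset_mm)
    return solution, ffr


def _row(ctx: StudyContext, value, spec: StenosisSpec | None) -> dict:
    solution, ffr = solve_case(ctx, spec)
    flows = {f"Q_{oid}_ml_min": m3s_to_mlmin(q)
             for oid, q in solution.outlet_flows_m3s.items()}
    return {"value": value, "ffr_ct": ffr,
            "total_outlet_flow_ml_min": m3s_to_mlmin(solution.inlet_flow_m3s),
            "iterations": solution.iterations, **flows}


def sweep_ds(ctx: StudyContext, ds_values=None) -> SweepResult:
    """FFR_CT versus diameter stenosis at the default location and length."""
    cfg = ctx.config
    ds_values = tuple(cfg.sweep.ds_values if ds_values is None else ds_values)
    if not ds_values:
        raise ExperimentError("empty DS grid")
    rows = []
    for ds in sorted(ds_values):
        spec = spec_at_location(ctx.tree, ds, cfg.sweep.default_length_mm,
                                cfg.sweep.default_location)
        rows.append(_row(ctx, ds, spec))
    return SweepResult("ds", pd.DataFrame(rows), ctx.config.config_hash())


def sweep_location(ctx: StudyContext, locations=None) -> SweepResult:
    """FFR_CT versus stenosis location (proximal 'A' to distal 'D')."""
    cfg = ctx.config
    locations = tuple(cfg.sweep.locations if locations is None else locations)
    if not locations:
        raise ExperimentError("empty location grid")
    known = ctx.tree.locations()
    rows = []
    for loc in locations:
        if loc not in known:
            raise ExperimentError(f"location {loc!r} not defined in tree metadata")
        spec = spec_at_location(ctx.tree, cfg.sweep.default_ds,
                                cfg.sweep.default_length_mm, loc)
        rows.append(_row(ctx, loc, spec))
    return SweepResult("location", pd.DataFrame(rows), ctx.config.config_hash())


def sweep_length(ctx: StudyContext, lengths_mm=None) -> SweepResult:
    """FFR_CT versus stenosis length at the default DS and location."""
    cfg = ctx.config
    lengths = tuple(cfg.sweep.lengths_mm if lengths_mm is None else lengths_mm)
    if not lengths:
        raise ExperimentError("empty length grid")
    rows = []
    for length in sorted(lengths):
        if length == 0:
            spec = spec_at_location(ctx.tree, 0.0, cfg.sweep.default_length_mm,
                                    cfg.sweep.default_location)
        else:
            spec = spec_at_location(ctx.tree, cfg.sweep.default_ds, length,
                                    cfg.sweep.default_location)
        rows.append(_row(ctx, length, spec))
    return SweepResult("length", pd.DataFrame(rows), ctx.config.config_hash())


def resistance_sensitivity(ctx: StudyContext, factors=None,
                           spec: StenosisSpec | None = None) -> pd.DataFrame:
    """FFR_CT change under uniform scaling of all outlet resistances.

    Returns a table of (factor, ffr_ct, rel_diff_percent) against the
    factor-1 reference; the maximum |rel_diff_percent| quantifies how
    robust FFR_CT is to errors in the calibrated resistances.
    """
    cfg = ctx.config
    factors = tuple(cfg.sweep.sensitivity_factors if factors is None else factors)
    if any(f <= 0 for f in factors):
        raise ExperimentError("sensitivity factors must be positive")
    if spec is None:
        spec = spec_at_location(ctx.tree, cfg.sweep.default_ds,
                                cfg.sweep.default_length_mm, cfg.sweep.default_location)
    _sol, ffr_ref = solve_case(ctx, spec)
    rows = []
    for factor in sorted(set(factors) | {1.0}):
        if factor == 1.0:
            ffr = ffr_ref
        else:
            bcs = scale_resistances(ctx.hyperemic_bcs, factor)
            _sol, ffr = solve_case(ctx, spec, bcs=bcs)
        rows.append({"factor": factor, "ffr_ct": ffr,
                     "rel_diff_percent": abs(ffr - ffr_ref) / ffr_ref * 100.0})
    return pd.DataFrame(rows)


def threshold_ds(sweep: SweepResult, ffr_threshold: float = 0.8) -> float:
    """%DS at which the DS sweep crosses the FFR threshold (nearest 1%)."""
    table = sweep.table
    ds = np.asarray(table["value"], dtype=float)
    ffr = np.asarray(table["ffr_ct"], dtype=float)
    if np.any(np.diff(ffr) >= 0):
        raise ExperimentError("FFR column is not strictly decreasing in DS")
    exact = np.isclose(ffr, ffr_threshold)
    if exact.any():
        return float(round(ds[exact][0] * 100.0))
    if not (ffr.min() < ffr_threshold < ffr.max()):
        raise ExperimentError(
            f"threshold {ffr_threshold} not bracketed by FFR range "
            f"[{ffr.min():.3f}, {ffr.max():.3f}]")
    # np.interp needs increasing x; FFR decreases with DS
    crossing = np.interp(ffr_threshold, ffr[::-1], ds[::-1])
    return float(round(crossing * 100.0))


def flow_report(ctx: StudyContext, ds_values=None) -> pd.DataFrame:
    """Per-outlet flow table (mL/min) across the DS grid, plus baseline."""
    cfg = ctx.config
    ds_values = tuple(cfg.sweep.ds_values if ds_values is None else ds_values)
    rows = []
    for ds in (0.0,) + tuple(sorted(ds_values)):
        if ds == 0.0:
            solution, _ = solve_case(ctx, None)
        else:
            spec = spec_at_location(ctx.tree, ds, cfg.sweep.default_length_mm,
                                    cfg.sweep.default_location)
            solution, _ = solve_case(ctx, spec)
        row = {"ds": ds, "total_ml_min": m3s_to_mlmin(solution.inlet_flow_m3s)}
        for oid, q in solution.outlet_flows_m3s.items():
            row[oid] = m3s_to_mlmin(q)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_sweeps(ds: SweepResult, loc: SweepResult, length: SweepResult, path) -> None:
    """Three-panel line plot of the DS / location / length sweeps."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    axes[0].plot(ds.table["value"] * 100, ds.table["ffr_ct"], "o-")
    axes[0].axhline(0.8, ls="--", c="gray")
    axes[0].set_xlabel("diameter stenosis [%]")
    axes[1].plot(loc.table["value"], loc.table["ffr_ct"], "o-")
    axes[1].set_xlabel("stenosis location")
    axes[2].plot(length.table["value"], length.table["ffr_ct"], "o-")
    axes[2].set_xlabel("stenosis length [mm]")
    for ax in axes:
        ax.set_ylabel("FFR$_{CT}$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
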