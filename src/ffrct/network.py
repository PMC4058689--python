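"""Coupled steady flow network solve and FFR_CT.

The tree is assembled into a nonlinear resistive network: the trunk is cut
at every branch take-off into pieces, each piece and each branch carrying
a signed drop law dP(Q) = a_v Q + a_t Q|Q|. The inlet carries a prescribed
total pressure; every outlet carries a resistance boundary condition
P_i = R_i Q_i + P_{0,i} representing its downstream vascular bed.

The coupling is solved with a two-level iteration: an inner damped Newton
solve of the junction mass balances with outlet pressures held fixed,
wrapped in an outer implicit underrelaxed outlet-pressure update

    P_i^{n+1} = P_i^n + omega * (R_i Q_i^{n+1} + P_{0,i} - P_i^n)

which stops when the largest outlet-pressure change falls below tol_pa.
FFR_CT is the ratio of trunk pressure sampled distal over proximal to the
stenotic extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import Fluid, SolverConfig
from .geometry import CoronaryTree, StenosisSpec, VesselSegment
from .segment_models import SegmentLaw, poiseuille_law, stenosis_law, viscous_drop_profile
from .units import MM_TO_M


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class TrunkPiece:
    """Portion of the trunk between consecutive nodes (junctions or ends)."""

    s_start: float  # global trunk arclength, mm
    s_end: float
    segment: VesselSegment  # local profile, s in [0, s_end - s_start]
    law: SegmentLaw
    stenosis: StenosisSpec | None = None  # local-coordinate spec if stenosed


@dataclass
class NetworkProblem:
    tree: CoronaryTree
    fluid: Fluid
    trunk_pieces: list[TrunkPiece]
    branch_laws: dict  # branch id -> SegmentLaw
    inlet_total_pressure_pa: float
    outlet_bcs: dict  # outlet id -> OutletBC
    numerics: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        missing = set(self.tree.outlets) - set(self.outlet_bcs)
        if missing:
            raise NetworkError(f"outlets without boundary conditions: {sorted(missing)}")


@dataclass
class NetworkSolution:
    converged: bool
    iterations: int
    node_pressures_pa: dict  # "inlet", junction node names, outlet ids
    outlet_flows_m3s: dict
    outlet_pressures_pa: dict
    inlet_flow_m3s: float
    inlet_static_pressure_pa: float
    trace: list  # per outer iteration: max outlet-pressure change [Pa]
    problem: NetworkProblem


def _extract_piece(trunk: VesselSegment, s0: float, s1: float) -> VesselSegment:
    s = np.asarray(trunk.samples_s)
    d = np.asarray(trunk.samples_d)
    inner = (s > s0) & (s < s1)
    s_new = np.concatenate([[s0], s[inner], [s1]])
    d_new = np.interp(s_new, s, d)
    return VesselSegment.from_profile(f"{trunk.id}[{s0:g},{s1:g}]", s_new - s0, d_new,
                                      role=trunk.role)


def build_problem(tree: CoronaryTree, fluid: Fluid,
                  inlet_total_pressure_pa: float, outlet_bcs: dict,
                  stenosis: StenosisSpec | None = None, Kt: float = 1.52,
                  numerics: SolverConfig | None = None,
                  stenosis_law_override: SegmentLaw | None = None,
                  law_backend: str = "algebraic",
                  axisym_flow_grid_m3s: tuple[float, ...] | None = None) -> NetworkProblem:
    """Assemble segment laws for a (possibly stenosed) tree.

    ``stenosis`` describes where the quadratic-loss law applies; the tree
    must already carry the narrowed profile. ``stenosis_law_override``
    substitutes an externally fitted law for the algebraic one on the
    stenosed piece; ``law_backend='axisym'`` tabulates that law from the
    axisymmetric Navier-Stokes solver over ``axisym_flow_grid_m3s``.
    """
    trunk = tree.trunk
    cuts = [0.0] + [j.s for j in tree.children_of(tree.inlet)] + [trunk.length]
    pieces: list[TrunkPiece] = []
    for s0, s1 in zip(cuts[:-1], cuts[1:]):
        seg = _extract_piece(trunk, s0, s1)
        local_spec = None
        if stenosis is not None and s0 <= stenosis.center_s <= s1:
            if stenosis.s_start < s0 or stenosis.s_end > s1:
                raise NetworkError("stenotic extent crosses a junction")
            local_spec = StenosisSpec(ds=stenosis.ds, length=stenosis.length,
                                      center_s=stenosis.center_s - s0,
                                      shape=stenosis.shape)
            if stenosis_law_override is not None:
                law = stenosis_law_override
            elif law_backend == "axisym":
                from .segment_models import tabulate_from_axisym
                grid_q = axisym_flow_grid_m3s or (5e-7, 1e-6, 2e-6)
                law = tabulate_from_axisym(seg, fluid, np.asarray(grid_q))
            else:
                law = stenosis_law(seg, local_spec, fluid, Kt=Kt)
        else:
            law = poiseuille_law(seg, fluid)
        pieces.append(TrunkPiece(s_start=s0, s_end=s1, segment=seg, law=law,
                                 stenosis=local_spec))
    branch_laws = {}
    for j in tree.children_of(tree.inlet):
        branch_laws[j.child] = poiseuille_law(tree.segment(j.child), fluid)
    return NetworkProblem(tree=tree, fluid=fluid, trunk_pieces=pieces,
                          branch_laws=branch_laws,
                          inlet_total_pressure_pa=inlet_total_pressure_pa,
                          outlet_bcs=outlet_bcs,
                          numerics=numerics or SolverConfig())


# ---------------------------------------------------------------------------
# Inner solve: junction pressures with outlet pressures held fixed
# ---------------------------------------------------------------------------

def _solve_inner(problem: NetworkProblem, p_inlet: float,
                 outlet_p: dict, p_junctions0: np.ndarray
                 ) -> tuple[np.ndarray, dict, float, dict]:
    """Damped Newton on junction mass balance with outlet pressures fixed.

    Returns junction pressures, outlet flows, inlet flow, and the network
    flow sensitivity g_i = -dQ_i/dP_i at each outlet (the Thevenin
    conductance seen from the outlet), used to make the outer
    outlet-pressure update implicit in Q^{n+1}.
    """
    tree = problem.tree
    junctions = tree.children_of(tree.inlet)
    m = len(junctions)
    pieces = problem.trunk_pieces
    # chain: node 0 = inlet, nodes 1..m = junctions, node m+1 = trunk outlet
    p_chain = np.empty(m + 2)
    p_chain[0] = p_inlet
    p_chain[-1] = outlet_p[tree.inlet]
    x = p_junctions0.copy()

    if m == 0:  # single-tube degenerate tree
        q = pieces[0].law.flow(p_inlet - p_chain[-1])
        return x, {tree.inlet: q}, float(q), {tree.inlet: pieces[0].law.conductance(q)}

    def residual(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        p_chain[1:m + 1] = x
        q_pieces = np.array([pieces[k].law.flow(p_chain[k] - p_chain[k + 1])
                             for k in range(m + 1)])
        q_branches = np.array([problem.branch_laws[j.child].flow(x[k] - outlet_p[j.child])
                               for k, j in enumerate(junctions)])
        res = q_pieces[:-1] - q_pieces[1:] - q_branches
        return res, q_pieces, q_branches

    def jacobian(x: np.ndarray, q_pieces: np.ndarray, q_branches: np.ndarray) -> np.ndarray:
        g_piece = np.array([pieces[k].law.conductance(q_pieces[k]) for k in range(m + 1)])
        g_branch = np.array([problem.branch_laws[j.child].conductance(q_branches[k])
                             for k, j in enumerate(junctions)])
        jac = np.zeros((m, m))
        for k in range(m):
            jac[k, k] = -g_piece[k] - g_piece[k + 1] - g_branch[k]
            if k > 0:
                jac[k, k - 1] = g_piece[k]
            if k < m - 1:
                jac[k, k + 1] = g_piece[k + 1]
        return jac

    res, q_pieces, q_branches = residual(x)
    scale = max(abs(q_pieces[0]), 1e-12)
    damping = problem.numerics.newton_damping
    for it in range(200):
        if np.max(np.abs(res)) < 1e-13 * scale:
            break
        jac = jacobian(x, q_pieces, q_branches)
        try:
            step = np.linalg.solve(jac, -res)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise NetworkError("singular network Jacobian") from exc
        lam = damping if it < 3 else 1.0
        x_new = x + lam * step
        res_new, qp_new, qb_new = residual(x_new)
        # backtrack if the step grew the residual
        k_bt = 0
        while np.max(np.abs(res_new)) > np.max(np.abs(res)) and k_bt < 30:
            lam *= 0.5
            x_new = x + lam * step
            res_new, qp_new, qb_new = residual(x_new)
            k_bt += 1
        x, res, q_pieces, q_branches = x_new, res_new, qp_new, qb_new
        scale = max(abs(q_pieces[0]), 1e-12)
    outlet_flows = {j.child: q_branches[k] for k, j in enumerate(junctions)}
    outlet_flows[tree.inlet] = q_pieces[-1]

    # Thevenin conductance at each outlet: linearize the network at the
    # solution and propagate a unit outlet-pressure perturbation through
    # the junction system.
    jac = jacobian(x, q_pieces, q_branches)
    jinv = np.linalg.inv(jac)
    g_piece = np.array([pieces[k].law.conductance(q_pieces[k]) for k in range(m + 1)])
    sens = {}
    for k, j in enumerate(junctions):
        gb = problem.branch_laws[j.child].conductance(q_branches[k])
        # d res/d P_out,i = +gb at row k; dx = -Jinv * (gb e_k)
        dxk = -jinv[k, k] * gb
        sens[j.child] = gb * (1.0 - dxk)
    gt = g_piece[-1]
    dxm = -jinv[m - 1, m - 1] * gt
    sens[tree.inlet] = gt * (1.0 - dxm)
    return x, outlet_flows, float(q_pieces[0]), sens


def solve_network(problem: NetworkProblem) -> NetworkSolution:
    """Outer underrelaxed outlet coupling around the inner Newton solve."""
    tree = problem.tree
    num = problem.numerics
    junctions = tree.children_of(tree.inlet)
    bcs = problem.outlet_bcs

    p_total = problem.inlet_total_pressure_pa
    d_inlet_m = float(tree.trunk.samples_d[0]) * MM_TO_M
    area_inlet = np.pi / 4.0 * d_inlet_m ** 2

    # initialize each outlet on its resistance line at the flow a linear
    # series estimate (bed + epicardial path, viscous part only) predicts
    junc_list = tree.children_of(tree.inlet)
    path_r = {}
    cum = 0.0
    for k, piece in enumerate(problem.trunk_pieces):
        cum += piece.law.a_v
        if k < len(junc_list):
            path_r[junc_list[k].child] = cum + problem.branch_laws[junc_list[k].child].a_v
    path_r[tree.inlet] = cum
    outlet_p = {}
    q_init = {}
    for oid in tree.outlets:
        bc = bcs[oid]
        q0 = max((p_total - bc.back_pressure_pa)
                 / (bc.resistance_pa_s_m3 + path_r[oid]), 0.0)
        q_init[oid] = q0
        outlet_p[oid] = bc.back_pressure_pa + bc.resistance_pa_s_m3 * q0
    p_inlet = p_total

    p_junc = np.linspace(p_inlet, np.mean(list(outlet_p.values())),
                         len(junctions) + 2)[1:-1]
    trace: list[float] = []
    converged = False
    q_in = 0.0
    outlet_flows: dict = {}
    for it in range(1, num.max_iters + 1):
        p_junc, outlet_flows, q_in, sens = _solve_inner(problem, p_inlet, outlet_p, p_junc)
        max_change = 0.0
        for oid in tree.outlets:
            bc = bcs[oid]
            # implicit underrelaxed update: P^{n+1} = P^n + omega (R Q^{n+1}
            # + P0 - P^n) with Q^{n+1} ~= Q^n - g (P^{n+1} - P^n), where g is
            # the network conductance seen from the outlet. Solving for
            # P^{n+1} keeps the Eq.-(4) fixed point and is unconditionally
            # stable even though the bed resistance R dwarfs the epicardial
            # resistance.
            r = bc.resistance_pa_s_m3
            target = r * outlet_flows[oid] + bc.back_pressure_pa
            new_p = outlet_p[oid] + num.omega * (target - outlet_p[oid]) \
                / (1.0 + num.omega * r * sens[oid])
            # converge on the BC residual |R Q + P0 - P|, which bounds the
            # pressure change and is the invariant the solution must satisfy
            max_change = max(max_change, abs(target - outlet_p[oid]))
            outlet_p[oid] = new_p
        if num.total_pressure_inlet:
            v_in = q_in / area_inlet
            head = 0.5 * problem.fluid.density_kg_m3 * v_in ** 2
            # the dynamic head is a small correction (<1 mmHg); clamp and
            # underrelax it so a poor transient flow cannot destabilize
            head = min(head, 0.2 * p_total)
            p_inlet_new = p_inlet + num.omega * ((p_total - head) - p_inlet)
            max_change = max(max_change, abs(p_inlet_new - p_inlet))
            p_inlet = p_inlet_new
        trace.append(max_change)
        if max_change < num.tol_pa:
            converged = True
            break
    node_pressures = {"inlet": p_inlet}
    for k, j in enumerate(junctions):
        node_pressures[f"junction_{j.child}"] = float(p_junc[k])
    for oid in tree.outlets:
        node_pressures[oid] = float(outlet_p[oid])
    if q_in < 0:
        converged = False  # backward inlet flow signals inconsistent BCs
    return NetworkSolution(
        converged=converged, iterations=len(trace),
        node_pressures_pa=node_pressures,
        outlet_flows_m3s=dict(outlet_flows),
        outlet_pressures_pa=dict(outlet_p),
        inlet_flow_m3s=q_in,
        inlet_static_pressure_pa=float(p_inlet),
        trace=trace, problem=problem)


# ---------------------------------------------------------------------------
# Trunk pressure sampling, pullback and FFR
# ---------------------------------------------------------------------------

def _piece_flows(solution: NetworkSolution) -> list[float]:
    """Flow through each trunk piece, proximal to distal."""
    q = solution.inlet_flow_m3s
    flows = [q]
    tree = solution.problem.tree
    for j in tree.children_of(tree.inlet):
        q = q - solution.outlet_flows_m3s[j.child]
        flows.append(q)
    return flows


def trunk_pressure_profile(solution: NetworkSolution,
                           n_per_piece: int = 80) -> tuple[np.ndarray, np.ndarray]:
    """(s [mm], P [Pa]) along the trunk from inlet to distal end.

    Viscous losses accumulate with the local d^-4 Poiseuille kernel; the
    expansion loss of a stenosed piece is deposited across the stenotic
    extent in proportion to the local excess narrowing, which concentrates
    it at the throat.
    """
    problem = solution.problem
    flows = _piece_flows(solution)
    s_all: list[np.ndarray] = []
    p_all: list[np.ndarray] = []
    p_node = solution.inlet_static_pressure_pa
    for piece, q in zip(problem.trunk_pieces, flows):
        s_local = np.linspace(0.0, piece.s_end - piece.s_start, n_per_piece)
        if piece.stenosis is not None:
            s_local = np.unique(np.concatenate([
                s_local,
                np.linspace(piece.stenosis.s_start, piece.stenosis.s_end, 101)]))
            s_local = s_local[(s_local >= 0) & (s_local <= piece.s_end - piece.s_start)]
        visc = viscous_drop_profile(piece.segment, problem.fluid, s_local) * q
        p_local = p_node - visc
        if piece.stenosis is not None and piece.law.a_t > 0:
            dp_t = piece.law.a_t * q * abs(q)
            d = np.asarray(piece.segment.diameter(s_local), dtype=float)
            d_ref = np.interp(s_local,
                              [0.0, piece.segment.length],
                              [piece.segment.samples_d[0], piece.segment.samples_d[-1]])
            excess = np.maximum(d ** -4 - d_ref ** -4, 0.0)
            cum = np.concatenate([[0.0], np.cumsum(0.5 * (excess[1:] + excess[:-1])
                                                   * np.diff(s_local))])
            total = cum[-1]
            ramp = cum / total if total > 0 else np.linspace(0, 1, s_local.size)
            p_local = p_local - dp_t * ramp
        s_all.append(s_local + piece.s_start)
        p_all.append(p_local)
        p_node = float(p_local[-1])
    s = np.concatenate(s_all)
    p = np.concatenate(p_all)
    order = np.argsort(s, kind="stable")
    s, p = s[order], p[order]
    keep = np.concatenate([[True], np.diff(s) > 0])  # drop duplicated piece joints
    return s[keep], p[keep]


def pressure_pullback(solution: NetworkSolution, n_points: int = 100) -> np.ndarray:
    """Rows of (s [mm], P [mmHg], P / P_inlet) sampled along the trunk."""
    from .units import PA_TO_MMHG

    if n_points < 2:
        raise NetworkError("pullback needs at least 2 points")
    s_prof, p_prof = trunk_pressure_profile(solution)
    s = np.linspace(0.0, solution.problem.tree.trunk.length, n_points)
    p = np.interp(s, s_prof, p_prof)
    p_in = solution.inlet_static_pressure_pa
    return np.column_stack([s, p * PA_TO_MMHG, p / p_in])


def trunk_pressure_drop_mmhg(solution: NetworkSolution) -> float:
    """Total static pressure drop from trunk inlet to distal trunk end."""
    from .units import PA_TO_MMHG

    _s, p = trunk_pressure_profile(solution)
    return float((p[0] - p[-1]) * PA_TO_MMHG)


def compute_ffr(solution: NetworkSolution, spec: StenosisSpec,
                pa_offset_mm: float = 5.0, pd_offset_mm: float = 10.0) -> float:
    """FFR_CT = P_d / P_a across the stenotic extent.

    P_a is sampled ``pa_offset_mm`` proximal to the extent start and P_d
    ``pd_offset_mm`` distal to the extent end; both samples clip to the
    trunk bounds and never cross the adjacent junction.
    """
    tree = solution.problem.tree
    trunk_len = tree.trunk.length
    s_a = spec.s_start - pa_offset_mm
    s_d = spec.s_end + pd_offset_mm
    if not (0 <= spec.s_start and spec.s_end <= trunk_len):
        raise NetworkError("stenotic extent outside trunk")
    junc_s = [j.s for j in tree.children_of(tree.inlet)]
    prox_junc = max([s for s in junc_s if s < spec.s_start], default=0.0)
    dist_junc = min([s for s in junc_s if s > spec.s_end], default=trunk_len)
    s_a = float(np.clip(s_a, prox_junc, spec.s_start))
    s_d = float(np.clip(s_d, spec.s_end, dist_junc))
    s_prof, p_prof = trunk_pressure_profile(solution)
    p_a = float(np.interp(s_a, s_prof, p_prof))
    p_d = float(np.interp(s_d, s_prof, p_prof))
    if p_a <= 0:
        raise NetworkError("nonpositive proximal pressure; solution unphysical")
    return p_d / p_a
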