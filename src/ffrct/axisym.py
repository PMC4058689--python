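"""Steady incompressible axisymmetric Navier-Stokes finite-volume solver.

A single (possibly stenosed) tube of radius R(z) is discretized on a
radially mapped structured grid: nz columns in z, nr cells in the
normalized radius eta = r / R(z), so the wall is always a grid line.
Control volumes are the physical (slightly non-orthogonal) quadrilaterals
of revolution; all fluxes are written per radian of azimuth, which makes
the symmetry axis trivial (its faces have zero area).

Discretization choices: colocated cell-centered unknowns with Rhie-Chow
momentum interpolation, SIMPLE pressure-velocity coupling, first-order
upwind convection, central diffusion with an explicit non-orthogonal
correction, a second-order one-sided wall flux (so Poiseuille wall shear
is reproduced exactly), and the axisymmetric -mu u_r / r^2 sink in the
radial momentum equation. Boundary conditions: prescribed parabolic
inflow, no-slip rigid wall, zero-gradient outflow with outlet pressure
pinned at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import Fluid
from .geometry import VesselSegment
from .units import MM_TO_M, M_TO_MM


class AxisymError(ValueError):
    pass


@dataclass(frozen=True)
class AxisymNumerics:
    """Grid size, relaxation and convergence controls.

    Scaled residuals of continuity and both momentum components must all
    fall below ``tol``. Velocity/pressure under-relaxation defaults 0.7 /
    0.3; ``laminar_re_cap`` rejects flows whose throat Reynolds number
    exceeds the laminar assumption.
    """

    nz: int = 160
    nr: int = 16
    alpha_u: float = 0.7
    alpha_p: float = 0.3
    tol: float = 1e-6
    max_iters: int = 20000
    laminar_re_cap: float = 2000.0
    convection: str = "central_dc"  # central_dc (deferred correction) | upwind

    def __post_init__(self) -> None:
        if self.nz < 8 or self.nr < 8:
            raise AxisymError("grid must have nz, nr >= 8")
        if not (0 < self.alpha_u <= 1 and 0 < self.alpha_p <= 1):
            raise AxisymError("relaxation factors must be in (0, 1]")
        if self.convection not in ("central_dc", "upwind"):
            raise AxisymError("convection must be central_dc or upwind")


@dataclass
class AxisymGrid:
    """Radially mapped structured grid; all lengths in meters."""

    zf: np.ndarray          # z faces, (nz+1,)
    ef: np.ndarray          # eta faces, (nr+1,)
    Rf: np.ndarray          # wall radius at z faces, (nz+1,)
    Rc: np.ndarray          # wall radius at z centers, (nz,)
    dRc: np.ndarray         # dR/dz at z centers, (nz,)

    @property
    def nz(self) -> int:
        return self.Rc.size

    @property
    def nr(self) -> int:
        return self.ef.size - 1

    @property
    def zc(self) -> np.ndarray:
        return 0.5 * (self.zf[:-1] + self.zf[1:])

    @property
    def ec(self) -> np.ndarray:
        return 0.5 * (self.ef[:-1] + self.ef[1:])

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        z = np.broadcast_to(self.zc[:, None], (self.nz, self.nr)).copy()
        r = self.ec[None, :] * self.Rc[:, None]
        return z, r


@dataclass
class AxisymField:
    grid: AxisymGrid
    u_z: np.ndarray         # (nz, nr), m/s
    u_r: np.ndarray         # (nz, nr), m/s
    p: np.ndarray           # (nz, nr), Pa, relative to the outlet
    converged: bool
    iterations: int
    residual_history: list
    pressure_drop_pa: float
    q_in_m3s: float
    fluid: Fluid
    mdot_ew: np.ndarray | None = None  # converged z-face mass fluxes, per radian

    def face_flow(self, i: int) -> float:
        """Volumetric flow (m^3/s) through z-face i from the conserved
        face mass fluxes (the discretely transported quantity)."""
        if self.mdot_ew is None:
            raise AxisymError("face fluxes not stored")
        return float(2.0 * math.pi * self.mdot_ew[i, :].sum() / self.fluid.density_kg_m3)

    def section_flow(self, i: int) -> float:
        """Flow through z-column i integrated from cell-center velocities
        (an interpolated diagnostic; prefer :meth:`face_flow`)."""
        g = self.grid
        de2 = g.ef[1:] ** 2 - g.ef[:-1] ** 2
        return float(2.0 * math.pi * np.sum(self.u_z[i] * 0.5 * de2 * g.Rc[i] ** 2))


def build_grid(segment: VesselSegment, nz: int, nr: int) -> AxisymGrid:
    """Map a diameter profile (mm) onto the solver grid (m)."""
    length = segment.length * MM_TO_M
    zf = np.linspace(0.0, length, nz + 1)
    ef = np.linspace(0.0, 1.0, nr + 1)
    Rf = 0.5 * np.asarray(segment.diameter(zf * M_TO_MM), dtype=float) * MM_TO_M
    zc = 0.5 * (zf[:-1] + zf[1:])
    Rc = 0.5 * np.asarray(segment.diameter(zc * M_TO_MM), dtype=float) * MM_TO_M
    dRc = (Rf[1:] - Rf[:-1]) / np.diff(zf)
    if np.any(Rf <= 0):
        raise AxisymError("wall radius must be positive everywhere")
    return AxisymGrid(zf=zf, ef=ef, Rf=Rf, Rc=Rc, dRc=dRc)


class _Metrics:
    """Precomputed geometric/diffusion quantities for one grid."""

    def __init__(self, grid: AxisymGrid, fluid: Fluid):
        nz, nr = grid.nz, grid.nr
        ef = grid.ef
        self.dz = np.diff(grid.zf)
        de2 = ef[1:] ** 2 - ef[:-1] ** 2

        self.V = 0.5 * de2[None, :] * (grid.Rc ** 2)[:, None] * self.dz[:, None]
        self.zc2, self.rc2 = grid.cell_centers()

        # east-west faces (normal +z), per radian: (nz+1, nr)
        self.A_ew = 0.5 * de2[None, :] * (grid.Rf ** 2)[:, None]

        # north-south faces at eta=ef[j]: area vector per radian
        # S = eta R_c dz (-eta dR/dz, 1), shape (nz, nr+1)
        eta = ef[None, :]
        base = eta * grid.Rc[:, None] * self.dz[:, None]
        self.S_ns_r = base
        self.S_ns_z = -base * eta * grid.dRc[:, None]

        # closure sums (constant field => zero Gauss gradient)
        self.sumS_z = (self.A_ew[1:, :] - self.A_ew[:-1, :]
                       + self.S_ns_z[:, 1:] - self.S_ns_z[:, :-1])
        self.sumS_r = self.S_ns_r[:, 1:] - self.S_ns_r[:, :-1]

        # interior face center-to-center vectors
        self.d_ew_z = self.zc2[1:, :] - self.zc2[:-1, :]       # (nz-1, nr)
        self.d_ew_r = self.rc2[1:, :] - self.rc2[:-1, :]
        self.d_ns_r = self.rc2[:, 1:] - self.rc2[:, :-1]       # (nz, nr-1)

        mu = fluid.viscosity_pa_s
        A = self.A_ew[1:-1, :]
        self.D_ew = mu * A / self.d_ew_z                       # S=(A,0), S.d = A dz
        Sz = self.S_ns_z[:, 1:-1]
        Sr = self.S_ns_r[:, 1:-1]
        self.D_ns = mu * (Sz ** 2 + Sr ** 2) / (Sr * self.d_ns_r)

        # wall: second-order one-sided flux, radial distance h to 1st center
        self.S_wall = np.hypot(self.S_ns_z[:, -1], self.S_ns_r[:, -1])
        self.h_wall = grid.Rc - self.rc2[:, -1]
        # flux_out = mu S (9 u_P - u_PP) / (6 h): implicit 1.5 mu S/h on P
        self.Dw_P = 1.5 * mu * self.S_wall / self.h_wall
        self.Dw_PP = -mu * self.S_wall / (6.0 * self.h_wall)   # explicit on u[:, -2]

        self.d_in = self.zc2[0, :] - grid.zf[0]
        self.D_in = mu * self.A_ew[0, :] / self.d_in
        self.d_out = grid.zf[-1] - self.zc2[-1, :]
        self.D_out = mu * self.A_ew[-1, :] / self.d_out


def _gauss_grad(phi, met, in_face=None, wall_face=None, out_face=None):
    """Green-Gauss cell gradient (d/dz, d/dr) with boundary face values;
    None means zero-gradient (copy the adjacent cell value)."""
    nzv, nrv = phi.shape
    phi_ew = np.empty((nzv + 1, nrv))
    phi_ew[1:-1] = 0.5 * (phi[:-1] + phi[1:])
    phi_ew[0] = phi[0] if in_face is None else in_face
    phi_ew[-1] = phi[-1] if out_face is None else out_face
    phi_ns = np.empty((nzv, nrv + 1))
    phi_ns[:, 1:-1] = 0.5 * (phi[:, :-1] + phi[:, 1:])
    phi_ns[:, 0] = phi[:, 0]
    phi_ns[:, -1] = phi[:, -1] if wall_face is None else wall_face
    sz = (phi_ew[1:] * met.A_ew[1:] - phi_ew[:-1] * met.A_ew[:-1]
          + phi_ns[:, 1:] * met.S_ns_z[:, 1:] - phi_ns[:, :-1] * met.S_ns_z[:, :-1])
    sr = (phi_ns[:, 1:] * met.S_ns_r[:, 1:] - phi_ns[:, :-1] * met.S_ns_r[:, :-1])
    gz = (sz - phi * met.sumS_z) / met.V
    gr = (sr - phi * met.sumS_r) / met.V
    return gz, gr


def solve_axisym(segment: VesselSegment, q_in_m3s: float, fluid: Fluid,
                 numerics: AxisymNumerics | None = None) -> AxisymField:
    """SIMPLE solve of steady laminar flow through the tube ``segment``.

    The prescribed inflow enters with a parabolic profile carrying exactly
    ``q_in_m3s``. Non-convergence is flagged on the returned field, never
    silently ignored. Raises when the throat Reynolds number exceeds the
    laminar cap.
    """
    num = numerics or AxisymNumerics()
    if q_in_m3s <= 0:
        raise AxisymError("inflow must be positive")
    d_min = float(np.min(segment.samples_d)) * MM_TO_M
    re = 4.0 * fluid.density_kg_m3 * q_in_m3s / (math.pi * fluid.viscosity_pa_s * d_min)
    if re > num.laminar_re_cap:
        raise AxisymError(f"throat Reynolds number {re:.0f} exceeds the "
                          f"laminar cap {num.laminar_re_cap:.0f}")

    grid = build_grid(segment, num.nz, num.nr)
    met = _Metrics(grid, fluid)
    nz, nr = grid.nz, grid.nr
    n = nz * nr
    rho = fluid.density_kg_m3
    mu = fluid.viscosity_pa_s

    # inlet parabola and exact per-face inflow mass fluxes (per radian)
    R0 = grid.Rf[0]
    u_max = 2.0 * q_in_m3s / (math.pi * R0 ** 2)
    r_f = grid.ef * R0

    def cum(r):
        return u_max * (r ** 2 / 2.0 - r ** 4 / (4.0 * R0 ** 2))

    mdot_in = rho * (cum(r_f[1:]) - cum(r_f[:-1]))
    r_in_c = grid.ec * R0
    u_in_face = u_max * (1.0 - (r_in_c / R0) ** 2)
    mdot_total = float(mdot_in.sum())          # = rho Q / (2 pi)

    # initial state: plug flow matching local area
    u_z = np.tile((q_in_m3s / (math.pi * grid.Rc ** 2))[:, None], (1, nr))
    u_r = np.zeros((nz, nr))
    p = np.zeros((nz, nr))
    mdot_ew = np.tile(mdot_in[None, :], (nz + 1, 1))
    mdot_ns = np.zeros((nz, nr + 1))

    # sparse pattern indices
    ii, jj = np.meshgrid(np.arange(nz), np.arange(nr), indexing="ij")
    cell = (ii * nr + jj)
    ew_own = cell[:-1, :].ravel()       # owner of interior EW face i (west cell)
    ew_nb = cell[1:, :].ravel()
    ns_own = cell[:, :-1].ravel()
    ns_nb = cell[:, 1:].ravel()
    cells = np.arange(n)
    rows = np.concatenate([ew_own, ew_nb, ns_own, ns_nb, cells])
    cols = np.concatenate([ew_nb, ew_own, ns_nb, ns_own, cells])

    u_scale = max(q_in_m3s / (math.pi * np.min(grid.Rc) ** 2), 1e-12)
    mom_scale = max(mdot_total * u_scale, 1e-300)
    hist: list[tuple[float, float, float]] = []
    converged = False
    it = 0
    dV_aP = np.ones((nz, nr))

    for it in range(1, num.max_iters + 1):
        m_ew = mdot_ew[1:-1, :].ravel()
        m_ns = mdot_ns[:, 1:-1].ravel()
        D_ew = met.D_ew.ravel()
        D_ns = met.D_ns.ravel()

        a_ew_N = np.minimum(m_ew, 0.0) - D_ew      # coeff of neighbor in owner row
        a_ew_P = np.maximum(m_ew, 0.0) + D_ew
        a_ns_N = np.minimum(m_ns, 0.0) - D_ns
        a_ns_P = np.maximum(m_ns, 0.0) + D_ns

        diag = np.zeros(n)
        np.add.at(diag, ew_own, a_ew_P)
        np.add.at(diag, ew_nb, -a_ew_N)
        np.add.at(diag, ns_own, a_ns_P)
        np.add.at(diag, ns_nb, -a_ns_N)

        bdiag = np.zeros((nz, nr))
        bdiag[0, :] += met.D_in
        bdiag[-1, :] += np.maximum(mdot_ew[-1, :], 0.0)
        bdiag[:, -1] += met.Dw_P
        imb = (mdot_ew[1:, :] - mdot_ew[:-1, :] + mdot_ns[:, 1:] - mdot_ns[:, :-1])
        diag += (bdiag - imb).ravel()

        off = np.concatenate([a_ew_N, -a_ew_P, a_ns_N, -a_ns_P])

        gpz, gpr = _gauss_grad(p, met)
        guz = _gauss_grad(u_z, met, in_face=u_in_face, wall_face=0.0)
        gur = _gauss_grad(u_r, met, in_face=np.zeros(nr), wall_face=0.0)

        def deferred(gz, gr, phi):
            """Explicit non-orthogonal diffusion + one-sided wall term.

            True face flux mu grad(phi).S minus the orthogonal surrogate
            D (grad(phi).d); owner gains +corr, neighbor -corr."""
            src = np.zeros((nz, nr))
            # EW faces: S=(A,0), S.d = A dz -> only the radial skew remains
            gr_f = 0.5 * (gr[:-1] + gr[1:])
            corr = -met.D_ew * (gr_f * met.d_ew_r)
            src[:-1, :] += corr
            src[1:, :] -= corr
            # NS faces: S.d = S_r d_r
            gzn = 0.5 * (gz[:, :-1] + gz[:, 1:])
            grn = 0.5 * (gr[:, :-1] + gr[:, 1:])
            Sz = met.S_ns_z[:, 1:-1]
            Sr = met.S_ns_r[:, 1:-1]
            corr_ns = (mu * (gzn * Sz + grn * Sr)
                       - met.D_ns * grn * met.d_ns_r)
            src[:, :-1] += corr_ns
            src[:, 1:] -= corr_ns
            # wall: explicit part of the one-sided flux (on u[:, -2])
            src[:, -1] -= met.Dw_PP * phi[:, -2]
            # deferred-correction central convection: explicit
            # mdot*(phi_central - phi_upwind) on interior faces
            if num.convection == "central_dc":
                me = mdot_ew[1:-1, :]
                up = np.where(me >= 0, phi[:-1], phi[1:])
                dc = me * (0.5 * (phi[:-1] + phi[1:]) - up)
                src[:-1, :] -= dc
                src[1:, :] += dc
                mn = mdot_ns[:, 1:-1]
                upn = np.where(mn >= 0, phi[:, :-1], phi[:, 1:])
                dcn = mn * (0.5 * (phi[:, :-1] + phi[:, 1:]) - upn)
                src[:, :-1] -= dcn
                src[:, 1:] += dcn
            return src

        # ---- z momentum ----------------------------------------------
        diag_z = diag / num.alpha_u
        b_z = (-gpz * met.V + deferred(*guz, u_z))
        b_z[0, :] += mdot_in * u_in_face + met.D_in * u_in_face
        b_z = b_z.ravel() + (1.0 - num.alpha_u) * diag_z * u_z.ravel()
        A_z = sp.csr_matrix((np.concatenate([off, diag_z]), (rows, cols)), shape=(n, n))
        res_z = float(np.abs(A_z @ u_z.ravel() - b_z).sum()) / mom_scale
        u_z = spla.spsolve(A_z, b_z).reshape(nz, nr)

        # ---- r momentum ----------------------------------------------
        sink = mu * met.V / met.rc2 ** 2
        diag_r = (diag + sink.ravel()) / num.alpha_u
        b_r = (-gpr * met.V + deferred(*gur, u_r)).ravel() \
            + (1.0 - num.alpha_u) * diag_r * u_r.ravel()
        A_r = sp.csr_matrix((np.concatenate([off, diag_r]), (rows, cols)), shape=(n, n))
        res_r = float(np.abs(A_r @ u_r.ravel() - b_r).sum()) / mom_scale
        u_r = spla.spsolve(A_r, b_r).reshape(nz, nr)

        dV_aP = met.V / diag_z.reshape(nz, nr)

        # ---- Rhie-Chow face fluxes -----------------------------------
        gpz, gpr = _gauss_grad(p, met)
        # interior EW faces
        df = 0.5 * (dV_aP[:-1] + dV_aP[1:])
        c_ew = rho * df * met.A_ew[1:-1, :] / met.d_ew_z
        gp_d = (0.5 * (gpz[:-1] + gpz[1:]) * met.d_ew_z
                + 0.5 * (gpr[:-1] + gpr[1:]) * met.d_ew_r)
        mdot_ew[1:-1, :] = (rho * 0.5 * (u_z[:-1] + u_z[1:]) * met.A_ew[1:-1, :]
                            + c_ew * (gp_d - (p[1:] - p[:-1])))
        mdot_ew[0, :] = mdot_in
        # zero-gradient outflow with global mass conservation: scale the
        # outlet face fluxes so total outflow equals the prescribed inflow
        # (otherwise the uniform mode of p' carries the defect forever)
        m_out_raw = rho * u_z[-1, :] * met.A_ew[-1, :]
        out_sum = float(m_out_raw.sum())
        mdot_ew[-1, :] = m_out_raw * (mdot_total / out_sum if out_sum > 0 else 1.0)
        # interior NS faces
        dfn = 0.5 * (dV_aP[:, :-1] + dV_aP[:, 1:])
        Sz = met.S_ns_z[:, 1:-1]
        Sr = met.S_ns_r[:, 1:-1]
        c_ns = rho * dfn * (Sz ** 2 + Sr ** 2) / (Sr * met.d_ns_r)
        gp_dn = 0.5 * (gpr[:, :-1] + gpr[:, 1:]) * met.d_ns_r
        mdot_ns[:, 1:-1] = (rho * (0.5 * (u_z[:, :-1] + u_z[:, 1:]) * Sz
                                   + 0.5 * (u_r[:, :-1] + u_r[:, 1:]) * Sr)
                            + c_ns * (gp_dn - (p[:, 1:] - p[:, :-1])))
        mdot_ns[:, 0] = 0.0
        mdot_ns[:, -1] = 0.0

        # ---- pressure correction -------------------------------------
        c_out = rho * dV_aP[-1, :] * met.A_ew[-1, :] / met.d_out
        imb = (mdot_ew[1:, :] - mdot_ew[:-1, :] + mdot_ns[:, 1:] - mdot_ns[:, :-1])
        res_c = float(np.abs(imb).sum()) / mdot_total

        pdiag = np.zeros(n)
        np.add.at(pdiag, ew_own, c_ew.ravel())
        np.add.at(pdiag, ew_nb, c_ew.ravel())
        np.add.at(pdiag, ns_own, c_ns.ravel())
        np.add.at(pdiag, ns_nb, c_ns.ravel())
        pd2 = pdiag.reshape(nz, nr)
        pd2[-1, :] += c_out
        poff = np.concatenate([-c_ew.ravel(), -c_ew.ravel(),
                               -c_ns.ravel(), -c_ns.ravel()])
        A_p = sp.csr_matrix((np.concatenate([poff, pd2.ravel()]), (rows, cols)),
                            shape=(n, n))
        pc = spla.spsolve(A_p, -imb.ravel()).reshape(nz, nr)

        # corrections
        mdot_ew[1:-1, :] += c_ew * (pc[:-1] - pc[1:])
        mdot_ew[-1, :] += c_out * pc[-1, :]
        mdot_ns[:, 1:-1] += c_ns * (pc[:, :-1] - pc[:, 1:])
        p += num.alpha_p * pc
        gcz, gcr = _gauss_grad(pc, met, out_face=0.0)
        u_z -= dV_aP * gcz
        u_r -= dV_aP * gcr

        hist.append((res_c, res_z, res_r))
        if max(res_c, res_z, res_r) < num.tol:
            converged = True
            break

    # area-averaged static pressures at inlet/outlet faces
    gpz, gpr = _gauss_grad(p, met)
    p_in_face = p[0, :] - gpz[0, :] * met.d_in
    w_in = met.A_ew[0, :] / met.A_ew[0, :].sum()
    p_out_face = p[-1, :] + gpz[-1, :] * met.d_out
    w_out = met.A_ew[-1, :] / met.A_ew[-1, :].sum()
    dp = float((p_in_face * w_in).sum() - (p_out_face * w_out).sum())

    return AxisymField(grid=grid, u_z=u_z, u_r=u_r, p=p, converged=converged,
                       iterations=it, residual_history=hist,
                       pressure_drop_pa=dp, q_in_m3s=q_in_m3s, fluid=fluid,
                       mdot_ew=mdot_ew)


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

def wall_shear_profile(field: AxisymField) -> tuple[np.ndarray, np.ndarray]:
    """(z [m], tau_w [Pa]) signed wall shear from the one-sided fit.

    Positive tau means forward (downstream-directed) near-wall flow;
    separation shows as a sign change to negative.
    """
    g = field.grid
    mu = field.fluid.viscosity_pa_s
    # tangential unit vector along the wall (downstream-directed)
    tz = 1.0 / np.hypot(1.0, g.dRc)
    tr = g.dRc / np.hypot(1.0, g.dRc)
    met_h = g.Rc - g.ec[-1] * g.Rc  # radial distance of last cell center
    u1 = field.u_z[:, -1] * tz + field.u_r[:, -1] * tr
    u2 = field.u_z[:, -2] * tz + field.u_r[:, -2] * tr
    h = met_h
    dudn = (9.0 * u1 - u2) / (6.0 * h)
    return g.zc, mu * dudn


def recirculation_metrics(field: AxisymField,
                          throat_z_m: float | None = None) -> tuple[float, float]:
    """(reattachment length [mm], reversed-flow area [mm^2]).

    The reattachment point is the first wall location downstream of the
    throat where the wall shear changes sign from negative to positive;
    the length is measured from the throat. Both metrics are zero when no
    reversed flow exists.
    """
    if not field.converged:
        raise AxisymError("recirculation metrics require a converged field")
    g = field.grid
    z, tau = wall_shear_profile(field)
    if throat_z_m is None:
        throat_z_m = float(g.zc[np.argmin(g.Rc)])
    # reversed-flow area in the r-z plane (mm^2)
    de = np.diff(g.ef)
    cell_area = de[None, :] * g.Rc[:, None] * np.diff(g.zf)[:, None]
    rev_mask = field.u_z < 0.0
    area_mm2 = float(np.sum(cell_area[rev_mask]) * M_TO_MM ** 2)

    after = z >= throat_z_m
    tau_a = tau[after]
    z_a = z[after]
    neg = np.where(tau_a < 0.0)[0]
    if neg.size == 0:
        return 0.0, area_mm2
    last_neg = neg[-1]
    if last_neg + 1 >= tau_a.size:
        reattach = float(z_a[-1])  # recirculation reaches the outlet
    else:
        t0, t1 = tau_a[last_neg], tau_a[last_neg + 1]
        frac = t0 / (t0 - t1)
        reattach = float(z_a[last_neg] + frac * (z_a[last_neg + 1] - z_a[last_neg]))
    return (reattach - throat_z_m) * M_TO_MM, area_mm2


def export_vtk(field: AxisymField, path: str | Path) -> None:
    """Legacy ASCII VTK structured grid with u_z, u_r, p point arrays."""
    g = field.grid
    z2, r2 = g.cell_centers()
    nz, nr = g.nz, g.nr
    lines = ["# vtk DataFile Version 3.0", "ffrct axisymmetric field", "ASCII",
             "DATASET STRUCTURED_GRID", f"DIMENSIONS {nr} {nz} 1",
             f"POINTS {nz * nr} float"]
    for i in range(nz):
        for j in range(nr):
            lines.append(f"{z2[i, j]:.6g} {r2[i, j]:.6g} 0")
    lines.append(f"POINT_DATA {nz * nr}")
    for name, arr in (("u_z", field.u_z), ("u_r", field.u_r), ("p", field.p)):
        lines += [f"SCALARS {name} float 1", "LOOKUP_TABLE default"]
        lines += [f"{arr[i, j]:.6g}" for i in range(nz) for j in range(nr)]
    Path(path).write_text("\n".join(lines) + "\n")


def export_wall_shear_csv(field: AxisymField, path: str | Path) -> None:
    z, tau = wall_shear_profile(field)
    lines = ["z_mm,tau_wall_pa"]
    lines += [f"{zi * M_TO_MM:.6g},{ti:.6g}" for zi, ti in zip(z, tau)]
    Path(path).write_text("\n".join(lines) + "\n")
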