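"""Algebraic pressure-drop laws for vessel segments.

Every segment is reduced to a signed drop law

    dP(Q) = a_v * Q + a_t * Q * |Q|

with a linear (viscous) coefficient ``a_v`` [Pa s/m^3] from integrated
Poiseuille resistance over the diameter profile, and a quadratic
(separation/expansion-loss) coefficient ``a_t`` [Pa s^2/m^6] that is zero
for stenosis-free segments. For stenoses the quadratic term follows the
Young-Tsai empirical decomposition:

    a_t = Kt * (rho / 2) * (1/A_s - 1/A_0)^2

with A_s the throat area, A_0 the local normal lumen area, and Kt an
empirical expansion-loss coefficient (default 1.52). The law can instead
be tabulated from the axisymmetric Navier-Stokes solver by least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import Fluid
from .geometry import StenosisSpec, VesselSegment
from .units import MM_TO_M


class SegmentModelError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentLaw:
    a_v: float  # Pa s / m^3
    a_t: float  # Pa s^2 / m^6
    provenance: str  # poiseuille | stenosis_algebraic | axisym_tabulated
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.a_v <= 0:
            raise SegmentModelError(f"a_v must be positive, got {self.a_v}")
        if self.a_t < 0:
            raise SegmentModelError(f"a_t must be >= 0, got {self.a_t}")

    def dp(self, q: float) -> float:
        """Signed pressure drop [Pa] at signed flow q [m^3/s]."""
        return self.a_v * q + self.a_t * q * abs(q)

    def flow(self, dp: float) -> float:
        """Invert dp(Q); the law is strictly monotone so the root is unique."""
        if self.a_t == 0.0:
            return dp / self.a_v
        sign = 1.0 if dp >= 0 else -1.0
        mag = abs(dp)
        return sign * (-self.a_v + math.sqrt(self.a_v ** 2 + 4.0 * self.a_t * mag)) / (2.0 * self.a_t)

    def conductance(self, q: float) -> float:
        """dQ/d(dP) at flow q (inverse of the local incremental resistance)."""
        return 1.0 / (self.a_v + 2.0 * self.a_t * abs(q))


def _resampled_inv_d4(segment: VesselSegment, min_points: int = 400) -> tuple[np.ndarray, np.ndarray]:
    """Dense (s [m], d^-4 [m^-4]) profile; the d^-4 kernel makes any throat
    dominate the quadrature, so the profile is refined well beyond its
    stored samples."""
    s_mm = np.asarray(segment.samples_s)
    n = max(min_points, 2 * s_mm.size)
    s_dense = np.union1d(np.linspace(0.0, segment.length, n), s_mm)
    d_m = np.interp(s_dense, s_mm, segment.samples_d) * MM_TO_M
    return s_dense * MM_TO_M, d_m ** -4


def poiseuille_law(segment: VesselSegment, fluid: Fluid) -> SegmentLaw:
    """Integrated Poiseuille resistance a_v = int 128 mu / (pi d(s)^4) ds."""
    s, inv_d4 = _resampled_inv_d4(segment)
    a_v = 128.0 * fluid.viscosity_pa_s / math.pi * np.trapezoid(inv_d4, s)
    return SegmentLaw(a_v=float(a_v), a_t=0.0, provenance="poiseuille")


def viscous_drop_profile(segment: VesselSegment, fluid: Fluid,
                         s_query_mm: np.ndarray) -> np.ndarray:
    """Cumulative viscous resistance [Pa s/m^3] from s=0 to each query point."""
    s, inv_d4 = _resampled_inv_d4(segment)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (inv_d4[1:] + inv_d4[:-1]) * np.diff(s))])
    cum *= 128.0 * fluid.viscosity_pa_s / math.pi
    return np.interp(np.asarray(s_query_mm, dtype=float) * MM_TO_M, s, cum)


def stenosis_law(segment_with_stenosis: VesselSegment, spec: StenosisSpec,
                 fluid: Fluid, Kt: float = 1.52) -> SegmentLaw:
    """Viscous + expansion-loss law for a stenosed segment.

    ``segment_with_stenosis`` must already carry the narrowed profile (see
    :func:`ffrct.geometry.insert_stenosis`). A ds=0 spec degenerates to the
    pure Poiseuille law.
    """
    if Kt <= 0:
        raise SegmentModelError(f"Kt must be positive, got {Kt}")
    base = poiseuille_law(segment_with_stenosis, fluid)
    if spec.ds == 0.0:
        return base
    d_throat = float(segment_with_stenosis.diameter(spec.center_s)) * MM_TO_M
    d_normal = d_throat / (1.0 - spec.ds)
    area_s = math.pi / 4.0 * d_throat ** 2
    area_0 = math.pi / 4.0 * d_normal ** 2
    a_t = Kt * (fluid.density_kg_m3 / 2.0) * (1.0 / area_s - 1.0 / area_0) ** 2
    return SegmentLaw(a_v=base.a_v, a_t=float(a_t), provenance="stenosis_algebraic")


def fit_law_from_samples(flows: np.ndarray, drops: np.ndarray) -> SegmentLaw:
    """Least-squares fit of (a_v, a_t) to sampled (Q, dP) pairs, a_t >= 0."""
    from scipy.optimize import nnls

    q = np.asarray(flows, dtype=float)
    dp = np.asarray(drops, dtype=float)
    if q.size < 3:
        raise SegmentModelError("need at least 3 flow samples to fit (a_v, a_t)")
    if np.any(q <= 0):
        raise SegmentModelError("flow grid must be positive")
    # normalize the flow scale so the two columns are comparable for nnls
    q_ref = float(np.max(q))
    x = q / q_ref
    design = np.column_stack([x, x * np.abs(x)])
    coef, _ = nnls(design, dp)
    a_v = coef[0] / q_ref
    a_t = coef[1] / q_ref ** 2
    if a_v <= 0:
        raise SegmentModelError("fitted a_v is nonpositive; samples are inconsistent")
    if a_t * q_ref ** 2 < 1e-8 * float(np.max(np.abs(dp))):
        a_t = 0.0  # numerically negligible quadratic part
    resid = float(np.max(np.abs(a_v * q + a_t * q * np.abs(q) - dp)))
    return SegmentLaw(a_v=float(a_v), a_t=float(a_t),
                      provenance="axisym_tabulated", fit_residual=resid)


def tabulate_from_axisym(segment_with_stenosis: VesselSegment, fluid: Fluid,
                         flow_grid_m3s: np.ndarray, **solver_kwargs) -> SegmentLaw:
    """Fit (a_v, a_t) to pressure drops computed by the axisymmetric solver.

    Each grid flow is solved to convergence; a non-converged solve aborts
    the tabulation naming the offending flow.
    """
    from .axisym import solve_axisym

    flows = np.asarray(flow_grid_m3s, dtype=float)
    if flows.size < 3:
        raise SegmentModelError("axisym tabulation needs a flow grid of >= 3 flows")
    drops = []
    for q in flows:
        field = solve_axisym(segment_with_stenosis, q, fluid, **solver_kwargs)
        if not field.converged:
            raise SegmentModelError(
                f"axisymmetric solve did not converge at Q = {q:.3e} m^3/s")
        drops.append(field.pressure_drop_pa)
    return fit_law_from_samples(flows, np.asarray(drops))
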