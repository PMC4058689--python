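# Methods

This note documents the models inside `ffrct`, the defaults they ship
with, why those defaults were chosen, and what the package's tests do and
do not demonstrate about real coronary physiology.

## Geometry: the emulated porcine LAD

The study object is a parametric emulation of a porcine left anterior
descending artery: a single tapering trunk carrying seven primary
branches. The anatomical constraints the emulator enforces are a trunk
at least 2 mm in diameter over its full length, branches at least 1 mm,
and a monotone taper. Within those constraints the specific dimensions
are the package's own documented choices (no reference animal is
reproduced):

| parameter | default | unit |
|---|---|---|
| trunk length | 100 | mm |
| trunk taper | 3.5 → 2.0 (linear) | mm |
| branch positions ("a"–"g") | 10, 30, 42, 54, 66, 78, 90 | mm |
| branch diameters | 2.0, 1.8, 1.6, 1.5, 1.3, 1.2, 1.0 | mm |
| branch lengths | 20 | mm |
| lesion locations A–D | 20, 36, 60, 84 | mm |

The branch spacing leaves a 20 mm trunk run between branches "a" and
"b" so that the longest lesion of the length sweep (16 mm) fits at
location A without its extent touching a junction; locations B–D sit
mid-way between successive branch take-offs. All values are overridable
through the `geometry` config section.

Stenoses are concentric and axisymmetric: within the extent
[c − L/2, c + L/2] the normal diameter is multiplied by 1 − ds·w(s),
where the window w rises smoothly (cosine by default; trapezoid
available) from 0 at the edges to exactly 1 at the throat, so the
throat diameter is exactly (1 − ds) times the local normal diameter.
For lesions longer than 4 mm the cosine window is clipped to a flat
throat over the central 20% of the extent, which keeps the minimum
lumen length from shrinking as the lesion lengthens.

## Baseline flow split

Healthy outlet flows follow the generalized Murray law
Q_i ∝ d_i^k using each outlet's terminal diameter. The default exponent
k = 7/3 is the generalized value for coronary trees; k = 3 (classical)
is selectable. Only terminal diameters enter the split — no full-subtree
morphometry is modeled.

## Outlet calibration and hyperemia

Each outlet's downstream bed is a resistance closure
P_i = R_i Q_i + P_{0,i}. The pair (R_i, P_{0,i}) is the exact two-point
linear fit through the outlet's (Q_i, P_i) samples from two steady
baseline solves with Murray-prescribed flows — a peak-systolic and a
peak-diastolic inlet state. With flows prescribed, those baseline solves
are a single linear marching pass down the tree.

The two calibration states are not observable from the resting
time-averages alone, and they are the one genuinely free physiological
input. The defaults,

* systole: 84 mmHg at 100 mL/min,
* diastole: 55 mmHg at 35 mL/min,

were chosen so that (i) their means (69.5 mmHg, 67.5 mL/min) bracket the
resting anchors (69.54 mmHg, 66.75 mL/min), and (ii) the implied back
pressure — the zero-flow intercept of the fitted line, ≈ 39 mmHg — falls
in the range reported for coronary zero-flow pressure. Note the fit
requires Q_sys/Q_dia ≥ P_sys/P_dia for a non-negative back pressure; a
state pair violating this (e.g. a large pressure pulse with a small flow
pulse) is rejected with a calibration error rather than silently
producing an unphysical bed. A single-point mode (fixed back pressure,
default 0) is available as an alternative.

Maximal hyperemia multiplies every R_i by a fixed factor, default 0.21
(bed resistance falls to 21% of rest); back pressures are unchanged, and
the hyperemic inlet total pressure default is 69.87 mmHg. Hyperemic flow
is emergent, not prescribed: with the defaults the healthy tree settles
at ≈ 277 mL/min, a coronary flow reserve of ≈ 4. Because the
microvascular bed is assumed insensitive to the epicardial lesion,
calibrated BCs transfer unchanged from the healthy tree to every
stenosed variant.

## Segment pressure-drop laws

Every vessel piece carries a signed law ΔP(Q) = a_v Q + a_t Q|Q|.

* a_v is the integrated Poiseuille resistance ∫ 128 μ/(π d(s)⁴) ds,
  evaluated by composite trapezoid on the diameter profile resampled to
  ≥ 400 points (the d⁻⁴ kernel makes the throat dominate, so the
  stenotic extent is always refined).
* For stenoses, a_t = K_t (ρ/2)(1/A_s − 1/A_0)² with A_s the throat
  area and A_0 the local normal area — the Young–Tsai viscous +
  expansion-loss decomposition. K_t defaults to the standard empirical
  value 1.52.

The law family is strictly monotone in Q, reduces exactly to Poiseuille
at ds = 0, and is nondecreasing in ds at fixed flow. As an alternative
backend, (a_v, a_t) can be fitted by non-negative least squares to
pressure drops computed by the axisymmetric Navier–Stokes solver over a
flow grid (≥ 3 flows); the fit residual is reported and a_t is clamped
at ≥ 0.

Cross-validation against the Navier–Stokes solver on padded single
tubes puts the algebraic law within ~5–25% of the computed drop for
ds ≤ 0.55 at throat Reynolds numbers ≤ 400 (tested band: 30%). The
algebraic law is consistently on the high side, as expected for an
expansion-loss coefficient calibrated at higher Reynolds numbers.

## Coupled network solve

The trunk is cut at each branch take-off; junction pressures are the
unknowns of a nonlinear resistive network (each edge law inverted in
closed form), solved by damped Newton with analytic tridiagonal
Jacobian to machine precision. Around it, outlet pressures follow the
underrelaxed implicit update

    P_i^{n+1} = P_i^n + ω (R_i Q_i^{n+1} + P_{0,i} − P_i^n).

The superscript n+1 on the flow matters. An explicit variant (evaluate
R_i Q_i at the old outlet pressure, fully converge the network, update)
is unconditionally unstable here: linearizing the single-outlet case
shows the explicit map contracts only for ω < 2 a_v/(a_v + R), and the
bed resistance R exceeds the epicardial resistance a_v by a factor
20–50, demanding ω < 0.1. Treating Q^{n+1} implicitly through the
network's Thévenin conductance g_i at each outlet (computed exactly from
the Newton Jacobian) turns the update into

    P_i^{n+1} = P_i^n + ω (R_i Q_i^n + P_{0,i} − P_i^n) / (1 + ω R_i g_i),

whose scalar error amplification is (1 − ω)/(1 + ω R g) < 1 for every
ω ∈ (0, 1]: unconditionally stable, same fixed point, and ω = 1
converges essentially in one step. Convergence is declared when every
outlet's closure residual |R_i Q_i + P_{0,i} − P_i| falls below `tol_pa`
(default 0.1 Pa); defaults ω = 0.5, ≤ 500 outer iterations.

The prescribed inlet total pressure is converted to static pressure by
subtracting the dynamic head ½ρ(Q/A_in)² (underrelaxed alongside the
outlets and clamped to 20% of the total pressure for robustness during
transients; toggleable — the converged correction is < 1 mmHg).

FFR_CT is read from the trunk pressure profile: P_a is sampled 5 mm
proximal to the stenotic extent and P_d 10 mm distal (clinical wire
placement is well beyond the lesion), both clipped to the trunk and to
the nearest junction so a sample never crosses a branch take-off. The
pullback distributes each piece's viscous drop along the local d⁻⁴
kernel and deposits the expansion loss across the stenotic extent in
proportion to the local excess narrowing, concentrating it at the
throat; it is monotone non-increasing for forward flow.

## Axisymmetric Navier–Stokes solver

Single stenosed tubes are solved as steady incompressible axisymmetric
flow on a radially mapped structured grid (η = r/R(z), so the wall is a
grid line; all fluxes per radian of azimuth, making the axis trivial).

Discretization: colocated cell-centered unknowns with Rhie–Chow
momentum interpolation and SIMPLE coupling. Convection defaults to
deferred-correction central differencing over an implicit first-order
upwind skeleton (`convection="upwind"` selects pure upwind); diffusion
is central with an explicit non-orthogonal correction from Green–Gauss
gradients; the wall uses a second-order one-sided flux, which
reproduces Poiseuille wall shear exactly; the radial momentum equation
carries the axisymmetric −μ u_r/r² sink. Boundary conditions: parabolic
inflow carrying exactly the prescribed flow (exact analytic per-face
mass fluxes), no-slip rigid wall, and zero-gradient outflow whose face
fluxes are globally scaled to the inflow each iteration, with the
pressure correction pinned to zero at the outlet (without the global
scaling, the uniform mode of the pressure correction carries the mass
defect forever and the iteration stalls). Under-relaxation 0.7/0.3
(velocity/pressure); convergence at scaled continuity and momentum
residuals < 10⁻⁶.

Verification: on a straight tube the solver reproduces the parabolic
profile (centerline/mean = 2.00 within 1%, already at 12 radial cells)
and the Poiseuille pressure drop within 2%; with central convection the
pressure drop changes by < 2% under simultaneous (2nz, 2nr) refinement
from a 160×20 base grid for ds up to 0.55 at throat Re ≤ 200. Stenosed
runs exhibit the expected separation bubble downstream of the throat;
the reattachment point is located by the sign change of the wall shear,
and both reattachment length and reversed-flow area grow monotonically
with ds and with Reynolds number. Flows whose throat Reynolds number
exceeds 2000 are rejected (laminar model). Fields export to legacy
ASCII VTK; wall shear to CSV.

Domain padding for stenosed tubes defaults to 3 diameters upstream and
10 downstream of the lesion so the outflow boundary does not clip the
recirculation zone; at ds = 0.75 and Re ≈ 400 the bubble can still
reach the outlet, in which case the reattachment length saturates at
the domain length (flagged by construction, not an error).

## Parametric studies and problem sizes

The shipped sweeps mirror the study design: DS ∈ {45, 55, 65, 75}% (4 mm
lesion at location A), locations A–D (55%, 4 mm), lengths
{4, 8, 12, 16} mm (55% at A), all under hyperemic BCs, plus a
resistance-sensitivity study that uniformly rescales every outlet
resistance over {0.29, 0.5, 0.76, 1.0, 1.24, 1.5, 1.71} — spanning the
24–71% uncertainty range in both directions, since the sign of the
stated variations is ambiguous (per-outlet scaling is also available).
The revascularization threshold is the linear interpolation of the DS
sweep at FFR_CT = 0.80, reported to the nearest percent. Network solves
take milliseconds; the full sweep suite runs in under a second on one
CPU. Navier–Stokes verification runs use 80×12 to 320×40 grids (seconds
to minutes each); these sizes resolve the laminar flows studied here, as
the grid-refinement checks document.

Every stage is deterministic given the configuration — there are no
stochastic components — and all outputs carry a SHA-256 hash of the full
configuration for provenance.

## What the emulator does and does not show

The synthetic LAD reproduces the *structure* of the problem — tapering
trunk, Murray-split branches, resistance beds, hyperemic scaling,
concentric lesions — with every printed physiological anchor honored.
It does not reproduce any particular animal's or patient's anatomy:
real coronary lumens are non-circular, tortuous, and diffusely
diseased, and real lesion pressure losses depend on surface ruggedness
that an idealized concentric narrowing cannot carry. Passing tests
therefore demonstrate correctness of the implemented models and the
qualitative physiology (monotone FFR–DS relation, branch steal, flow
reduction, proximal-lesion severity), not patient-level predictive
accuracy.

Two quantitative limitations of the model family itself are worth
stating plainly:

* The Young–Tsai throat loss grows like (1 − ds)⁻⁴, which is steeper in
  ds than fully resolved 3-D computations on smooth idealized lesions
  tend to show; with every anchor at its default the simulated FFR_CT
  at DS = 75% lands near 0.68, at the aggressive end of the expected
  ~0.74 ± 0.05 band, while the 45% endpoint (0.92 vs 0.89 ± 0.05) and
  the 0.80-threshold crossing (61% DS) sit inside theirs.
* FFR_CT in any pressure-driven model with resistance outlets is
  *necessarily* sensitive to uniform bed-resistance rescaling once the
  lesion drop is appreciable: scaling R by c changes the stenosis flow
  by roughly (1 − c)·R Q relative to the total driving pressure, and
  the quadratic throat loss by about twice that. With the default
  calibration the 55% DS model shows a maximum FFR_CT change of ≈ 14%
  across the {0.29…1.71} factor grid. A markedly smaller sensitivity
  would require the hyperemic bed drop to be only a couple of mmHg,
  which is incompatible with the same model producing FFR_CT ≈ 0.85 at
  55% DS. Reported near-insensitivity of FFR_CT to resistance
  uncertainty is therefore reproducible here only under per-outlet
  perturbations with mixed signs (which largely cancel) or with a
  prescribed inlet flow; the uniform-scaling study reports the honest
  value.

## Other limitations

Steady flow only (no pulsatility, no intramyocardial pump), rigid
walls, Newtonian rheology, laminar regime, axisymmetric lesions, no
microvascular disease modifiers, and no image-derived geometry — the
geometry module is the system's only source of anatomy.
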