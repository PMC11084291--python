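# Methods

This note records the models implemented in `graftflow`, their
assumptions, the defaults and why they were chosen, and what the
synthetic fixtures do and do not establish about real aortic flows.

## Physical model and scope

Blood is treated as an incompressible Newtonian fluid with dynamic
viscosity μ = 0.004 Pa s and density ρ = 1060 kg/m³, the standard
whole-blood values for aortic flow modelling. The package deliberately
stops short of 3D CFD: the simulated object is a **0D (lumped-parameter)
surrogate** of the LVAD-supported aorta — two inflows into a single rigid
pressure node drained by seven three-element Windkessel outlets. The 3D
machinery around such simulations (waveform synthesis, outlet-parameter
estimation, geometry parameterisation, post-processing metrics, grid
verification) is implemented in full and is exercised on analytic fields
whose answers are known in closed form.

## Inlet waveforms

**Artificial pulse.** The HMIII controller modulates pump speed every
2 s: −2000 rpm from the set speed for 0.15 s, then +4000 rpm *from the
reduced speed* for 0.2 s, then the set speed for 1.65 s. The default set
speed is 5500 rpm, the midpoint of the device's typical 5000–6000 rpm
band; the band is enforced and configurable. The alternative reading of
the speed rise (+4000 above the set speed) is available via
`PulseSchedule(rise_from_base=True)`, but the default matches published
descriptions of the artificial pulse, under which the elevated phase runs
at set speed + 2000 rpm.

**Speed-to-flow calibration.** The pump's true head-flow behaviour is not
modelled. The OG flow waveform is obtained by a proportional calibration
`Q(t) = Q_mean · s(t) / ⟨s⟩` of the speed program, which preserves the
waveform's shape and pins its cycle mean exactly — the two features the
downstream network actually consumes. The waveform is then represented as
an 8-harmonic Fourier series, the truncation used throughout.

**Residual native ejection.** In chronic heart failure under LVAD
support, the ventricle still ejects weakly through the aortic valve. The
native waveform is a half-sine systolic lobe (systolic fraction 0.35 of a
0.7 s cycle — a standard ejection-template shape chosen because the
reference waveform itself is not available in reproducible form), scaled
so the cycle mean equals the target output (default 3.2 L/min =
5.33×10⁻⁵ m³/s) and fitted with 8 harmonics. In the combined inlet
program the native flow is scaled to a 5% residual and gated on during
exactly one native cycle at the start of every block of five pump cycles;
an `av_open=False` mode models the persistently closed valve.

**Fourier fitting** uses ordinary least squares on the sine/cosine design
matrix rather than an FFT so that non-uniform sampling is supported. On a
uniform full-period grid the design columns are orthogonal, so the fitted
`a0` equals the sample mean — this projection property is tested.

## Windkessel outlets and their sizing

Each outlet is an RCR circuit: proximal resistance R_p (viscous
resistance of the branch), distal resistance R_d (capillary/venous bed),
compliance C (vessel distension). The shipped seven-branch table encodes
the LVAD-supported systemic state used throughout: systolic/diastolic
pressures 78/69 mmHg, mean arterial pressure (MAP) 73 mmHg, cardiac
output (CO) 6.7×10⁻⁵ m³/s, heart rate 30 BPM. Internal consistency of
the table is enforced by tests: every row has R_p/(R_p+R_d) ≈ 0.070, the
parallel combination of the seven series resistances agrees with MAP/CO
within 1%, and the compliances sum to 1.117×10⁻⁸ m³/Pa.

`estimate_rcr` inverts this construction: given a systemic state and
branch flow fractions f_i, it sets R_i = (MAP/CO)/f_i, splits it with a
proximal fraction (default 0.07, obtained by inverting the shipped table,
which gives ≈7.0% on all seven rows), and apportions total compliance as
C_i = f_i·C_total. By construction the parallel recombination returns
MAP/CO exactly, independent of fractions and split — a tested identity.
The default total compliance is the table sum; a distensibility-based
derivation (relative distensibility 7.9×10⁻³ mmHg⁻¹ times a reference
volume) is kept as the documented alternative. The printed distensibility
unit is ambiguous in the source material; it is treated as mmHg⁻¹.
Pressure conversion is fixed at 133.322 Pa/mmHg; all internal computation
is SI.

## The 0D network

With rigid walls there is no storage at the aortic node, so the node
pressure is algebraic in the capacitor states:

    P = (q_in + Σ P_c,i/R_p,i) / (Σ 1/R_p,i),  q_i = (P − P_c,i)/R_p,i

which conserves mass identically at every step (tested to 1e-9 relative).
The capacitor ODEs are integrated with fixed-step classic RK4 at
dt = 1 ms, the time step used for the reference 3D simulations; the step
is snapped so an integer number of steps tiles each pump cycle, making
runs deterministic and byte-reproducible. Convergence to the periodic
state is declared when the relative L2 distance between consecutive pump
cycles of the node pressure drops below 10⁻³ (the desk equivalent of
monitoring outlet-pressure plots for a repeating pattern); from a
discharged start the default network converges in under ten 2 s cycles,
consistent with the ~1.5 s R_d·C time constants of all seven branches.
The node pressure is a surrogate for the spatially averaged aortic
pressure of a 3D solution, not an equivalence — no claim is made about
spatial pressure distribution.

## Anastomosis geometry

Coordinates are right-handed patient coordinates: axial axis +z, coronal
plane x–z (normal +y), sagittal plane y–z (normal +x). The angle
convention — the one reading under which "angle between the coronal plane
and the graft axis" is non-zero for a coronal-sided graft — is: a
*coronal-sided* graft attaches on the +y aspect of the ascending aorta
with its axis in the y–z plane, tilted downward toward the pump, so the
axis-to-coronal-plane angle equals the configured angle exactly;
sagittal mirrors this with +x. The convention is documented here because
the anatomical anchor of the angle vertex is genuinely underdetermined;
all build/measure operations share it, so round-trips are exact by
construction and the tolerances (0.5 mm, 0.5°, 0.1 mm on diameter) absorb
only meshing and fitting error.

The default aorta is an idealised Type-I "candy-cane": straight ascending
segment (110 mm), semicircular arch (40 mm radius), straight descending
segment, 15 mm lumen radius, with labelled ostia for the seven outlets.
The distance d is measured between two planes normal to the axial axis,
through the ventriculo-arterial junction and the anastomosis centre.
Valid attachments are restricted to the ascending segment. Tubes are
swept with parallel-transported frames; the junction is emitted as two
labelled open tubes rather than a watertight boolean union — parameter
measurement and STL export need no CSG, and downstream CAD tools perform
the union natively. Measurement fits a cylinder to the graft-labelled
vertices by least squares (PCA initialisation; the axis-point offset is
confined to the plane normal to the axis, since the along-axis component
is unidentifiable). A graft leaning equally toward both plane normals
(within 1°) is reported as side-`ambiguous` rather than forced into a
category.

## Field metrics

TAWSS and OSI follow the standard formulas — time-averaged shear
*magnitude*, and `0.5·(1 − |∫τ dt|/∫|τ| dt)` — adopted because the
quantities are otherwise described only in words. Points with zero
cumulative shear would make OSI 0/0; they return 0 and are counted in the
log. Vorticity and the strain-rate dissipation use second-order central
differences on structured grids only; unstructured inputs are rejected
with a pointer to the structured generators. The energy-loss formula is
interpreted as the dissipation *density* μ/2 Σᵢⱼ(∂uᵢ/∂xⱼ+∂uⱼ/∂xᵢ)²
integrated over both the sampled volume and the time window, giving
joules; for steady Poiseuille flow this reproduces ΔP·Q (verified to
within 2% on a 64² cross-section). TKE uses the resolved-fluctuation
(ensemble) definition k = ½⟨|u′|²⟩; whether a RANS solver's modelled k
would match depends on the turbulence model, so the quantity is labelled
as the ensemble definition.

## Grid convergence

The observed order solves the standard Richardson relation; for unequal
refinement ratios the relation is solved by bracketing root-finding on
p ∈ (0, 64], which is robust where fixed-point iteration can cycle.
Oscillatory convergence (medium value outside the fine/coarse bracket) is
flagged `monotone=False` with an effective order from the
error-magnitude ratio — possibly negative — rather than feeding a
meaningless order into a GCI. The safety factor defaults to 1.25, the
accepted value for three-grid studies. The asymptotic check
gci32/(r^p·gci21) equals 1 exactly only in the small-error limit because
GCIs are built on *relative* errors; tests construct that limit
explicitly.

## Synthetic fixtures: what they do and do not show

The generators produce fields whose metric values are known in closed
form: Poiseuille flow (Hagen–Poiseuille rate, wall shear ΔP·R/2L,
dissipation ΔP·Q), solid-body rotation (curl 2Ω, zero strain),
direction-switching wall shear (OSI = 0.5(1−|1−2f|) for reversal fraction
f), uniform flow, and seeded noisy Fourier samples. The Poiseuille tube
is sampled on a Cartesian grid with the smooth analytic profile retained
outside the lumen — central differences then stay exact for the parabolic
profile — while the quadrature measure carries sub-sampled in-lumen cell
fractions (8×8 per boundary cell), keeping volume integrals accurate at
modest resolution. The oscillating-shear program is zero exactly at the
switch instant so trapezoidal integrals of symmetric programs cancel
exactly; its TAWSS consequently carries an O(1/n_t) quadrature deficit,
which tests tolerate explicitly.

Passing on these fixtures establishes that the metric implementations are
correct discretisations of their definitions. It does *not* establish
anything about real LVAD aortic flow: the fixtures have none of the
secondary flows, turbulence, moving boundaries or measurement noise of
the clinical setting, and the 0D network cannot resolve spatial patterns
(jet impingement, recirculation zones) at all. Conclusions about optimal
graft placement require the 3D CFD this package deliberately does not
contain.

## Numerical choices and limitations

* Fixed-step RK4 at 1 ms; the implicit-Euler fallback (exact update for
  the linear RC ODE) is available for stiff parameter sets.
* Problem sizes in tests and the acceptance script are desk-scale by
  design: ≤64³ grids, ≤30 pump cycles, dense-grid quadrature at 10⁴–10⁵
  samples — each check runs in seconds.
* Degenerate inputs error early with named parameters (out-of-range
  angles/distances, non-increasing sample times, underdetermined fits,
  empty branch sets); non-finite solver states raise with the failing
  step and time-step advice.
* Branch flow fractions for outlet sizing are inputs; the shipped default
  is the set implied by the table's conductances. How such fractions are
  best apportioned clinically (area-based vs literature splits) is left
  to the user.
* Womersley pulsatile closed forms are a possible extension of the
  fixture family, not currently included.
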