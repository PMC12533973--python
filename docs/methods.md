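# Methods

This note documents the models inside `embotrace`, the defaults they ship
with, the numerical choices, and what the synthetic setting does and does
not capture. All defaults are set in code (`FluidProperties`,
`CardiacWaveform`, `EmbolusProperties`, `RunPolicy`, the geometry template
in `vasculature.py`) and every one of them can be overridden per call or
via YAML configs in the CLI.

## 1. Synthetic vascular anatomy

The baseline network is a hand-designed, anatomically plausible
heart-to-brain arterial tree: aortic root (radius 12.5 mm) and arch,
descending aorta, brachiocephalic trunk, bilateral subclavian, vertebral,
common/internal/external carotid arteries, basilar artery, and a complete
Circle of Willis (M1, A1, A2, P1, P2 segments, AcoA, both PCoAs). Eleven
outlets: descending aorta, L/R subclavian, L/R external carotid, L/R MCA,
L/R ACA, L/R PCA. Coordinates are millimetres, patient-left = +x,
anterior = +y, cranial = +z; centerlines are cubic-spline polylines with
linear radius profiles.

Design choices that matter for transport:

* **Arch branching order.** The geometry is left-right symmetric *except*
  that the brachiocephalic trunk branches from the arch first and feeds the
  right carotid/subclavian, while the left vessels originate directly from
  the arch slightly downstream. Any right-preferential recruitment of
  cardiogenic emboli therefore emerges from branching geometry, not from a
  hard-coded bias. A perfectly symmetric variant (midline arch junction,
  twin brachiocephalic trunks) is available for symmetry oracles
  (`symmetric_arch: true`).
* **Carotid siphon.** The internal carotid executes a smooth S of bends
  (minimum centerline curvature radius ~13 mm) before the communicating
  segment. The bends drive the Dean secondary circulation that stirs the
  vessel cross-section; without them, the azimuthal position a particle
  acquires at release would be frozen all the way to the terminal
  bifurcation and junction splits would be purely geometric rather than
  flux-sensitive.
* **Two-stage carotid terminus.** The PCoA joins the ICA at a communicating
  (C7) node a few millimetres proximal to the terminal ICA bifurcation into
  M1 and A1, and its approach is angled so that reverse (collateral,
  posterior-to-anterior) PCoA flow merges *up* the terminal ICA. Likewise
  P1 continues smoothly into P2 at the posterior junction with the PCoA
  merging tangentially. Mouth angles at junctions are load-bearing in this
  reconstruction: a tributary jet aimed down a stagnant parent vessel
  creates particle traps that a real 3D flow does not have.

### Stenosis parameterization

Severity is the NASCET diameter ratio. A stenosis of severity `s` on the
proximal ICA (default site) multiplies the radius profile by a cosine taper
reaching `1 - s/100` at the throat, over a length
`L = k (s/100) L_segment` with `k = 0.5` (more severe stenoses disturb a
longer span; the proportional rule and `k` are configurable). Severity 100
flags the segment occluded: no flow, no release, excluded from particle
ownership. The model family enumerates all (mild, moderate/severe) pairs of
{10, 25, 40} x {50, 70, 85} on both side assignments (18 bilateral models)
plus one fully occluded carotid against each of the six severities
(12 CCO models).

## 2. Hemodynamics

The 3D pulsatile problem is reduced to a resistive network solved for nodal
pressures at every time step (`dt_flow` = 1 ms, three cycles marched, the
final cycle returned; with a purely resistive network the cycles are
identical, so periodicity is exact by construction).

* Blood: Newtonian, viscosity 4.0 cP, density 1.06 g/cc.
* Inlet: periodic pulse with period 0.83 s and mean flow (cardiac output)
  79 mL/s. The default shape is a sin^2 systolic bump over 35% of the cycle
  on a 4% diastolic baseline — the measured-waveform shape it stands in for
  is config-replaceable; only period and mean are treated as fixed
  parameters of the study conditions.
* Segment resistance: `R = 8 mu / (pi r(s)^4)` integrated along the radius
  profile. Stenosed segments add a Young–Tsai-type quadratic loss
  `K_t rho (A_ref/A_throat - 1)^2 Q|Q| / (2 A_ref^2)`, `K_t = 1.52`; a pure
  Poiseuille law would badly underestimate severe-stenosis losses and the
  flow rerouting they drive. The nonlinearity is solved by damped fixed
  point on the effective conductances (tolerance 1e-12 relative, warm
  started across time steps); interior-node mass residuals are at machine
  precision, far below the 1e-9 x CO requirement.
* Outlet boundary conditions: lumped resistances to zero reference
  pressure. Targets: 65% of CO to the descending aorta; six cerebral
  fractions defaulting to MCA 3.75%, ACA 2.0%, PCA 1.75% per side (15% of
  CO total cerebral flow, physiologic MCA > ACA >= PCA ordering,
  config-replaceable); the remainder split across external carotids and
  subclavians proportional to outlet cross-sectional areas. Tuning
  multiplies each outlet resistance by its flow-to-target ratio and
  rescales globally to hold the inlet mean pressure at MAP = 93.33 mmHg
  (from 120/80 via MAP = DBP + PP/3), so total admittance is consistent
  with TAR = MAP/CO. Convergence to within 1% per outlet takes a few
  iterations. The tuned set is computed once on the no-stenosis baseline
  and reused unchanged for all 30 models, so differences between models are
  attributable to the stenoses alone.

Consequences worth knowing: with fixed outlet resistances and a complete
CoW, outlet flow fractions stay nearly constant across models (within ~15%
relative even at 40L85R) while the *cervical* supply reroutes strongly —
an 85% ICA's flow collapses to a few percent of total cerebral blood flow
and the contralateral ICA, basilar, AcoA and P1 segments compensate. The
AcoA always carries mean flow toward the more severely stenosed side and
its magnitude grows with that severity.

### Velocity reconstruction

Particle forcing needs a space-time velocity field, rebuilt analytically
from the per-segment flows:

* In-segment: quasi-steady Poiseuille,
  `w = 2 Q(t)/(pi R(s)^2) (1 - (rho/R)^2)` along the centerline tangent,
  plus the first-order radial component required by mass conservation where
  `R(s)` varies. Quasi-steady profiles (not Womersley) are used: at a
  particle Stokes number of 0.005 the fate is dominated by flow splits and
  near-wall shear, not by profile phase lag.
* Dean secondary flow: where the centerline curves, a two-vortex
  circulation (core fluid toward the outer wall, wall fluid returning along
  the sides) is added from an in-plane stream function with no-slip at the
  wall; magnitude = `min(0.15, 0.02 sqrt(De))` of the local mean axial
  speed, with `De = Re sqrt(R kappa)`. Its contribution to the gradient
  tensor and Eulerian acceleration is neglected.
* Junctions: inside a spherical neighbourhood of each node (radius 1.5x the
  largest adjacent vessel radius) the adjacent segment fields are blended
  with inverse-axis-distance weights *scaled by the flux each branch
  carries* — in a junction the strongly flowing branches shape the field,
  not a wide but stagnant parent — and every branch carrying flow away from
  the node additionally draws fluid toward its mouth as a softened sink of
  its instantaneous flux. The sink term is what divides an incoming jet
  among daughters by flow rate; it decays as 1/r^2 and is not faded at the
  blend boundary (the resulting velocity discontinuity there is of order
  10 mm/s, small against the jets it corrects). Junction interiors also
  carry a convex "bulb" wall (sphere of the largest adjacent radius) so
  that wall contact at a branch point funnels into the daughters instead of
  snagging on a parent's end cap.
* The cross-sectional flux of the sampled field matches the network flow to
  0.1% away from junctions (checked by Gauss–Legendre quadrature), no-slip
  is exact at segment walls, and the field arrays are frozen read-only
  (one-way coupling is enforced at the API level).

## 3. Embolus dynamics

Emboli are rigid spheres, default diameter 500 um. The density default,
1.15 g/cc, is chosen so that the bare Stokes response time
`tau = rho_p d^2 / (18 mu)` equals 4 ms at the default viscosity —
within reported thrombus density ranges — giving a cardiac-cycle Stokes
number of ~0.005 (near-tracer, but not passive). Forces per unit volume:

* Stokes drag `18 mu (u - v)/d^2`, with an optional Schiller–Naumann
  finite-Reynolds factor (off by default);
* undisturbed-flow/pressure-gradient force `(1 + C_m) rho_f Du/Dt` with
  Auton added mass `C_m = 0.5` absorbed into the effective inertia
  `rho_p + C_m rho_f` (so the measured velocity-relaxation time is
  `tau (rho_p + C_m rho_f)/rho_p`, about 5.8 ms at defaults);
* Saffman–Mei shear lift `~ d^2 sqrt(rho_f mu) (u - v) x omega / sqrt(|omega|)`;
* a wall-corrected lift: within one diameter of a wall the hydrodynamic
  image system drives the sphere toward the core even at vanishing slip.
  It is imposed as a bounded migration velocity `v_w = C gammadot a` with
  `C = 0.1` and cubic decay in the gap, relaxed through the drag term —
  a force-based contact-strength form (coefficient ~9 at contact) is
  physically equivalent but numerically stiff beyond what the explicit
  Euler step can integrate at cerebral shear rates.
* The Basset history force is omitted (standard at this Stokes number);
  gravity/buoyancy is omitted by default (near-neutral buoyancy).

Wall collisions use a wet, velocity-dependent restitution as the
elastohydrodynamic-lubrication stand-in: with impact Stokes number
`St_n = rho_p d v_n / (9 mu)`, the rebound coefficient is
`e = e0 max(0, 1 - St_c/St_n)` with `e0 = 0.8`, `St_c = 10`. At arterial
impact speeds `St_n` is almost always below threshold, so collisions are
fully damped and particles slide frictionlessly; the dry restitution is
recovered in the (rarely reached) fast-impact limit. Penetrating positions
are projected back to the wall-offset surface.

Integration is explicit Euler at 0.05 ms (stable: the shortest force time
scale is the ~5.8 ms effective response time). Each particle runs
10 cardiac cycles from its own release time; if more than 10% of a batch
has not exited, all unresolved trajectories are extended once by another
10 cycles, and any experiment still above 10% afterwards is flagged in its
record rather than iterated further. Particles are mutually independent,
so batch integration is bitwise identical to particle-by-particle
integration, and everything is deterministic given the release states.

Particle bookkeeping: each particle is "owned" by one segment; ownership
hands over at segment ends, preferring branches whose instantaneous flow
carries the particle away from the junction. Exit is recorded when a
particle crosses the distal plane of an outlet stub.

## 4. Release protocol and campaign

Carotid releases sample the stenosis-length wall patch uniformly by surface
area, offset inward by one embolus radius; cardiogenic releases sample the
aortic-root inlet disc (radius minus embolus radius) uniformly by area.
Release times are uniform over one cardiac cycle (no phase information is
assumed; the choice is seed-controlled), and initial velocities equal the
local fluid velocity. Default 5,500 emboli per source; the 78-experiment
campaign tunes once, solves each model once, isolates per-experiment
failures, writes JSON records plus a manifest, and resumes by skipping
records that already exist for the same (model, source, n, seed, policy)
hash.

Statistics follow the non-parametric toolkit: one-sample Wilcoxon
signed-rank against a hypothesized median (the canonical reading of a
"one-sample Wilcoxon test"; exact p for n <= 25 without ties), Mann–Whitney
U (exact for n m <= 400 without ties), Shapiro–Wilk for normality checks.
The contralateral denominator is emboli reaching the six cerebral outlets
(not all released emboli); `denominator="released"` switches the
convention.

## 5. Problem sizes used in tests and the acceptance script

The shipped test suite runs the full 30-model family with all 48 carotid
releases plus a 6-model cardiogenic subset at 100 emboli per release, and
the acceptance script uses 1,000 emboli for the 40L85R transport target —
sample sizes at which the qualitative campaign findings reported below are
stable (binomial error on a contralateral fraction of ~0.2 at n = 100 is
~0.04). The full default campaign (5,500 per source) runs unattended via
`embotrace campaign` in a few hours on one core.

## 6. What the synthetic study reproduces, and what it does not

Reproduced qualitatively (asserted by the end-to-end suite):

* every release from the milder (or CCO-patent) carotid yields strictly
  positive contralateral transport, significant by signed-rank test;
* releases from the milder side cross far more than releases from the
  severely stenosed side (Mann–Whitney p < 0.01);
* the 12 CCO releases cross more on average than the 36 bilateral-model
  releases;
* the contralateral fraction trends upward with the contralateral severity
  within each mild level (positive within-sweep rank correlation);
* cardiogenic emboli preferentially travel the right common carotid, and
  reach both hemispheres at every severity combination;
* with fixed outlet resistances, outlet flow fractions are nearly constant
  across models while cervical recruitment (LICA/RICA/basilar shares of
  total cerebral blood flow) shifts monotonically with severity, and the
  AcoA reverses toward the severe side with growing magnitude.

Known limitations (deliberate consequences of the reduction):

* **Magnitudes are not patient magnitudes.** The lumped stenosis law
  starves a severely stenosed ICA more aggressively than a 3D lumen would,
  so collateral recruitment — and with it the absolute contralateral
  fractions (~15–40% here) — is larger than the patient-specific values
  (a few to ten percent). Trends, not magnitudes, are the model's output.
* **Severe-side crossing is essentially zero.** In a purely resistive
  network the instantaneous AcoA flow never reverses against its mean
  direction within the cycle, so emboli released at the *severe* carotid
  have no route to the opposite hemisphere; the study this emulates found
  small (sub-5%) severe-side crossing, which requires flow features
  (compliance-driven transients, 3D recirculation) that the reduction does
  not carry.
* **Cardiogenic hemisphere splits are more variable across models** than
  the near-insensitivity reported on patient geometry: junction capture in
  the blended field remains partially geometric, so the hemispheric split
  of the (relatively few) brain-bound cardiogenic emboli moves with
  severity more than the patient-specific study suggests. The right-carotid
  recruitment preference is robust; the per-model coefficient of variation
  of hemisphere splits is not a reproduced quantity.
* Individual near-wall trajectories are chaotic (Dean mixing plus wall
  interactions), so halving the time step changes individual destinations
  while leaving destination *distributions* unchanged within sampling
  noise; robustness is therefore asserted distributionally.
* No wall compliance, cerebral autoregulation, distal collaterals,
  stenosis-adaptive distal resistances, embolus deformation/breakup,
  embolus-embolus interaction, margination forces, or multi-size showers.
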