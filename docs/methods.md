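# Model and methods

`thromboflow` is a desk-scale 2D simulator of continuum thrombosis risk in
blood-contacting devices.  It couples a steady incompressible flow field to
five transported scalars — residence time (RT), resting and activated
platelets (RPs, APs), lumped coagulation factors (CFs) and a thrombotic-clot
surrogate (TCs) — with threshold-gated reactions and a two-way clot–flow
feedback.  This note records the governing model, the numerical choices, and
the judgement calls a maintainer would want to know about.

## Governing model

**Flow.**  Steady laminar incompressible Navier–Stokes on a structured 2D
grid with an effective viscosity and a clot momentum sink:

    rho (v · grad) v = -grad p + div(mu_eff grad v) - k_M phi_TC v
    mu_eff = mu0 (1 + 100 phi_TC)

The sink is the Brinkman (velocity-proportional) form; `sink_form="constant"`
switches to a constant-magnitude drag opposing the previous iterate's
velocity direction, for compatibility with a literal reading of the source
term.  The constant form is a dry-friction-like force with no smooth stalled
state; it is only well-posed while weaker than the pressure driving, and the
Brinkman form is the default for that reason.

**Scalar shear stress.**  The gating stress is `sqrt(J2)` of the symmetrized
viscous stress deviator,

    sigma = sqrt( 1/6 * sum_{i<j} (s_ii - s_jj)^2 + sum_{i<j} s_ij^2 ),
    s_ij = mu (dv_i/dx_j + dv_j/dx_i),

which is frame-invariant and equals `mu * gamma_dot` in simple shear, so a
shear rate of 10 000 1/s at 3.5 mPa s reads exactly 35 Pa — the platelet
activation threshold.  Turbulent (Reynolds-stress) contributions are
deliberately excluded; every shipped configuration is laminar.

**Species.**  With `phi(x; x0) = x/x0` where `x >= 0.4 x0` and 0 below
(reactions stop when a driver falls under ~0.4 of its threshold):

    dRT/dt  + v·grad RT  = D_RT lap RT + 1
    dRPs/dt + v·grad RPs = D_p lap RPs - r12          (while RPs > 0)
    dAPs/dt + v·grad APs = D_p lap APs + r12
    dCFs/dt + v·grad CFs = D_ceff lap CFs + (k_CFs / u_c) r12
    dTCs/dt              = k_TCs [ phi(TCs;TC0) APs/(APs+RPs) + phi(RT;RT0) ]

    r12   = k1 phi(SSS;NPSS0) RPs + k2 phi(CFs;CF0) APs
    D_p   = D_pt + alpha * SSS / mu
    D_ceff= D_c * phi(gamma;gamma0)

`u_c = 1e-6 mol/m^3` converts the per-platelet release `k_CFs` (mol) into
the internal CF/TC concentration unit of nmol/L; all thresholds are ratios,
so the unit choice cancels everywhere except in that one source term.
TCs has no advection or diffusion: clots stay where they form.

Boundary conditions: inlet carries fresh blood (RT 0 s, APs 25e12 /m^3,
RPs 475e12 /m^3, CFs and TCs 0); outlets and walls are zero-flux, except the
CF wall boundary, which releases a flux `k_ceff` wherever the wall shear
stress is below 0.2 Pa and the local clot level has not reached TC0
(low-shear agonist release at the artificial surface).  `k_ceff` has no
published value; the default 1e-6 (nmol/L)·m/s keeps the wall source small
relative to bulk release at inlet composition, and quantitative use of the
wall term should treat it as a required calibration input.

### Three interpretive decisions

The printed model leaves three points open; the package resolves them as
follows, with the alternatives kept available behind flags.

1. **Clot-source gating** (`tc_gate`, default `"tcs"`).  The first TC source
   term is gated by the clot level itself, `phi(TCs; TC0)` — autocatalytic
   growth seeded by the residence-time term.  This is the only reading under
   which a sub-threshold channel stays clot-free exactly; the alternatives
   (`"unity"`: ungated; `"ap_fraction"`: gate on the activated fraction) are
   selectable.

2. **CF release** (`cf_release`, default `"activation"`).  Factors are
   released in proportion to the RPs→APs conversion rate (the agonist
   content of each newly activated platelet), not the standing APs
   concentration.  The literal standing-concentration source
   (`"aps_rate"`) releases ~750 nmol/L/s at inlet composition and would
   push CFs past their reaction cutoff within ~5 ms everywhere blood flows,
   destroying the existence of a null state.  With the default, a
   shear-quiet channel has identically zero CFs and TCs.

3. **RPs floor.**  The CF-driven exchange term `k2 phi_CF APs` is
   proportional to APs, so integrated literally it drives RPs negative after
   exhaustion.  Conversion stops at RPs = 0 (an absorbing floor), located by
   event detection in the ODE oracle and by crossing bisection plus a
   conserving clip in the PDE path.

## Discretization

**Flow solver.**  Marker-and-cell (staggered) finite volumes: u on vertical
faces, v on horizontal faces, p at cell centers.  Convection is first-order
upwind, linearized by Picard (Oseen) iteration; diffusion is central with a
variable-viscosity Laplacian `div(mu grad v)` (the extra transpose term of
the full stress divergence is dropped; it vanishes for constant viscosity
and the clot feedback regime is dominated by the sink).  Each Picard step
solves the fully coupled momentum/continuity system with a sparse direct
factorization — at desk-scale sizes (≤ ~20k unknowns) this is more robust
than segregated pressure-correction sweeps, and continuity is then satisfied
to machine precision at every iterate.  No-slip staircase walls use
half-cell ghost values for the tangential velocity (recovering second-order
plane Poiseuille profiles); moving walls (lid-driven cavities) carry a
per-cell tangential wall velocity.  Inlets are supported as velocity
profiles (plug or parabolic) or fixed-pressure plenums; sealed domains pin
one pressure.  Convergence is declared when the normalized nonlinear
momentum residual falls below `tol` (default 1e-6); non-convergence raises
an error carrying the residual history.  The solver is intended for laminar
configurations (Re up to a few hundred); the shipped fixtures respect that.

**Species stepping.**  Transport is backward-Euler in pseudo-time with
conservative upwind advection and central diffusion, factorized once per
frozen flow and re-used — unconditionally stable, and the steady state
solves the exact steady equations independent of dt.  Reactions advance by
classical RK4 within each step, sub-cycled so the fastest local rate times
the sub-step stays ≤ 1 (the CF–activation loop transiently reaches
~150 1/s), with per-cell bisection onto threshold-cutoff crossings
(`crossing_depth` halvings; default 3 for field runs, 40 where the
single-cell limit is compared against the ODE oracle at 1e-6).  The RT unit
source lives in the reaction stage so gate crossings in time are located
sharply.  An explicit scheme with the CFL/Fourier bound (0.8 safety factor)
and step-size errors is available via `scheme="explicit"`; it is impractical
for clot-growth horizons (convective dt ~ 2e-5 s at clearance scales) and
exists for verification.

Platelet conservation is exact by construction: RPs and APs share one
transport operator in flux form, the exchange terms cancel analytically,
and negative-value clips transfer between the pools.  Sealed-domain runs
hold the platelet total to ~1e-15 relative per step.

**Steady detection.**  RT, RPs, APs and CFs are steady when their relative
change per unit time drops below `steady_tol`; TCs grows without bound by
construction, so its growth *rate* must stabilize instead.  Reaching the
horizon without steadiness returns the partial state with a warning — dead
zones age indefinitely, so some fixtures never formally steady.

**Feedback.**  Every `feedback_interval` steps, if any cell's clot gate is
open, the flow is re-solved (warm-started) with `mu_eff` and the Brinkman
sink from the current TC field, and the transport operators are rebuilt.

## Surrogate fixtures

The generator emulates the flow features that concentrate device thrombosis
risk, as deterministic functions of their spec (no randomness anywhere):

- `channel` — plane Poiseuille at 0.5 m/s in a 5 mm duct: wall shear 2.1 Pa,
  far below the 14 Pa reaction cutoff.  The null model: the outlet keeps the
  5% inlet activated fraction and CFs and TCs stay identically zero.  Its
  wall-normal resolution is fixed at 0.2 mm because the age of the discrete
  wall layer is set by the half-cell sampled velocity; the feature-free
  reference is meaningful only while that layer stays below the RT cutoff.
- `step_recirculation` — a backward-facing step (0.5 mm duct, 3× expansion,
  0.45 m/s): near-wall shear ~18 Pa (mild activation, below the 35 Pa
  threshold and below ignition of the CF feedback loop) and a recirculation
  bubble holding residence times above 1 s.
- `gap_jet` — a pressure-driven clearance (0.25 mm throat opening into a 3×
  relief inside the plate, default 4 kPa drive → ~2 m/s jet): shear stress
  >100 Pa in the throat, strong activation, and a large slow recirculation
  in the jet expansion where clots accumulate.
- `combined_surrogate` — the clearance discharging over an additional
  backward step; all mechanisms in one domain.

Severity ordering (channel < step < gap jet in outlet AP% and
volume-averaged TCs, mirroring the ranking structure reported across
clinical devices) is a designed property of these defaults and is verified
end-to-end in the test suite over a common 30 s transport window.

The obstruction-feedback experiment runs the gap fixture at a 1 Pa drive —
a pump near standstill, the canonical low-flow thrombosis scenario.  At
~2 mm/s the clearance itself holds residence times of tens of seconds, clots
cross TC0 inside the slit within ~600 s of model time, and re-solving the
flow with the clot feedback collapses the through-gap flux by ~98%.  At the
full-speed operating point the same experiment is physically different:
clots form beside the jet (in the expansion recirculation), and
Brinkman-solidifying a recirculation that carries no net flux changes the
through-flow only marginally — occlusion of a fast jet proceeds by slow
front advance that is out of reach of desk-scale horizons.  The low-flow
operating point is therefore the shipped feedback demonstration.

## What the fixtures do and do not show

The surrogates exercise every mechanism of the model — threshold-gated
shear activation, CF amplification, residence-time-seeded autocatalytic
clot growth, hotspot co-location and clot–flow feedback — on geometries
whose flow structure (jets, bubbles, wall layers) is qualitatively that of
real pump passages.  They do not reproduce any real device's absolute
numbers: that requires the device geometry, 3D turbulence-resolving CFD and
rotating-frame machinery, all out of scope.  Passing tests certify the
model's internal mechanics and orderings, not clinical quantities.

## Numerical parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| `k1`, `k2` | 0.3, 0.1 1/s | shear- and CF-driven activation rates |
| `k_CFs` | 3e-17 mol | CF released per activated platelet |
| `k_TCs` | 2e-2 (nmol/L)/s | clot source coefficient |
| `k_M` | 1e7 kg/(m^3 s) | Brinkman sink coefficient |
| `D_RT`, `D_pt`, `alpha`, `D_c` | 1.14e-11, 1.6e-13 m^2/s, 7e-13 m^2, 1e-8 m^2/s | diffusivities |
| `mu0`, `rho` | 3.5 mPa s, 1055 kg/m^3 | blood properties |
| thresholds | 1 s, 35 Pa, 100 1/s, 10 nmol/L, 200 nmol/L | RT0, NPSS0, gamma0, CF0, TC0 |
| `cutoff_fraction` | 0.4 | reactions stop below this fraction of a threshold |
| `k_ceff` | 1e-6 (nmol/L)·m/s | low-shear wall CF flux (unpublished; calibration input) |

The cutoff default 0.4 (~1/2.5) reflects the stated "below two to three
times less than the threshold" stopping rule and matches the display bands
used for hotspot maps (15 Pa ≈ 35/2.33; 0.35 s ≈ 1/2.86); it is
configurable.

## Known limitations

- 2D planar, laminar, steady background flow; no turbulence model, no
  rotating frames, no pulsatile modes.
- First-order upwind transport: numerical diffusion flushes small
  recirculation features near fast jets, so residence-time retention is
  resolution- and speed-dependent; fixture geometry was designed with this
  in mind and refinement studies are part of the test suite.
- No wall adhesion/detachment kinetics and no resolved coagulation cascade;
  CFs are one lumped agonist species.
- The clot field is local (no transport), so emboli and downstream seeding
  are outside the model.
- Hard threshold cutoffs make the reaction field non-smooth; the integrators
  locate crossings rather than smoothing them, which is faithful but makes
  parameter sensitivities near ignition points steep (the step fixture's
  activation is deliberately kept below the CF-loop ignition knee).
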