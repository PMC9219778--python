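# thromboflow

Desk-scale 2D simulation of device-induced thrombosis risk.

Implanted blood pumps (ventricular assist devices) trade one failure mode
for another: their narrow clearances generate non-physiological shear stress
that activates platelets, while their recirculation pockets and ducts hold
blood long enough for activated material to deposit.  Predicting *where*
and *how strongly* a design promotes clotting — before animal or clinical
data exist — is a continuum-modelling problem: transport a handful of
scalar fields over the pump's flow field and let threshold-gated kinetics
turn flow features into risk maps.

`thromboflow` implements such a continuum thrombosis-risk model for
researchers and device engineers who want the mechanism at desk scale:
canonical 2D surrogate geometries (plane channel, backward-facing step,
clearance gap jet) stand in for proprietary pump passages, and every stage —
steady laminar flow, coupled species transport, clot–flow feedback, risk
metrics — runs in seconds to minutes on one CPU.

## The model

Five scalars are carried over a steady incompressible flow:

- **RT** — residence time, transported with a unit source (`∂t RT + v·∇RT =
  D_RT ∇²RT + 1`): the age of blood since entering the domain.
- **RPs / APs** — resting and activated platelet concentrations, exchanged
  at rate `k1·φ(σ;σ0)·RPs + k2·φ(CFs;CF0)·APs`, where `σ` is the scalar
  shear stress (`√J2` of the viscous stress deviator; 10 000 1/s ↔ 35 Pa)
  and `φ(x;x0) = x/x0` above a cutoff at `0.4·x0`, zero below.
- **CFs** — lumped coagulation factors (ADP, TXA2, thrombin …) released on
  platelet activation; they amplify further activation.
- **TCs** — a clot surrogate with no transport of its own, growing as
  `k_TCs·[φ(TCs;TC0)·APs/(APs+RPs) + φ(RT;RT0)]`: seeded where old blood
  pools, amplified where activated platelets dominate.

Clots feed back on the flow through an amplified viscosity
`μ = μ0(1+100·φ_TC)` and a Brinkman momentum sink `−k_M·φ_TC·v`, so a
growing clot throttles the passage that feeds it.  Reported metrics are the
flux-weighted activated-platelet percentage at the outlet, volume-averaged
clot burden, max–min normalized per-region risk, and high-shear (>15 Pa) /
long-residence (>0.35 s) hotspot masks.

See `docs/methods.md` for the full model, the numerical schemes, and the
design decisions.

## Worked example

Run the clearance ("gap jet") surrogate — a 0.25 mm slit driven to a ~2 m/s
jet — and extract the risk report:

```python
from thromboflow import (FixtureSpec, generate_fixture, SpeciesBCs,
                         TransportControls, run_to_steady, region_report)

fx = generate_fixture(FixtureSpec(kind="gap_jet"))
state, report, flow = run_to_steady(
    fx.grid, fx.flow, SpeciesBCs(),
    controls=TransportControls(dt=0.1, horizon=30.0),
    inflow=fx.inflow,
)
risk = region_report(state, fx.grid, flow)
print(f"outlet activated platelets: {risk.outlet_ap_percent:.2f} %")
print(f"volume-averaged TCs:        {risk.volume_avg_tcs:.3f} nmol/L")
print(f"normalized regional risk:   {risk.region_risk_normalized}")
```

prints

```
outlet activated platelets: 16.71 %
volume-averaged TCs:        0.383 nmol/L
normalized regional risk:   {0: 0.0, 1: 5.651084828789404e-05, 2: 1.0}
```

Reading: blood leaves this clearance with 16.7% of platelets activated
(up from the 5% inlet background) after 30 s of pseudo-time; clots
accumulate almost exclusively in region 2, the jet-expansion recirculation
downstream of the slit, where shear-activated platelets meet long residence
times — the co-location the model exists to expose.  The run warns that
full steadiness was not reached: dead zones age indefinitely, so the clot
field grows without bound by construction.

The same pipeline is scriptable from the shell:

```bash
thromboflow fixtures --kind gap_jet --out out/gap
thromboflow run --config run.json --outdir out/run
thromboflow metrics --fields out/run
thromboflow validate-config run.json
```

`run` writes legacy-VTK fields, a CSV region table, a JSON risk report and
a log; `metrics` recomputes the report from the saved fields exactly.

## Scope

2D planar, laminar, steady background flow with canonical surrogate
geometries.  Reproducing any real device's absolute metrics (activation
percentages, pressure heads) requires that device's geometry and 3D
turbulence-resolving CFD, which is out of scope by design; what this package
offers is the model's mechanics — thresholds, transport, feedback and risk
metrics — in a form small enough to verify end to end.
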