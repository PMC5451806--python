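# Methods

## Model structure and assumptions

The simulator represents a tumour cord: a cylinder of tissue supplied by a
single axial blood vessel, with cylindrical symmetry so the state varies
only radially and axially. Tissue is split into compartments of edge
`d = 20 μm` (radial shells × axial discs), each identified with one layer
of biological cells; grid refinement is deliberately not a model feature,
because the compartment *is* the biological unit. Each compartment carries
free extracellular (`C1`), free intracellular (`C2`) and bound (`C3`) drug.
Binding is saturable and reversible — rate `k2·C2·(C0 − C3) − k₋2·C3`
against a finite intracellular site concentration `C0` — which for
doxorubicin (DNA intercalation plus other cell binding) is the dominant
interaction. Modelling assumptions worth stating explicitly:

* **No clearance except via the vessel.** Tumour tissue lacks functional
  lymphatics and there are no data to parameterize a generic tissue
  clearance, so drug only leaves by returning to the vessel. This renders
  long-horizon absolute exposures optimistic, which is why the standard
  horizon is 72 h.
* **No interstitial convection.** Elevated interstitial fluid pressure is
  real but unmodelled; transport in tissue is purely diffusive
  (intercellular permeability `k0`, equivalent diffusivity `D = 2·k0·r`).
* **The vessel is one-dimensional and advective** (upwind differencing,
  velocity `λ`), fed at inflow by the PK profile, with no outflow boundary
  condition needed; plasma protein binding is not a separate compartment.
* **Parameters are spatially uniform** within a run; heterogeneous
  vasculature is explored through parameter sweeps and presets, not fields.

Capacity factors: the extracellular balance divides by `δ1·V`, the
intracellular ones by `δ2·V`, with `δ1 = δ/(1+δ)`, `δ2 = 1/(1+δ)` so that
`δ1/δ2 = V1/V2 = δ` (the histological extracellular:intracellular volume
ratio, 0.0625) and `δ1 + δ2 = 1`. The membrane area per compartment is
`a = α·V` using the histological membrane-surface:tissue-volume ratio
`α = 1.94028×10⁵ m⁻¹`; the ratio's defining formula is kept out of the
code because only its numeric value is well determined, and `a = α·V` is
the dimensionally consistent closure that reduces to the well-mixed model's
`a/V` coupling.

## Parameters

All lengths are metres, times seconds, concentrations μM; exposures are
divided by 3600 at the reporting boundary to print μM·h. Baseline values
(`cordsim.TABLE_DEFAULTS`): vessel radius `l = 16 μm`, cord radius
`L_r = 196 μm` (9 shells), cord length `L_z = 500 μm` (25 discs), cell
radius `r = 10 μm`, `k0 = 2.5e-6 m/s`, `k1 = 1.0e-6 m/s`,
`k2 = 0.9e-6 1/(μM·s)`, `k₋2 = 1.4e-5 1/s` (so `β = 140/9 μM`),
`kv = 2.8e-6 m/s`, `C0 = 2600 μM`, `λ = 1e-3 m/s`. Derived values (`β`,
`D`, `δ1`, `δ2`) are always recomputed from the raw inputs and validated,
including the geometric closures `l + n·d = L_r` and `m·d = L_z`. Presets:
`modified_vasculature` (narrow, leaky, slow: `kv→10kv`, `λ→λ/10`, `l→l/2`,
with `L_r` re-closed) and `strong_binding`
(`k2 = 2.95e-2 1/(μM·s)`, `k₋2 = 4.38e-7 1/s`).

The PK profiles share one dose calibration: the tri-exponential constants
(`A…C′`, population averages for doxorubicin) with dose
`D0 = 119.827 μmol` give a closed-form total AUC of
`D0·(A/A′ + B/B′ + C/C′) = 9982.6 μM·s = 2.773 μM·h`, about 0.2% below the
nominal 10⁴ μM·s; the printed dose is treated as authoritative and
AUC-based checks carry a 1% tolerance. The constant profile's conventional
level is 0.926 μM over 3 h; `plateau_for_auc` exists for exact matched-AUC
constructions, which the dose sweep uses so the same-AUC property survives
dose scaling.

## Numerics

The semi-discrete system is stiff (vessel advection relaxes at `λ/d = 50
s⁻¹` while unbinding proceeds at `1.4e-5 s⁻¹`), so integration uses the
implicit BDF method (`scipy.integrate.solve_ivp`) with an explicitly
constructed Jacobian sparsity pattern — nearest-neighbour diffusion,
within-compartment binding, the vessel chain and the wall coupling. Default
tolerances are `rtol = 1e-8`, `atol = 1e-12` μM for concentrations and
`1e-10` μM·s for exposure states; exposures across sweeps span several
orders of magnitude, and a tenfold tolerance tightening changes 72 h
exposures by far less than 0.1% (tested). Exposures `∫C dt` are integrated
as augmented ODE states (`dE/dt = C`) so they inherit solver accuracy
instead of adding quadrature error; the clamped mode can additionally carry
`∫C2·C3 dt` cross terms for the saturation identity. One extra state
integrates the net boundary influx, giving every run a mass audit
(`|content − ∫influx| / peak content`), which sits at round-off (~1e-15)
and is asserted below 1e-6 in the tests. Integration restarts at every
profile breakpoint (infusion ends, repeat administrations, plateau end) to
avoid step-size thrashing at discontinuities. Degenerate inputs are handled
exactly: a zero-dose profile yields identically zero fields, and bound
drug can never exceed `C0` because `dC3/dt < 0` there.

Horizons: 72 h is the standard reporting horizon (the no-clearance
assumption degrades beyond that); the conservation identities — per-shell
`∫C1 dt = ∫C2 dt = AUC` and `β∫C3 dt + ∫C2C3 dt = C0·AUC` — are exact only
as `t → ∞`, so identity checks run the clamped-vessel mode to 1000 h
(≈ 50 unbinding time constants), at which point they hold to ~1e-7. The
clamped quasi-1D mode is realised on a single-disc grid: with the vessel
clamped the axial fluxes vanish identically, so this is exactly the radial
chain, at 1/25th the cost.

## Design choices where the design was open

* **β sweep realization.** `β = k₋2/k2` can be swept by varying either
  rate. Varying `k2` at fixed `k₋2` is the physically meaningful axis:
  lowering β then strengthens the capture rate `k2·C0`, producing the
  far-field optimum (bind too avidly and the drug is captured by the first
  cell layers — at β = 1e-3 the far corner receives ~1 μM·h versus ~285 at
  β = 1). Varying `k₋2` instead leaves capture untouched and shows no
  optimum. A `binding_scale` sweep (both rates jointly) is provided to
  exercise β-equivalence: at low dose and long horizon, (k2, k₋2) and
  (10k2, 10k₋2) give bound exposures equal to ~2e-6 relative; at 72 h the
  equivalence degrades to ~20% because the unbinding timescale (~20 h) is
  commensurate with the horizon — the "very weak unbinding" caveat.
* **Survival weighting.** The threshold survival fraction (a cell dies if
  `∫C3 dt` exceeds the threshold — the Heaviside/infinite-Hill-exponent
  limit of a cell-kill curve) is volume-weighted by default, because an
  outer shell compartment represents proportionally more cells; a
  count-weighted mode (one compartment ≈ one cell) is provided.
* **Spheroid coupling.** The avascular spheroid uses concentric 20 μm
  shells (shell ≈ cell layer), a zero-flux centre by symmetry, and couples
  the outermost shell to the bath concentration `C_v(t)` through the
  spheroid surface with the intercellular permeability `k0`. The choice of
  `k0` (rather than `kv` or instantaneous equilibration) treats the
  spheroid surface as a tissue–tissue interface, which is what
  "surrounded by vascularized tissue" describes; this sub-model is a
  reconstruction and its absolute exposures should be read accordingly.
* **Sample points.** "Near" is the first compartment (centre r = 26 μm,
  z = 10 μm); "far" is the outer downstream corner (r = 186 μm, z = 490 μm
  on the baseline grid), generalized as 10 μm inside the rim and end for
  other grid sizes.

## What the defaults emulate — and what they do not

The baseline parameter set describes doxorubicin around a single,
well-perfused capillary in tumour tissue; the PK profiles are population
averages. Simulated exposures therefore characterize the *transport and
binding physics* under clean conditions: no vessel tortuosity or
intermittent perfusion, no heterogeneous cell packing, no active efflux,
metabolism or extravascular clearance, and a single cord rather than a
vascular network. Passing tests demonstrate internal consistency
(conservation, identities, limits) and the qualitative response surface —
not patient-level predictive accuracy. Absolute exposures at high dose
additionally inherit the no-clearance optimism noted above.

## Known limitations

Upwind vessel advection is first-order (adequate because the vessel
transit time, 0.5 ms, is far below every other timescale). The 72 h
truncation makes schedule comparisons horizon-dependent for slowly
delivering profiles (the repeated-infusion profile has delivered only
~90% of its AUC by then). Exposure fields at doses ≥1000× baseline are
saturation-dominated and near-uniform, so near/far orderings there are not
meaningful beyond a few percent.
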