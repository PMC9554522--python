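# Methods

## Model and assumptions

`bondflow` models well-mixed compartmental networks in which matter moves
by two mechanisms: thermodynamic mass-action reactions and advection by a
prescribed incompressible fluid flow. The energy bookkeeping follows the
bond-graph convention: every species store has a chemical potential
`μ = RT ln(K x/V)`, every edge carries a molar flow, and the product of the
two is a power.

Key assumptions, inherited from the modelling framework the package
implements:

- **One-way hydro-chemical coupling.** The hydraulic flow `Q(t)` strongly
  determines the chemical transport, but the chemical state has negligible
  effect back on the pressures and flows. Flows are therefore *inputs*
  (`FlowProfile` objects: constant, step, sinusoid, piecewise), never
  states; pressures appear only as the diagnostic `ΔP = c Δμ`.
- **Exact upwind switch.** The advective flux is `Q c_up` for `Q > 0`,
  `Q c_down` for `Q < 0`, exactly 0 at `Q = 0`. The switch is a kink, not a
  discontinuity, in the right-hand side; the implicit integrator handles
  it without event detection for flows that cross zero at isolated times.
  An optional `smoothing` width (tanh blend, default off) exists for flows
  that chatter around zero.
- **Incompressible, rigid compartments.** Volumes are constants.
- **Chemostats as boundaries.** A chemostat species is removed from the
  state; its amount is read from a time profile. This realises both
  held-concentration boundaries and on/off administration protocols.

Generalised advection between stores of different capacity uses the edge's
reference constant `K_ref` (the carrying fluid's constant): the flux for
positive flow is `Q · (K_up c_up) / K_ref`, which reduces to `Q c_up` for
a homogeneous edge (`K_ref = K_up`, the default) and to
`Q c_pool / λ` for a tissue pool with partition coefficient `λ`
discharging into blood.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `RT` | energy/mol | 1 | toy models are normalised; only potentials/powers scale with it |
| species `K` | 1/concentration | 1 | unit parameters in the worked examples |
| `λ` (unified edge) | – | 0 | 0 = advection, 1 = transformation |
| unified `κ₀` | flow/activity | `None` = flow-matched `Q/K` | compares the two mechanisms at equal exchange rate; a fixed value decouples the reactive variant from the flow |
| pipe `N` | – | 5 | published lump count for the circulation example; `N=100` used for the delay-convergence measurement |
| solver | – | BDF, rtol 1e-8, atol 1e-10 | the PK model mixes volumes over five orders of magnitude and is stiff |
| PK: `V_A`, `V_V`, `Q` | l, l, l/min | 1.4, 4.0, 6.48 | printed whole-body values |
| PK: `κ_av` | 1/min | `100 Q` | unprinted; chosen so alveolar blood tracks lung air within ~1% at steady inspiration (equilibration assumption); configurable |
| PK: alveolar blood volume | l | 0.1 | unprinted; physiological order for pulmonary capillary blood; only sets a ~1 s mixing lag |

The seven-pool pharmacokinetic table (volume, blood-flow fraction, tissue:
blood partition coefficient per pool) ships as
`src/bondflow/data/mapleson_pools.csv`. Pool stores use the amount-form
constant `K_p = 1/(λ_p V_p)`; the zero-volume shunt is realised as its
arterial pipe spliced directly into its venous pipe with no store. The
printed brain/kidney volumes (0.0007 l) are taken as given.

## Worked-example conventions

- **Orifice system**: unit volumes and constants, `κ₁ = κ₂ = 1`,
  chemostats `x_A = 2`, `x_B = 1`; default drive steps the flow from 2 to
  10 at `t = 10`. Initial free amounts default to 1 (not printed in the
  source material; steady states and delays, which the acceptance checks
  target, are initial-condition independent). The transformation variant
  is *flow-matched* (`κ₀ = Q/K`) — this is what makes it respond to flow
  steps and reach the equal-split steady state ≈ 1.5 at `Q = 10`.
- **Circulation**: unit parameters, transport pipes of volume 5 with
  `N = 5` lumps, ligand chemostats `x_A1 = 2`, `x_A2 = 1`. Pipe lumps are
  initialised at carrier concentration 1, matching the unit initial
  amounts of every other store; under this initialisation the pipe variant
  shares its steady state with the orifice variant and the ligand-release
  flux is delayed by ≈ τ = 5 (measured 4.99 by 50%-crossing difference).
  With empty initial pipes the conserved carrier is diluted into the pipe
  volume and the variants no longer share steady states.
- **Delay metric**: the transport delay of a monotone step-like response is
  its first 50%-crossing of the net change, linearly interpolated between
  samples. Under time-varying (sinusoidal) flow an instantaneous delay is
  undefined; the oscillation period of the output flux is checked instead.
- **Pharmacokinetics**: inspired concentration 1 for `t < t_on = 2` min,
  then 0; all outputs are ratios to the inspired concentration. The
  arterial delay quoted (`V_A/Q ≈ 0.216 min`) is analytic; the measured
  half-rise lag of a tissue pool additionally contains that pool's own
  first-order lag `λ_p V_p / (δ_p Q)` (≈ 0.18 min for the kidney), so
  half-rise lags exceed the bare transit time.

## Numerics

- Default integration: `scipy.integrate.solve_ivp` with BDF,
  rtol 1e-8 / atol 1e-10. A trajectory dipping below `−100·atol` aborts
  with an error suggesting tighter tolerances; smaller undershoots are
  floored to 0 in reported outputs.
- Steady states: growing-horizon implicit integration (chunks of 50, ×4 up
  to 2000 time units) followed by a damped-Newton (`scipy.optimize.root`,
  hybr) polish; accepted only if the derivative max-norm is below 1e-10.
  Requires an autonomous model (constant flows/profiles/rates).
- Chemical potential at zero concentration: concentrations are clamped at
  1e-30 inside `chemical_potential`, giving a finite large-negative
  sentinel (≈ −69·RT) instead of −∞. All fluxes are evaluated in
  concentration form and are regular at `c = 0`; the potential is purely a
  diagnostic.
- The analytic pipe step response uses the regularized lower incomplete
  gamma function; it is cross-checked against direct ODE integration of
  the lump chain for `N ∈ {1, 2, 5, 10}` at 2e-6 absolute tolerance.
- Problem sizes: the delay-convergence measurement uses a 100-lump pipe to
  `t = 10` (201-dimensional oracle runs are unnecessary — the closed form
  is exact); the PK model has 77 states (7 pools × 10 pipe lumps + pools +
  alveolar blood) integrated over 20 min of model time.

## Synthetic fixtures

`generate_random_network(seed, …)` emulates small reaction-transport
networks: log-normal volumes and species constants (σ = 0.3 around 1),
uniform rate constants in [0.5, 2], a connectivity chain plus random extra
edges, unimolecular reactions only (so closed models conserve total
moles exactly — the conservation oracle used in tests), constant positive
flows. It is deterministic per seed. It does not emulate: multi-molecular
stoichiometry, flow reversal, time-varying drives, or wide volume
separations — those regimes are covered by the purpose-built example
models instead, so the random-network tests certify assembly correctness,
not stiff-regime robustness.

## Known limitations

- No PDE/3-D transport, no dispersion (Taylor/shear) or Womersley effects;
  a pipe is a pure lag chain.
- No hydraulic state dynamics: pressures and flows are never solved for.
- Flow reversal is handled pointwise by the upwind switch; rapidly
  oscillating flows through long pipes are untested territory (the
  optional smoothing exists for this).
- The pharmacokinetic model inherits two unprinted constants (alveolar
  exchange rate, alveolar blood volume) as documented assumptions; its
  trajectories are therefore validated qualitatively (rise/fall around the
  administration window, fat accumulation, flow balance, delay bracketing),
  not pointwise.
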