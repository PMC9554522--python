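# bondflow

Energy-based modelling of **advection** — the transport of a dissolved
substance by bulk fluid flow — alongside chemical **transformation**, in the
bond-graph style used for physiological network models.

Physiological models (blood circulation, gas exchange, drug uptake) need two
different kinds of molar flow in one framework: mass-action reaction fluxes
that *transform* one species into another, and advective fluxes that *carry*
a species from place to place with the fluid. `bondflow` provides the
component library and ODE assembly for both, with consistent energy
(power) accounting, plus three ready-made model families: a two-compartment
orifice system contrasting advection with transformation, a circulatory
binding/unbinding cycle, and a whole-body compartmental pharmacokinetic
model of anaesthetic-gas (N₂O) uptake.

## The model

Each species store carries a chemical potential

```
μ = RT ln(K c),        c = x / V
```

with amount `x`, compartment volume `V` and species thermodynamic constant
`K` (so the *activity* is `a = K c`). Three kinds of edges move matter:

- **Reaction (Re)** — thermodynamic mass action,
  `v = κ (∏ₛ (Kₛ cₛ)^ν − ∏ₚ (Kₚ cₚ)^ν)`; zero exactly at equilibrium.
- **Advective resistor (RA)** — flow-modulated transport with an exact
  upwind switch: `f = Q c_up` if `Q > 0`, `Q c_down` if `Q < 0`, `0` if
  `Q = 0`. The hydraulic flow `Q(t)` is a prescribed input (the coupling
  from chemistry back to hydraulics is neglected). Its dissipation
  `P_RA = f Δμ` may be negative, and the pressure-drop diagnostic is
  `ΔP = c Δμ` with `Q ΔP = f Δμ`.
- **Unified element** — `v = κ K (c₁ − λ c₂)` with
  `κ = λ κ₀ + (1 − λ) Q/K`: `λ = 0` is pure advection, `λ = 1` pure
  transformation, so the two mechanisms can be compared within one model.

A **pipe** is a chain of `N` equal well-mixed lumps joined by advective
resistors; at constant flow its step response is the Erlang-N CDF
`c_N/c₀ = P(N, N t/τ)` with transit time `τ = V/Q`, approaching a pure
delay as `N → ∞`.

Networks assemble into `ẋ = S v` over the non-chemostat species
(chemostats are boundary species held at prescribed amounts) and integrate
with a stiff implicit solver.

## Worked example

The two-compartment system A ⇌ C₁ → C₂ ⇌ B (A, B chemostatted at
concentrations 2 and 1, unit parameters) behaves qualitatively differently
depending on whether the central connection transports or transforms:

```python
import bondflow as bf

flow = bf.FlowProfile.constant(10.0)
adv = bf.steady_state(bf.build_orifice_model(bf.OrificeScenario(lam=0.0, flow=flow)))
rxn = bf.steady_state(bf.build_orifice_model(bf.OrificeScenario(lam=1.0, flow=flow)))
print({k: round(v, 4) for k, v in adv.items()})
print({k: round(v, 4) for k, v in rxn.items()})
```

prints

```
{'C1': 0.1818, 'C2': 2.8182}
{'C1': 1.5238, 'C2': 1.4762}
```

Advection (`lam=0`) at strong flow empties the upstream store and piles the
boundary total (≈ 3) into the downstream one; transformation (`lam=1`)
equalises the two stores at ≈ 1.5. Both satisfy the exact sum rule
`c₁ + c₂ = (K_A c_A + K_B c_B)/K_C = 3`.

A pipe delays rather than just relaxes:

```bash
$ bondflow demo pipe --n-lumps 20 --out pipe.csv
wrote pipe.csv; outlet half-crossing delay = 4.9169 (tau = V/Q = 5.0000)
```

and the pharmacokinetic model (litres/minutes, parameters from the
published seven-pool table, cardiac output 6.48 l/min) writes normalised
N₂O concentration curves for every compartment:

```bash
$ bondflow pk --t-on 2 --t-end 20 --out pk.csv
```

The arterial transit delay is `V_A/Q = 1.4/6.48 ≈ 0.216 min` (≈ 13 s) and
is visible as the lag of every tissue pool behind the alveolar blood; fat
(partition coefficient 1.4, 12.2 l) accumulates the most gas and releases
it slowest.

Models can also be described as JSON documents (see
`src/bondflow/examples/orifice_lambda0.json`) and run with
`bondflow simulate model.json`.

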