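"""Prebuilt coupled advection/transformation models and their closed forms.

Two families of worked examples:

* the *orifice* system: species A is transformed to C in an upstream
  compartment, C is carried (or transformed) into a downstream compartment,
  and there transformed to B, with A and B held as chemostats.  The central
  connection is the unified advection/transformation element, so one model
  covers both the advective (``lam = 0``) and reactive (``lam = 1``)
  variants, or a lumped pipe in place of the orifice.

* the *circulation* system: a binding/unbinding cycle split over two
  locations (A1 + E1 <-> C1 at location 1, C2 <-> A2 + E2 at location 2)
  with the bound complex C and free enzyme E carried between locations by
  four transport paths (forward/reverse for each carrier), realised as
  orifices, pipes, or — when the forward and reverse orifices are
  identical — an equivalent pair of reaction elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .components import (
    AdvectionEdge,
    FlowProfile,
    ReactionEdge,
    SpeciesState,
    UnifiedEdge,
)
from .errors import ModelValidationError
from .network import NetworkModel, simulate
from .pipe import Pipe, half_crossing_time

__all__ = [
    "OrificeScenario",
    "CirculationScenario",
    "build_orifice_model",
    "build_circulation_model",
    "steady_state_large_flow",
    "compare_connections",
]


def _default_step_flow() -> FlowProfile:
    # flow stepped from 2 to 10 at t = 10, the drive of the orifice example
    return FlowProfile.step(2.0, 10.0, 10.0)


@dataclass
class OrificeScenario:
    """Parameters of the two-compartment orifice example.

    ``lam`` selects the central connection: 0 = advection through an
    orifice, 1 = unimolecular transformation, intermediate values blend the
    two.  ``kappa0 = None`` makes the reactive limit *flow-matched*: its
    rate constant tracks the advective equivalent ``Q / K_C``, so the two
    variants are compared at equal exchange rate and both respond to flow
    steps.  Setting ``pipe_V`` replaces the orifice (``lam = 0`` only) by a
    lumped pipe of that total volume with ``pipe_N`` lumps.
    """

    lam: float = 0.0
    kappa1: float = 1.0
    kappa2: float = 1.0
    kappa0: float | None = None
    K_A: float = 1.0
    K_B: float = 1.0
    K_C: float = 1.0
    cA: float = 2.0
    cB: float = 1.0
    V1: float = 1.0
    V2: float = 1.0
    x1_0: float = 1.0
    x2_0: float = 1.0
    flow: FlowProfile = field(default_factory=_default_step_flow)
    pipe_V: float | None = None
    pipe_N: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if self.pipe_V is not None and self.lam != 0.0:
            raise ValueError("a pipe connection is purely advective; requires lam = 0")


def build_orifice_model(scenario: OrificeScenario) -> NetworkModel:
    """Assemble the three-flux network of the orifice example.

    Fluxes: ``v1 = kappa1 (K_A cA - K_C c1)`` upstream,
    the unified central flux between C1 and C2, and
    ``v2 = kappa2 (K_C c2 - K_B cB)`` downstream; chemostats A and B close
    the boundary.  State derivatives are ``x1' = v1 - v`` and
    ``x2' = v - v2``.
    """
    s = scenario
    species = [
        SpeciesState("A", x0=s.cA, V=1.0, K=s.K_A, chemostat=True),
        SpeciesState("C1", x0=s.x1_0, V=s.V1, K=s.K_C),
        SpeciesState("C2", x0=s.x2_0, V=s.V2, K=s.K_C),
        SpeciesState("B", x0=s.cB, V=1.0, K=s.K_B, chemostat=True),
    ]
    reactions = [
        ReactionEdge("r1", s.kappa1, [("A", 1.0)], [("C1", 1.0)]),
        ReactionEdge("r2", s.kappa2, [("C2", 1.0)], [("B", 1.0)]),
    ]
    unified: list[UnifiedEdge] = []
    pipes: list[Pipe] = []
    if s.pipe_V is not None:
        pipes.append(
            Pipe(
                name="r",
                V=s.pipe_V,
                N=s.pipe_N,
                flow=s.flow,
                K=s.K_C,
                inlet="C1",
                outlet="C2",
            )
        )
    else:
        unified.append(
            UnifiedEdge("r", "C1", "C2", lam=s.lam, flow=s.flow, kappa0=s.kappa0, K=s.K_C)
        )
    return NetworkModel(
        species=species,
        reactions=reactions,
        unified=unified,
        pipes=pipes,
        name=f"orifice-lam{s.lam:g}" + ("-pipe" if s.pipe_V is not None else ""),
    )


def steady_state_large_flow(
    lam: float,
    K_A: float = 1.0,
    cA: float = 2.0,
    K_B: float = 1.0,
    cB: float = 1.0,
    K_C: float = 1.0,
) -> tuple[float, float]:
    """Large-flow asymptotic steady concentrations ``(c1, c2)``.

    For equal boundary rate constants and flow large compared with them,
    ``c1 ~ lam c2`` and ``c2 ~ (K_A cA + K_B cB) / ((1 + lam) K_C)``: pure
    advection (``lam = 0``) empties the upstream store into the downstream
    one, while transformation (``lam = 1``) equalises the two.
    """
    if K_C <= 0.0:
        raise ValueError("K_C must be positive")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    c2 = (K_A * cA + K_B * cB) / ((1.0 + lam) * K_C)
    return lam * c2, c2


def _constant_one() -> FlowProfile:
    return FlowProfile.constant(1.0)


@dataclass
class CirculationScenario:
    """Parameters of the split binding/unbinding circulation example.

    The bound complex C travels location 1 -> 2 via path CF and back via
    CR; the free enzyme E travels 2 -> 1 via EF and back via ER.  Ligand
    amounts are chemostatted (``x_A1``, ``x_A2``).  ``connection`` picks
    orifices, pipes (volume ``pipe_V``, ``pipe_N`` lumps per path) or the
    reaction-element replacement of each identical forward/reverse orifice
    pair.
    """

    connection: str = "orifice"  # orifice | pipe | re_equivalent
    kappa1: float = 1.0
    kappa2: float = 1.0
    K_A: float = 1.0
    K_E: float = 1.0
    K_C: float = 1.0
    x_A1: float = 2.0
    x_A2: float = 1.0
    x_E1: float = 1.0
    x_E2: float = 1.0
    x_C1: float = 1.0
    x_C2: float = 1.0
    flow_cf: FlowProfile = field(default_factory=_constant_one)
    flow_cr: FlowProfile = field(default_factory=_constant_one)
    flow_ef: FlowProfile = field(default_factory=_constant_one)
    flow_er: FlowProfile = field(default_factory=_constant_one)
    pipe_V: float = 5.0
    pipe_N: int = 5
    #: initial carrier concentration inside the pipes.  The default 1 matches
    #: the unit initial amounts of the free stores; it also gives the pipe
    #: variant the same conserved enzyme-per-volume as the orifice variant,
    #: so the two share steady states and differ by a pure transport delay.
    pipe_c0: float = 1.0

    def __post_init__(self) -> None:
        if self.connection not in {"orifice", "pipe", "re_equivalent"}:
            raise ValueError(f"unknown connection {self.connection!r}")


def build_circulation_model(scenario: CirculationScenario) -> NetworkModel:
    """Assemble the split binding cycle joined by four transport paths."""
    s = scenario
    species = [
        SpeciesState("A1", x0=s.x_A1, K=s.K_A, chemostat=True),
        SpeciesState("A2", x0=s.x_A2, K=s.K_A, chemostat=True),
        SpeciesState("E1", x0=s.x_E1, K=s.K_E),
        SpeciesState("E2", x0=s.x_E2, K=s.K_E),
        SpeciesState("C1", x0=s.x_C1, K=s.K_C),
        SpeciesState("C2", x0=s.x_C2, K=s.K_C),
    ]
    reactions = [
        ReactionEdge("r1", s.kappa1, [("A1", 1.0), ("E1", 1.0)], [("C1", 1.0)]),
        ReactionEdge("r2", s.kappa2, [("C2", 1.0)], [("A2", 1.0), ("E2", 1.0)]),
    ]
    advections: list[AdvectionEdge] = []
    pipes: list[Pipe] = []
    if s.connection == "orifice":
        advections = [
            AdvectionEdge("CF", "C1", "C2", s.flow_cf),
            AdvectionEdge("CR", "C2", "C1", s.flow_cr),
            AdvectionEdge("EF", "E2", "E1", s.flow_ef),
            AdvectionEdge("ER", "E1", "E2", s.flow_er),
        ]
    elif s.connection == "pipe":
        x0 = s.pipe_c0 * s.pipe_V / s.pipe_N  # lump amount at concentration pipe_c0
        pipes = [
            Pipe("CF", V=s.pipe_V, N=s.pipe_N, flow=s.flow_cf, K=s.K_C, inlet="C1", outlet="C2", x0=x0),
            Pipe("CR", V=s.pipe_V, N=s.pipe_N, flow=s.flow_cr, K=s.K_C, inlet="C2", outlet="C1", x0=x0),
            Pipe("EF", V=s.pipe_V, N=s.pipe_N, flow=s.flow_ef, K=s.K_E, inlet="E2", outlet="E1", x0=x0),
            Pipe("ER", V=s.pipe_V, N=s.pipe_N, flow=s.flow_er, K=s.K_E, inlet="E1", outlet="E2", x0=x0),
        ]
    else:  # re_equivalent
        if s.flow_cf != s.flow_cr or s.flow_ef != s.flow_er:
            raise ModelValidationError(
                "the reaction-element replacement of an orifice pair requires "
                "identical forward and reverse flows"
            )
        # a pair of identical opposed orifices carrying Q gives a net flux
        # Q (c1 - c2) = kappa K (c1 - c2) with kappa = Q / K
        kappa_c = _scaled_rate(s.flow_cf, 1.0 / s.K_C)
        kappa_e = _scaled_rate(s.flow_ef, 1.0 / s.K_E)
        reactions.append(ReactionEdge("Cx", kappa_c, [("C1", 1.0)], [("C2", 1.0)]))
        reactions.append(ReactionEdge("Ex", kappa_e, [("E2", 1.0)], [("E1", 1.0)]))
    return NetworkModel(
        species=species,
        reactions=reactions,
        advections=advections,
        pipes=pipes,
        name=f"circulation-{s.connection}",
    )


def _scaled_rate(flow: FlowProfile, factor: float):
    """A rate constant tracking ``factor * Q(t)``; constant flows stay plain floats."""
    if flow.is_constant:
        return factor * flow(0.0)
    return lambda t: factor * flow(t)


def compare_connections(
    orifice: CirculationScenario | None = None,
    pipe: CirculationScenario | None = None,
    t_end: float = 40.0,
    n_samples: int = 1601,
    **solver_opts,
) -> dict:
    """Aligned ligand-release fluxes of the orifice and pipe circulations.

    Simulates both scenarios (the pipe one defaults to the orifice scenario
    with the connection swapped), tabulates the flux of the unbinding
    reaction — the rate at which ligand is delivered to location 2 — and
    measures the transport delay as the difference of the two 50%-crossing
    times.
    """
    if orifice is None:
        orifice = CirculationScenario(connection="orifice")
    if pipe is None:
        pipe = replace(orifice, connection="pipe")
    res_o = simulate(build_orifice_or_circulation(orifice), t_end, n_samples=n_samples, **solver_opts)
    res_p = simulate(build_orifice_or_circulation(pipe), t_end, n_samples=n_samples, **solver_opts)
    table = pd.DataFrame(
        {
            "time": res_o.times,
            "flux_orifice": np.asarray(res_o.fluxes["r2"]),
            "flux_pipe": np.asarray(res_p.fluxes["r2"]),
        }
    )
    delay_o = half_crossing_time(res_o.times, table["flux_orifice"].to_numpy())
    delay_p = half_crossing_time(res_p.times, table["flux_pipe"].to_numpy())
    return {
        "table": table,
        "delay_orifice": delay_o,
        "delay_pipe": delay_p,
        "delay_difference": delay_p - delay_o,
        "results": (res_o, res_p),
    }


def build_orifice_or_circulation(scenario) -> NetworkModel:
    """Dispatch a scenario object to its builder."""
    if isinstance(scenario, OrificeScenario):
        return build_orifice_model(scenario)
    if isinstance(scenario, CirculationScenario):
        return build_circulation_model(scenario)
    raise TypeError(f"not a scenario: {type(scenario).__name__}")
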