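"""Constitutive relations of the individual energy-based components.

The building blocks follow the bond-graph convention for biochemical
networks: a species store (``Ce``) carries a logarithmic chemical potential
``mu = RT ln(K c)``, a thermodynamic reaction element (``Re``) carries a
mass-action flux expressed as a difference of activities, and the advective
resistor (``RA``) carries a molar flow ``f = Q c_upstream`` modulated by a
prescribed hydraulic flow ``Q`` with an exact upwind switch on the sign of
``Q``.  All functions here are pure; the network assembly module wires them
into ODE right-hand sides.

Units are not enforced: the toy models use normalised quantities (RT = 1,
unit species constants), while the pharmacokinetic module uses litres and
minutes.  The species constant ``K`` is on a reciprocal-concentration scale
so that the *activity* ``a = K c`` is dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "CONC_FLOOR",
    "FlowProfile",
    "SpeciesState",
    "ReactionEdge",
    "AdvectionEdge",
    "UnifiedEdge",
    "PowerRecord",
    "chemical_potential",
    "advective_flux",
    "mass_action_flux",
    "unified_flux",
    "advective_power",
    "pressure_drop",
]

#: Concentrations below this floor are clamped before taking the logarithm in
#: :func:`chemical_potential`.  Advection naturally drives compartments to
#: zero concentration; the potential is then reported as the large negative
#: sentinel ``RT * ln(K * CONC_FLOOR)`` instead of ``-inf``.  Fluxes are
#: always evaluated in concentration form and are regular at c = 0.
CONC_FLOOR = 1e-30


def chemical_potential(x: float, V: float, K: float, RT: float = 1.0) -> float:
    """Chemical potential ``mu = RT ln(K x / V)`` of a well-mixed store.

    Parameters
    ----------
    x : amount of the species (mol, or dimensionless in normalised models).
    V : compartment volume, > 0.
    K : species thermodynamic constant (reciprocal-concentration scale), > 0.
    RT : thermodynamic scale constant, > 0 (1 in normalised models).

    For ``x = 0`` the concentration is clamped at :data:`CONC_FLOOR` and the
    documented large-negative sentinel ``RT * ln(K * CONC_FLOOR)`` is
    returned; the potential is a diagnostic quantity and never enters flux
    computations in that limit.
    """
    if V <= 0.0:
        raise ValueError(f"volume must be positive, got {V}")
    if K <= 0.0:
        raise ValueError(f"species constant must be positive, got {K}")
    if RT <= 0.0:
        raise ValueError(f"RT must be positive, got {RT}")
    if x < 0.0:
        raise ValueError(f"amount must be non-negative, got {x}")
    c = max(x / V, CONC_FLOOR)
    return RT * math.log(K * c)


def advective_flux(
    Q: float, c_up: float, c_down: float, smoothing: float = 0.0
) -> float:
    """Advective molar flow through an orifice (the RA constitutive relation).

    ``f = Q * c_up`` for ``Q > 0``, ``Q * c_down`` for ``Q < 0`` and exactly
    0 for ``Q = 0``: the transported concentration is always the upstream
    one (upwinding), so the flux direction follows the sign of the hydraulic
    flow and advection can never drive a concentration negative.

    ``smoothing`` > 0 replaces the exact switch by a ``tanh(Q/smoothing)``
    blend of the two branches; it is off by default and only intended for
    pathological flow profiles that chatter around zero.
    """
    if c_up < 0.0 or c_down < 0.0:
        raise ValueError("concentrations must be non-negative")
    if smoothing > 0.0:
        w = 0.5 * (1.0 + math.tanh(Q / smoothing))
        return Q * (w * c_up + (1.0 - w) * c_down)
    if Q > 0.0:
        return Q * c_up
    if Q < 0.0:
        return Q * c_down
    return 0.0


def mass_action_flux(
    reaction: "ReactionEdge",
    concentrations: Mapping[str, float],
    constants: Mapping[str, float] | None = None,
    t: float = 0.0,
) -> float:
    """Net flux of a thermodynamic mass-action reaction.

    ``v = kappa * (prod_s (K_s c_s)^nu_s - prod_p (K_p c_p)^nu_p)`` where the
    products run over substrates and products with their stoichiometric
    coefficients.  The flux vanishes exactly at thermodynamic equilibrium
    (equal activity products) and its sign gives the net forward direction.

    ``constants`` maps species names to their thermodynamic constants
    ``K``; missing species default to ``K = 1``.
    """
    constants = constants or {}
    kappa = _rate_value(reaction.kappa, t)
    if kappa < 0.0:
        raise ValueError("rate constant must be non-negative")
    fwd = 1.0
    for name, nu in reaction.substrates:
        fwd *= (constants.get(name, 1.0) * concentrations[name]) ** nu
    rev = 1.0
    for name, nu in reaction.products:
        rev *= (constants.get(name, 1.0) * concentrations[name]) ** nu
    return kappa * (fwd - rev)


def unified_flux(
    lam: float, kappa0: float, Q: float, K: float, c1: float, c2: float
) -> float:
    """Flux of the unified advection/transformation element.

    ``v = kappa * K * (c1 - lam * c2)`` with
    ``kappa = lam * kappa0 + (1 - lam) * kappa'`` and ``kappa' = Q / K``.

    ``lam = 0`` recovers pure advection ``f = Q c1`` (positive flow), and
    ``lam = 1`` recovers the unimolecular mass-action flux
    ``kappa0 * K * (c1 - c2)``.  Intermediate values interpolate between
    transport and transformation behaviour.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"mixing parameter must lie in [0, 1], got {lam}")
    if K <= 0.0:
        raise ValueError(f"species constant must be positive, got {K}")
    kprime = Q / K
    kappa = lam * kappa0 + (1.0 - lam) * kprime
    return kappa * K * (c1 - lam * c2)


def advective_power(f: float, mu_up: float, mu_down: float) -> float:
    """Power dissipated by an advective resistor: ``P_RA = f (mu_up - mu_down)``.

    Because the transport is driven by the hydraulic flow rather than by the
    chemical potential gradient, this power may be negative, unlike the
    dissipation of a reaction element.
    """
    return f * (mu_up - mu_down)


def pressure_drop(c: float, dmu: float) -> float:
    """Pressure-drop diagnostic of hydrochemical transduction: ``dP = c dmu``.

    With ``f = Q c`` the hydraulic power ``Q dP`` equals the chemical power
    ``f dmu``; the transduction itself is lossless.
    """
    if c < 0.0:
        raise ValueError("concentration must be non-negative")
    return c * dmu


# --------------------------------------------------------------------------
# component data types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FlowProfile:
    """A prescribed scalar function of time.

    Used both for hydraulic flows Q(t) (the hydraulic-to-chemical coupling is
    one-way, so flows are inputs rather than states) and for chemostat
    amount protocols.  Supported kinds:

    - ``constant``: ``Q0``
    - ``step``: ``Q0`` for ``t < t_step``, ``Q1`` afterwards
    - ``sinusoid``: ``Q0 + amplitude * sin(2 pi t / period)``
    - ``piecewise``: zero-order hold over ``times`` / ``values``
    """

    kind: str
    params: tuple[tuple[str, object], ...]

    # -- constructors ------------------------------------------------------
    @classmethod
    def constant(cls, Q0: float) -> "FlowProfile":
        return cls("constant", (("Q0", float(Q0)),))

    @classmethod
    def step(cls, Q0: float, Q1: float, t_step: float) -> "FlowProfile":
        return cls(
            "step", (("Q0", float(Q0)), ("Q1", float(Q1)), ("t_step", float(t_step)))
        )

    @classmethod
    def sinusoid(cls, Q0: float, amplitude: float, period: float) -> "FlowProfile":
        if period <= 0:
            raise ValueError("period must be positive")
        return cls(
            "sinusoid",
            (
                ("Q0", float(Q0)),
                ("amplitude", float(amplitude)),
                ("period", float(period)),
            ),
        )

    @classmethod
    def piecewise(
        cls, times: Sequence[float], values: Sequence[float]
    ) -> "FlowProfile":
        times = tuple(float(t) for t in times)
        values = tuple(float(v) for v in values)
        if len(times) != len(values) or not times:
            raise ValueError("times and values must be equal-length, non-empty")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        return cls("piecewise", (("times", times), ("values", values)))

    # -- evaluation --------------------------------------------------------
    @property
    def p(self) -> dict:
        return dict(self.params)

    def __call__(self, t):
        p = self.p
        if self.kind == "constant":
            return p["Q0"] if np.isscalar(t) else np.full_like(np.asarray(t, float), p["Q0"])
        if self.kind == "step":
            return np.where(np.asarray(t) < p["t_step"], p["Q0"], p["Q1"])[()]
        if self.kind == "sinusoid":
            return p["Q0"] + p["amplitude"] * np.sin(
                2.0 * np.pi * np.asarray(t) / p["period"]
            )[()]
        if self.kind == "piecewise":
            idx = np.clip(
                np.searchsorted(p["times"], np.asarray(t), side="right") - 1, 0, None
            )
            return np.asarray(p["values"])[idx][()]
        raise ValueError(f"unknown profile kind {self.kind!r}")

    @property
    def is_constant(self) -> bool:
        if self.kind == "constant":
            return True
        if self.kind == "sinusoid":
            return self.p["amplitude"] == 0.0
        if self.kind == "piecewise":
            return len(set(self.p["values"])) == 1
        return False


@dataclass
class SpeciesState:
    """A chemical species stored in a well-mixed compartment (a Ce store).

    ``K`` is the species thermodynamic constant on the reciprocal-
    concentration scale (exp of the standard potential over RT); the
    activity entering reaction fluxes is ``K * x / V``.  A chemostat species
    is held at a prescribed amount (``profile``, defaulting to constant
    ``x0``), acts as a boundary condition and is excluded from the
    integrated state.
    """

    name: str
    x0: float = 1.0
    V: float = 1.0
    K: float = 1.0
    chemostat: bool = False
    profile: FlowProfile | Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.V <= 0.0:
            raise ValueError(f"species {self.name!r}: volume must be positive")
        if self.K <= 0.0:
            raise ValueError(f"species {self.name!r}: K must be positive")
        if self.x0 < 0.0:
            raise ValueError(f"species {self.name!r}: amount must be non-negative")

    def held_amount(self, t):
        """Amount of a chemostat species at time ``t``."""
        if self.profile is None:
            return self.x0
        return self.profile(t)


RateLike = "float | FlowProfile | Callable[[float], float]"


def _rate_value(kappa, t: float) -> float:
    """Evaluate a rate constant that may be a number or a function of time."""
    if callable(kappa):
        return float(kappa(t))
    return float(kappa)


@dataclass
class ReactionEdge:
    """A thermodynamic mass-action reaction (Re element).

    ``substrates`` and ``products`` are lists of ``(species name,
    stoichiometric coefficient)``.  The rate constant ``kappa`` may be a
    time-varying profile, which is how an identical pair of forward/reverse
    orifices is represented as a single reaction element.
    """

    name: str
    kappa: object  # float | FlowProfile | callable(t)
    substrates: list[tuple[str, float]]
    products: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if not callable(self.kappa) and float(self.kappa) < 0.0:
            raise ValueError(f"reaction {self.name!r}: kappa must be >= 0")
        if not self.substrates or not self.products:
            raise ValueError(
                f"reaction {self.name!r}: needs at least one substrate and one product"
            )

    @property
    def species(self) -> list[str]:
        return [n for n, _ in self.substrates] + [n for n, _ in self.products]


@dataclass
class AdvectionEdge:
    """The advective resistor (RA element) between two species stores.

    Flux for positive flow is ``Q * a_up / K_ref`` where ``a_up = K_up c_up``
    is the upstream activity and ``K_ref`` is the constant of the carrying
    fluid (defaults to the upwind species' own constant, reducing to the
    plain ``f = Q c_up``).  A non-default ``K_ref`` expresses transport of a
    species between stores of different effective capacity, e.g. a tissue
    pool with a partition coefficient discharging into blood.
    """

    name: str
    upstream: str
    downstream: str
    flow: FlowProfile
    K_ref: float | None = None
    smoothing: float = 0.0

    def __post_init__(self) -> None:
        if self.K_ref is not None and self.K_ref <= 0.0:
            raise ValueError(f"advection {self.name!r}: K_ref must be positive")

    @property
    def species(self) -> list[str]:
        return [self.upstream, self.downstream]


@dataclass
class UnifiedEdge:
    """Unified advection/transformation element with mixing parameter ``lam``.

    ``lam = 0`` is a pure advective resistor driven by ``flow``; ``lam = 1``
    is a unimolecular reaction with rate constant ``kappa0``.  ``kappa0 =
    None`` means *flow-matched*: the rate constant tracks the advective
    equivalent ``kappa' = Q(t) / K``, so the two limits are compared at
    equal exchange rate.  Assumes non-negative flow.
    """

    name: str
    upstream: str
    downstream: str
    lam: float
    flow: FlowProfile
    kappa0: float | None = None
    K: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"unified edge {self.name!r}: lam must lie in [0, 1]")
        if self.K <= 0.0:
            raise ValueError(f"unified edge {self.name!r}: K must be positive")

    @property
    def species(self) -> list[str]:
        return [self.upstream, self.downstream]


@dataclass
class PowerRecord:
    """Per-advection-edge power and pressure diagnostics along a trajectory.

    ``table`` has one column per edge and quantity:
    ``<edge>.P_RA`` (advective dissipation ``f * dmu``, sign-unrestricted),
    ``<edge>.dP`` (pressure-drop diagnostic ``c_upwind * dmu``) and
    ``<edge>.P_TF`` (transduced power ``Q * dP``).
    """

    RT: float
    table: "object" = None  # pandas.DataFrame; typed loosely to keep numpy-only imports

    def __getitem__(self, key):
        return self.table[key]
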