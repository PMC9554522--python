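"""Assembly and integration of advection-reaction networks.

A :class:`NetworkModel` collects species stores, reaction elements,
advective resistors, unified edges and lumped pipes.  Assembly produces the
ODE ``xdot = S v`` over the non-chemostat amounts: each species' derivative
is inflows minus outflows summed over incident edges, with chemostat
species' concentrations read from their time profiles instead of being
integrated.  Integration uses an implicit stiff solver by default, since
compartment volumes can span many orders of magnitude (the pharmacokinetic
model mixes 0.0007 l and 39.2 l pools).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .components import (
    AdvectionEdge,
    FlowProfile,
    PowerRecord,
    ReactionEdge,
    SpeciesState,
    UnifiedEdge,
    _rate_value,
    chemical_potential,
)
from .errors import ModelValidationError, SimulationError
from .pipe import Pipe

__all__ = [
    "NetworkModel",
    "SimulationResult",
    "build_rhs",
    "simulate",
    "steady_state",
    "generate_random_network",
]


@dataclass
class NetworkModel:
    """A full advection-reaction network.

    Pipes are stored as blocks and expanded into lump species plus chained
    advective edges at assembly time.  ``RT`` is the thermodynamic scale
    constant used for potential and power diagnostics (1 in normalised
    models).
    """

    species: list[SpeciesState] = field(default_factory=list)
    reactions: list[ReactionEdge] = field(default_factory=list)
    advections: list[AdvectionEdge] = field(default_factory=list)
    unified: list[UnifiedEdge] = field(default_factory=list)
    pipes: list[Pipe] = field(default_factory=list)
    RT: float = 1.0
    name: str = "model"

    # -- expansion & validation -------------------------------------------
    def expanded(self) -> tuple[list[SpeciesState], list]:
        """All species (incl. pipe lumps) and all edges (incl. pipe edges)."""
        species = list(self.species)
        edges: list = list(self.reactions) + list(self.advections) + list(self.unified)
        for pipe in self.pipes:
            species.extend(pipe.lump_species())
            edges.extend(pipe.lump_edges())
        return species, edges

    def validate(self) -> None:
        species, edges = self.expanded()
        names = [s.name for s in species]
        seen = set()
        for n in names:
            if n in seen:
                raise ModelValidationError(f"duplicate species name {n!r}")
            seen.add(n)
        for e in edges:
            for n in e.species:
                if n not in seen:
                    kind = type(e).__name__
                    raise ModelValidationError(
                        f"{kind} {e.name!r} references unknown species {n!r}"
                    )

    def content_hash(self) -> str:
        """Stable hash of the model structure (for result provenance)."""
        species, edges = self.expanded()
        parts = [f"RT={self.RT!r}"]
        for s in species:
            parts.append(
                f"S:{s.name}:{s.x0!r}:{s.V!r}:{s.K!r}:{s.chemostat}:{s.profile!r}"
            )
        for e in edges:
            parts.append(f"E:{type(e).__name__}:{e.name}:{e!r}")
        return hashlib.md5("|".join(parts).encode()).hexdigest()[:12]


@dataclass
class SimulationResult:
    """Trajectories, fluxes and power diagnostics of one simulation.

    ``amounts``, ``fluxes`` and ``powers.table`` share the ``times`` grid.
    Amounts of non-chemostat species are floored at 0 in the report (solver
    undershoot below ``-100 * atol`` aborts the simulation instead).
    """

    times: np.ndarray
    amounts: pd.DataFrame
    fluxes: pd.DataFrame
    powers: PowerRecord
    volumes: dict[str, float]
    metadata: dict

    @property
    def concentrations(self) -> pd.DataFrame:
        vols = pd.Series(self.volumes)
        return self.amounts / vols[self.amounts.columns]

    def to_frame(self) -> pd.DataFrame:
        """Single wide table: time, amounts, fluxes, powers."""
        blocks = [
            pd.DataFrame({"time": self.times}),
            self.amounts.reset_index(drop=True),
            self.fluxes.reset_index(drop=True).add_prefix("flux:"),
        ]
        if self.powers.table is not None and not self.powers.table.empty:
            blocks.append(self.powers.table.reset_index(drop=True).add_prefix("power:"))
        return pd.concat(blocks, axis=1)


class CompiledNetwork:
    """A validated model lowered to index-based flux closures."""

    def __init__(self, model: NetworkModel):
        model.validate()
        self.model = model
        self.RT = model.RT
        species, edges = model.expanded()
        self.species = species
        self.edges = edges
        self.index = {s.name: i for i, s in enumerate(species)}
        self.V = np.array([s.V for s in species])
        self.K = np.array([s.K for s in species])
        self.dynamic = [s for s in species if not s.chemostat]
        self.dyn_names = [s.name for s in self.dynamic]
        self.dyn_idx = np.array([self.index[s.name] for s in self.dynamic], dtype=int)
        self.dyn_pos = {s.name: j for j, s in enumerate(self.dynamic)}
        self.chemostats = [s for s in species if s.chemostat]
        self.n = len(self.dynamic)
        self._compiled = [self._compile_edge(e) for e in edges]
        self.x0 = np.array([s.x0 for s in self.dynamic])

    # -- edge lowering -----------------------------------------------------
    def _stoich(self, e) -> list[tuple[int, float]]:
        out: list[tuple[int, float]] = []
        if isinstance(e, ReactionEdge):
            for name, nu in e.substrates:
                if name in self.dyn_pos:
                    out.append((self.dyn_pos[name], -nu))
            for name, nu in e.products:
                if name in self.dyn_pos:
                    out.append((self.dyn_pos[name], +nu))
        else:  # advective or unified: unit transfer upstream -> downstream
            if e.upstream in self.dyn_pos:
                out.append((self.dyn_pos[e.upstream], -1.0))
            if e.downstream in self.dyn_pos:
                out.append((self.dyn_pos[e.downstream], +1.0))
        return out

    def _compile_edge(self, e):
        idx = self.index
        K = self.K
        if isinstance(e, ReactionEdge):
            subs = [(idx[n], nu) for n, nu in e.substrates]
            prods = [(idx[n], nu) for n, nu in e.products]
            kappa = e.kappa

            def flux(t, c, subs=subs, prods=prods, kappa=kappa):
                fwd = 1.0
                for i, nu in subs:
                    fwd *= (K[i] * c[i]) ** nu
                rev = 1.0
                for i, nu in prods:
                    rev *= (K[i] * c[i]) ** nu
                return _rate_value(kappa, t) * (fwd - rev)

        elif isinstance(e, AdvectionEdge):
            iu, idn = idx[e.upstream], idx[e.downstream]
            flow, kref, eps = e.flow, e.K_ref, e.smoothing

            def flux(t, c, iu=iu, idn=idn, flow=flow, kref=kref, eps=eps):
                Q = flow(t)
                if eps > 0.0:
                    w = 0.5 * (1.0 + math.tanh(Q / eps))
                    au = K[iu] * c[iu] / (kref if kref is not None else K[iu])
                    ad = K[idn] * c[idn] / (kref if kref is not None else K[idn])
                    return Q * (w * au + (1.0 - w) * ad)
                if Q > 0.0:
                    return Q * K[iu] * c[iu] / (kref if kref is not None else K[iu])
                if Q < 0.0:
                    return Q * K[idn] * c[idn] / (kref if kref is not None else K[idn])
                return 0.0

        elif isinstance(e, UnifiedEdge):
            iu, idn = idx[e.upstream], idx[e.downstream]
            lam, kappa0, flow, Ke = e.lam, e.kappa0, e.flow, e.K

            def flux(t, c, iu=iu, idn=idn, lam=lam, kappa0=kappa0, flow=flow, Ke=Ke):
                Q = flow(t)
                kprime = Q / Ke
                k0 = kprime if kappa0 is None else kappa0
                kap = lam * k0 + (1.0 - lam) * kprime
                return kap * Ke * (c[iu] - lam * c[idn])

        else:  # pragma: no cover - guarded by expanded()
            raise ModelValidationError(f"unknown edge type {type(e).__name__}")
        return flux, self._stoich(e)

    # -- evaluation --------------------------------------------------------
    def concentrations(self, t: float, y: np.ndarray) -> np.ndarray:
        c = np.empty(len(self.species))
        c[self.dyn_idx] = y / self.V[self.dyn_idx]
        for s in self.chemostats:
            i = self.index[s.name]
            c[i] = s.held_amount(t) / s.V
        return c

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        c = self.concentrations(t, y)
        dy = np.zeros(self.n)
        for flux, stoich in self._compiled:
            f = flux(t, c)
            for j, coef in stoich:
                dy[j] += coef * f
        return dy

    def edge_fluxes(self, t: float, y: np.ndarray) -> np.ndarray:
        c = self.concentrations(t, y)
        return np.array([flux(t, c) for flux, _ in self._compiled])

    def is_autonomous(self) -> bool:
        for e in self.edges:
            flow = getattr(e, "flow", None)
            if isinstance(flow, FlowProfile) and not flow.is_constant:
                return False
            if flow is not None and not isinstance(flow, FlowProfile):
                return False
            kappa = getattr(e, "kappa", None)
            if kappa is not None and callable(kappa):
                if isinstance(kappa, FlowProfile):
                    if not kappa.is_constant:
                        return False
                else:
                    return False
        for s in self.chemostats:
            if s.profile is not None:
                if not (isinstance(s.profile, FlowProfile) and s.profile.is_constant):
                    return False
        return True


def build_rhs(model: NetworkModel):
    """Compile a model and return ``(rhs, compiled)``.

    ``rhs(t, y)`` maps the non-chemostat amount vector to its derivative;
    ``compiled`` exposes the state ordering (``dyn_names``), default
    initial amounts and per-edge flux evaluation.
    """
    compiled = CompiledNetwork(model)
    return compiled.rhs, compiled


def _initial_vector(compiled: CompiledNetwork, initial) -> np.ndarray:
    if initial is None:
        y0 = compiled.x0.copy()
    elif isinstance(initial, dict):
        y0 = compiled.x0.copy()
        for name, val in initial.items():
            if name not in compiled.dyn_pos:
                raise ModelValidationError(
                    f"initial amount given for unknown or chemostat species {name!r}"
                )
            y0[compiled.dyn_pos[name]] = float(val)
    else:
        y0 = np.asarray(initial, dtype=float)
        if y0.shape != (compiled.n,):
            raise ModelValidationError(
                f"initial vector has shape {y0.shape}, expected ({compiled.n},)"
            )
    if np.any(y0 < 0.0):
        raise ModelValidationError("initial amounts must be non-negative")
    return y0


def simulate(
    model: NetworkModel,
    t_end: float,
    initial=None,
    t_eval=None,
    method: str = "BDF",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_samples: int = 501,
    record_powers: bool = True,
    seed=None,
) -> SimulationResult:
    """Integrate a model from ``t = 0`` to ``t_end`` and record diagnostics.

    Returns a :class:`SimulationResult` with per-species amount
    trajectories, per-edge flux trajectories and, for advective edges,
    power/pressure diagnostics evaluated along the solution.  ``initial``
    may be a dict of per-species amounts (defaults from each species'
    ``x0``) or a full state vector.
    """
    if t_end <= 0.0:
        raise ValueError("t_end must be positive")
    rhs, compiled = build_rhs(model)
    y0 = _initial_vector(compiled, initial)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(
        rhs, (0.0, float(t_end)), y0, method=method, rtol=rtol, atol=atol, t_eval=t_eval
    )
    if not sol.success:
        raise SimulationError(f"integrator failed: {sol.message}")
    if sol.y.size and sol.y.min() < -100.0 * atol:
        raise SimulationError(
            f"negative amount {sol.y.min():.3e} beyond tolerance; "
            "tighten rtol/atol or reduce step size"
        )
    return _package_result(
        compiled, sol.t, np.maximum(sol.y, 0.0), method, rtol, atol, record_powers, seed
    )


def _package_result(
    compiled: CompiledNetwork, times, Y, method, rtol, atol, record_powers, seed
) -> SimulationResult:
    amounts = pd.DataFrame(Y.T, columns=compiled.dyn_names)
    edge_names = [e.name for e in compiled.edges]
    F = np.empty((len(times), len(compiled.edges)))
    for k, t in enumerate(times):
        F[k, :] = compiled.edge_fluxes(t, Y[:, k])
    fluxes = pd.DataFrame(F, columns=edge_names)

    power_table = None
    if record_powers:
        cols = {}
        conc = np.empty((len(times), len(compiled.species)))
        for k, t in enumerate(times):
            conc[k, :] = compiled.concentrations(t, Y[:, k])
        for j, e in enumerate(compiled.edges):
            if not isinstance(e, AdvectionEdge):
                continue
            iu, idn = compiled.index[e.upstream], compiled.index[e.downstream]
            mu_u = np.array(
                [
                    chemical_potential(c * compiled.V[iu], compiled.V[iu], compiled.K[iu], compiled.RT)
                    for c in conc[:, iu]
                ]
            )
            mu_d = np.array(
                [
                    chemical_potential(c * compiled.V[idn], compiled.V[idn], compiled.K[idn], compiled.RT)
                    for c in conc[:, idn]
                ]
            )
            dmu = mu_u - mu_d
            f = F[:, j]
            Q = np.array([e.flow(t) for t in times], dtype=float)
            c_upwind = np.where(Q >= 0.0, conc[:, iu], conc[:, idn])
            cols[f"{e.name}.P_RA"] = f * dmu
            cols[f"{e.name}.dP"] = c_upwind * dmu
            cols[f"{e.name}.P_TF"] = Q * c_upwind * dmu
        power_table = pd.DataFrame(cols)
    powers = PowerRecord(RT=compiled.RT, table=power_table)

    volumes = {s.name: s.V for s in compiled.species}
    metadata = {
        "method": method,
        "rtol": rtol,
        "atol": atol,
        "model_hash": compiled.model.content_hash(),
        "model_name": compiled.model.name,
        "seed": seed,
        "n_states": compiled.n,
    }
    return SimulationResult(
        times=np.asarray(times, float),
        amounts=amounts,
        fluxes=fluxes,
        powers=powers,
        volumes=volumes,
        metadata=metadata,
    )


def steady_state(
    model: NetworkModel,
    initial=None,
    t_max: float = 2000.0,
    tol: float = 1e-10,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> dict[str, float]:
    """Steady state of an autonomous model.

    Long-horizon implicit integration (in growing chunks up to ``t_max``)
    followed by a Newton root-polish on the right-hand side; the returned
    state has derivative max-norm below ``tol``.  Raises if the model is
    non-autonomous or if neither stage converges.
    """
    rhs, compiled = build_rhs(model)
    if not compiled.is_autonomous():
        raise ModelValidationError(
            "steady_state requires an autonomous model (constant flows, "
            "constant chemostat profiles, constant rate constants)"
        )
    y = _initial_vector(compiled, initial)
    if compiled.n == 0:
        return {}
    if float(np.max(np.abs(rhs(0.0, y)))) <= tol:
        return dict(zip(compiled.dyn_names, y))

    t_chunk = 50.0
    while t_chunk <= t_max:
        sol = solve_ivp(rhs, (0.0, t_chunk), y, method="BDF", rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(f"integrator failed en route to steady state: {sol.message}")
        y = sol.y[:, -1]
        if float(np.max(np.abs(rhs(0.0, y)))) < 1e-6:
            break
        t_chunk *= 4.0

    polished = root(lambda z: rhs(0.0, z), y, method="hybr", tol=1e-13)
    if polished.success and float(np.max(np.abs(rhs(0.0, polished.x)))) <= tol:
        y = polished.x
    residual = float(np.max(np.abs(rhs(0.0, y))))
    if residual > tol:
        raise SimulationError(
            f"steady state not reached: derivative max-norm {residual:.3e} > {tol:.1e}"
        )
    y = np.maximum(y, 0.0)
    return dict(zip(compiled.dyn_names, y))


def generate_random_network(
    seed: int,
    n_species: int = 4,
    n_reactions: int = 3,
    n_advections: int = 0,
    chemostats: int = 0,
) -> NetworkModel:
    """Random small network for property testing; deterministic per seed.

    Species get positive log-normal volumes and constants and uniform
    initial amounts.  Reactions are unimolecular (mole-conserving) and,
    together with the advective edges, connect the species into a single
    chain plus random extra edges; flows are constant and positive.  With
    ``chemostats = 0`` the model is closed and total moles are conserved.
    """
    if n_species < 1 or n_reactions < 0 or n_advections < 0:
        raise ValueError("counts must be non-negative (n_species >= 1)")
    if chemostats > n_species:
        raise ValueError("more chemostats than species")
    rng = np.random.default_rng(seed)
    species = [
        SpeciesState(
            name=f"S{i + 1}",
            x0=float(rng.uniform(0.2, 2.0)),
            V=float(np.exp(rng.normal(0.0, 0.3))),
            K=float(np.exp(rng.normal(0.0, 0.3))),
            chemostat=i < chemostats,
        )
        for i in range(n_species)
    ]

    def pair(k: int) -> tuple[str, str]:
        # first edges form a chain for connectivity, the rest are random
        if k < n_species - 1:
            return f"S{k + 1}", f"S{k + 2}"
        i, j = rng.choice(n_species, size=2, replace=False)
        return f"S{i + 1}", f"S{j + 1}"

    reactions = []
    for k in range(n_reactions):
        a, b = pair(k)
        reactions.append(
            ReactionEdge(
                name=f"r{k + 1}",
                kappa=float(rng.uniform(0.5, 2.0)),
                substrates=[(a, 1.0)],
                products=[(b, 1.0)],
            )
        )
    advections = []
    for k in range(n_advections):
        a, b = pair(n_reactions + k)
        advections.append(
            AdvectionEdge(
                name=f"adv{k + 1}",
                upstream=a,
                downstream=b,
                flow=FlowProfile.constant(float(rng.uniform(0.5, 2.0))),
            )
        )
    model = NetworkModel(
        species=species, reactions=reactions, advections=advections, name=f"random-{seed}"
    )
    model.validate()
    return model
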