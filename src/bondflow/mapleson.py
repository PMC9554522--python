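"""Compartmental pharmacokinetics of anaesthetic-gas (N2O) uptake.

A Mapleson-style circulation model: inspired gas equilibrates with alveolar
blood across the lung, arterial blood carries it to seven parallel tissue
pools (each receiving a fraction ``delta_p`` of the cardiac output ``Q``)
and venous blood returns it to the lung.  Arteries and veins are modelled
as lumped pipes, so each pool sees the arterial transit delay
``tau = V_A / Q`` before its concentration responds.

A tissue pool of volume ``V_p`` and tissue:blood partition coefficient
``lambda_p`` stores the gas with effective capacity ``lambda_p V_p``; its
thermodynamic constant is ``K_p = 1 / (lambda_p V_p)`` on the amount scale,
i.e. a species constant ``1 / lambda_p`` relative to blood.  The venous
blood leaving a pool is in equilibrium with the tissue, carrying
concentration ``c_pool / lambda_p``.

Units in this module are litres and minutes; RT is normalised to 1 and all
reported concentrations are ratios to the inspired concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .components import FlowProfile, ReactionEdge, SpeciesState
from .errors import ModelValidationError
from .network import NetworkModel, SimulationResult, simulate
from .pipe import Pipe

__all__ = [
    "PoolSpec",
    "MaplesonConfig",
    "default_pools",
    "pool_constant",
    "build_mapleson_model",
    "run_protocol",
    "arterial_delay",
]

#: lung (gas) volume in litres; the lung row of the pool table carries no
#: flow fraction or partition coefficient and is kept separate.
LUNG_VOLUME = 0.6


@dataclass(frozen=True)
class PoolSpec:
    """One tissue pool: volume (l), blood-flow fraction and partition coefficient."""

    name: str
    V_p: float
    delta: float
    partition: float

    def __post_init__(self) -> None:
        if self.V_p < 0.0:
            raise ValueError(f"pool {self.name!r}: volume must be >= 0")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"pool {self.name!r}: flow fraction must lie in [0, 1]")
        if self.partition <= 0.0:
            raise ValueError(f"pool {self.name!r}: partition coefficient must be > 0")

    @property
    def is_pass_through(self) -> bool:
        """Zero-volume pools (the shunt) store nothing: artery feeds vein directly."""
        return self.V_p == 0.0


def default_pools() -> list[PoolSpec]:
    """The packaged seven-pool parameter table."""
    with resources.files("bondflow").joinpath("data/mapleson_pools.csv").open() as fh:
        table = pd.read_csv(fh)
    return [
        PoolSpec(row.pool, float(row.V_p), float(row.delta_p), float(row.lambda_p))
        for row in table.itertuples()
    ]


def pool_constant(spec: PoolSpec) -> float:
    """Thermodynamic constant ``K_p = 1 / (lambda_p V_p)`` of a pool store."""
    if spec.is_pass_through:
        raise ValueError(
            f"pool {spec.name!r} has zero volume (pass-through); it stores "
            "nothing and has no thermodynamic constant"
        )
    return 1.0 / (spec.partition * spec.V_p)


@dataclass
class MaplesonConfig:
    """Whole-body circulation parameters.

    Defaults are the printed values: arterial blood ``V_A = 1.4`` l, venous
    blood ``V_V = 4.0`` l, cardiac output ``Q = 6.48`` l/min, ``N = 5``
    pipe lumps per arterial/venous segment.  ``kappa_av`` is the alveolar
    exchange rate constant; the default ``100 * Q`` is large enough that
    alveolar blood tracks lung air to within about 1% at steady
    inspiration (the equilibration assumption).  ``alveolar_volume`` is the
    pulmonary capillary blood volume, a fast mixing store.
    """

    pools: list[PoolSpec] = field(default_factory=default_pools)
    V_A: float = 1.4
    V_V: float = 4.0
    Q: float = 6.48
    N: int = 5
    kappa_av: float | None = None
    alveolar_volume: float = 0.1
    lung_volume: float = LUNG_VOLUME
    inspired_concentration: float = 1.0

    def __post_init__(self) -> None:
        if min(self.V_A, self.V_V, self.Q) <= 0.0:
            raise ValueError("V_A, V_V and Q must be positive")
        if self.N < 1:
            raise ValueError("N must be >= 1")

    @property
    def exchange_rate(self) -> float:
        return 100.0 * self.Q if self.kappa_av is None else self.kappa_av


def arterial_delay(config: MaplesonConfig | None = None) -> float:
    """Arterial transit delay ``tau = V_A / Q`` in minutes."""
    config = config or MaplesonConfig()
    return config.V_A / config.Q


def build_mapleson_model(
    config: MaplesonConfig | None = None, protocol: FlowProfile | None = None
) -> NetworkModel:
    """Assemble the full uptake network.

    Lung air is a chemostat whose amount follows ``protocol`` (default:
    constant inspired concentration); it exchanges with alveolar blood via
    a reaction element.  For each pool, the arterial pipe (volume
    ``delta_p V_A``, N lumps) carries flow ``delta_p Q`` from the alveolar
    store to the pool, and the venous pipe (volume ``delta_p V_V``) returns
    it.  The zero-volume shunt splices its arterial pipe directly into its
    venous pipe with no pool store.
    """
    config = config or MaplesonConfig()
    delta_sum = sum(p.delta for p in config.pools)
    if abs(delta_sum - 1.0) > 0.01:
        warnings.warn(
            f"pool flow fractions sum to {delta_sum:.4f}, more than 1% from 1",
            stacklevel=2,
        )
    if protocol is None:
        protocol = FlowProfile.constant(config.inspired_concentration * config.lung_volume)

    species = [
        SpeciesState("lung", x0=protocol(0.0), V=config.lung_volume, K=1.0,
                     chemostat=True, profile=protocol),
        SpeciesState("alveolar", x0=0.0, V=config.alveolar_volume, K=1.0),
    ]
    reactions = [
        ReactionEdge("rav", config.exchange_rate, [("lung", 1.0)], [("alveolar", 1.0)])
    ]
    pipes: list[Pipe] = []
    for p in config.pools:
        if p.delta <= 0.0:
            raise ModelValidationError(f"pool {p.name!r} has non-positive flow fraction")
        flow = FlowProfile.constant(p.delta * config.Q)
        art = Pipe(
            name=f"{p.name}.art",
            V=p.delta * config.V_A,
            N=config.N,
            flow=flow,
            K=1.0,
            inlet="alveolar",
            K_ref=1.0,
        )
        ven = Pipe(
            name=f"{p.name}.ven",
            V=p.delta * config.V_V,
            N=config.N,
            flow=flow,
            K=1.0,
            outlet="alveolar",
            K_ref=1.0,
        )
        if p.is_pass_through:
            # shunt: arterial pipe discharges straight into the venous pipe
            art.outlet = ven.lump_names[0]
            ven.inlet = None
        else:
            species.append(
                SpeciesState(p.name, x0=0.0, V=p.V_p, K=1.0 / p.partition)
            )
            art.outlet = p.name
            ven.inlet = p.name
        pipes.extend([art, ven])
    return NetworkModel(species=species, reactions=reactions, pipes=pipes, name="mapleson")


def run_protocol(
    config: MaplesonConfig | None = None,
    t_on: float = 2.0,
    t_end: float = 20.0,
    normalize: bool = True,
    n_samples: int = 2001,
    **solver_opts,
) -> SimulationResult:
    """Simulate the inspired-gas protocol.

    The inspired (lung-air chemostat) concentration is held at the
    configured level on ``[0, t_on)`` and at 0 afterwards, starting from a
    gas-free body.  With ``normalize`` set (the default), the result's
    ``concentrations`` are expressed relative to the inspired
    concentration, matching the usual presentation of uptake curves.
    """
    config = config or MaplesonConfig()
    if not 0.0 < t_on < t_end:
        raise ValueError("need 0 < t_on < t_end")
    level = config.inspired_concentration * config.lung_volume
    protocol = FlowProfile.step(level, 0.0, t_on)
    model = build_mapleson_model(config, protocol)
    result = simulate(model, t_end, n_samples=n_samples, **solver_opts)
    if normalize and config.inspired_concentration != 1.0:
        result.amounts /= config.inspired_concentration
        result.fluxes /= config.inspired_concentration
    result.metadata.update({"t_on": t_on, "normalized": normalize})
    return result
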