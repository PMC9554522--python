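"""Lumped pipes: chains of well-mixed compartments approximating transport delay.

A pipe of total volume ``V`` carrying a hydraulic flow ``Q`` delays the
concentration signal at its inlet by the transit time ``tau = V / Q``.  A
chain of ``N`` identical well-mixed lumps, each of volume ``V / N`` and
connected by advective resistors, realises this as a cascade of first-order
lags with time constant ``tau / N``; its step response is the Erlang
(regularized lower incomplete gamma) CDF and converges to the pure delay
``Heaviside(t - tau)`` as ``N`` grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc

from .components import AdvectionEdge, FlowProfile, SpeciesState

__all__ = ["Pipe", "make_pipe", "pipe_step_response", "delay_halftime", "half_crossing_time"]


@dataclass
class Pipe:
    """An N-lump pipe carrying one species between two stores.

    The lumps are created at network-assembly time as species named
    ``"<name>.<i>"`` (i = 1..N) of volume ``V / N``, chained by ``N + 1``
    advective edges sharing one flow profile: inlet -> lump 1 -> ... ->
    lump N -> outlet.  ``inlet``/``outlet`` may be ``None`` to omit the
    corresponding boundary edge (used when pipes are spliced end-to-end).

    Every inter-lump edge is a full advective resistor, so the upwind
    switch applies lump-by-lump under flow reversal; the transfer-function
    analysis of :func:`pipe_step_response` assumes constant positive flow.
    """

    name: str
    V: float
    N: int
    flow: FlowProfile
    K: float = 1.0
    inlet: str | None = None
    outlet: str | None = None
    K_ref: float | None = None
    x0: float = 0.0  # initial amount per lump

    def __post_init__(self) -> None:
        if self.V <= 0.0:
            raise ValueError(f"pipe {self.name!r}: volume must be positive")
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"pipe {self.name!r}: N must be an integer >= 1")
        self.N = int(self.N)
        if self.K <= 0.0:
            raise ValueError(f"pipe {self.name!r}: K must be positive")

    @property
    def lump_volume(self) -> float:
        return self.V / self.N

    @property
    def lump_names(self) -> list[str]:
        return [f"{self.name}.{i}" for i in range(1, self.N + 1)]

    def tau(self, Q: float) -> float:
        """Transit time ``V / Q`` at constant flow ``Q``."""
        if Q <= 0.0:
            raise ValueError("transit time is defined for positive flow")
        return self.V / Q

    # -- expansion into plain species + edges ------------------------------
    def lump_species(self) -> list[SpeciesState]:
        return [
            SpeciesState(name=n, x0=self.x0, V=self.lump_volume, K=self.K)
            for n in self.lump_names
        ]

    def lump_edges(self) -> list[AdvectionEdge]:
        names = self.lump_names
        edges = []
        if self.inlet is not None:
            edges.append(
                AdvectionEdge(
                    f"{self.name}.in", self.inlet, names[0], self.flow, K_ref=self.K_ref
                )
            )
        for i in range(self.N - 1):
            edges.append(
                AdvectionEdge(
                    f"{self.name}.a{i + 1}",
                    names[i],
                    names[i + 1],
                    self.flow,
                    K_ref=self.K_ref,
                )
            )
        if self.outlet is not None:
            edges.append(
                AdvectionEdge(
                    f"{self.name}.out", names[-1], self.outlet, self.flow, K_ref=self.K_ref
                )
            )
        return edges


def make_pipe(
    V: float,
    N: int,
    K: float = 1.0,
    flow: FlowProfile | None = None,
    inlet: str | None = None,
    outlet: str | None = None,
    name: str = "pipe",
    x0: float = 0.0,
    K_ref: float | None = None,
) -> Pipe:
    """Construct an N-lump pipe of total volume ``V`` (lump volume ``V/N``)."""
    if flow is None:
        flow = FlowProfile.constant(1.0)
    return Pipe(
        name=name, V=V, N=N, flow=flow, K=K, inlet=inlet, outlet=outlet, x0=x0, K_ref=K_ref
    )


def pipe_step_response(N: int, tau: float, t):
    """Closed-form outlet response ``c_N / c_0`` to a unit inlet step.

    The N-lump pipe at constant flow is a cascade of N identical first-order
    lags of time constant ``tau / N``; its step response is the lower-tail
    regularized incomplete gamma function of order ``N`` at ``N t / tau``
    (the Erlang-N CDF).  Monotone non-decreasing in ``t``, 0 at ``t = 0``
    and -> 1 as ``t -> inf``; as ``N -> inf`` it approaches the delayed step
    ``Heaviside(t - tau)``.
    """
    if int(N) != N or N < 1:
        raise ValueError("N must be an integer >= 1")
    if tau <= 0.0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("t must be non-negative")
    return gammainc(int(N), int(N) * t / tau)[()]


def half_crossing_time(times, values) -> float:
    """First time a monotone step-like trajectory crosses 50% of its net change.

    Linear interpolation between samples.  Raises if the trajectory never
    reaches the midpoint of ``values[0]`` and ``values[-1]``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.shape != values.shape or times.size < 2:
        raise ValueError("times and values must be equal-length 1-D arrays")
    v0, v1 = values[0], values[-1]
    if v1 == v0:
        raise ValueError("trajectory has no net change; half-crossing undefined")
    target = v0 + 0.5 * (v1 - v0)
    sign = 1.0 if v1 > v0 else -1.0
    above = sign * (values - target) >= 0.0
    if not above[1:].any():
        raise ValueError("trajectory never crosses 50% of its net change")
    k = 1 + int(np.argmax(above[1:]))  # first crossing index
    t0, t1 = times[k - 1], times[k]
    y0, y1 = values[k - 1], values[k]
    if y1 == y0:
        return float(t1)
    return float(t0 + (target - y0) * (t1 - t0) / (y1 - y0))


def delay_halftime(result, species: str) -> float:
    """Operational transport delay: 50%-crossing time of a species' response.

    ``result`` is a :class:`~bondflow.network.SimulationResult`; the named
    trajectory must be a monotone step-like response (e.g. the outlet lump
    of a pipe after an inlet concentration step).
    """
    return half_crossing_time(result.times, np.asarray(result.amounts[species]))
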