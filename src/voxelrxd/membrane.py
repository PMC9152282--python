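"""Membrane mechanisms coupled to surface voxels.

Hodgkin-Huxley currents (squid-axon kinetics at 6.3 C with the classic
conductance densities) drive sodium accumulation: the per-segment sodium
current is distributed across the segment's surface voxels in proportion to
their marching-cubes areas, and the sodium reversal potential is recomputed
every step from the surface concentration via the Nernst equation, closing
the loop between chemistry and excitability.  Electrical surface areas use
the 1D frusta (lateral) area; the 3D areas only apportion the current.

An event-driven synaptic flux produces mass at a chosen surface voxel at a
rate ``g`` (molecules/ms) that jumps by a weight at each event and decays
exponentially with time constant ``tau`` — the standard first-order
approximation of a metabotropic response.  Mass-based units make the total
delivered amount independent of the spatial and temporal discretization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["HHState", "hh_advance", "nernst", "SynapticFlux", "hh_rates"]

R_GAS = 8.31446261815324  # J/(mol K)
FARADAY = 96485.0         # C/mol
CM = 1.0                  # uF/cm^2


def nernst(c_in: float, c_out: float, z: int = 1, T: float = 279.45) -> float:
    """Nernst reversal potential in mV (default temperature 6.3 C)."""
    if np.any(np.asarray(c_in) <= 0) or np.any(np.asarray(c_out) <= 0):
        raise ValueError("concentrations must be positive")
    return 1e3 * R_GAS * T / (z * FARADAY) * np.log(c_out / c_in)


def _vtrap(x, y):
    """x / (exp(x / y) - 1) with the removable singularity handled."""
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.abs(x / y) < 1e-6, y * (1.0 - x / y / 2.0),
                       x / np.expm1(np.clip(x / y, -500, 500)))
    return out


def hh_rates(v):
    """Classic Hodgkin-Huxley alpha/beta rates (1/ms) at 6.3 C."""
    alpha_m = 0.1 * _vtrap(-(v + 40.0), 10.0)
    beta_m = 4.0 * np.exp(-(v + 65.0) / 18.0)
    alpha_h = 0.07 * np.exp(-(v + 65.0) / 20.0)
    beta_h = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    alpha_n = 0.01 * _vtrap(-(v + 55.0), 10.0)
    beta_n = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)


@dataclass
class HHState:
    """Membrane state of one segment with HH channels.

    Conductances are S/cm^2 (the classic densities by default); ``area`` is
    the segment's lateral (frusta) surface area in um^2, the area cable
    simulators use for electrical purposes.
    """

    area: float                 # um^2, 1D lateral area
    v: float = -65.0            # mV
    m: float = 0.0
    h: float = 0.0
    n: float = 0.0
    gnabar: float = 0.12
    gkbar: float = 0.036
    gl: float = 0.0003
    ena: float = 50.0           # mV, recomputed when sodium is dynamic
    ek: float = -77.0
    el: float = -54.3
    T: float = 279.45           # K (6.3 C)

    def __post_init__(self):
        if self.m == self.h == self.n == 0.0:
            self.init_gates()

    def init_gates(self):
        am, bm, ah, bh, an, bn = hh_rates(self.v)
        self.m = float(am / (am + bm))
        self.h = float(ah / (ah + bh))
        self.n = float(an / (an + bn))

    @property
    def area_cm2(self) -> float:
        return self.area * 1e-8


def hh_advance(state: HHState, i_inject_nA: float, dt: float):
    """Advance one HH segment by ``dt`` ms.

    Gates use the exponential-Euler update; the voltage update is implicit
    in the linear conductances (unconditionally stable).  Returns the
    per-ion segment currents ``(i_na, i_k, i_leak)`` in nA at the new time,
    positive outward, for distribution onto surface voxels.
    """
    am, bm, ah, bh, an, bn = hh_rates(state.v)
    for gate, a, b in (("m", am, bm), ("h", ah, bh), ("n", an, bn)):
        x = getattr(state, gate)
        tau = 1.0 / (a + b)
        xinf = a * tau
        setattr(state, gate, xinf + (x - xinf) * math.exp(-dt / tau))
    gna = state.gnabar * state.m ** 3 * state.h
    gk = state.gkbar * state.n ** 4
    gtot = gna + gk + state.gl
    i_inj = i_inject_nA * 1e-6 / state.area_cm2      # mA/cm^2
    erev = gna * state.ena + gk * state.ek + state.gl * state.el
    # S/cm^2 * mV = mA/cm^2; over uF/cm^2 that is V/s, hence the factor 1e3
    k = 1e3 * dt / CM
    state.v = (state.v + k * (erev + i_inj)) / (1.0 + k * gtot)
    to_nA = state.area_cm2 * 1e6
    i_na = gna * (state.v - state.ena) * to_nA
    i_k = gk * (state.v - state.ek) * to_nA
    i_l = state.gl * (state.v - state.el) * to_nA
    return i_na, i_k, i_l


@dataclass
class SynapticFlux:
    """Event-driven exponentially decaying mass source at surface voxels.

    ``g`` is the production rate in molecules/ms; events ``(time, weight)``
    add their weight to ``g``.  ``advance`` integrates the decay exactly
    over a step and returns the mass (molecules) delivered, so the total
    delivered per event approaches ``weight * tau`` regardless of dt.
    """

    tau: float
    g: float = 0.0
    events: list = field(default_factory=list)
    t: float = 0.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        self.events = sorted(self.events)
        if self.g < 0:
            raise ValueError("g must be >= 0")

    def advance(self, dt: float) -> float:
        """Advance by dt ms; returns molecules produced during the step."""
        t_end = self.t + dt
        delivered = 0.0
        t = self.t
        pending = [e for e in self.events if t < e[0] <= t_end]
        for ev_t, w in pending:
            span = ev_t - t
            delivered += self.g * self.tau * -math.expm1(-span / self.tau)
            self.g *= math.exp(-span / self.tau)
            self.g += w
            t = ev_t
        span = t_end - t
        delivered += self.g * self.tau * -math.expm1(-span / self.tau)
        self.g *= math.exp(-span / self.tau)
        self.t = t_end
        return delivered
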