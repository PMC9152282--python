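"""Closed-form reference solutions and derived estimators for validation.

Pure diffusion from an interval (or box) of elevated concentration has an
error-function solution built from the free-space Green's function

    G(x, t) = (4 pi D t)^(-1/2) exp(-x^2 / (4 D t)),

with reflective boundaries handled by the method of images.  The scalar
bistable equation u_t = D Lap(u) - u (1 - u)(alpha - u) supports traveling
fronts whose plane-wave speed is sqrt(2 D) (1/2 - alpha), used to validate
reaction-diffusion coupling; the front tracker reproduces the measurement
procedure (farthest point above a threshold, crossing times interpolated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = [
    "IntervalIC",
    "BistableParams",
    "green1d",
    "green3d_box",
    "bistable_wave_speed",
    "track_wave_front",
]


@dataclass(frozen=True)
class IntervalIC:
    """Initial plug: concentration ``c`` on [a, b] (um), zero elsewhere."""

    a: float
    b: float
    c: float = 1.0

    def __post_init__(self):
        if not self.a < self.b:
            raise ValueError("need a < b")


@dataclass(frozen=True)
class BistableParams:
    """Threshold and diffusion constant of the scalar bistable equation."""

    alpha: float
    d: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("rightward front needs 0 < alpha < 1/2")


def _interval_term(x, t, d, a, b):
    s = math.sqrt(4.0 * d * t)
    return 0.5 * (erf((x - a) / s) - erf((x - b) / s))


def green1d(x, t, d, ic: IntervalIC, domain=None, tol=1e-15):
    """Concentration at ``x`` (um) and ``t`` (ms) diffusing from a plug.

    ``domain=(x0, x1)`` adds method-of-images terms for reflective ends,
    stopping when the next image pair changes the result by less than
    ``tol``.  ``x`` may be an array.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    x = np.asarray(x, dtype=float)
    out = _interval_term(x, t, d, ic.a, ic.b)
    if domain is not None:
        # Neumann boundaries at x0 and x1: image sources at (A + 2nL, B + 2nL)
        # and (2 x0 - B + 2nL, 2 x0 - A + 2nL) for all integer n.
        x0, x1 = domain
        L = x1 - x0
        if L <= 0:
            raise ValueError("empty domain")
        out = out + _interval_term(x, t, d, 2 * x0 - ic.b, 2 * x0 - ic.a)
        for n in range(1, 65):
            add = np.zeros_like(out)
            for shift in (2 * n * L, -2 * n * L):
                add += _interval_term(x, t, d, ic.a + shift, ic.b + shift)
                add += _interval_term(
                    x, t, d, 2 * x0 - ic.b + shift, 2 * x0 - ic.a + shift
                )
            out = out + add
            if np.max(np.abs(add)) < tol:
                break
    return ic.c * out


def green3d_box(p, t, d, box, c=1.0):
    """Concentration at points ``p`` diffusing from an axis-aligned box.

    ``box`` is ((ax, bx), (ay, by), (az, bz)); by separability the solution
    is the product of the three 1D interval solutions (free space).
    ``p`` has shape (..., 3).
    """
    if t <= 0:
        raise ValueError("t must be positive")
    p = np.asarray(p, dtype=float)
    out = np.ones(p.shape[:-1])
    for axis in range(3):
        a, b = box[axis]
        out = out * _interval_term(p[..., axis], t, d, a, b)
    return c * out


def bistable_wave_speed(alpha: float, d: float = 1.0) -> float:
    """Plane-wave front speed sqrt(2 D) (1/2 - alpha), um/ms."""
    return math.sqrt(2.0 * d) * (0.5 - alpha)


def track_wave_front(times, positions, profiles, threshold=0.5,
                     x_start=100.0, x_end=200.0):
    """Estimate front speed from recorded 1D concentration profiles.

    ``profiles[k]`` is the mean 1D concentration per position at
    ``times[k]``.  The front is the *farthest* position whose value exceeds
    the threshold (interior dips are ignored); the crossing times of
    ``x_start`` and ``x_end`` are linearly interpolated and the speed is
    the distance over the time difference.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    profiles = np.asarray(profiles, dtype=float)
    fronts = np.empty(len(times))
    for k, prof in enumerate(profiles):
        above = np.flatnonzero(prof > threshold)
        fronts[k] = positions[above[-1]] if above.size else -np.inf

    def crossing(xq):
        idx = np.flatnonzero(fronts >= xq)
        if idx.size == 0 or idx[0] == 0:
            raise ValueError(f"front never crosses {xq} inside the record")
        k = idx[0]
        f0, f1 = fronts[k - 1], fronts[k]
        if not np.isfinite(f0) or f1 == f0:
            return times[k]
        return times[k - 1] + (times[k] - times[k - 1]) * (xq - f0) / (f1 - f0)

    t0 = crossing(x_start)
    t1 = crossing(x_end)
    if t1 <= t0:
        raise ValueError("degenerate crossing times")
    return (x_end - x_start) / (t1 - t0)
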