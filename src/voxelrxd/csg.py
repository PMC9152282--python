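"""Constructive solid geometry for voxelizing morphologies.

The 3D volume of a cell is the union of convex solids: one right-circular
cone frustum per consecutive sample pair and, at interior sample points and
branch points, a *join sphere* clipped by the end-face planes of the frusta
that meet there.  Each solid knows its owning electrical segment so that
voxels can be mapped back to compartments.

Signed distances are negative inside.  The frustum distance is the exact
Euclidean distance to the capped cone; the clipped sphere uses the max of
the sphere and half-space distances (exact except near clip edges, which is
sufficient for surface interpolation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .morphology import Morphology, Segment

__all__ = ["Frustum", "JoinSphere", "build_csg", "union_sdf"]

log = logging.getLogger(__name__)

_COLLINEAR_TOL = 1e-12


@dataclass
class Frustum:
    """Truncated right circular cone between two axis points."""

    p0: np.ndarray
    p1: np.ndarray
    r0: float
    r1: float
    segment: Segment

    def __post_init__(self):
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        self.length = float(np.linalg.norm(self.p1 - self.p0))
        if self.length <= 0:
            raise ValueError("zero-length frustum")
        self.axis = (self.p1 - self.p0) / self.length

    def bbox(self):
        # tight box: each end disc extends r * sqrt(1 - u_i^2) per axis
        w = np.sqrt(np.maximum(1.0 - self.axis ** 2, 0.0))
        lo = np.minimum(self.p0 - self.r0 * w, self.p1 - self.r1 * w)
        hi = np.maximum(self.p0 + self.r0 * w, self.p1 + self.r1 * w)
        return lo, hi

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        """Exact signed distance of points (n, 3) to the capped cone."""
        pts = np.atleast_2d(pts)
        a, b = self.p0, self.p1
        ra, rb = self.r0, self.r1
        ba = b - a
        baba = float(ba @ ba)
        pa = pts - a
        paba = (pa @ ba) / baba
        # radial distance via the explicit perpendicular component: the
        # squared-norm difference cancels catastrophically far from the
        # origin and would jitter on-surface membership tests
        perp = pa - paba[:, None] * ba
        x = np.linalg.norm(perp, axis=1)
        cax = np.maximum(0.0, x - np.where(paba < 0.5, ra, rb))
        cay = np.abs(paba - 0.5) - 0.5
        rba = rb - ra
        k = rba * rba + baba
        f = np.clip((rba * (x - ra) + paba * baba) / k, 0.0, 1.0)
        cbx = x - ra - f * rba
        cby = paba - f
        s = np.where((cbx < 0.0) & (cay < 0.0), -1.0, 1.0)
        return s * np.sqrt(
            np.minimum(cax * cax + cay * cay * baba, cbx * cbx + cby * cby * baba)
        )


@dataclass
class JoinSphere:
    """Sphere at a join point, clipped to the wedge between adjacent frusta.

    ``planes`` is a list of ``(normal, offset)`` half-space definitions; the
    kept region satisfies ``normal . x <= offset`` for every plane, so the
    clipped solid is convex.
    """

    center: np.ndarray
    radius: float
    planes: list = field(default_factory=list)
    segment: Segment = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    def bbox(self):
        return self.center - self.radius, self.center + self.radius

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        d = np.linalg.norm(pts - self.center, axis=1) - self.radius
        for n, b in self.planes:
            d = np.maximum(d, pts @ n - b)
        return d


def union_sdf(objects, pts: np.ndarray) -> np.ndarray:
    """Signed distance to the union of solids (min over objects)."""
    pts = np.atleast_2d(pts)
    d = np.full(len(pts), np.inf)
    for obj in objects:
        np.minimum(d, obj.sdf(pts), out=d)
    return d


def build_csg(m: Morphology) -> list:
    """Build the frustum + join-sphere list for a segmentized morphology.

    One frustum per consecutive point pair (zero-length pairs are dropped
    with a log entry).  A join sphere of radius ``max`` of the incident end
    radii is placed at every point where two or more frusta meet, clipped by
    the incident end-face planes; the sphere is suppressed when two incident
    frusta are collinear head-to-tail (the wedge between their faces is
    empty, so the sphere could add nothing).
    """
    if m.segments is None:
        m.segmentize()
    objects = []
    # joins: key -> list of (direction into frustum, end radius, segment)
    joins: dict[tuple, list] = {}

    def _join_key(p):
        return (round(p[0], 9), round(p[1], 9), round(p[2], 9))

    for sec in m.sections:
        for seg in sec.segments:
            pts = seg.points
            for i in range(len(pts) - 1):
                p0, p1 = pts[i], pts[i + 1]
                length = float(np.linalg.norm(p1.xyz - p0.xyz))
                if length <= 1e-12:
                    log.info("dropping zero-length frustum in %s", sec.name)
                    continue
                fr = Frustum(p0.xyz, p1.xyz, p0.r, p1.r, seg)
                objects.append(fr)
                joins.setdefault(_join_key(p0.xyz), []).append((fr.axis, p0.r, seg))
                joins.setdefault(_join_key(p1.xyz), []).append((-fr.axis, p1.r, seg))

    for key, incident in joins.items():
        if len(incident) < 2:
            continue  # free end: flat face, no smoothing needed
        dirs = [d for d, _, _ in incident]
        collinear = any(
            float(dirs[i] @ dirs[j]) <= -(1.0 - _COLLINEAR_TOL)
            for i in range(len(dirs))
            for j in range(i + 1, len(dirs))
        )
        if collinear:
            continue  # pass-through join: wedge between faces is degenerate
        center = np.array(key, dtype=float)
        radius = max(r for _, r, _ in incident)
        if radius <= 0:
            continue
        seg = min((s for _, _, s in incident), key=lambda s: s.root_distance)
        planes = [(d, float(d @ center)) for d, _, _ in incident]
        objects.append(JoinSphere(center, radius, planes, seg))
    return objects
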