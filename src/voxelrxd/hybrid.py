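"""Hybrid 1D-3D simulation: branched cable diffusion weakly coupled to the grid.

Each section of a morphology is simulated either on the 3D voxel grid or as
a 1D cable (per-segment concentrations on the branched tree).  Where a 1D
section meets a 3D section (only at section ends), the voxels of the 3D
side that intersect the junction plane exchange mass with the adjacent 1D
segment by a Fickian flux each step:

    flux = D * area * (c_1D - c_voxel) / distance      [mM um^3 / ms]

with distance estimated as half a voxel edge plus half the 1D segment
length and the exchange area as the voxel interior volume to the 2/3 power.
Fluxes are computed at the start of the step from the current state, then
both domains advance independently (weak coupling).  The exchange is
exactly antisymmetric, so total mass across both domains is conserved to
round-off; large ``dt`` can destabilize the junction (no automatic control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .core import Model3D, SimParams, Species
from .csg import build_csg
from .morphology import Morphology, Section
from .voxelize import GridParams, VoxelGrid, voxelize

__all__ = [
    "SolveTypeMap",
    "Cable1D",
    "HybridJunction",
    "find_junctions",
    "junction_exchange",
    "HybridModel",
]

log = logging.getLogger(__name__)


class SolveTypeMap:
    """Per-section simulation dimension (1 or 3); the last assignment wins."""

    def __init__(self, default: int = 1):
        if default not in (1, 3):
            raise ValueError("dimension must be 1 or 3")
        self.default = default
        self._dim: dict[int, int] = {}

    def set(self, sections, dimension: int):
        if dimension not in (1, 3):
            raise ValueError("dimension must be 1 or 3")
        if isinstance(sections, Section):
            sections = [sections]
        for sec in sections:
            self._dim[id(sec)] = dimension
        return self

    def dimension(self, sec: Section) -> int:
        return self._dim.get(id(sec), self.default)


@dataclass
class HybridJunction:
    """A 1D boundary segment paired with its 3D boundary voxels."""

    segment: object                 # the 1D boundary Segment
    voxels: np.ndarray              # storage indices into the grid
    distances: np.ndarray           # um
    areas: np.ndarray               # um^2


class Cable1D:
    """Branched 1D diffusion on per-segment compartments (backward Euler).

    Segment volumes are frusta sums; axial coupling uses the cross-section
    area at the shared boundary over the center-to-center distance, with
    conservation enforced by antisymmetric fluxes (symmetric conductances),
    including across branch points.
    """

    def __init__(self, sections, morphology: Morphology):
        self.sections = list(sections)
        self.morph = morphology
        segs = []
        for sec in self.sections:
            segs.extend(sec.segments)
        self.segments = segs
        self.index = {id(s): i for i, s in enumerate(segs)}
        n = len(segs)
        self.volumes = np.array([_segment_volume(s) for s in segs])
        rows, cols, vals = [], [], []

        def couple(sa, sb, area, dist):
            ia, ib = self.index[id(sa)], self.index[id(sb)]
            g = area / dist
            rows.extend([ia, ia, ib, ib])
            cols.extend([ib, ia, ia, ib])
            vals.extend([g, -g, g, -g])

        for sec in self.sections:
            for a, b in zip(sec.segments[:-1], sec.segments[1:]):
                r = sec.interpolate(a.arc1).r
                dist = 0.5 * (a.length + b.length)
                couple(a, b, np.pi * r * r, dist)
            if sec.parent is not None and id(sec.parent.segments[0]) in self.index:
                parent = sec.parent
                arc = sec.parent_x * parent.length
                pseg = next(
                    s for s in parent.segments if s.arc0 - 1e-9 <= arc <= s.arc1 + 1e-9
                )
                child = sec.segments[0]
                r = sec.points[0].r
                dist = 0.5 * (pseg.length + child.length)
                couple(pseg, child, np.pi * r * r, dist)
        self._g = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        self.conc = np.zeros(n)
        self._solver = None
        self._solver_key = None

    def positions(self) -> np.ndarray:
        """Root-path distance of each segment center."""
        return np.array([s.root_distance for s in self.segments])

    def step(self, d: float, dt: float):
        key = (d, dt)
        if self._solver_key != key:
            n = len(self.segments)
            A = sp.diags(self.volumes) - dt * d * self._g
            self._solver = splu(A.tocsc())
            self._solver_key = key
        self.conc = self._solver.solve(self.volumes * self.conc)

    def mass(self) -> float:
        return float(np.dot(self.conc, self.volumes)) * 1e-18


def _segment_volume(seg) -> float:
    v = 0.0
    for p0, p1 in zip(seg.points[:-1], seg.points[1:]):
        h = float(np.linalg.norm(p1.xyz - p0.xyz))
        v += np.pi * h * (p0.r ** 2 + p0.r * p1.r + p1.r ** 2) / 3.0
    return v


def find_junctions(solve_map: SolveTypeMap, morph: Morphology, grid: VoxelGrid,
                   cable: Cable1D) -> list[HybridJunction]:
    """Identify 1D-3D junctions by section adjacency and plane intersection.

    Every 3D section's parent is checked against the 1D set and vice versa;
    a junction's boundary voxels are the voxels of the 3D section that
    intersect the plane through the shared end, perpendicular to the edge
    frustum axis there.
    """
    junctions = []
    volumes = grid.volumes
    pairs = []  # (sec3d, sec1d, at_start_of_3d)
    for sec in morph.sections:
        if sec.parent is None:
            continue
        dp = solve_map.dimension(sec.parent)
        dc = solve_map.dimension(sec)
        if dp == dc:
            continue
        if dc == 3:
            pairs.append((sec, sec.parent, True))
        else:
            pairs.append((sec.parent, sec, False))
    for sec3, sec1, at_start in pairs:
        if at_start:
            point = sec3.points[0].xyz
            axis = sec3.points[1].xyz - sec3.points[0].xyz
            # the 1D boundary segment: where the 3D child attaches
            arc = sec3.parent_x * sec1.length
            seg1 = next(
                s for s in sec1.segments if s.arc0 - 1e-9 <= arc <= s.arc1 + 1e-9
            )
        else:
            arc = sec1.parent_x * sec3.length
            point = sec3.interpolate(arc).xyz
            p_prev = sec3.interpolate(max(arc - 1e-6 * sec3.length, 0.0)).xyz
            axis = point - p_prev
            seg1 = sec1.segments[0]
        n = axis / np.linalg.norm(axis)
        outward = -n if at_start else n  # away from the 3D section
        seg_ids = [s.id for s in sec3.segments]
        cand = np.isin(grid.seg_id, seg_ids)
        centers = grid.centers[cand]
        signed = (centers - point) @ outward
        half_support = 0.5 * grid.dx * np.abs(outward).sum()
        # the layer of voxels just inside the junction plane
        hit = (signed >= -half_support - 1e-12) & (signed <= 1e-12)
        vox = np.flatnonzero(cand)[hit]
        if vox.size == 0:
            log.info("junction at %s has no boundary voxels", point)
            continue
        v = volumes[vox]
        junctions.append(
            HybridJunction(
                segment=seg1,
                voxels=vox,
                distances=np.full(vox.size, 0.5 * grid.dx + 0.5 * seg1.length),
                areas=v ** (2.0 / 3.0),
            )
        )
    return junctions


def junction_exchange(junctions, cable: Cable1D, u: np.ndarray,
                      volumes: np.ndarray, d: float, dt: float):
    """Apply one explicit Fickian exchange across every junction, in place.

    Equal and opposite masses are applied to the 1D segment and the 3D
    boundary voxels, so the update conserves total mass exactly.
    """
    for j in junctions:
        i1 = cable.index[id(j.segment)]
        c1 = cable.conc[i1]
        flux = d * j.areas * (c1 - u[j.voxels]) / j.distances  # mM um^3/ms
        dm = flux * dt
        u[j.voxels] += dm / volumes[j.voxels]
        cable.conc[i1] -= dm.sum() / cable.volumes[i1]


class HybridModel:
    """A single-species hybrid model over one morphology.

    Sections flagged 3D are voxelized and advanced with the operator-split
    3D solver; the rest form a branched 1D cable.  Junctions are cached at
    construction and reused every step (recompute by rebuilding the model
    if the morphology changes).
    """

    def __init__(self, morph: Morphology, solve_map: SolveTypeMap, species: Species,
                 grid_params: GridParams, params: SimParams | None = None,
                 rates=(), initial_1d=None):
        self.morph = morph
        self.solve_map = solve_map
        self.species = species
        self.params = params or SimParams()
        if morph.segments is None:
            morph.segmentize()
        self.sections3d = [s for s in morph.sections if solve_map.dimension(s) == 3]
        self.sections1d = [s for s in morph.sections if solve_map.dimension(s) == 1]
        self.model3d = None
        self.cable = None
        self.junctions = []
        if self.sections3d:
            objs = [o for o in build_csg(morph)
                    if o.segment.section in self.sections3d]
            grid = voxelize(objs, grid_params, compute_areas=False)
            self.model3d = Model3D(grid, [species], rates=rates, params=self.params)
        if self.sections1d:
            self.cable = Cable1D(self.sections1d, morph)
            if initial_1d is not None:
                pos = self.cable.positions()
                self.cable.conc[:] = np.asarray(
                    initial_1d(pos), dtype=float
                ) * np.ones(len(pos))
        if self.model3d is not None and self.cable is not None:
            self.junctions = find_junctions(
                solve_map, morph, self.model3d.grid, self.cable
            )
        self.t = 0.0

    def step(self, dt: float | None = None):
        dt = self.params.dt if dt is None else dt
        if self.junctions:
            junction_exchange(
                self.junctions, self.cable, self.model3d.conc[self.species.name],
                self.model3d.volumes, self.species.d, dt,
            )
        if self.cable is not None:
            self.cable.step(self.species.d, dt)
        if self.model3d is not None:
            self.model3d.step(dt)
        self.t += dt

    def run(self, t_stop: float, dt: float | None = None):
        dt = self.params.dt if dt is None else dt
        for _ in range(int(round((t_stop - self.t) / dt))):
            self.step(dt)

    def mass(self) -> float:
        m = 0.0
        if self.model3d is not None:
            m += self.model3d.mass(self.species.name)
        if self.cable is not None:
            m += self.cable.mass()
        return m
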