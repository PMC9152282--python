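"""Point-diameter morphologies and electrical segmentation.

A neuron reconstruction is a tree of unbranched *sections*, each an ordered
run of ``(x, y, z; d)`` samples (micrometers).  Electrical state lives on
``nseg`` equal arc-length compartments ("segments") per section; chemistry in
3D is carried by the union of one frustum per consecutive sample pair plus
clipped join spheres that smooth bends and branch points (see
:mod:`voxelrxd.csg`).

Conventions
-----------
* All coordinates and diameters are micrometers.
* Sections attach to their parent at an arc-length fraction in ``[0, 1]``
  (1.0 = parent end, the default; interior fractions are used for spines).
* The SWC dialect is 7-column whitespace text with ``#`` comments, 1-based
  ids and radii (converted to diameters on read).  A sample starts a new
  section at branch points and at type changes; soma rows collapse to a
  single section, with a lone soma sample expanded to a cylinder of length
  equal to its diameter.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Point3D",
    "Section",
    "Segment",
    "Morphology",
    "read_swc",
    "write_swc",
    "segmentize",
    "suggest_dx",
    "spine_attach_offset",
    "MorphologyError",
]


class MorphologyError(ValueError):
    """Structural or parse error in a morphology description."""


@dataclass(frozen=True)
class Point3D:
    """A reconstruction sample: position plus local diameter, micrometers."""

    x: float
    y: float
    z: float
    d: float

    def __post_init__(self):
        for name in ("x", "y", "z", "d"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise MorphologyError(f"non-finite coordinate in {self!r}")
            object.__setattr__(self, name, v)
        if self.d < 0:
            raise MorphologyError(f"negative diameter in {self!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def r(self) -> float:
        return 0.5 * self.d


class Section:
    """An unbranched run of samples with an electrical compartment count."""

    def __init__(self, name, points, nseg=1, swc_type=3, pt3d_style=False):
        points = list(points)
        if len(points) < 2:
            raise MorphologyError(f"section {name!r} needs >=2 points")
        if nseg < 1:
            raise MorphologyError("nseg must be >= 1")
        self.name = name
        self.points: list[Point3D] = points
        self.nseg = int(nseg)
        self.swc_type = swc_type
        # pt3d_style: the first point is a repositioned start (spine offset
        # rule) rather than the parent attachment location.
        self.pt3d_style = bool(pt3d_style)
        self.parent: Section | None = None
        self.parent_x: float = 1.0
        self.children: list[Section] = []
        self.segments: list[Segment] | None = None

    def __repr__(self):
        return f"<Section {self.name} n={len(self.points)} nseg={self.nseg}>"

    def connect(self, parent: "Section", parent_x: float = 1.0) -> "Section":
        if not 0.0 <= parent_x <= 1.0:
            raise MorphologyError("attachment position must be in [0, 1]")
        if self.parent is not None:
            raise MorphologyError(f"section {self.name} already has a parent")
        self.parent = parent
        self.parent_x = float(parent_x)
        parent.children.append(self)
        return self

    @property
    def arcs(self) -> np.ndarray:
        """Cumulative arc length at each sample, starting at 0."""
        pts = np.array([p.xyz for p in self.points])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arcs[-1])

    def interpolate(self, arc: float) -> Point3D:
        """Linear interpolation of position and diameter at an arc length."""
        arcs = self.arcs
        arc = min(max(arc, 0.0), arcs[-1])
        i = int(np.searchsorted(arcs, arc, side="right")) - 1
        i = min(i, len(arcs) - 2)
        a0, a1 = arcs[i], arcs[i + 1]
        t = 0.0 if a1 == a0 else (arc - a0) / (a1 - a0)
        p0, p1 = self.points[i], self.points[i + 1]
        return Point3D(
            p0.x + t * (p1.x - p0.x),
            p0.y + t * (p1.y - p0.y),
            p0.z + t * (p1.z - p0.z),
            p0.d + t * (p1.d - p0.d),
        )


class Segment:
    """One electrical compartment: an arc-length interval of a section.

    ``points`` spans the interval including interpolated boundary points, so
    consecutive point pairs are exactly the frusta owned by this compartment.
    """

    def __init__(self, section, index, points, arc0, arc1):
        self.section = section
        self.index = int(index)
        self.points: list[Point3D] = points
        self.arc0 = float(arc0)
        self.arc1 = float(arc1)
        self.id: int = -1           # global index, set by Morphology.segmentize
        self.root_distance = np.nan  # path distance from root to segment center

    @property
    def length(self) -> float:
        return self.arc1 - self.arc0

    @property
    def x(self) -> float:
        """Normalized center position along the section, as in 1D cable use."""
        L = self.section.length
        return 0.5 * (self.arc0 + self.arc1) / L if L else 0.0

    def __repr__(self):
        return f"<Segment {self.section.name}[{self.index}] id={self.id}>"


class Morphology:
    """A connected tree of sections with a single root."""

    def __init__(self, sections):
        self.sections: list[Section] = list(sections)
        roots = [s for s in self.sections if s.parent is None]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._check_tree()
        self.segments: list[Segment] | None = None

    def _check_tree(self):
        seen = set()
        stack = [self.root]
        while stack:
            s = stack.pop()
            if id(s) in seen:
                raise MorphologyError("cycle detected in section tree")
            seen.add(id(s))
            stack.extend(s.children)
        if len(seen) != len(self.sections):
            raise MorphologyError("section tree is not connected")

    def section_start_distance(self, sec: Section) -> float:
        """Path distance from the root to the 0-end of a section."""
        d = 0.0
        while sec.parent is not None:
            d += sec.parent_x * sec.parent.length
            sec = sec.parent
        return d

    def segmentize(self, nseg_map=None) -> list[Segment]:
        """Split every section into its electrical compartments.

        Interpolated points are inserted at compartment boundaries
        ``k / nseg`` so that every frustum lies wholly in one segment.
        ``nseg_map`` optionally overrides ``nseg`` per section (by object or
        by name).
        """
        segs: list[Segment] = []
        for sec in self.sections:
            nseg = sec.nseg
            if nseg_map is not None:
                nseg = nseg_map.get(sec, nseg_map.get(sec.name, nseg))
                sec.nseg = int(nseg)
            segs.extend(_segmentize_section(sec))
        for i, sg in enumerate(segs):
            sg.id = i
        for sec in self.sections:
            d0 = self.section_start_distance(sec)
            for sg in sec.segments:
                sg.root_distance = d0 + 0.5 * (sg.arc0 + sg.arc1)
        self.segments = segs
        return segs


def _segmentize_section(sec: Section) -> list[Segment]:
    L = sec.length
    if L <= 0:
        raise MorphologyError(f"section {sec.name} has zero length")
    arcs = list(sec.arcs)
    pts = list(sec.points)
    bounds = [k * L / sec.nseg for k in range(sec.nseg + 1)]
    # merge sample arcs and boundary arcs, inserting interpolated points
    merged_arcs: list[float] = []
    merged_pts: list[Point3D] = []
    tol = 1e-9 * max(L, 1.0)
    for b in sorted(set(arcs) | set(bounds)):
        close = [a for a in merged_arcs if abs(a - b) <= tol]
        if close:
            continue
        merged_arcs.append(b)
        j = int(np.searchsorted(arcs, b, side="right")) - 1
        j = min(max(j, 0), len(arcs) - 2)
        if abs(arcs[j] - b) <= tol:
            merged_pts.append(pts[j])
        elif abs(arcs[j + 1] - b) <= tol:
            merged_pts.append(pts[j + 1])
        else:
            merged_pts.append(sec.interpolate(b))
    segs = []
    for k in range(sec.nseg):
        a0, a1 = bounds[k], bounds[k + 1]
        idx = [i for i, a in enumerate(merged_arcs) if a0 - tol <= a <= a1 + tol]
        seg_pts = [merged_pts[i] for i in idx]
        segs.append(Segment(sec, k, seg_pts, a0, a1))
    sec.segments = segs
    return segs


def segmentize(m: Morphology, nseg_map=None) -> list[Segment]:
    """Module-level alias for :meth:`Morphology.segmentize`."""
    return m.segmentize(nseg_map)


def suggest_dx(m: Morphology, dx: float):
    """Check frusta against the voxel size and suggest a safe ``dx``.

    A frustum whose length or diameter is smaller than the largest distance
    that fits within a voxel cannot be guaranteed to place at least one grid
    corner inside it, which breaks the marching-cubes surface estimate.  The
    warning threshold uses the voxel space diagonal ``sqrt(3)*dx``; the
    suggested voxel size is one third of the smallest frustum dimension.

    Returns ``(warnings, suggested_dx)``; ``suggested_dx`` is ``None`` when
    nothing is too small.
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    thresh = math.sqrt(3.0) * dx
    warnings = []
    min_dim = math.inf
    for sec in m.sections:
        pts = sec.points
        for i in range(len(pts) - 1):
            length = float(np.linalg.norm(pts[i + 1].xyz - pts[i].xyz))
            if length <= 0:
                continue
            diam = min(pts[i].d, pts[i + 1].d)
            dim = min(length, diam) if diam > 0 else length
            min_dim = min(min_dim, dim)
            if dim < thresh:
                warnings.append(
                    f"{sec.name} frustum {i}: min dimension {dim:.4g} um < "
                    f"sqrt(3)*dx = {thresh:.4g} um"
                )
    suggested = None if not warnings else min_dim / 3.0
    return warnings, suggested


def spine_attach_offset(r_d: float, r_n: float) -> float:
    """Inset depth for starting a spine neck just inside its dendrite.

    For a cylindrical dendrite of radius ``r_d`` with an orthogonal neck of
    radius ``r_n``, the neck base can sit at most ``r_d - d`` from the
    dendrite axis while keeping the neck cross-section inside the dendrite,
    where ``d = r_d - sqrt(r_d**2 - r_n**2)``.  This function returns ``d``.
    """
    if not 0 <= r_n <= r_d:
        raise ValueError("need 0 <= r_n <= r_d")
    return r_d - math.sqrt(r_d * r_d - r_n * r_n)


# ---------------------------------------------------------------------------
# SWC input/output
# ---------------------------------------------------------------------------

def read_swc(source) -> Morphology:
    """Read a 7-column SWC stream (or text) into a :class:`Morphology`."""
    if isinstance(source, str):
        source = io.StringIO(source)
    records: dict[int, tuple] = {}
    for ln, line in enumerate(source, 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise MorphologyError(f"line {ln}: expected 7 fields, got {len(parts)}")
        try:
            sid = int(parts[0])
            typ = int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            parent = int(parts[6])
        except ValueError as e:
            raise MorphologyError(f"line {ln}: non-numeric field ({e})") from None
        if sid in records:
            raise MorphologyError(f"duplicate sample id {sid}")
        records[sid] = (typ, x, y, z, r, parent)

    if not records:
        raise MorphologyError("empty SWC")
    roots = [sid for sid, rec in records.items() if rec[5] == -1]
    if len(roots) != 1:
        raise MorphologyError(f"expected one root sample, found {len(roots)}")
    for sid, rec in records.items():
        if rec[5] != -1 and rec[5] not in records:
            raise MorphologyError(f"sample {sid} references undefined parent {rec[5]}")
    # cycle check by walking to the root from every sample
    for sid in records:
        seen = set()
        cur = sid
        while cur != -1:
            if cur in seen:
                raise MorphologyError("cycle in SWC parent pointers")
            seen.add(cur)
            cur = records[cur][5]

    children: dict[int, list[int]] = {sid: [] for sid in records}
    for sid, rec in records.items():
        if rec[5] != -1:
            children[rec[5]].append(sid)

    def _pt(sid):
        typ, x, y, z, r, _ = records[sid]
        return Point3D(x, y, z, 2.0 * r)

    sections: list[Section] = []
    sec_of_sample: dict[int, Section] = {}
    arc_of_sample: dict[int, float] = {}

    def _new_section_start(sid):
        rec = records[sid]
        if rec[5] == -1:
            return True
        prec = records[rec[5]]
        return prec[0] != rec[0] or len(children[rec[5]]) > 1

    # walk samples in id order, building unbranched chains
    counter = 0
    for sid in sorted(records):
        if sid in sec_of_sample:
            continue
        if not _new_section_start(sid):
            continue
        chain = [sid]
        cur = sid
        while len(children[cur]) == 1:
            nxt = children[cur][0]
            if _new_section_start(nxt):
                break
            chain.append(nxt)
            cur = nxt
        rec = records[sid]
        pts = [_pt(s) for s in chain]
        prepended = False
        if rec[5] != -1:
            ppos = records[rec[5]][1:4]
            if np.linalg.norm(np.array(ppos) - pts[0].xyz) > 1e-9:
                # parent sample is not duplicated: prepend it so the section
                # connects geometrically (child's own starting diameter).
                pts.insert(0, Point3D(*ppos, pts[0].d))
                prepended = True
        if len(pts) == 1:
            # lone soma sample: expand to a cylinder of length = diameter
            p = pts[0]
            pts = [
                Point3D(p.x - p.r, p.y, p.z, p.d),
                Point3D(p.x + p.r, p.y, p.z, p.d),
            ]
        name = f"sec{counter}"
        counter += 1
        sec = Section(name, pts, swc_type=rec[0])
        sections.append(sec)
        off = 1 if prepended else 0
        arcs = sec.arcs
        for i, s in enumerate(chain):
            sec_of_sample[s] = sec
            arc_of_sample[s] = arcs[min(i + off, len(arcs) - 1)]
        if rec[5] != -1:
            psec = sec_of_sample[rec[5]]
            L = psec.length
            frac = arc_of_sample[rec[5]] / L if L else 1.0
            sec.connect(psec, frac)
    return Morphology(sections)


def write_swc(m: Morphology, stream=None) -> str:
    """Write a morphology as canonical SWC text.

    Floats are written with ``repr`` (shortest exact form) so a
    write -> read -> write cycle is byte-stable.
    """
    out = stream or io.StringIO()
    next_id = 1
    last_sample: dict[int, int] = {}  # id(section) -> id of its last sample

    def emit(sec: Section, parent_sample: int, skip_first: bool):
        nonlocal next_id
        pts = sec.points[1:] if skip_first else sec.points
        prev = parent_sample
        for p in pts:
            out.write(
                f"{next_id} {sec.swc_type} {p.x!r} {p.y!r} {p.z!r} {p.r!r} {prev}\n"
            )
            prev = next_id
            next_id += 1
        last_sample[id(sec)] = prev

    order = _preorder(m)
    for sec in order:
        if sec.parent is None:
            emit(sec, -1, False)
        else:
            psec = sec.parent
            # attach to the parent sample nearest the attachment arc
            arcs = psec.arcs
            target = sec.parent_x * psec.length
            j = int(np.argmin(np.abs(arcs - target)))
            # sample ids of the parent section run consecutively backwards
            n = len(psec.points)
            pid = last_sample[id(psec)] - (n - 1 - j)
            share = np.linalg.norm(sec.points[0].xyz - psec.points[j].xyz) <= 1e-9
            emit(sec, pid, share)
    text = out.getvalue() if isinstance(out, io.StringIO) else None
    return text


def _preorder(m: Morphology) -> list[Section]:
    order = []
    stack = [m.root]
    while stack:
        s = stack.pop()
        order.append(s)
        stack.extend(reversed(s.children))
    return order
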