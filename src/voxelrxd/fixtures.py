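"""Programmatic validation geometries.

Every geometry used in the validation studies is generated here from its
defining parameters, so no reconstruction files are needed: simple
cylinders at arbitrary orientations, the 30-degree Y branch, the
stepped-diameter cylinder pair, and a spiny dendrite with two thin-necked
spines.  All builders are deterministic; orientation studies draw their
angles from a seeded generator.
"""

from __future__ import annotations

import math

import numpy as np

from .morphology import Morphology, Point3D, Section, spine_attach_offset

__all__ = [
    "make_cylinder",
    "make_y",
    "make_stepped",
    "make_spiny",
    "random_orientations",
    "rotation_from_angles",
]


def rotation_from_angles(phi: float, theta: float) -> np.ndarray:
    """Rotation matrix sending +x to the direction (phi, theta).

    ``theta`` is the polar angle from the +z axis, ``phi`` the azimuth, as
    in spherical coordinates.
    """
    st, ct = math.sin(theta), math.cos(theta)
    sp, cp = math.sin(phi), math.cos(phi)
    u = np.array([st * cp, st * sp, ct])  # new x axis
    # build an orthonormal frame around u
    helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(helper, u)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return np.column_stack([u, v, w])


def random_orientations(n: int, seed: int, mode: str = "angle") -> np.ndarray:
    """``n`` seeded random orientations ``(phi, theta)``.

    ``mode='angle'`` draws each spherical angle uniformly over its range
    (the convention of the discretization studies); ``mode='sphere'`` draws
    directions uniformly on the sphere (cos(theta) uniform).
    """
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    if mode == "angle":
        theta = rng.uniform(0.0, math.pi, n)
    elif mode == "sphere":
        theta = np.arccos(rng.uniform(-1.0, 1.0, n))
    else:
        raise ValueError(f"unknown orientation mode {mode!r}")
    return np.column_stack([phi, theta])


def make_cylinder(L: float, d: float, orientation=None, nseg: int = 1) -> Morphology:
    """A two-point cylinder section, optionally rotated about its center.

    ``orientation`` is ``(phi, theta)``; ``None`` leaves the axis along +x
    from the origin.
    """
    if L <= 0 or d <= 0:
        raise ValueError("cylinder needs positive length and diameter")
    if orientation is None:
        p0 = np.zeros(3)
        p1 = np.array([L, 0.0, 0.0])
    else:
        R = rotation_from_angles(*orientation)
        half = R @ np.array([L / 2.0, 0.0, 0.0])
        p0, p1 = -half, half
    sec = Section("cyl", [Point3D(*p0, d), Point3D(*p1, d)], nseg=nseg)
    return Morphology([sec])


def make_y(arm_len: float = 10.0, d: float = 2.0, angle_deg: float = 30.0,
           nseg: int = 1) -> Morphology:
    """Three-section Y: a trunk along +x and two arms bending by ``angle``.

    With the defaults the trunk runs (0,0,0) -> (10,0,0) and the arms
    continue to (10 + 5*sqrt(3), +/-5, 0): 30-degree direction changes.
    """
    a = math.radians(angle_deg)
    tip = arm_len * np.array([math.cos(a), math.sin(a), 0.0])
    j = np.array([arm_len, 0.0, 0.0])
    trunk = Section("trunk", [Point3D(0, 0, 0, d), Point3D(*j, d)], nseg=nseg)
    up = Section("arm_up", [Point3D(*j, d), Point3D(*(j + tip), d)], nseg=nseg)
    dn = Section(
        "arm_down",
        [Point3D(*j, d), Point3D(*(j + tip * np.array([1, -1, 1])), d)],
        nseg=nseg,
    )
    up.connect(trunk, 1.0)
    dn.connect(trunk, 1.0)
    return Morphology([trunk, up, dn])


def make_stepped(L1: float = 5.0, d1: float = 5.0, n1: int = 9,
                 L2: float = 5.0, d2: float = 1.0, n2: int = 5) -> Morphology:
    """Two collinear cylinders with an abrupt diameter step at the join.

    The narrow child starts at the parent's diameter and tapers to its own
    diameter by the midpoint of its first electrical segment (the stylized
    join cone a cable simulator produces when a thin section attaches to a
    thick one), so the step is bridged by a short cone visible in a 2D
    projection of the surface voxels.
    """
    wide = Section(
        "wide", [Point3D(0, 0, 0, d1), Point3D(L1, 0, 0, d1)], nseg=n1
    )
    mid = L1 + L2 / n2 / 2.0  # midpoint of the child's first segment
    narrow = Section(
        "narrow",
        [Point3D(L1, 0, 0, d1), Point3D(mid, 0, 0, d2), Point3D(L1 + L2, 0, 0, d2)],
        nseg=n2,
    )
    narrow.connect(wide, 1.0)
    return Morphology([wide, narrow])


def make_spiny(d_dend: float = 2.5, L_dend: float = 6.0,
               neck_L: float = 3.0, neck_d: float = 0.1,
               head_L: float = 0.5, head_d: float = 0.6,
               angle_sep_deg: float = 180.0, attach_arc: float = 3.0,
               nseg_dend: int = 1, nseg_spine: int = 1) -> Morphology:
    """A cylindrical dendrite with two orthogonal spines at one arc position.

    The two spines are separated by ``angle_sep_deg`` around the dendrite
    circumference, centred on +y.  Each neck base is inset from the dendrite
    surface by :func:`spine_attach_offset` so the neck cross-section stays
    inside the dendrite while overlapping it as little as possible.
    """
    r_d, r_n = d_dend / 2.0, neck_d / 2.0
    if r_n > r_d:
        raise ValueError("neck wider than dendrite")
    dend = Section(
        "dend", [Point3D(0, 0, 0, d_dend), Point3D(L_dend, 0, 0, d_dend)],
        nseg=nseg_dend,
    )
    sections = [dend]
    inset = spine_attach_offset(r_d, r_n)
    base_r = r_d - inset
    half = math.radians(angle_sep_deg) / 2.0
    for sign, tag in ((+1, "a"), (-1, "b")):
        ang = sign * half
        u = np.array([0.0, math.cos(ang), math.sin(ang)])  # radial direction
        base = np.array([attach_arc, 0.0, 0.0]) + base_r * u
        neck_end = base + neck_L * u
        head_end = neck_end + head_L * u
        neck = Section(
            f"neck_{tag}",
            [Point3D(*base, neck_d), Point3D(*neck_end, neck_d)],
            nseg=nseg_spine,
            pt3d_style=True,
        )
        head = Section(
            f"head_{tag}",
            [Point3D(*neck_end, head_d), Point3D(*head_end, head_d)],
            nseg=nseg_spine,
        )
        neck.connect(dend, attach_arc / L_dend)
        head.connect(neck, 1.0)
        sections.extend([neck, head])
    return Morphology(sections)
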