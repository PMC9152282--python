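"""Validation experiments: each reference benchmark as a callable study.

Every function builds its own fixture geometry, runs the method, and
returns the measured quantity, so results are reproducible from a seed
alone.  Problem sizes default to scaled-down versions chosen to keep each
study in the minutes range on one CPU; the full-size settings are plain
arguments.
"""

from __future__ import annotations

import math

import numpy as np

from ._kernels import bistable_backward_euler
from .core import Model3D, SimParams, Species, dg_adi_step, segment_feedback
from .csg import build_csg
from .fixtures import make_cylinder, make_spiny, make_y, random_orientations
from .hybrid import HybridModel, SolveTypeMap
from .membrane import HHState, hh_advance, nernst
from .morphology import Morphology, Point3D, Section
from .oracles import IntervalIC, bistable_wave_speed, green1d, green3d_box, track_wave_front
from .voxelize import GridParams, voxelize

__all__ = [
    "cylinder_discretization_study",
    "y_voxel_count",
    "line_diffusion_error",
    "point_source_error",
    "hybrid_midpoint_analytic",
    "hybrid_error",
    "conservation_drift",
    "wave_speed_study",
    "spine_study",
    "hh_soma_study",
]


def cylinder_discretization_study(dxs, n_orientations=100, seed=0, vr=1,
                                  L=5.0, d=2.0, with_areas=True):
    """Volume/area errors of the voxelized cylinder over random orientations.

    Returns a dict with per-dx mean absolute errors against the analytic
    volume (pi L d^2 / 4) and lateral+cap area (pi d L + pi d^2 / 2), plus
    the log-log convergence slopes when more than one dx is given.
    """
    dxs = list(dxs)
    oris = random_orientations(n_orientations, seed)
    vol_true = math.pi * (d / 2.0) ** 2 * L
    area_true = math.pi * d * L + 2.0 * math.pi * (d / 2.0) ** 2
    res = {"dx": dxs, "volume_mae": [], "area_mae": [],
           "volume_sd": [], "area_sd": []}
    for dx in dxs:
        verr, aerr = [], []
        for phi, th in oris:
            m = make_cylinder(L, d, (phi, th))
            m.segmentize()
            g = voxelize(build_csg(m), GridParams(dx=dx, vr=vr),
                         compute_areas=with_areas)
            verr.append(abs(g.total_volume - vol_true))
            if with_areas:
                aerr.append(abs(g.total_surface_area - area_true))
        res["volume_mae"].append(float(np.mean(verr)))
        res["volume_sd"].append(float(np.std(verr)))
        if with_areas:
            res["area_mae"].append(float(np.mean(aerr)))
            res["area_sd"].append(float(np.std(aerr)))
    if len(dxs) > 1:
        res["volume_slope"] = float(
            np.polyfit(np.log(dxs), np.log(res["volume_mae"]), 1)[0]
        )
        if with_areas:
            res["area_slope"] = float(
                np.polyfit(np.log(dxs), np.log(res["area_mae"]), 1)[0]
            )
    return res


def y_voxel_count(dx=0.25) -> int:
    """Stored voxel count for the 30-degree Y geometry."""
    m = make_y()
    m.segmentize()
    g = voxelize(build_csg(m), GridParams(dx=dx), compute_areas=False)
    return len(g)


def line_diffusion_error(dx, L=200.0, d=1.0, plug=(95.0, 105.0), D=1.0,
                         dt=0.025, t_end=100.0):
    """Max abs error vs the erf solution for plug diffusion in a cylinder."""
    m = make_cylinder(L, d)
    m.segmentize()
    g = voxelize(build_csg(m), GridParams(dx=dx), compute_areas=False)
    a, b = plug
    mod = Model3D(
        g,
        [Species("u", d=D,
                 initial=lambda x, y, z: np.where((x >= a) & (x <= b), 1.0, 0.0))],
        params=SimParams(dt=dt),
    )
    mod.run(t_end)
    x = g.centers[:, 0]
    exact = green1d(x, t_end, D, IntervalIC(a, b, 1.0), domain=(0.0, L))
    return float(np.abs(mod.conc["u"] - exact).max())


def point_source_error(diameter=16.0, height=16.0, t_end=5.0, dx=0.25,
                       dt=0.025, D=1.0, cube=2.0, n_points=100, r_max=4.0,
                       seed=0):
    """Max relative error (%) vs the box Green's function near the source.

    A cube of 1 mM (side 2*cube) diffuses inside a reflective cylinder
    large enough that boundaries are negligible at ``t_end``; the relative
    error is evaluated at the voxels containing ``n_points`` random points
    within ``r_max`` of the origin.
    """
    half = height / 2.0
    sec = Section("domain", [Point3D(-half, 0, 0, diameter),
                             Point3D(half, 0, 0, diameter)])
    m = Morphology([sec])
    m.segmentize()
    g = voxelize(build_csg(m), GridParams(dx=dx), compute_areas=False)
    ic = lambda x, y, z: np.where(
        (np.abs(x) <= cube) & (np.abs(y) <= cube) & (np.abs(z) <= cube), 1.0, 0.0
    )
    mod = Model3D(g, [Species("u", d=D, initial=ic)], params=SimParams(dt=dt))
    mod.run(t_end)
    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n_points:
        p = rng.uniform(-r_max, r_max, 3)
        if np.linalg.norm(p) <= r_max:
            pts.append(p)
    pts = np.array(pts)
    vox = np.array([g.voxel_at_point(p) for p in pts])
    ok = vox >= 0
    centers = g.centers[vox[ok]]
    exact = green3d_box(centers, t_end, D, [(-cube, cube)] * 3, 1.0)
    rel = np.abs(mod.conc["u"][vox[ok]] - exact) / exact
    return float(rel.max() * 100.0)


def hybrid_midpoint_analytic(L=153.0, plug=(70.0, 83.0), D=1.0, t=50.0):
    """Closed-form concentration at the cylinder midpoint (mM)."""
    return float(green1d(L / 2.0, t, D, IntervalIC(*plug, 1.0), domain=(0.0, L)))


def _three_section_cylinder(L=153.0, d=2.0, cut1=51.0, cut2=102.0,
                            seg_per_um=2.0):
    a = Section("a", [Point3D(0, 0, 0, d), Point3D(cut1, 0, 0, d)],
                nseg=int(round(cut1 * seg_per_um)))
    b = Section("b", [Point3D(cut1, 0, 0, d), Point3D(cut2, 0, 0, d)],
                nseg=int(round((cut2 - cut1) * seg_per_um)))
    c = Section("c", [Point3D(cut2, 0, 0, d), Point3D(L, 0, 0, d)],
                nseg=int(round((L - cut2) * seg_per_um)))
    b.connect(a, 1.0)
    c.connect(b, 1.0)
    m = Morphology([a, b, c])
    m.segmentize()
    return m, (a, b, c)


def hybrid_error(dx=0.25, vr=2, mode="1d-middle", L=153.0, d=2.0,
                 plug=(70.0, 83.0), D=1.0, dt=0.025, t_end=50.0,
                 seg_per_um=2.0):
    """Max abs error of the volume-weighted concentration profile (mM).

    ``mode`` selects the discretization strategy for the three-section
    cylinder: '1d-middle' (3D outer thirds), '3d-middle', pure '1d' or
    pure '3d'.  The profile pools 1D segment values and per-slab
    volume-weighted 3D means, compared with the erf solution.
    """
    m, (a, b, c) = _three_section_cylinder(L, d, seg_per_um=seg_per_um)
    smap = SolveTypeMap(default=1)
    if mode == "1d-middle":
        smap.set([a, c], 3)
    elif mode == "3d-middle":
        smap.set([b], 3)
    elif mode == "3d":
        smap.set([a, b, c], 3)
    elif mode != "1d":
        raise ValueError(f"unknown mode {mode!r}")
    pa, pb = plug
    sp = Species("u", d=D,
                 initial=lambda x, y, z: np.where((x >= pa) & (x <= pb), 1.0, 0.0))
    model = HybridModel(
        m, smap, sp, GridParams(dx=dx, vr=vr), SimParams(dt=dt),
        initial_1d=lambda pos: np.where((pos >= pa) & (pos <= pb), 1.0, 0.0),
    )
    model.run(t_end)

    positions, values = [], []
    if model.cable is not None:
        positions.append(model.cable.positions())
        values.append(model.cable.conc)
    if model.model3d is not None:
        g = model.model3d.grid
        u = model.model3d.conc["u"]
        V = model.model3d.volumes
        xi = g.keys[:, 0]
        order = np.argsort(xi)
        uniq, start = np.unique(xi[order], return_index=True)
        wsum = np.zeros(uniq.size)
        msum = np.zeros(uniq.size)
        inv = np.searchsorted(uniq, xi)
        np.add.at(wsum, inv, V)
        np.add.at(msum, inv, u * V)
        xcent = np.asarray(g.frame.origin)[0] + (uniq + 0.5) * g.dx
        positions.append(xcent)
        values.append(msum / wsum)
    pos = np.concatenate(positions)
    val = np.concatenate(values)
    exact = green1d(pos, t_end, D, IntervalIC(pa, pb, 1.0), domain=(0.0, L))
    return float(np.abs(val - exact).max())


def conservation_drift(dts=(0.025,), n_steps=100_000, dx=0.25, D=1.0):
    """Relative total-mass drift of diffusion on the Y geometry per dt.

    The trunk starts at 1 uM and the arms at 100 nM; the drift is pure
    round-off accumulation of the conservative scheme.
    """
    out = []
    for dt in dts:
        m = make_y()
        m.segmentize()
        g = voxelize(build_csg(m), GridParams(dx=dx), compute_areas=False)
        trunk_ids = [s.id for s in m.sections[0].segments]
        ic = lambda x, y, z: np.where(x <= 10.0, 1e-3, 1e-4)
        mod = Model3D(g, [Species("u", d=D, initial=ic)], params=SimParams(dt=dt))
        # assign by owning segment rather than position for the arms' overlap
        mod.conc["u"][:] = np.where(
            np.isin(g.seg_id, trunk_ids), 1e-3, 1e-4
        )
        m0 = mod.mass("u")
        for _ in range(int(n_steps)):
            mod.step()
        out.append(abs(mod.mass("u") - m0) / m0)
    return out


def wave_speed_study(n_orientations=5, seed=0, dx=0.25, alpha=0.25, D=1.0,
                     dt=0.025, L=251.0, d=2.0, init_len=50.0,
                     x_start=100.0, x_end=200.0, record_every=20,
                     t_max=700.0, seg_per_um=2.0):
    """Relative wave-speed errors of the scalar bistable front, per orientation.

    Returns the list of relative errors (fractions) against the plane-wave
    speed sqrt(2 D) (1/2 - alpha).  The front position is the farthest 1D
    segment whose volume-weighted mean concentration exceeds 1/2.
    """
    c_true = bistable_wave_speed(alpha, D)
    oris = random_orientations(n_orientations, seed)
    errors = []
    for phi, th in oris:
        nseg = int(round(L * seg_per_um))
        m = make_cylinder(L, d, (phi, th), nseg=nseg)
        m.segmentize()
        g = voxelize(build_csg(m), GridParams(dx=dx), compute_areas=False)
        # axial position of each voxel: projection onto the cylinder axis
        sec = m.sections[0]
        p0 = sec.points[0].xyz
        axis = (sec.points[-1].xyz - p0) / L
        proj = (g.centers - p0) @ axis
        sp = Species("u", d=D, initial=0.0)
        mod = Model3D(g, [sp], params=SimParams(dt=dt))
        u = mod.conc["u"]
        u[:] = np.where(proj <= init_len, 1.0, 0.0)
        seg_pos = np.array([s.root_distance for s in m.segments])
        times, profiles = [], []
        while mod.t < t_max:
            for _ in range(record_every):
                # operator split: implicit reaction, then DG-ADI diffusion
                bistable_backward_euler(u, alpha, dt,
                                        mod.params.reaction_tol,
                                        mod.params.reaction_max_iter)
                dg_adi_step(u, g, mod.lines, D, dt, mod.volumes, mod._ws)
                mod.t += dt
            prof = segment_feedback(g, u, "all", mod.volumes)
            times.append(mod.t)
            profiles.append(prof)
            above = np.flatnonzero(prof > 0.5)
            if above.size and seg_pos[above[-1]] > x_end + 2.0:
                break
        speed = track_wave_front(times, seg_pos, np.array(profiles),
                                 0.5, x_start, x_end)
        errors.append(abs(speed - c_true) / c_true)
    return errors


def spine_study(dx=0.05, dt=0.025, D=0.01, t_end=1.0, angles=(30.0, 180.0)):
    """Peak dendritic concentration for spine pairs at different separations.

    Two spines filled to 2 mM release into a clean dendrite; returns a dict
    angle -> (peak concentration mM, peak time ms) plus the ratio (%) of
    the first angle's peak to the second's.
    """
    results = {}
    for ang in angles:
        m = make_spiny(angle_sep_deg=ang)
        m.segmentize()
        g = voxelize(build_csg(m), GridParams(dx=dx), compute_areas=False)
        dend_ids = [s.id for s in m.sections[0].segments]
        in_dend = np.isin(g.seg_id, dend_ids)
        mod = Model3D(g, [Species("u", d=D, initial=0.0)], params=SimParams(dt=dt))
        mod.conc["u"][:] = np.where(in_dend, 0.0, 2.0)
        peak, peak_t = 0.0, 0.0
        for _ in range(int(round(t_end / dt))):
            mod.step()
            cmax = float(mod.conc["u"][in_dend].max())
            if cmax > peak:
                peak, peak_t = cmax, mod.t
        results[ang] = (peak, peak_t)
    ratio = 100.0 * results[angles[0]][0] / results[angles[1]][0]
    results["ratio_percent"] = ratio
    return results


def hh_soma_study(d_na, dx=0.5, L=10.0, diam=10.0, i_inj=0.1, t_end=100.0,
                  dt=0.025, nai0=10.0, nao=140.0, feedback="surface",
                  record_every=4, solve_3d=True):
    """Sodium accumulation in an HH soma under constant current injection.

    Returns (times, v_trace, na_trace) where ``na_trace`` is the surface
    (or well-mixed 1D when ``solve_3d=False``) sodium concentration seen by
    the membrane, with the sodium reversal potential recomputed from it
    every step.
    """
    from .core import FARADAY, distribute_segment_current

    area_1d = math.pi * diam * L  # um^2, lateral frusta area
    hh = HHState(area=area_1d, ena=nernst(nai0, nao))
    if solve_3d:
        m = make_cylinder(L, diam)
        m.segmentize()
        g = voxelize(build_csg(m), GridParams(dx=dx))
        mod = Model3D(g, [Species("na", d=d_na, z=1, initial=nai0)],
                      params=SimParams(dt=dt, feedback=feedback))
        seg_id = m.segments[0].id
    else:
        vol = math.pi * (diam / 2.0) ** 2 * L
        nai = nai0
    times, vs, nas = [], [], []
    nsteps = int(round(t_end / dt))
    for k in range(nsteps):
        if solve_3d:
            na_seen = float(mod.segment_concentration("na")[seg_id])
        else:
            na_seen = nai
        hh.ena = nernst(na_seen, nao)
        i_na, _, _ = hh_advance(hh, i_inj, dt)
        if solve_3d:
            rates = distribute_segment_current(i_na, 1, seg_id, mod.grid,
                                               mod.volumes)
            mod.conc["na"] += rates * dt
            mod.step()
        else:
            nai += -i_na * 1e6 / (1.0 * FARADAY * vol) * dt
        if k % record_every == 0:
            times.append((k + 1) * dt)
            vs.append(hh.v)
            nas.append(na_seen)
    return np.array(times), np.array(vs), np.array(nas)
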