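import math

import numpy as np
import pytest

from voxelrxd.csg import Frustum, JoinSphere, build_csg
from voxelrxd.fixtures import make_cylinder, make_stepped
from voxelrxd.voxelize import (
    GridFrame,
    GridParams,
    export_grid,
    import_png_stack,
    voxelize,
    voxelize_object,
)


class TestSingleObjects:
    def test_aligned_frustum_volume_converges(self):
        true = 5.0 * math.pi
        errs = []
        for dx in (0.5, 0.25, 0.125):
            m = make_cylinder(5.0, 2.0)
            m.segmentize()
            g = voxelize(build_csg(m), GridParams(dx=dx, vr=2),
                         compute_areas=False)
            errs.append(abs(g.total_volume - true))
        assert errs[2] < errs[0]
        assert errs[2] < 0.01 * true

    def test_sphere_volume(self):
        r = 2.0
        sp = JoinSphere(np.zeros(3), r)
        g = voxelize([sp], GridParams(dx=r / 10, vr=2), compute_areas=False)
        assert g.total_volume == pytest.approx(4 * math.pi * r ** 3 / 3, rel=0.05)

    def test_object_outside_frame_is_empty(self):
        fr = Frustum(np.array([100.0, 0, 0]), np.array([105.0, 0, 0]), 1, 1, None)
        frame = GridFrame(0.5, (0.0, 0.0, 0.0), (10, 10, 10))
        ov = voxelize_object(fr, GridParams(dx=0.5), frame=frame)
        assert len(ov.voxel_keys) == 0

    def test_rows_are_contiguous_runs(self):
        m = make_cylinder(4.0, 2.0, (0.3, 0.9))
        m.segmentize()
        obj = build_csg(m)[0]
        ov = voxelize_object(obj, GridParams(dx=0.25))
        rows = ov.rows()
        assert rows
        total = sum(hi - lo + 1 for _, _, lo, hi in rows)
        assert total == len(ov.voxel_keys)


class TestMerge:
    def test_idempotent_merge(self):
        m = make_cylinder(5.0, 2.0, (0.7, 1.1))
        m.segmentize()
        obj = build_csg(m)[0]
        g1 = voxelize([obj], GridParams(dx=0.25), compute_areas=False)
        import copy

        g2 = voxelize([obj, copy.deepcopy(obj)], GridParams(dx=0.25),
                      compute_areas=False)
        assert np.array_equal(g1.keys, g2.keys)
        assert g1.frac == pytest.approx(g2.frac)

    def test_stepped_segment_boundaries(self):
        """Surface voxels project onto the analytic segment boundaries."""
        m = make_stepped()
        m.segmentize()
        g = voxelize(build_csg(m), GridParams(dx=0.125), compute_areas=False)
        x = g.centers[:, 0]
        # wide cylinder: boundaries every 5/9 um; narrow: every 1 um
        for seg in m.sections[0].segments:
            sel = g.seg_id == seg.id
            assert sel.any()
            assert x[sel].min() >= seg.arc0 - g.dx
            assert x[sel].max() <= seg.arc1 + g.dx
        for seg in m.sections[1].segments:
            sel = g.seg_id == seg.id
            assert sel.any()
            lo, hi = 5.0 + seg.arc0, 5.0 + seg.arc1
            assert x[sel].min() >= lo - g.dx
            assert x[sel].max() <= hi + g.dx

    def test_no_interior_voxel_flagged_surface(self, y_grid):
        _, g = y_grid
        # interior voxels have full volume and no area
        interior = ~g.is_surface
        assert np.all(g.frac[interior] == 1.0)
        assert np.all(g.area[interior] == 0.0)

    def test_surface_closure(self, y_grid):
        """Interior voxels are never 6-adjacent to an unstored position."""
        _, g = y_grid
        stored = set(map(tuple, g.keys))
        interior = g.keys[~g.is_surface]
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            for ijk in interior[:: max(1, len(interior) // 500)]:
                assert (ijk[0] + di, ijk[1] + dj, ijk[2] + dk) in stored

    def test_root_closest_assignment(self, y_grid):
        m, g = y_grid
        trunk = m.sections[0].segments[0]
        # voxels at the branch point belong to the trunk (closest to root)
        branch = np.array([10.0, 0.0, 0.0])
        idx = g.voxel_at_point(branch - 0.3)
        assert g.seg_id[idx] == trunk.id


class TestPartialVolumes:
    def test_interior_is_one(self, small_cylinder_grid):
        _, g = small_cylinder_grid
        assert np.all(g.frac[~g.is_surface] == 1.0)

    def test_never_zero(self, small_cylinder_grid):
        _, g = small_cylinder_grid
        assert np.all(g.frac > 0.0)

    def test_half_space_midplane_fraction(self):
        """A face-parallel cut through the test-point midplane gives 2/3."""
        # half space x <= 0.25 over a voxel [0, 0.5]^3: test-point planes at
        # 0, 0.25, 0.5; boundary points count as inside -> 18/27
        fr = Frustum(np.array([-10.0, 0.25, 0.25]), np.array([0.25, 0.25, 0.25]),
                     20.0, 20.0, None)
        g = voxelize([fr], GridParams(dx=0.5, vr=2), compute_areas=False)
        vox = g.voxel_at_point((0.1, 0.25, 0.25))
        assert g.frac[vox] == pytest.approx(2.0 / 3.0)

    def test_vr_refinement_improves_volume(self):
        m = make_cylinder(5.0, 2.0, (0.7, 1.1))
        m.segmentize()
        objs = build_csg(m)
        true = 5 * math.pi
        errs = {
            vr: abs(
                voxelize(objs, GridParams(dx=0.25, vr=vr),
                         compute_areas=False).total_volume - true
            )
            for vr in (1, 2, 6)
        }
        assert errs[6] < errs[1]


class TestSurfaceArea:
    def test_half_space_area_is_dx_squared(self):
        """An axis-aligned cut through voxel mid-edges: dx^2 per cut voxel."""
        fr = Frustum(np.array([-10.0, 0.25, 0.25]), np.array([0.25, 0.25, 0.25]),
                     20.0, 20.0, None)
        g = voxelize([fr], GridParams(dx=0.5))
        cut = g.area > 0
        # cut voxels well inside the end-face see exactly one planar patch
        centers = g.centers[cut]
        inner = (np.abs(centers[:, 1] - 0.25) < 9.0) & \
                (np.abs(centers[:, 2] - 0.25) < 9.0) & \
                (np.abs(centers[:, 0] - 0.25) < 0.5)
        assert inner.any()
        assert g.area[cut][inner] == pytest.approx(0.25, abs=1e-9)

    def test_cylinder_area_converges_from_below(self):
        true = 12 * math.pi
        vals = []
        for dx in (0.5, 0.25, 0.125):
            m = make_cylinder(5.0, 2.0, (0.7, 1.1))
            m.segmentize()
            g = voxelize(build_csg(m), GridParams(dx=dx))
            vals.append(g.total_surface_area)
        assert vals[0] < vals[1] < vals[2] < true  # marching cubes underestimates
        assert vals[2] == pytest.approx(true, rel=0.02)


class TestExport:
    def test_table_rows(self, small_cylinder_grid, tmp_path):
        import pandas as pd

        _, g = small_cylinder_grid
        out = tmp_path / "mesh.tsv"
        export_grid(g, out, fmt="table")
        df = pd.read_csv(out, sep="\t")
        assert len(df) == len(g)

    def test_png_round_trip(self, small_cylinder_grid, tmp_path):
        _, g = small_cylinder_grid
        files = export_grid(g, tmp_path / "stack", fmt="png_stack")
        keys = import_png_stack(files)
        assert keys == set(map(tuple, g.keys))

    def test_empty_grid_export_fails(self, small_cylinder_grid, tmp_path):
        _, g = small_cylinder_grid
        import copy

        empty = copy.copy(g)
        empty.keys = empty.keys[:0]
        with pytest.raises(ValueError):
            export_grid(empty, tmp_path / "x", fmt="table")


def test_memory_is_sparse(y_grid):
    """Stored voxels are far fewer than the bounding box voxels."""
    _, g = y_grid
    bbox = np.prod(np.asarray(g.frame.nvox))
    assert len(g) < 0.35 * bbox


def test_partial_volumes_beat_naive_counting():
    """Counting full voxels overestimates; partial volumes are far closer."""
    from voxelrxd.fixtures import make_cylinder

    m = make_cylinder(5.0, 2.0, (0.7, 1.1))
    m.segmentize()
    g = voxelize(build_csg(m), GridParams(dx=0.25), compute_areas=False)
    true = 5.0 * math.pi
    naive_err = len(g) * 0.25 ** 3 - true
    pv_err = g.total_volume - true
    assert naive_err > 0  # full-voxel counting always overestimates
    assert abs(pv_err) < 0.05 * abs(naive_err)
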