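import types

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tests_helpers import dense_cn_step
from voxelrxd.core import (
    MOLECULES_PER_MM_UM3,
    Model3D,
    PointFlux,
    Rate,
    SimParams,
    Species,
    build_lines,
    dg_adi_step,
    distribute_segment_current,
    reaction_step,
    segment_feedback,
    total_mass,
)
from voxelrxd.csg import build_csg
from voxelrxd.fixtures import make_cylinder
from voxelrxd.voxelize import GridParams, voxelize


def fake_grid(keys, dx=0.5, frac=None):
    keys = np.asarray(keys, dtype=np.int64)
    vols = (frac if frac is not None else np.ones(len(keys))) * dx ** 3
    return types.SimpleNamespace(keys=keys, dx=dx, volumes=vols)


class TestLines:
    def test_block_lines(self, block_grid):
        lines = build_lines(block_grid)
        for a in range(3):
            assert list(lines.lengths(a)) == [4] * 16

    def test_l_shape_brute_force(self):
        keys = [(i, 0, 0) for i in range(3)] + [(2, j, 0) for j in (1, 2)]
        lines = build_lines(fake_grid(keys))
        assert sorted(lines.lengths(0)) == [1, 1, 3]
        assert sorted(lines.lengths(1)) == [1, 1, 3]
        assert sorted(lines.lengths(2)) == [1, 1, 1, 1, 1]

    def test_partition_property(self, y_grid):
        _, g = y_grid
        lines = build_lines(g)
        for a in range(3):
            assert lines.lengths(a).sum() == len(g)
            assert sorted(lines.order[a]) == list(range(len(g)))


class TestReactionStep:
    def _single(self, u0, rate, dt, dfn=None):
        grid = fake_grid([(0, 0, 0)])
        concs = {"u": np.array([u0])}
        species = {"u": Species("u")}
        reaction_step(concs, species, [Rate("u", rate, dfn=dfn)], [], dt,
                      grid.volumes)
        return concs["u"][0]

    def test_no_reactions_is_identity(self):
        grid = fake_grid([(0, 0, 0)])
        concs = {"u": np.array([0.7])}
        reaction_step(concs, {"u": Species("u")}, [], [], 0.025, grid.volumes)
        assert concs["u"][0] == 0.7

    def test_backward_euler_decay(self):
        # u' = -u, dt = 0.025: implicit update is u0 / 1.025
        u1 = self._single(1.0, lambda c: -c["u"], 0.025)
        assert u1 == pytest.approx(1.0 / 1.025, abs=1e-12)

    @pytest.mark.parametrize("u0", [0.0, 0.25, 1.0])
    def test_bistable_fixed_points(self, u0):
        alpha = 0.25
        u1 = self._single(u0, lambda c: -c["u"] * (1 - c["u"]) * (alpha - c["u"]),
                          0.025)
        assert u1 == pytest.approx(u0, abs=1e-10)

    def test_parameters_untouched(self):
        grid = fake_grid([(0, 0, 0)])
        concs = {"u": np.array([1.0]), "p": np.array([2.0])}
        species = {"u": Species("u"), "p": Species("p", kind="parameter")}
        reaction_step(concs, species,
                      [Rate("u", lambda c: -c["p"] * c["u"])], [], 0.025,
                      grid.volumes)
        assert concs["p"][0] == 2.0
        assert concs["u"][0] == pytest.approx(1.0 / 1.05)

    def test_analytic_derivative_matches_fd(self):
        alpha = 0.25
        rate = lambda c: -c["u"] * (1 - c["u"]) * (alpha - c["u"])
        dfn = lambda c: -((1 - c["u"]) * (alpha - c["u"])
                          - c["u"] * (alpha - c["u"]) - c["u"] * (1 - c["u"]))
        assert self._single(0.6, rate, 0.1) == pytest.approx(
            self._single(0.6, rate, 0.1, dfn=dfn), abs=1e-11
        )


class TestDiffusion:
    def test_uniform_is_fixed_point(self, y_grid):
        _, g = y_grid
        lines = build_lines(g)
        u = np.full(len(g), 0.37)
        dg_adi_step(u, g, lines, 1.0, 0.025)
        assert u == pytest.approx(np.full(len(g), 0.37), abs=1e-13)

    def test_dense_oracle_splitting_order(self, block_grid):
        """One DG-ADI step matches dense Crank-Nicolson to O(dt^3)."""
        lines = build_lines(block_grid)
        rng = np.random.default_rng(3)
        u0 = rng.uniform(0.2, 0.8, 64)
        diffs = []
        for dt in (0.02, 0.01, 0.005):
            ucn = dense_cn_step(lines, block_grid.volumes, u0, 1.0, dt)
            udg = u0.copy()
            dg_adi_step(udg, block_grid, lines, 1.0, dt, block_grid.volumes)
            diffs.append(np.abs(udg - ucn).max())
        assert diffs[0] > diffs[1] > diffs[2]
        # better than O(dt^2): halving dt shrinks the gap by > 4x
        assert diffs[0] / diffs[1] > 4.0
        assert diffs[1] / diffs[2] > 4.0

    def test_maximum_principle(self, y_grid):
        _, g = y_grid
        rng = np.random.default_rng(11)
        mod = Model3D(g, [Species("u", d=1.0, initial=0.0)])
        mod.conc["u"][:] = rng.uniform(0.0, 1.0, len(g))
        lo, hi = mod.conc["u"].min(), mod.conc["u"].max()
        for _ in range(100):
            mod.step()
        assert mod.conc["u"].min() >= lo - 1e-10
        assert mod.conc["u"].max() <= hi + 1e-10

    def test_conservation_short_run(self, y_grid):
        _, g = y_grid
        mod = Model3D(
            g, [Species("u", d=1.0,
                        initial=lambda x, y, z: np.where(x < 10, 1e-3, 1e-4))]
        )
        m0 = mod.mass("u")
        for _ in range(2000):
            mod.step()
        assert abs(mod.mass("u") - m0) / m0 < 1e-10

    def test_negative_diffusion_rejected(self, y_grid):
        _, g = y_grid
        lines = build_lines(g)
        with pytest.raises(ValueError):
            dg_adi_step(np.zeros(len(g)), g, lines, -1.0, 0.025)

    @given(n=st.integers(2, 12))
    @settings(max_examples=20, deadline=None)
    def test_thomas_matches_dense_solver(self, n):
        """The per-line tridiagonal solve agrees with a dense solve."""
        from voxelrxd._kernels import axis_solve

        rng = np.random.default_rng(n)
        V = rng.uniform(0.1, 2.0, n)
        ge = np.concatenate([rng.uniform(0.05, 1.0, n - 1), [0.0]])
        rhs = rng.uniform(-1, 1, n)
        c = 0.3
        A = np.diag(V.astype(float))
        for i in range(n - 1):
            A[i, i] += c * ge[i]
            A[i, i + 1] -= c * ge[i]
            A[i + 1, i + 1] += c * ge[i]
            A[i + 1, i] -= c * ge[i]
        expect = np.linalg.solve(A, rhs)
        out = np.zeros(n)
        order = np.arange(n, dtype=np.int64)
        ptr = np.array([0, n], dtype=np.int64)
        axis_solve(rhs, V, order, ptr, ge, c, out, np.empty(n), np.empty(n))
        assert out == pytest.approx(expect, rel=1e-9)


class TestCurrentsAndFeedback:
    def test_single_surface_voxel_gets_all(self, small_cylinder_grid):
        _, g = small_cylinder_grid
        seg = g.segments[0]
        rates = distribute_segment_current(0.1, 1, seg.id, g)
        total = np.dot(rates, g.volumes)  # mM um^3/ms
        # 0.1 nA inward for z=1: |I|/F = 1.0364e-15 mol/s = 1.0364 mM um^3/ms
        assert total == pytest.approx(-0.1e-9 / 96485.0 * 1e18 / 1e3, rel=1e-9)

    def test_proportional_shares(self, small_cylinder_grid):
        _, g = small_cylinder_grid
        seg = g.segments[0]
        rates = distribute_segment_current(1.0, 1, seg.id, g)
        mass_rates = rates * g.volumes
        sel = (g.seg_id == seg.id) & (g.area > 0)
        ratio = mass_rates[sel] / g.area[sel]
        assert np.allclose(ratio, ratio[0])

    def test_no_surface_voxels_is_error(self, small_cylinder_grid):
        _, g = small_cylinder_grid
        with pytest.raises(ValueError):
            distribute_segment_current(1.0, 1, 9999, g)

    def test_feedback_uniform(self, small_cylinder_grid):
        _, g = small_cylinder_grid
        u = np.full(len(g), 3.5)
        for mode in ("surface", "all"):
            vals = segment_feedback(g, u, mode)
            assert vals[g.segments[0].id] == pytest.approx(3.5)

    def test_feedback_weighted_mean(self):
        g = fake_grid([(0, 0, 0), (1, 0, 0)], dx=1.0,
                      frac=np.array([0.25, 0.75]))
        g.seg_id = np.array([0, 0])
        g.is_surface = np.array([True, True])
        g.area = np.array([1.0, 1.0])
        vals = segment_feedback(g, np.array([0.0, 4.0]), "all", g.volumes)
        assert vals[0] == pytest.approx(3.0)


class TestMassAndFluxes:
    def test_unit_conversion(self):
        g = fake_grid([(0, 0, 0)], dx=1.0)
        assert total_mass(np.array([1.0]), g, g.volumes) == pytest.approx(1e-18)
        assert MOLECULES_PER_MM_UM3 == pytest.approx(6.02214076e5)

    def test_point_flux_mass_independent_of_discretization(self):
        """The same total mass enters regardless of dx and dt."""
        added = {}
        for dx, dt in ((0.5, 0.025), (0.25, 0.025), (0.5, 0.0125)):
            m = make_cylinder(4.0, 2.0)
            m.segmentize()
            g = voxelize(build_csg(m), GridParams(dx=dx), compute_areas=False)
            mod = Model3D(g, [Species("u", d=1.0, initial=0.0)],
                          fluxes=[PointFlux("u", g.voxel_at_point((2, 0, 0)),
                                            1e4)],
                          params=SimParams(dt=dt))
            mod.run(1.0)
            added[(dx, dt)] = mod.mass("u") * MOLECULES_PER_MM_UM3 / 1e-18
        vals = list(added.values())
        # 1e4 molecules/ms for 1 ms = 1e4 molecules
        assert vals == pytest.approx([1e4] * 3, rel=1e-9)

    def test_per_second_units(self):
        pf = PointFlux("u", 0, 500.0, units="/s")
        assert pf.molecules_per_ms(0.0) == pytest.approx(0.5)
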