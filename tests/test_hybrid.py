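import numpy as np
import pytest

from voxelrxd.core import Species
from voxelrxd.hybrid import Cable1D, HybridModel, SolveTypeMap
from voxelrxd.morphology import Morphology, Point3D, Section
from voxelrxd.oracles import IntervalIC, green1d
from voxelrxd.voxelize import GridParams


def three_sections(L=30.0, d=2.0, nseg=20):
    a = Section("a", [Point3D(0, 0, 0, d), Point3D(L / 3, 0, 0, d)], nseg=nseg)
    b = Section("b", [Point3D(L / 3, 0, 0, d), Point3D(2 * L / 3, 0, 0, d)],
                nseg=nseg)
    c = Section("c", [Point3D(2 * L / 3, 0, 0, d), Point3D(L, 0, 0, d)],
                nseg=nseg)
    b.connect(a, 1.0)
    c.connect(b, 1.0)
    m = Morphology([a, b, c])
    m.segmentize()
    return m, (a, b, c)


class TestSolveTypeMap:
    def test_last_assignment_wins(self):
        m, (a, b, c) = three_sections()
        smap = SolveTypeMap(default=1)
        smap.set([a, b], 3)
        smap.set([b], 1)
        assert smap.dimension(a) == 3
        assert smap.dimension(b) == 1
        assert smap.dimension(c) == 1

    def test_invalid_dimension(self):
        with pytest.raises(ValueError):
            SolveTypeMap().set([], 2)


class TestJunctions:
    def test_all_3d_has_no_junctions(self):
        m, (a, b, c) = three_sections()
        smap = SolveTypeMap(default=3)
        model = HybridModel(m, smap, Species("u", d=1.0),
                            GridParams(dx=0.25))
        assert model.junctions == []
        assert model.cable is None

    def test_junction_voxels_tile_the_disc(self):
        m, (a, b, c) = three_sections()
        smap = SolveTypeMap(default=1)
        smap.set([a], 3)
        model = HybridModel(m, smap, Species("u", d=1.0),
                            GridParams(dx=0.25))
        assert len(model.junctions) == 1
        j = model.junctions[0]
        dx = 0.25
        n_expected = np.pi * 1.0 ** 2 / dx ** 2  # disc area over voxel faces
        assert n_expected * 0.7 <= len(j.voxels) <= n_expected * 2.2
        # the boundary voxels sit on the cut plane
        x = model.model3d.grid.centers[j.voxels, 0]
        assert np.all(np.abs(x - 10.0) <= dx)

    def test_full_voxel_exchange_area_is_face(self):
        m, (a, b, c) = three_sections()
        smap = SolveTypeMap(default=1)
        smap.set([a], 3)
        model = HybridModel(m, smap, Species("u", d=1.0),
                            GridParams(dx=0.25))
        j = model.junctions[0]
        full = np.isclose(model.model3d.volumes[j.voxels], 0.25 ** 3)
        assert full.any()
        assert j.areas[full] == pytest.approx(0.25 ** 2)
        # distance = dx/2 + half the 1D segment length
        seg_len = j.segment.length
        assert j.distances[0] == pytest.approx(0.125 + seg_len / 2)


class TestExchange:
    def _model(self, dx=0.25):
        m, (a, b, c) = three_sections()
        smap = SolveTypeMap(default=1)
        smap.set([a, c], 3)
        sp = Species("u", d=1.0,
                     initial=lambda x, y, z: np.where(x <= 10.0, 1.0, 0.0))
        return HybridModel(
            m, smap, sp, GridParams(dx=dx),
            initial_1d=lambda pos: np.zeros_like(pos),
        )

    def test_equal_concentrations_no_flux(self):
        model = self._model()
        model.model3d.conc["u"][:] = 0.5
        model.cable.conc[:] = 0.5
        m0 = model.mass()
        model.step()
        assert model.model3d.conc["u"] == pytest.approx(0.5, abs=1e-12)
        assert model.cable.conc == pytest.approx(0.5, abs=1e-12)
        assert model.mass() == pytest.approx(m0, rel=1e-12)

    def test_exchange_antisymmetry(self):
        from voxelrxd.hybrid import junction_exchange

        model = self._model()
        m3d_0 = model.model3d.mass("u")
        m1d_0 = model.cable.mass()
        junction_exchange(model.junctions, model.cable,
                          model.model3d.conc["u"], model.model3d.volumes,
                          1.0, 0.025)
        d3 = model.model3d.mass("u") - m3d_0
        d1 = model.cable.mass() - m1d_0
        assert d3 == pytest.approx(-d1, rel=1e-12)
        assert d3 != 0.0

    def test_hybrid_conservation(self):
        model = self._model()
        m0 = model.mass()
        model.run(20.0)
        assert abs(model.mass() - m0) / m0 < 1e-10

    def test_junction_free_equals_pure_domains(self):
        """With one domain empty the hybrid step is the plain 3D step."""
        m, _ = three_sections()
        smap = SolveTypeMap(default=3)
        sp = Species("u", d=1.0,
                     initial=lambda x, y, z: np.where(x <= 10.0, 1.0, 0.0))
        hyb = HybridModel(m, smap, sp, GridParams(dx=0.25))
        from voxelrxd.core import Model3D

        ref = Model3D(hyb.model3d.grid, [sp])
        hyb.run(5.0)
        ref.run(5.0)
        assert hyb.model3d.conc["u"] == pytest.approx(ref.conc["u"], abs=1e-13)


class TestCable1D:
    def test_uniform_fixed_point(self):
        m, _ = three_sections()
        cable = Cable1D(m.sections, m)
        cable.conc[:] = 2.0
        cable.step(1.0, 0.025)
        assert cable.conc == pytest.approx(2.0, abs=1e-12)

    def test_mass_conserved(self):
        m, _ = three_sections()
        cable = Cable1D(m.sections, m)
        pos = cable.positions()
        cable.conc[:] = np.where((pos > 10) & (pos < 20), 1.0, 0.0)
        m0 = cable.mass()
        for _ in range(4000):
            cable.step(1.0, 0.025)
        assert cable.mass() == pytest.approx(m0, rel=1e-12)

    def test_pure_1d_matches_erf_solution(self):
        """Backward-Euler cable diffusion tracks the interval solution."""
        L = 153.0
        sec = Section("s", [Point3D(0, 0, 0, 2), Point3D(L, 0, 0, 2)],
                      nseg=int(2 * L))
        m = Morphology([sec])
        m.segmentize()
        cable = Cable1D([sec], m)
        pos = cable.positions()
        cable.conc[:] = np.where((pos >= 70) & (pos <= 83), 1.0, 0.0)
        for _ in range(2000):
            cable.step(1.0, 0.025)
        exact = green1d(pos, 50.0, 1.0, IntervalIC(70, 83, 1.0),
                        domain=(0.0, L))
        assert np.abs(cable.conc - exact).max() < 5e-4


def test_growing_3d_region_converges_to_pure_3d():
    """Enlarging the 3D subdomain leaves region-of-interest values unchanged.

    With the junction moved far from the observed region, the hybrid result
    matches the pure-3D result to solver precision.
    """
    def observable(dims):
        a = Section("a", [Point3D(0, 0, 0, 2), Point3D(10, 0, 0, 2)], nseg=20)
        b = Section("b", [Point3D(10, 0, 0, 2), Point3D(20, 0, 0, 2)], nseg=20)
        c = Section("c", [Point3D(20, 0, 0, 2), Point3D(30, 0, 0, 2)], nseg=20)
        b.connect(a, 1.0)
        c.connect(b, 1.0)
        mo = Morphology([a, b, c])
        mo.segmentize()
        smap = SolveTypeMap(default=1)
        secs = {"a": a, "b": b, "c": c}
        smap.set([secs[k] for k in dims], 3)
        sp = Species("u", d=1.0,
                     initial=lambda x, y, z: np.where(x <= 5, 1.0, 0.0))
        h = HybridModel(mo, smap, sp, GridParams(dx=0.25),
                        initial_1d=lambda pos: np.where(pos <= 5, 1.0, 0.0))
        h.run(10.0)
        g = h.model3d.grid
        u = h.model3d.conc["u"]
        V = h.model3d.volumes
        sel = g.centers[:, 0] <= 5.0
        return float((u[sel] * V[sel]).sum() / V[sel].sum())

    near = observable("a")      # junction right next to the plug
    far = observable("ab")      # junction 15 um away
    full = observable("abc")    # no junction at all
    assert abs(far - full) < abs(near - full)
    assert far == pytest.approx(full, abs=1e-6)
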