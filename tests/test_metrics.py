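"""Per-cell metrics: area, deformation sum, strain energy, epicenter, contractility."""

import numpy as np
import pytest

from tfm.displacement import DisplacementField
from tfm.metrics import (
    CellMask,
    cell_area,
    contractility,
    deformation_sum,
    force_epicenter,
    strain_energy,
    summarize,
)
from tfm.traction import TractionField

PS = 0.46  # um/px


def _square_mask(size_px=100, frame=512):
    raster = np.zeros((frame, frame), dtype=bool)
    lo = (frame - size_px) // 2
    raster[lo : lo + size_px, lo : lo + size_px] = True
    return CellMask(cell_boundary=raster, traction_area=raster, pixel_size=PS)


def _full_mask(extent_px=512):
    raster = np.ones((extent_px, extent_px), dtype=bool)
    return CellMask(cell_boundary=raster, traction_area=raster, pixel_size=PS)


def _fields(n=100, h=2.0):
    coords = np.arange(n) * h
    xg, yg = np.meshgrid(coords, coords)
    return xg, yg


def _radial_traction(xg, yg, center, t_mag, r_in, r_out, sign=-1.0):
    dx, dy = xg - center[0], yg - center[1]
    r = np.hypot(dx, dy)
    inside = (r >= r_in) & (r <= r_out) & (r > 0)
    tx = np.where(inside, sign * t_mag * dx / np.where(r > 0, r, 1), 0.0)
    ty = np.where(inside, sign * t_mag * dy / np.where(r > 0, r, 1), 0.0)
    return tx, ty


class TestCellArea:
    def test_square_mask_area(self):
        assert cell_area(_square_mask(100)) == pytest.approx(2116.0)

    def test_single_pixel(self):
        raster = np.zeros((64, 64), dtype=bool)
        raster[3, 3] = True
        mask = CellMask(cell_boundary=raster, traction_area=raster, pixel_size=PS)
        assert cell_area(mask) == pytest.approx(0.2116)

    def test_empty_mask_rejected_at_construction(self):
        raster = np.zeros((64, 64), dtype=bool)
        with pytest.raises(ValueError):
            CellMask(cell_boundary=raster, traction_area=raster, pixel_size=PS)


class TestDeformationSum:
    def test_zero_field(self):
        xg, yg = _fields()
        disp = DisplacementField(x=xg, y=yg, u=np.zeros_like(xg),
                                 v=np.zeros_like(xg),
                                 valid=np.ones_like(xg, dtype=bool),
                                 window_size=4.0, overlap=2.0, pixel_size=PS)
        assert deformation_sum(disp, _full_mask()) == 0.0

    def test_uniform_magnitude_counts_nodes(self):
        xg, yg = _fields()
        disp = DisplacementField(x=xg, y=yg, u=np.full_like(xg, 0.3),
                                 v=np.full_like(xg, 0.4),
                                 valid=np.ones_like(xg, dtype=bool),
                                 window_size=4.0, overlap=2.0, pixel_size=PS)
        mask = _full_mask()
        # every node inside the raster contributes |d| = 0.5
        from tfm.metrics import _grid_membership

        n_in = _grid_membership(mask.traction_area, xg, yg, PS).sum()
        assert deformation_sum(disp, mask) == pytest.approx(0.5 * n_in)

    def test_disjoint_mask_rejected(self):
        xg, yg = _fields(10, 2.0)
        disp = DisplacementField(x=xg + 5000, y=yg + 5000, u=np.ones_like(xg),
                                 v=np.ones_like(xg),
                                 valid=np.ones_like(xg, dtype=bool),
                                 window_size=4.0, overlap=2.0, pixel_size=PS)
        with pytest.raises(ValueError):
            deformation_sum(disp, _square_mask())


class TestStrainEnergy:
    def test_aligned_uniform_closed_form(self):
        # |t| = 100 Pa aligned with |d| = 1 um over 1000 um^2 -> 0.05 pJ
        h = 2.0
        xg, yg = _fields(100, h)
        n_target = int(round(1000.0 / h**2))  # 250 nodes = 1000 um^2
        flat = np.zeros(xg.size, dtype=bool)
        flat[:n_target] = True
        sel = flat.reshape(xg.shape)
        raster = np.zeros((512, 512), dtype=bool)
        rows = np.round(yg[sel] / PS).astype(int)
        cols = np.round(xg[sel] / PS).astype(int)
        keep = (rows < 512) & (cols < 512)
        raster[rows[keep], cols[keep]] = True
        mask = CellMask(cell_boundary=raster, traction_area=raster, pixel_size=PS)

        disp = DisplacementField(x=xg, y=yg, u=np.ones_like(xg),
                                 v=np.zeros_like(xg),
                                 valid=np.ones_like(xg, dtype=bool),
                                 window_size=4.0, overlap=2.0, pixel_size=PS)
        trac = TractionField(x=xg, y=yg, tx=np.full_like(xg, 100.0),
                             ty=np.zeros_like(xg), grid_spacing=h)
        n_in = keep.sum()
        expect = 0.5 * 100.0 * 1e-6 * n_in * (h * 1e-6) ** 2 * 1e12
        assert strain_energy(disp, trac, mask) == pytest.approx(expect, rel=1e-9)
        # and for the nominal 1000 um^2 that is 0.05 pJ
        assert expect == pytest.approx(0.05 * n_in / n_target, rel=1e-9)

    def test_zero_displacement_zero_energy(self):
        xg, yg = _fields()
        disp = DisplacementField(x=xg, y=yg, u=np.zeros_like(xg),
                                 v=np.zeros_like(xg),
                                 valid=np.ones_like(xg, dtype=bool),
                                 window_size=4.0, overlap=2.0, pixel_size=PS)
        trac = TractionField(x=xg, y=yg, tx=np.full_like(xg, 123.0),
                             ty=np.zeros_like(xg), grid_spacing=2.0)
        assert strain_energy(disp, trac, _full_mask()) == 0.0

    def test_plane_wave_quarter_rule(self):
        # U = 1/4 f0 u0 A for in-phase cosines (spatial mean of cos^2 = 1/2)
        h = 2.0
        n = 100
        xg, yg = _fields(n, h)
        lam = 40.0
        f0, u0 = 94.25, 0.1
        trac = TractionField(x=xg, y=yg,
                             tx=f0 * np.cos(2 * np.pi * xg / lam),
                             ty=np.zeros_like(xg), grid_spacing=h)
        disp = DisplacementField(x=xg, y=yg,
                                 u=u0 * np.cos(2 * np.pi * xg / lam),
                                 v=np.zeros_like(xg),
                                 valid=np.ones_like(xg, dtype=bool),
                                 window_size=4.0, overlap=2.0, pixel_size=PS)
        mask = _full_mask()
        from tfm.metrics import _grid_membership

        n_in = _grid_membership(mask.traction_area, xg, yg, PS).sum()
        area_m2 = n_in * (h * 1e-6) ** 2
        expect = 0.25 * f0 * u0 * 1e-6 * area_m2 * 1e12
        assert strain_energy(disp, trac, mask) == pytest.approx(expect, rel=0.02)

    def test_mismatched_grids_rejected(self):
        xg, yg = _fields(50)
        xg2, yg2 = _fields(40)
        disp = DisplacementField(x=xg, y=yg, u=np.zeros_like(xg),
                                 v=np.zeros_like(xg),
                                 valid=np.ones_like(xg, dtype=bool),
                                 window_size=4.0, overlap=2.0, pixel_size=PS)
        trac = TractionField(x=xg2, y=yg2, tx=np.zeros_like(xg2),
                             ty=np.zeros_like(xg2), grid_spacing=2.0)
        with pytest.raises(ValueError):
            strain_energy(disp, trac, _full_mask())


class TestForceEpicenter:
    def test_radial_field_center(self):
        xg, yg = _fields()
        tx, ty = _radial_traction(xg, yg, (100.0, 100.0), 80.0, 5.0, 40.0)
        trac = TractionField(x=xg, y=yg, tx=tx, ty=ty, grid_spacing=2.0)
        (x, y), degenerate = force_epicenter(trac, _full_mask())
        assert not degenerate
        assert x == pytest.approx(100.0, abs=0.5)
        assert y == pytest.approx(100.0, abs=0.5)

    def test_four_corner_forces(self):
        xg, yg = _fields()
        tx = np.zeros_like(xg)
        ty = np.zeros_like(yg)
        c = 100.0
        for sx, sy in [(-1, -1), (-1, 1), (1, -1), (1, 1)]:
            iy = np.argmin(np.abs(yg[:, 0] - (c + sy * 30)))
            ix = np.argmin(np.abs(xg[0, :] - (c + sx * 30)))
            tx[iy, ix] = -sx * 70.0
            ty[iy, ix] = -sy * 70.0
        trac = TractionField(x=xg, y=yg, tx=tx, ty=ty, grid_spacing=2.0)
        (x, y), degenerate = force_epicenter(trac, _full_mask())
        assert not degenerate
        assert (x, y) == pytest.approx((c, c), abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        xg, yg = _fields(60, 2.0)
        tx = np.zeros_like(xg)
        ty = np.zeros_like(yg)
        sel = rng.random(xg.shape) < 0.1
        tx[sel] = rng.normal(0, 100, sel.sum())
        ty[sel] = rng.normal(0, 100, sel.sum())
        trac = TractionField(x=xg, y=yg, tx=tx, ty=ty, grid_spacing=2.0)
        mask = _full_mask()
        (x, y), _ = force_epicenter(trac, mask)

        def torque_objective(cx, cy):
            return np.sum(((xg - cx) * ty - (yg - cy) * tx) ** 2)

        # 1 um brute-force grid over the field
        gx = np.arange(0.0, 120.0, 1.0)
        vals = np.array([[torque_objective(cx, cy) for cx in gx] for cy in gx])
        iy, ix = np.unravel_index(vals.argmin(), vals.shape)
        assert torque_objective(x, y) <= vals.min() + 1e-9
        assert abs(x - gx[ix]) <= 1.0 and abs(y - gx[iy]) <= 1.0

    def test_parallel_forces_degenerate_fallback(self):
        xg, yg = _fields(50, 2.0)
        tx = np.zeros_like(xg)
        tx[10:40, 10:40] = 50.0  # all forces along +x
        ty = np.zeros_like(yg)
        trac = TractionField(x=xg, y=yg, tx=tx, ty=ty, grid_spacing=2.0)
        (x, y), degenerate = force_epicenter(trac, _full_mask())
        assert degenerate
        # |f|-weighted centroid of the patch
        w = np.hypot(tx, ty)
        assert x == pytest.approx((xg * w).sum() / w.sum(), abs=1e-6)
        assert y == pytest.approx((yg * w).sum() / w.sum(), abs=1e-6)


class TestContractility:
    def test_annulus_closed_form(self):
        # inward 100 Pa on r in [15, 20] um -> C = 100 * pi * (400-225) um^2 = 55 nN
        from tfm.synthetic import SceneConfig, make_traction_template

        cfg = SceneConfig(template="annulus", peak_traction=100.0,
                          radius=20.0, inner_radius=15.0)
        trac, mask = make_traction_template("annulus", cfg)
        (epi, _) = force_epicenter(trac, mask)[0], None
        c = contractility(trac, mask)
        expect = 100.0 * np.pi * (20.0**2 - 15.0**2) * 1e-3  # nN
        assert c == pytest.approx(expect, rel=0.02)

    def test_opposed_point_forces(self):
        # two antiparallel forces pointing at each other -> C = 2F
        xg, yg = _fields(100, 2.0)
        tx = np.zeros_like(xg)
        iy = 50
        tx[iy, 30] = 250.0  # at x=60, pointing +x (toward the other)
        tx[iy, 70] = -250.0  # at x=140, pointing -x
        trac = TractionField(x=xg, y=yg, tx=tx, ty=np.zeros_like(xg),
                             grid_spacing=2.0)
        mask = _full_mask()
        c = contractility(trac, mask)
        f_each = 250.0 * (2e-6) ** 2 * 1e9  # nN
        assert c == pytest.approx(2 * f_each, rel=1e-6)

    def test_circulating_field_zero(self):
        xg, yg = _fields()
        dx, dy = xg - 100.0, yg - 100.0
        r = np.hypot(dx, dy)
        inside = (r > 10) & (r < 40)
        tx = np.where(inside, -dy / np.where(r > 0, r, 1) * 100, 0.0)
        ty = np.where(inside, dx / np.where(r > 0, r, 1) * 100, 0.0)
        trac = TractionField(x=xg, y=yg, tx=tx, ty=ty, grid_spacing=2.0)
        c = contractility(trac, _full_mask(), epicenter=(100.0, 100.0))
        total = trac.magnitude.sum() * (2e-6) ** 2 * 1e9
        assert abs(c) < 1e-6 * total

    def test_projection_bound(self, default_piv):
        from tfm.traction import fttc_invert
        from tfm.traction import SubstrateProperties

        _, disp = default_piv
        trac = fttc_invert(disp, SubstrateProperties(9000.0, 0.5))
        mask = _full_mask()
        c = contractility(trac, mask)
        upper = trac.magnitude.sum() * (trac.grid_spacing * 1e-6) ** 2 * 1e9
        assert 0 <= c <= upper


class TestInvariances:
    def _disk_pair(self):
        from tfm.synthetic import SceneConfig, make_traction_template
        from tfm.traction import forward_displacement

        cfg = SceneConfig(template="contracting_disk", peak_traction=150.0,
                          radius=25.0)
        trac, mask = make_traction_template("contracting_disk", cfg)
        disp = forward_displacement(trac)
        return trac, disp, mask

    def test_strain_energy_translation_invariant(self):
        trac, disp, mask = self._disk_pair()
        u0 = strain_energy(disp, trac, mask)
        shift = 5  # grid nodes; compact fields -> rolling is a pure translation
        px_shift = int(round(5 * trac.grid_spacing / mask.pixel_size))
        trac2 = TractionField(x=trac.x, y=trac.y,
                              tx=np.roll(trac.tx, shift, axis=1),
                              ty=np.roll(trac.ty, shift, axis=1),
                              grid_spacing=trac.grid_spacing)
        disp2 = DisplacementField(x=disp.x, y=disp.y,
                                  u=np.roll(disp.u, shift, axis=1),
                                  v=np.roll(disp.v, shift, axis=1),
                                  valid=disp.valid, window_size=disp.window_size,
                                  overlap=disp.overlap, pixel_size=disp.pixel_size)
        mask2 = CellMask(cell_boundary=np.roll(mask.cell_boundary, px_shift, axis=1),
                         traction_area=np.roll(mask.traction_area, px_shift, axis=1),
                         pixel_size=mask.pixel_size)
        u1 = strain_energy(disp2, trac2, mask2)
        assert u1 == pytest.approx(u0, rel=1e-3)

    def test_contractility_rotation_invariant(self):
        trac, _, mask = self._disk_pair()
        c0 = contractility(trac, mask)
        # rotate the scene by 90 degrees: np.rot90 maps positions as
        # (x, y) -> (y, L - x), so vectors map as (tx, ty) -> (ty, -tx)
        trac_rot = TractionField(x=trac.x, y=trac.y,
                                 tx=np.rot90(trac.ty),
                                 ty=np.rot90(-trac.tx),
                                 grid_spacing=trac.grid_spacing)
        mask_rot = CellMask(cell_boundary=np.rot90(mask.cell_boundary),
                            traction_area=np.rot90(mask.traction_area),
                            pixel_size=mask.pixel_size)
        c1 = contractility(trac_rot, mask_rot)
        assert c1 == pytest.approx(c0, rel=1e-2)


class TestSummarize:
    def test_zero_traction_scene(self):
        xg, yg = _fields()
        zeros = np.zeros_like(xg)
        disp = DisplacementField(x=xg, y=yg, u=zeros, v=zeros,
                                 valid=np.ones_like(xg, dtype=bool),
                                 window_size=4.0, overlap=2.0, pixel_size=PS)
        eps = zeros.copy()
        eps[50, 50] = 1e-12  # epicenter needs a nonzero vector
        eps[50, 52] = -1e-12
        trac = TractionField(x=xg, y=yg, tx=eps, ty=zeros, grid_spacing=2.0)
        m = summarize(disp, trac, _square_mask(200))
        assert m.cell_area > 0
        assert m.strain_energy == pytest.approx(0.0, abs=1e-12)
        assert m.contractility == pytest.approx(0.0, abs=1e-9)

    def test_normalized_values_reproduce_raw(self, default_piv):
        from tfm.traction import SubstrateProperties, fttc_invert

        _, disp = default_piv
        trac = fttc_invert(disp, SubstrateProperties(9000.0, 0.5))
        m = summarize(disp, trac, _square_mask(200))
        area_m2 = m.cell_area * 1e-12
        assert m.strain_energy_normalized * area_m2 == pytest.approx(
            m.strain_energy * 1e-12, rel=1e-12)
        assert m.contractility_normalized * area_m2 == pytest.approx(
            m.contractility * 1e-9, rel=1e-12)
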