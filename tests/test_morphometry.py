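"""Morphometry: centerlines, lengths, widths, depth, pith, blockage, volume."""

import numpy as np
import pytest
from scipy import ndimage

from xylotrace.morphometry import (
    PithEstimate,
    SurfaceError,
    _slice_geometry,
    blockage_metrics,
    boring_depth,
    boring_volume,
    entrance_width,
    estimate_pith,
    extract_centerline,
    total_length,
    vertical_length,
)
from xylotrace.phantom import (
    PhantomConfig,
    RingModel,
    _ring_volume,
    rasterize_tube,
)
from xylotrace.segment import trunk_mask
from xylotrace.types import Centerline, CTVolume, GalleryMask

SPACING = (0.68, 0.339844, 0.339844)


def _trunk_scene(trunk_diameter_mm=60.0, n_slices=60, pith_offset=(0.0, 0.0)):
    """Ringed wood cylinder and its geometry helpers, no galleries."""
    cfg = PhantomConfig(
        trunk_diameter_mm=trunk_diameter_mm,
        n_slices=n_slices,
        counts={},
        noise_sd=0.0,
        seed=0,
        pith_offset_mm=pith_offset,
        pith_drift_mm_per_mm=(0.0, 0.0),
    )
    c = (cfg.shape[1] - 1) * cfg.spacing[1] / 2
    ring = RingModel(
        pith_mm=np.tile([c + pith_offset[0], c + pith_offset[1]], (cfg.shape[0], 1)),
        ring_period_mm=cfg.ring_period_mm,
        band_attenuations=(-700, -550),
        trunk_radius_mm=cfg.trunk_radius_mm,
        center_mm=(c, c),
    )
    vol = _ring_volume(cfg, ring)
    return cfg, vol, ring, c


def _carve(cfg, vol, ring, pts, radii):
    """Carve an air tube (clipped to the trunk) and return volume + mask."""
    ny = cfg.shape[1]
    c = ring.center_mm
    ys = np.arange(ny) * cfg.spacing[1]
    X, Y = np.meshgrid(np.arange(cfg.shape[2]) * cfg.spacing[2], ys)
    inside = np.hypot(Y - c[0], X - c[1]) <= ring.trunk_radius_mm
    tube = rasterize_tube(pts, radii, cfg.shape, cfg.spacing) & inside
    vol = vol.copy()
    vol[tube] = -1000.0
    volume = CTVolume(vol, cfg.spacing)
    gm = GalleryMask(tube.astype(np.int32), np.zeros(cfg.shape, bool), cfg.spacing)
    return volume, gm


class TestExtractCenterline:
    def test_straight_chord_tube_collinear(self):
        """A straight tube passing right through the trunk: the recovered
        centerline stays within one voxel of the true axis."""
        cfg, vol, ring, c = _trunk_scene()
        z0 = cfg.shape[0] * cfg.spacing[0] / 2
        R = ring.trunk_radius_mm
        start = np.array([z0, c, c + R + 1.0])
        d = np.array([0.0, 0.0, -1.0])
        pts = start + np.linspace(0, 2 * R + 2, 160)[:, None] * d
        volume, gm = _carve(cfg, vol, ring, pts, np.full(160, 2.0))
        geo = _slice_geometry(trunk_mask(volume), cfg.spacing)
        cl = extract_centerline(gm, 1, geo=geo)
        dev = np.hypot(cl.points_mm[:, 0] - z0, cl.points_mm[:, 1] - c)
        assert dev.max() <= 1.0
        assert cl.branch_mm is None

    def test_semicircular_tube_arc_length(self):
        """Half-ring of radius R with both ends on the trunk surface:
        recovered length within 3% of the analytic pi*R."""
        cfg, vol, ring, c = _trunk_scene(trunk_diameter_mm=80.0, n_slices=70)
        R = 14.0
        Rt = ring.trunk_radius_mm
        z0 = cfg.shape[0] * cfg.spacing[0] / 2
        # semicircle diameter endpoints both on the trunk circle, arc bulging
        # inward: circle centre offset sqrt(Rt^2 - R^2) from the trunk axis
        off = np.sqrt(Rt**2 - R**2)
        ctr = np.array([z0, c, c + off])
        t = np.linspace(0, np.pi, 200)
        pts = ctr + np.column_stack(
            [np.zeros_like(t), R * np.cos(t), -R * np.sin(t)]
        )
        volume, gm = _carve(cfg, vol, ring, pts, np.full(len(pts), 2.0))
        geo = _slice_geometry(trunk_mask(volume), cfg.spacing)
        cl = extract_centerline(gm, 1, geo=geo)
        assert total_length(cl) == pytest.approx(np.pi * R, rel=0.03)

    def test_buried_tube_without_opening_errors(self):
        cfg, vol, ring, c = _trunk_scene()
        z0 = cfg.shape[0] * cfg.spacing[0] / 2
        pts = np.array([[z0, c - 8.0, c], [z0, c + 8.0, c]])
        volume, gm = _carve(cfg, vol, ring, pts, [2.0, 2.0])
        geo = _slice_geometry(trunk_mask(volume), cfg.spacing)
        with pytest.raises(SurfaceError):
            extract_centerline(gm, 1, geo=geo)


class TestLengths:
    def test_two_point_polyline(self):
        cl = Centerline(np.array([[0.0, 0, 0], [10.0, 0, 0]]))
        assert total_length(cl) == 10.0

    def test_helix_arc_length_analytic(self):
        a, b = 8.0, 2.0  # radius, rise per radian
        t = np.linspace(0, 2 * np.pi, 400)
        pts = np.column_stack([b * t, a * np.sin(t), a * np.cos(t)])
        cl = Centerline(pts)
        assert total_length(cl) == pytest.approx(
            2 * np.pi * np.sqrt(a**2 + b**2), rel=0.02
        )

    def test_vertical_length_single_slice(self):
        lab = np.zeros((10, 8, 8), np.int32)
        lab[4, 2:5, 2:5] = 1
        gm = GalleryMask(lab, np.zeros_like(lab, bool), SPACING)
        assert vertical_length(gm, 1) == pytest.approx(SPACING[0])

    def test_vertical_length_axial_tube(self):
        L = 47.6  # an integer number of slices (70) at 0.68 mm
        lab = np.zeros((100, 12, 12), np.int32)
        z0 = 10
        nz = int(round(L / SPACING[0]))
        lab[z0 : z0 + nz, 4:8, 4:8] = 1
        gm = GalleryMask(lab, np.zeros_like(lab, bool), SPACING)
        assert vertical_length(gm, 1) == pytest.approx(L, abs=SPACING[0] + 1e-9)


class TestBoringVolume:
    def test_voxel_count_arithmetic(self):
        lab = np.zeros((20, 20, 20), np.int32)
        lab.ravel()[:1000] = 1
        gm = GalleryMask(lab, np.zeros_like(lab, bool), SPACING)
        assert boring_volume(gm, 1) == pytest.approx(1000 * np.prod(SPACING))

    def test_sphere_volume(self):
        shape = (40, 60, 60)
        c = np.array([13.0, 10.0, 10.0])
        r = 5.0
        mask = rasterize_tube(c[None, :], [r], shape, SPACING)
        gm = GalleryMask(mask.astype(np.int32), np.zeros(shape, bool), SPACING)
        assert boring_volume(gm, 1) == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)


class TestEntranceWidth:
    def _radial_tube(self, r_tube, angle_deg=0.0):
        cfg, vol, ring, c = _trunk_scene()
        a = np.deg2rad(angle_deg)
        z0 = cfg.shape[0] * cfg.spacing[0] / 2
        d = np.array([np.sin(a), 0.0, -np.cos(a)])
        start = np.array([z0, c, c + ring.trunk_radius_mm + 1.0])
        pts = start + np.linspace(0, 25, 100)[:, None] * d
        volume, gm = _carve(cfg, vol, ring, pts, np.full(100, r_tube))
        geo = _slice_geometry(trunk_mask(volume), cfg.spacing)
        cl = Centerline(start + 1.0 * d + np.linspace(0, 24, 100)[:, None] * d)
        return gm, cl, geo

    def test_perpendicular_tube_recovers_bore_diameter(self):
        gm, cl, geo = self._radial_tube(1.45)
        w = entrance_width(gm, 1, cl, geo)
        assert w == pytest.approx(2.90, abs=0.34)  # within one voxel pitch

    def test_oblique_entry_not_narrower(self):
        gm0, cl0, geo0 = self._radial_tube(1.45, 0.0)
        gm45, cl45, geo45 = self._radial_tube(1.45, 45.0)
        w0 = entrance_width(gm0, 1, cl0, geo0)
        w45 = entrance_width(gm45, 1, cl45, geo45)
        assert w45 >= w0 - 0.25

    def test_no_opening_raises(self):
        cfg, vol, ring, c = _trunk_scene()
        z0 = cfg.shape[0] * cfg.spacing[0] / 2
        pts = np.array([[z0, c - 8.0, c], [z0, c + 8.0, c]])
        volume, gm = _carve(cfg, vol, ring, pts, [2.0, 2.0])
        geo = _slice_geometry(trunk_mask(volume), cfg.spacing)
        cl = Centerline(pts)
        with pytest.raises(SurfaceError):
            entrance_width(gm, 1, cl, geo)


class TestPith:
    def test_centered_rings_recovered_within_a_voxel(self):
        cfg, vol, ring, c = _trunk_scene(pith_offset=(0.0, 0.0))
        volume = CTVolume(vol, cfg.spacing)
        est = estimate_pith(volume)
        err = np.abs(est.pith_mm - ring.pith_mm)
        assert err.max() <= 0.34

    def test_offset_rings_recovered(self):
        cfg, vol, ring, c = _trunk_scene(pith_offset=(4.0, -3.0))
        volume = CTVolume(vol, cfg.spacing)
        est = estimate_pith(volume)
        assert np.abs(est.pith_mm - ring.pith_mm).max() <= 0.34

    def test_drifting_pith_slope_recovered(self):
        cfg = PhantomConfig(
            trunk_diameter_mm=60.0,
            n_slices=120,
            counts={},
            noise_sd=10.0,
            seed=1,
            pith_offset_mm=(2.0, -1.0),
            pith_drift_mm_per_mm=(0.04, -0.03),
        )
        from xylotrace.phantom import generate_phantom

        volume, _, ring = generate_phantom(cfg)
        est = estimate_pith(volume)
        z = np.arange(cfg.n_slices) * cfg.spacing[0]
        for k, true_slope in enumerate((0.04, -0.03)):
            slope = np.polyfit(z, est.pith_mm[:, k], 1)[0]
            assert slope == pytest.approx(true_slope, rel=0.10)

    def test_uniform_slices_flagged(self):
        vox = np.full((24, 60, 60), -600.0, dtype=np.float32)
        volume = CTVolume(vox, SPACING)
        with pytest.raises(ValueError):
            estimate_pith(volume)


class TestBoringDepth:
    def test_constant_radius_zero_depth(self):
        pith = PithEstimate(np.tile([20.0, 20.0], (50, 1)), np.zeros(50, bool))
        t = np.linspace(0, np.pi, 60)
        pts = np.column_stack([5 + 3 * t, 20 + 10 * np.sin(t), 20 + 10 * np.cos(t)])
        cl = Centerline(pts)
        assert boring_depth(cl, pith, SPACING[0]) == pytest.approx(0.0, abs=1e-9)

    def test_entrance_80_innermost_50_gives_30(self):
        pith = PithEstimate(np.tile([0.0, 0.0], (200, 1)), np.zeros(200, bool))
        rr = np.concatenate([np.linspace(80, 50, 40), np.linspace(50, 80, 40)])
        zz = np.linspace(10, 40, 80)
        pts = np.column_stack([zz, np.zeros(80), rr])
        cl = Centerline(pts)
        assert boring_depth(cl, pith, SPACING[0]) == pytest.approx(30.0, abs=1e-9)

    def test_outward_gallery_uses_max_radius(self):
        pith = PithEstimate(np.tile([0.0, 0.0], (200, 1)), np.zeros(200, bool))
        rr = np.linspace(50, 75, 60)  # runs outward from its entrance
        pts = np.column_stack([np.linspace(5, 30, 60), np.zeros(60), rr])
        cl = Centerline(pts)
        assert boring_depth(cl, pith, SPACING[0]) == pytest.approx(25.0, abs=1e-9)


class TestBlockageMetrics:
    def test_no_blocked_voxels_zero(self):
        lab = np.zeros((20, 20, 20), np.int32)
        lab[5:15, 8:12, 8:12] = 1
        gm = GalleryMask(lab, np.zeros_like(lab, bool), SPACING)
        cl = Centerline(np.array([[4.0, 3.4, 3.4], [10.0, 3.4, 3.4]]))
        L, V, iv = blockage_metrics(gm, 1, cl)
        assert (L, V) == (0.0, 0.0) and iv == []

    def test_interval_length_and_volume(self):
        """A 2 mm-radius tube blocked over arc [10, 20] mm reports roughly
        10 mm and pi*4*10 mm^3."""
        shape = (60, 40, 40)
        d = np.array([1.0, 0.0, 0.0])
        start = np.array([2.0, 6.8, 6.8])
        pts = start + np.linspace(0, 35, 120)[:, None] * d
        tube = rasterize_tube(pts, np.full(120, 2.0), shape, SPACING)
        # a clean arc slab (no capsule end-caps bleeding past the interval)
        zz = np.arange(shape[0])[:, None, None] * SPACING[0]
        plug = tube & (zz - start[0] >= 10.0) & (zz - start[0] <= 20.0)
        gm = GalleryMask(tube.astype(np.int32), plug, SPACING)
        cl = Centerline(pts)
        L, V, iv = blockage_metrics(gm, 1, cl)
        assert L == pytest.approx(10.0, rel=0.10)
        assert V == pytest.approx(np.pi * 4 * 10, rel=0.10)
        assert len(iv) == 1


class TestResolutionConvergence:
    def test_finer_voxels_reduce_volume_error(self):
        """Halving the voxel spacing moves rasterized volumes toward the
        analytic value (monotone error decrease on a test sphere)."""
        r = 2.0
        true = 4 / 3 * np.pi * r**3
        rng = np.random.default_rng(0)
        offsets = rng.uniform(0, 0.68, size=(5, 3))
        errs = []
        for f in (1.0, 0.5):
            sp = (0.68 * f, 0.339844 * f, 0.339844 * f)
            shape = tuple(int(10 / s) for s in sp)
            e = []
            for off in offsets:  # average out discretization luck
                c = np.array([5.0, 5.0, 5.0]) + off
                m = rasterize_tube(c[None, :], [r], shape, sp)
                e.append(abs(m.sum() * np.prod(sp) - true) / true)
            errs.append(np.mean(e))
        assert errs[1] < errs[0]

    def test_finer_voxels_reduce_length_error(self):
        """A semicircular tube's centerline length error shrinks when the
        grid is refined."""
        R = 10.0
        errs = []
        for f in (1.0, 0.5):
            sp = (0.68 * f, 0.339844 * f, 0.339844 * f)
            t = np.linspace(0, np.pi, 200)
            ctr = np.array([10.0, 20.0, 20.0])
            pts = ctr + np.column_stack([np.zeros_like(t), R * np.cos(t), R * np.sin(t)])
            shape = tuple(int(40 / s) for s in sp)
            tube = rasterize_tube(pts, np.full(len(pts), 1.5), shape, sp)
            from skimage.morphology import skeletonize

            sk = skeletonize(tube)
            coords = np.argwhere(sk) * np.asarray(sp)
            # crude arc estimate: sum of nearest-neighbour chain distances
            from scipy.spatial import cKDTree

            order = np.argsort(np.arctan2(coords[:, 1] - 20, coords[:, 2] - 20))
            chain = coords[order]
            L = np.linalg.norm(np.diff(chain, axis=0), axis=1).sum()
            errs.append(abs(L - np.pi * R) / (np.pi * R))
        assert errs[1] < errs[0]
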