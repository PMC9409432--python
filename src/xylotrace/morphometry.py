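"""3D morphometry of segmented galleries.

From a labeled gallery mask this module derives, per gallery:

* a smoothed centerline (3D skeletonization, spur pruning, longest geodesic
  path between surface-reaching endpoints, smoothing-spline fit);
* the seven standard gallery parameters: entrance-hole width, boring depth
  (radial excursion relative to the pith, following the concentric-circle
  construction on annual rings), vertical (axial) extent, blockage length
  and volume, total centerline length, and boring volume.

The pith axis needed by the depth measurement is estimated from the annual
ring pattern itself: per slice, the candidate centre that minimises the
angular variance of attenuation at fixed radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

from .segment import trunk_mask
from .types import Centerline, CTVolume, GalleryMask, GalleryMetrics

__all__ = [
    "extract_centerline",
    "total_length",
    "entrance_width",
    "estimate_pith",
    "boring_depth",
    "vertical_length",
    "blockage_metrics",
    "boring_volume",
    "measure_all",
    "PithEstimate",
    "SurfaceError",
]


class SurfaceError(ValueError):
    """A gallery has no opening on the trunk surface where one is required."""


# ---------------------------------------------------------------------------
# trunk surface geometry
# ---------------------------------------------------------------------------


@dataclass
class _SliceGeometry:
    """Per-slice trunk disk: centroid (mm) and equivalent radius (mm)."""

    center_mm: np.ndarray  # (nz, 2) (y, x)
    radius_mm: np.ndarray  # (nz,)

    def surface_depth(self, points_mm: np.ndarray) -> np.ndarray:
        """Depth below the trunk surface for world points (z, y, x) in mm."""
        pts = np.atleast_2d(points_mm)
        zi = np.clip(
            np.round(pts[:, 0] / self._dz).astype(int), 0, len(self.radius_mm) - 1
        )
        c = self.center_mm[zi]
        r = np.hypot(pts[:, 1] - c[:, 0], pts[:, 2] - c[:, 1])
        return self.radius_mm[zi] - r


def _slice_geometry(trunk: np.ndarray, spacing) -> _SliceGeometry:
    dz, dy, dx = spacing
    nz = trunk.shape[0]
    center = np.zeros((nz, 2))
    radius = np.zeros(nz)
    for z in range(nz):
        sl = trunk[z]
        n = sl.sum()
        if n == 0:
            radius[z] = np.nan
            continue
        ys, xs = np.nonzero(sl)
        center[z] = (ys.mean() * dy, xs.mean() * dx)
        radius[z] = np.sqrt(n * dy * dx / np.pi)
    geo = _SliceGeometry(center, radius)
    geo._dz = dz
    return geo


def _surface_openings(
    mask: GalleryMask, label: int, geo: _SliceGeometry, shell_mm: float = 1.2
):
    """Connected components of the gallery's intersection with a thin shell
    just below the trunk surface.  Returns a list of (n_i, 3) mm coordinates."""
    sl = ndimage.find_objects((mask.labels == label).astype(np.int8))[0]
    idx = np.argwhere(mask.labels[sl] == label)
    offset = np.array([s.start for s in sl])
    pts_mm = (idx + offset) * np.asarray(mask.spacing)
    depth = geo.surface_depth(pts_mm)
    shell = depth <= shell_mm
    if not shell.any():
        return []
    shell_idx = idx[shell]
    crop = np.zeros(tuple(s.stop - s.start for s in sl), dtype=bool)
    crop[tuple(shell_idx.T)] = True
    lab, n = ndimage.label(crop, structure=ndimage.generate_binary_structure(3, 3))
    out = []
    for k in range(1, n + 1):
        comp = np.argwhere(lab == k)
        if len(comp) < 4:  # specks
            continue
        out.append((comp + offset) * np.asarray(mask.spacing))
    return out


# ---------------------------------------------------------------------------
# skeleton graph utilities
# ---------------------------------------------------------------------------

_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
)


def _skeleton_graph(coords: np.ndarray, shape, spacing):
    """Sparse weighted 26-adjacency graph over skeleton voxels (weights mm)."""
    flat = np.ravel_multi_index(coords.T, shape)
    index = {f: i for i, f in enumerate(flat)}
    rows, cols, w = [], [], []
    sp = np.asarray(spacing)
    for off in _OFFSETS:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        nb_flat = np.ravel_multi_index(nb[ok].T, shape)
        src = np.nonzero(ok)[0]
        for s, f in zip(src, nb_flat):
            j = index.get(f)
            if j is not None:
                rows.append(s)
                cols.append(j)
                w.append(float(np.linalg.norm(off * sp)))
    n = len(coords)
    return csr_matrix((w, (rows, cols)), shape=(n, n))


def _prune_spurs(
    coords: np.ndarray,
    graph: csr_matrix,
    local_radius: np.ndarray,
    protected: set[int],
    factor: float = 3.0,
):
    """Iteratively remove terminal branches shorter than ``factor`` times the
    local tube radius, keeping protected (surface) endpoints."""
    alive = np.ones(len(coords), dtype=bool)
    adj = graph.tolil().rows
    wts = {}
    gcoo = graph.tocoo()
    for i, j, v in zip(gcoo.row, gcoo.col, gcoo.data):
        wts[(i, j)] = v
    for _ in range(40):
        degree = np.array([sum(alive[j] for j in adj[i]) if alive[i] else 0 for i in range(len(coords))])
        changed = False
        for i in np.nonzero(alive & (degree == 1))[0]:
            if i in protected:
                continue
            # walk from the endpoint to the first junction
            path = [i]
            length = 0.0
            prev, cur = -1, i
            while True:
                nbrs = [j for j in adj[cur] if alive[j] and j != prev]
                if len(nbrs) != 1:
                    break
                nxt = nbrs[0]
                length += wts[(cur, nxt)]
                deg_next = sum(alive[j] for j in adj[nxt])
                if deg_next > 2:
                    break
                path.append(nxt)
                prev, cur = cur, nxt
            limit = factor * float(local_radius[path].max(initial=0.0))
            if length < max(limit, 1.0):
                alive[list(path)] = False
                changed = True
        if not changed:
            break
    return alive


def extract_centerline(
    mask: GalleryMask,
    label: int,
    volume: CTVolume | None = None,
    geo: _SliceGeometry | None = None,
    spline_smooth_mm: float = 0.4,
    sample_step_mm: float = 0.15,
) -> Centerline:
    """Skeleton-based centerline of one labeled gallery.

    The 3D skeleton is pruned of short spurs, the longest geodesic path
    between surface-reaching endpoints becomes the main path, any further
    surface-reaching endpoint contributes a branch (Y galleries), and a
    smoothing spline resampled at sub-voxel steps gives the final polyline.
    Orientation (entrance vs emergence) is resolved later by the caller.
    """
    if geo is None:
        if volume is None:
            raise ValueError("need either a precomputed slice geometry or the volume")
        geo = _slice_geometry(trunk_mask(volume), mask.spacing)
    spacing = np.asarray(mask.spacing)
    region = mask.labels == label
    if not region.any():
        raise ValueError(f"label {label} is empty")
    sl = ndimage.find_objects(region.astype(np.int8))[0]
    pad = tuple(
        slice(max(s.start - 2, 0), min(s.stop + 2, d))
        for s, d in zip(sl, region.shape)
    )
    crop = region[pad]
    offset = np.array([p.start for p in pad])

    skel = skeletonize(crop)
    if skel.sum() < 2:
        # thinning of slab-like regions (tubes a few z-slices thick) can
        # collapse to nothing; a one-voxel dilation restores a medial line
        work = crop
        for _ in range(2):
            work = ndimage.binary_dilation(work)
            skel = skeletonize(work)
            if skel.sum() >= 2:
                break
    coords = np.argwhere(skel)
    if len(coords) < 2:
        raise SurfaceError(f"label {label}: degenerate skeleton")
    # local tube radius at skeleton voxels (mm, anisotropy-aware)
    dt = ndimage.distance_transform_edt(crop, sampling=spacing)
    local_r = dt[tuple(coords.T)]

    graph = _skeleton_graph(coords, crop.shape, spacing)
    coords_mm = (coords + offset) * spacing

    opening_pts = _surface_openings(mask, label, geo)
    if not opening_pts:
        raise SurfaceError(f"label {label}: gallery has no trunk-surface opening")
    openings = [o.mean(axis=0) for o in opening_pts]
    vv = float(np.prod(spacing))
    # equivalent hole radius, from the opening's volume within the 1.2 mm
    # surface shell: wide holes (pupal-chamber exits) let the skeleton
    # retract further, so they get a wider matching radius
    opening_r = [np.sqrt(len(o) * vv / 1.2 / np.pi) for o in opening_pts]

    def opening_for(point_mm: np.ndarray):
        d = [float(np.linalg.norm(point_mm - o)) for o in openings]
        i = int(np.argmin(d))
        return openings[i] if d[i] <= 12.0 else None

    deg = np.diff(graph.indptr)
    endpoints = np.nonzero(deg == 1)[0]
    protected = set()
    for o in openings:
        d = np.linalg.norm(coords_mm[endpoints] - o, axis=1)
        protected.add(int(endpoints[np.argmin(d)]))

    alive = _prune_spurs(coords, graph, local_r, protected)
    keep = np.nonzero(alive)[0]
    sub = graph[keep][:, keep]
    coords_mm_k = coords_mm[keep]
    local_r_k = local_r[keep]
    deg_k = np.diff(sub.indptr)
    endpoints_k = np.nonzero(deg_k == 1)[0]

    # surface endpoints: one skeleton endpoint per surface opening
    surface_eps = []
    for o, r_o in zip(openings, opening_r):
        if len(endpoints_k) == 0:
            break
        d = np.linalg.norm(coords_mm_k[endpoints_k] - o, axis=1)
        i = int(endpoints_k[np.argmin(d)])
        # the local-radius term under-reads near the trunk cut face (the
        # distance transform sees the opening), hence the generous floor
        thresh = max(7.0, 2.5 * float(local_r_k[i]), 2.0 * r_o)
        if d.min() <= thresh and i not in surface_eps:
            surface_eps.append(i)
    if len(surface_eps) < 2:
        raise SurfaceError(
            f"label {label}: only {len(surface_eps)} surface endpoint(s); "
            "gallery incomplete"
        )

    # longest geodesic path among surface endpoint pairs = main path
    dist, pred = dijkstra(sub, indices=surface_eps, return_predecessors=True)
    best = (0.0, None)
    for a_i, a in enumerate(surface_eps):
        for b in surface_eps:
            if b <= a:
                continue
            d = dist[a_i, b]
            if np.isfinite(d) and d > best[0]:
                best = (d, (a_i, a, b))
    if best[1] is None:
        raise SurfaceError(f"label {label}: surface endpoints not connected")
    a_i, a, b = best[1]

    def walk(pred_row, start, stop):
        path = [stop]
        while path[-1] != start:
            p = pred_row[path[-1]]
            if p < 0:
                return None
            path.append(p)
        return path[::-1]

    main_idx = walk(pred[a_i], a, b)
    main_mm = coords_mm_k[main_idx]
    # skeletonization retracts terminal voxels from open tube ends by about
    # one tube radius; extend each end to the centre of its surface opening
    # (the hole centres are exactly where the length measurement anchors)
    head = opening_for(main_mm[0])
    tail = opening_for(main_mm[-1])
    if head is not None and np.linalg.norm(head - main_mm[0]) > 0.3:
        main_mm = np.vstack([head, main_mm])
    if tail is not None and np.linalg.norm(tail - main_mm[-1]) > 0.3:
        main_mm = np.vstack([main_mm, tail])

    branch_mm = None
    branch_attach = None
    extra = [e for e in surface_eps if e not in (a, b)]
    if extra:
        # the branch of a Y gallery: path from the third hole to the main path
        e = extra[0]
        e_i = surface_eps.index(e)
        on_main = np.zeros(sub.shape[0], dtype=bool)
        on_main[main_idx] = True
        d_row = dist[e_i]
        candidates = np.nonzero(on_main & np.isfinite(d_row))[0]
        if len(candidates):
            j = candidates[np.argmin(d_row[candidates])]
            p = walk(pred[e_i], e, int(j))
            if p is not None and len(p) >= 2:
                bpts = coords_mm_k[p]
                bhead = opening_for(bpts[0])
                if bhead is not None and np.linalg.norm(bhead - bpts[0]) > 0.3:
                    bpts = np.vstack([bhead, bpts])
                branch_mm = _smooth_path(bpts, spline_smooth_mm, sample_step_mm)
                branch_attach = int(np.argmin(
                    np.linalg.norm(main_mm - coords_mm_k[int(j)], axis=1)
                ))

    smooth = _smooth_path(main_mm, spline_smooth_mm, sample_step_mm)
    # re-express the branch attachment on the resampled main path
    if branch_mm is not None:
        branch_attach = int(
            np.argmin(np.linalg.norm(smooth - main_mm[branch_attach], axis=1))
        )
    return Centerline(points_mm=smooth, branch_mm=branch_mm, branch_attach=branch_attach)


def _smooth_path(path_mm: np.ndarray, smooth_mm: float, step_mm: float) -> np.ndarray:
    """Fit a smoothing spline through an ordered voxel path and resample it
    at sub-voxel arc steps.  Falls back to the raw polyline for tiny paths."""
    if len(path_mm) < 8:
        return path_mm.copy()
    seg = np.linalg.norm(np.diff(path_mm, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    u /= u[-1]
    try:
        tck, _ = splprep(path_mm.T, u=u, s=len(path_mm) * smooth_mm**2, k=3)
    except Exception:
        return path_mm.copy()
    total = float(seg.sum())
    n = max(int(np.ceil(total / step_mm)), 2)
    uu = np.linspace(0.0, 1.0, n + 1)
    return np.column_stack(splev(uu, tck))


# ---------------------------------------------------------------------------
# parameter measurements
# ---------------------------------------------------------------------------


def total_length(centerline: Centerline) -> float:
    """Arc length of the main path, entrance centre to emergence centre."""
    return centerline.total_arc_mm


def vertical_length(mask: GalleryMask, label: int) -> float:
    """Axial (trunk-direction) extent of the gallery."""
    zs = np.nonzero((mask.labels == label).any(axis=(1, 2)))[0]
    if len(zs) == 0:
        raise ValueError(f"label {label} is empty")
    return float((zs.max() - zs.min() + 1) * mask.spacing[0])


def boring_volume(mask: GalleryMask, label: int) -> float:
    """Gallery volume: voxel count times voxel volume, blocked voxels
    included."""
    n = int((mask.labels == label).sum())
    if n == 0:
        raise ValueError(f"label {label} is empty")
    return n * mask.voxel_volume_mm3


def entrance_width(
    mask: GalleryMask,
    label: int,
    centerline: Centerline,
    geo: _SliceGeometry,
    probe_depth_mm: float = 1.2,
    grid_step_mm: float = 0.1,
    grid_half_mm: float = 9.0,
) -> float:
    """Maximum width of the entrance hole.

    The two-perpendicular-lines caliper construction (a line along the widest
    part of the hole, a second line at 90 degrees) measures the bore diameter
    at the hole, independent of entry obliquity.  It is evaluated as the
    equivalent diameter of the gallery cross-section perpendicular to the
    centerline just below the surface, sampled on a fine sub-voxel grid —
    robust against the coarse axial voxel pitch.
    """
    openings = _surface_openings(mask, label, geo)
    entry = centerline.points_mm[0]
    if not openings or min(
        float(np.linalg.norm(o.mean(axis=0) - entry)) for o in openings
    ) > 12.0:
        raise SurfaceError(f"label {label}: no surface opening at the entrance")
    pts = centerline.points_mm
    depth = geo.surface_depth(pts)

    def probe(depth_mm: float, air_only: bool) -> tuple[float, float]:
        below = np.nonzero(depth >= depth_mm)[0]
        i = int(below[0]) if len(below) else len(pts) // 2
        i = min(max(i, 1), len(pts) - 2)
        arc = centerline.arc_length_mm[i]
        w = _cross_section_width(
            mask, label, pts, i, grid_step_mm, grid_half_mm, air_only=air_only
        )
        return w, arc

    # first pass sizes the bore; the real probes go deep enough that a wide
    # oblique bore's section clears the trunk surface.  Five sections one mm
    # apart are fitted with a line over arc position and extrapolated back to
    # the hole (galleries taper, so a probe at depth reads slightly wide);
    # the regression averages out section-level voxelization noise
    w0, _ = probe(probe_depth_mm, False)
    d1 = max(probe_depth_mm, 0.75 * w0)
    # open-air sections are exact (the threshold mask equals the true bore
    # there), so they set the level; sections through frass claims carry a
    # roughly constant wall uncertainty, so they still inform the taper slope
    full, air = [], []
    for k in range(5):
        w_k, s_k = probe(d1 + 1.0 * k, False)
        if w_k > 0:
            full.append((w_k, s_k))
        w_k, s_k = probe(d1 + 1.0 * k, True)
        if w_k > 0:
            air.append((w_k, s_k))
    ws, ss = zip(*(air or full)) if (air or full) else ((), ())
    ws, ss = list(ws), list(ss)
    slope_pairs = full if len(full) >= 2 else air
    # the path starts at the opening centroid, which already sits inside the
    # bore; the hole itself is where the depth profile extrapolates to zero
    arc = centerline.arc_length_mm
    head = arc <= min(4.0, arc[-1] / 3)
    s_surface = 0.0
    if head.sum() >= 2:
        dslope, dicept = np.polyfit(arc[head], depth[head], 1)
        if dslope > 0.05:
            s_surface = float(np.clip(-dicept / dslope, -3.0, arc[head][-1]))
    slope = 0.0
    if len(slope_pairs) >= 2:
        sw, ss_ = zip(*slope_pairs)
        if max(ss_) > min(ss_) + 0.5:
            slope = float(np.clip(np.polyfit(ss_, sw, 1)[0], 0.0, 0.25))
    if ws:
        w_entr = float(np.mean(ws)) - slope * (float(np.mean(ss)) - s_surface)
    else:
        w_entr = w0
    return max(w_entr, float(np.mean(mask.spacing[1:])))


def _cross_section_width(
    mask: GalleryMask,
    label: int,
    pts: np.ndarray,
    i: int,
    grid_step_mm: float,
    grid_half_mm: float,
    air_only: bool = False,
) -> float:
    p = pts[i]
    # a ~3 mm window keeps the tangent stable across the small kink where
    # the path was extended to the surface-opening centroid
    tang = pts[min(i + 20, len(pts) - 1)] - pts[max(i - 20, 0)]
    tang = tang / (np.linalg.norm(tang) + 1e-12)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(tang @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(tang, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(tang, e1)
    uu = np.arange(-grid_half_mm, grid_half_mm + grid_step_mm / 2, grid_step_mm)
    U, V = np.meshgrid(uu, uu)
    sample = p + U[..., None] * e1 + V[..., None] * e2
    coords = (sample / np.asarray(mask.spacing)).reshape(-1, 3).T
    # fine measurements avoid the slight dilation morphological smoothing
    # imparts on the bore; the trilinearly interpolated indicator thresholded
    # at 0.5 puts the boundary at the half-level surface (sub-voxel, and
    # unbiased where nearest-voxel membership over-reads oblique sections)
    grid = mask.labels if mask.unsmoothed is None else mask.unsmoothed
    ind = ndimage.map_coordinates(
        (grid == label).astype(np.float32), coords, order=1, mode="constant"
    )
    sel = ind >= 0.5
    if air_only:
        blk = ndimage.map_coordinates(
            mask.blocked.astype(np.float32), coords, order=1, mode="constant"
        )
        air = sel & (blk < 0.5)
        # a section running through a frass plug leaves only slivers of air;
        # only accept sections that are essentially open bore
        if air.sum() < 0.7 * max(sel.sum(), 1):
            return 0.0
        sel = air
    hit = sel.reshape(U.shape)
    if not hit.any():
        return 0.0
    # keep only the bore the centerline runs through (a nearby arm of the
    # same gallery may cut the sampling plane again)
    comp, _ = ndimage.label(hit)
    c = len(uu) // 2
    target = comp[c, c]
    if target == 0:
        ys, xs = np.nonzero(hit)
        j = np.argmin((ys - c) ** 2 + (xs - c) ** 2)
        target = comp[ys[j], xs[j]]
    area = float((comp == target).sum()) * grid_step_mm**2
    return 2.0 * np.sqrt(area / np.pi)


@dataclass
class PithEstimate:
    """Per-slice pith position with per-slice reliability flags."""

    pith_mm: np.ndarray  # (nz, 2) (y, x) mm
    flagged: np.ndarray  # (nz,) True where rings gave no usable signal

    def at(self, z_mm: np.ndarray, dz: float) -> np.ndarray:
        zi = np.clip(np.round(np.asarray(z_mm) / dz).astype(int), 0, len(self.pith_mm) - 1)
        return self.pith_mm[zi]


def estimate_pith(
    volume: CTVolume,
    trunk: np.ndarray | None = None,
    slice_step: int = 8,
    bin_mm: float = 0.8,
    wood_band: tuple[float, float] = (-780.0, -470.0),
) -> PithEstimate:
    """Locate the pith in each slice from the annual-ring pattern.

    For candidate centres the attenuation of wood voxels is binned by radius;
    the candidate minimising the within-radius-bin variance (i.e. maximising
    ring concentricity) wins.  A coarse-to-fine grid search reaches ~0.1 mm.
    Slices without ring contrast are flagged and interpolated from their
    neighbours.
    """
    if trunk is None:
        trunk = trunk_mask(volume)
    dz, dy, dx = volume.spacing
    nz = volume.shape[0]
    geo = _slice_geometry(trunk, volume.spacing)
    sel = list(range(0, nz, slice_step))
    if sel[-1] != nz - 1:
        sel.append(nz - 1)
    est = np.full((len(sel), 2), np.nan)
    flags = np.zeros(len(sel), dtype=bool)
    for si, z in enumerate(sel):
        sl = volume.voxels[z]
        m = trunk[z] & (sl > wood_band[0]) & (sl < wood_band[1])
        ys, xs = np.nonzero(m)
        if len(ys) < 500:
            flags[si] = True
            continue
        ys = ys[::2].astype(float) * dy
        xs = xs[::2].astype(float) * dx
        vals = sl[m][::2].astype(float)
        total_var = vals.var()
        if total_var < 1e-6:
            flags[si] = True
            continue
        center = geo.center_mm[z].copy()
        best = None
        for half, step in ((12.0, 3.0), (2.5, 0.8), (0.6, 0.2), (0.15, 0.05)):
            grid = np.arange(-half, half + step / 2, step)
            scores = np.empty((len(grid), len(grid)))
            for iy, gy in enumerate(grid):
                for ix, gx in enumerate(grid):
                    r = np.hypot(ys - (center[0] + gy), xs - (center[1] + gx))
                    b = (r / bin_mm).astype(int)
                    cnt = np.bincount(b)
                    s1 = np.bincount(b, weights=vals)
                    s2 = np.bincount(b, weights=vals**2)
                    ok = cnt > 0
                    within = (s2[ok] - s1[ok] ** 2 / cnt[ok]).sum() / len(vals)
                    scores[iy, ix] = within
            iy, ix = np.unravel_index(np.argmin(scores), scores.shape)
            center = center + np.array([grid[iy], grid[ix]])
            best = scores[iy, ix]
        if best is None or best > 0.85 * total_var:
            flags[si] = True  # rings too weak to localise
        else:
            est[si] = center
    sel = np.asarray(sel)
    good = ~flags
    pith = np.zeros((nz, 2))
    if good.sum() == 0:
        raise ValueError("no slice shows usable ring contrast")
    zs = np.arange(nz)
    for c in range(2):
        pith[:, c] = np.interp(zs, sel[good], est[good, c])
    flagged_full = np.ones(nz, dtype=bool)
    flagged_full[sel[good]] = False
    return PithEstimate(pith_mm=pith, flagged=flagged_full)


def boring_depth(
    centerline: Centerline, pith: PithEstimate, dz: float
) -> float:
    """Deepest boring depth: the absolute difference between the pith-centred
    radius of the entrance and the gallery's radially most extreme point
    (innermost for inward galleries, outermost for outward ones)."""
    pts = centerline.points_mm
    c = pith.at(pts[:, 0], dz)
    r = np.hypot(pts[:, 1] - c[:, 0], pts[:, 2] - c[:, 1])
    r_entry = r[0]
    inward = r_entry - r.min()
    outward = r.max() - r_entry
    return float(max(inward, outward))


def blockage_metrics(
    mask: GalleryMask,
    label: int,
    centerline: Centerline,
    near_mm: float = 0.8,
) -> tuple[float, float, list[tuple[float, float]]]:
    """Blockage length and volume of one gallery.

    Volume is the blocked voxel count times the voxel volume; length is the
    total arc length of centerline intervals running through (within
    ``near_mm`` of) the blocked mask, with the interval boundaries located
    sub-voxel by interpolating the proximity profile.  Returns (length,
    volume, intervals on the main path).
    """
    region = mask.labels == label
    blocked = mask.blocked & region
    n = int(blocked.sum())
    if n == 0:
        return 0.0, 0.0, []
    volume_mm3 = n * mask.voxel_volume_mm3
    sl = ndimage.find_objects(region.astype(np.int8))[0]
    pad = tuple(
        slice(max(s.start - 3, 0), min(s.stop + 3, d))
        for s, d in zip(sl, region.shape)
    )
    spacing = np.asarray(mask.spacing)
    offset = np.array([p.start for p in pad]) * spacing
    crop_shape = np.array([p.stop - p.start for p in pad])

    # each blocked voxel belongs to exactly one path (main or branch), so a
    # plug near the Y junction is never counted along both
    from scipy.spatial import cKDTree

    blocked_idx = np.argwhere(blocked[pad])
    blocked_mm = blocked_idx * spacing + offset
    paths = [centerline.points_mm]
    if centerline.branch_mm is not None:
        paths.append(centerline.branch_mm)
    if len(paths) > 1:
        dists = np.stack([cKDTree(p).query(blocked_mm, k=1)[0] for p in paths])
        owner = np.argmin(dists, axis=0)
    else:
        owner = np.zeros(len(blocked_mm), dtype=int)

    def runs(points_mm: np.ndarray, path_i: int):
        own = np.zeros(tuple(crop_shape), dtype=bool)
        sel = blocked_idx[owner == path_i]
        own[tuple(sel.T)] = True
        if not own.any():
            return []
        bdist = ndimage.distance_transform_edt(~own, sampling=spacing)
        idx = np.round((points_mm - offset) / spacing).astype(int)
        idx = np.clip(idx, 0, crop_shape - 1)
        prox = bdist[tuple(idx.T)]
        near = prox <= near_mm
        seg = np.linalg.norm(np.diff(points_mm, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])

        def crossing(k_out: int, k_in: int) -> float:
            """Sub-voxel arc where the proximity profile crosses near_mm."""
            p0, p1 = prox[k_out], prox[k_in]
            if p0 == p1:
                return float(arc[k_in])
            t = (p0 - near_mm) / (p0 - p1)
            return float(arc[k_out] + t * (arc[k_in] - arc[k_out]))

        out, i = [], 0
        while i < len(near):
            if near[i]:
                j = i
                while j + 1 < len(near) and near[j + 1]:
                    j += 1
                a = crossing(i - 1, i) if i > 0 else float(arc[0])
                b = crossing(j + 1, j) if j < len(near) - 1 else float(arc[j])
                # the proximity test flags points up to near_mm beyond the
                # plug faces; trim that margin back off each run end
                a, b = a + near_mm, b - near_mm
                if b > a:
                    out.append((a, b))
                i = j + 1
            else:
                i += 1
        return out

    intervals = runs(centerline.points_mm, 0)
    length = sum(b - a for a, b in intervals)
    if centerline.branch_mm is not None:
        # frass plugged into the shorter (branch) arm of a Y still counts
        length += sum(b - a for a, b in runs(centerline.branch_mm, 1))
    return float(length), volume_mm3, intervals


# ---------------------------------------------------------------------------
# per-gallery orchestration
# ---------------------------------------------------------------------------


def _orient(centerline, mask, label, geo, intervals):
    """Put the entrance first: the endpoint nearest a blocked interval, or
    (without blockage) the endpoint with the smaller surface opening.

    Branched (Y) galleries always use the opening-width rule: when the
    plugged arm ends up as the branch, blockage proximity along the main
    path points at the wrong end.
    """
    if intervals and not centerline.has_branch:
        arc_total = centerline.total_arc_mm
        d_start = min(a for a, _ in intervals)
        d_end = arc_total - max(b for _, b in intervals)
        if d_start <= d_end:
            return centerline, False
        return centerline.reversed(), True
    w_fwd = _opening_width_safe(mask, label, centerline, geo)
    w_rev = _opening_width_safe(mask, label, centerline.reversed(), geo)
    if w_rev < w_fwd:
        return centerline.reversed(), True
    return centerline, False


def _opening_width_safe(mask, label, centerline, geo):
    try:
        return entrance_width(mask, label, centerline, geo)
    except SurfaceError:
        return np.inf


def measure_gallery(
    mask: GalleryMask,
    label: int,
    geo: _SliceGeometry,
    pith: PithEstimate,
) -> tuple[GalleryMetrics, Centerline]:
    """All seven parameters for one gallery (type left undecided)."""
    cl = extract_centerline(mask, label, geo=geo)
    blk_len, blk_vol, intervals = blockage_metrics(mask, label, cl)
    cl, flipped = _orient(cl, mask, label, geo, intervals)
    if flipped and intervals:
        total = cl.total_arc_mm
        intervals = [(total - b, total - a) for a, b in intervals][::-1]
    metrics = GalleryMetrics(
        entrance_width_mm=entrance_width(mask, label, cl, geo),
        gallery_depth_mm=boring_depth(cl, pith, mask.spacing[0]),
        vertical_length_mm=vertical_length(mask, label),
        blockage_length_mm=blk_len,
        blockage_volume_mm3=blk_vol,
        total_length_mm=total_length(cl),
        boring_volume_mm3=boring_volume(mask, label),
        label=label,
        branch_length_mm=cl.branch_length_mm,
    )
    metrics.validate()
    return metrics, cl


def measure_all(
    volume: CTVolume, mask: GalleryMask
) -> tuple[list[GalleryMetrics], dict[int, Centerline], PithEstimate]:
    """Measure every labeled gallery in a volume.

    Galleries without two surface openings (larva still inside, or cut by the
    segment ends) are skipped — consistent with reporting complete galleries
    only — and returned metrics carry ``type_label='?'`` until classification.
    """
    trunk = trunk_mask(volume)
    geo = _slice_geometry(trunk, volume.spacing)
    pith = estimate_pith(volume, trunk=trunk)
    metrics: list[GalleryMetrics] = []
    centerlines: dict[int, Centerline] = {}
    for label in mask.label_ids():
        try:
            m, cl = measure_gallery(mask, label, geo, pith)
        except SurfaceError:
            continue
        metrics.append(m)
        centerlines[label] = cl
    return metrics, centerlines, pith
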