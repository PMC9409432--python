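"""Gallery segmentation: threshold, region grow, blockage bridging, smoothing.

The stages mirror a manual medical-imaging workflow on wood CT (mask
thresholding on an attenuation interval, seeded region growing, mask
splitting and 3D smoothing), with one deliberate difference: the manual
slice-by-slice selection of frass-blocked gallery sections is replaced by an
automatic *blockage bridging* step.  Frass plugs image at wood-like
attenuation, so air-thresholded galleries fall apart into fragments; the
bridging step reconnects fragments whose gap is small and traversable inside
a frass-attenuation corridor, and records the traversed voxels as the
blocked sub-mask.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import CTVolume, GalleryMask

__all__ = [
    "threshold_air",
    "trunk_mask",
    "auto_seeds",
    "region_grow",
    "bridge_blockage",
    "smooth_mask",
    "segment_volume",
    "SeedError",
]

#: default air attenuation interval (a Hounsfield-like band around air)
AIR_INTERVAL = (-1100.0, -850.0)
#: default frass attenuation and corridor half-width
FRASS_LEVEL = -620.0
FRASS_BAND_HALFWIDTH = 40.0
DEFAULT_MAX_GAP_MM = 30.0


class SeedError(ValueError):
    """One or more seeds do not fall on mask voxels."""

    def __init__(self, bad_seeds):
        super().__init__(f"seeds not on mask voxels: {bad_seeds}")
        self.bad_seeds = bad_seeds


def _structure(connectivity: int) -> np.ndarray:
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, rank)


def threshold_air(volume: CTVolume, low: float = AIR_INTERVAL[0], high: float = AIR_INTERVAL[1]) -> np.ndarray:
    """Voxels whose attenuation lies in [low, high] (an air interval mask)."""
    if low > high:
        raise ValueError("threshold interval requires low <= high")
    v = volume.voxels
    return (v >= low) & (v <= high)


def trunk_mask(volume: CTVolume, wood_threshold: float = -800.0) -> np.ndarray:
    """The filled trunk cross-section, slice by slice.

    Wood voxels are detected by attenuation and each slice is filled with the
    convex hull of its wood boundary; for (convex) circular trunk sections
    this seals gallery holes and entrance notches, so interior air can be
    told apart from the surrounding air gap.  The chord drawn across an
    entrance notch undercuts the true circle by well under a voxel at trunk
    scale.
    """
    from scipy.spatial import ConvexHull, QhullError
    from skimage.draw import polygon

    wood = volume.voxels > wood_threshold
    out = np.zeros_like(wood)
    for z in range(wood.shape[0]):
        sl = wood[z]
        if not sl.any():
            continue
        border = sl & ~ndimage.binary_erosion(sl)
        pts = np.argwhere(border)
        try:
            hull = ConvexHull(pts)
        except QhullError:
            out[z] = sl
            continue
        verts = pts[hull.vertices]
        rr, cc = polygon(verts[:, 0], verts[:, 1], shape=sl.shape)
        out[z][rr, cc] = True
        out[z] |= sl  # hull vertices/edges themselves
    return out


def auto_seeds(air_mask: np.ndarray, min_voxels: int = 50) -> np.ndarray:
    """One interior voxel per 26-connected air component of at least
    ``min_voxels`` voxels.  Returns an (n, 3) array of (z, y, x) indices."""
    labels, n = ndimage.label(air_mask, structure=_structure(26))
    if n == 0:
        return np.empty((0, 3), dtype=int)
    counts = np.bincount(labels.ravel())
    keep = [k for k in range(1, n + 1) if counts[k] >= min_voxels]
    seeds = []
    for sl, k in zip(ndimage.find_objects(labels), range(1, n + 1)):
        if k not in keep or sl is None:
            continue
        crop = labels[sl] == k
        # deepest interior voxel of the component
        dt = ndimage.distance_transform_edt(crop)
        zyx = np.unravel_index(np.argmax(dt), crop.shape)
        seeds.append([zyx[d] + sl[d].start for d in range(3)])
    return np.asarray(seeds, dtype=int)


def region_grow(air_mask: np.ndarray, seeds, connectivity: int = 26) -> np.ndarray:
    """Flood-fill labels from seed voxels over a binary mask.

    Each seed labels exactly its connected component (first seed wins if two
    share one); components containing no seed stay unlabeled.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=int))
    bad = [tuple(s) for s in seeds if not air_mask[tuple(s)]]
    if bad:
        raise SeedError(bad)
    comp, _ = ndimage.label(air_mask, structure=_structure(connectivity))
    out = np.zeros_like(comp, dtype=np.int32)
    next_label = 1
    assigned: dict[int, int] = {}
    for s in seeds:
        c = comp[tuple(s)]
        if c not in assigned:
            assigned[c] = next_label
            next_label += 1
    # vectorized relabel
    lut = np.zeros(comp.max() + 1, dtype=np.int32)
    for c, lab in assigned.items():
        lut[c] = lab
    out = lut[comp]
    return out


def _median3(volume: np.ndarray) -> np.ndarray:
    """Separable 3x1 median along each axis: suppresses single-voxel noise
    without ever inventing intermediate values at material interfaces."""
    out = volume
    for axis in range(3):
        size = [1, 1, 1]
        size[axis] = 3
        out = ndimage.median_filter(out, size=tuple(size), mode="nearest")
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def bridge_blockage(
    labeled: np.ndarray,
    air_mask: np.ndarray,
    volume: CTVolume,
    max_gap_mm: float = DEFAULT_MAX_GAP_MM,
    frass_level: float = FRASS_LEVEL,
    band_halfwidth: float = FRASS_BAND_HALFWIDTH,
    min_plug_voxels: int = 40,
) -> GalleryMask:
    """Merge gallery fragments separated by frass plugs.

    A corridor of frass-like attenuation is computed on a median-filtered
    volume (band ``frass_level +/- band_halfwidth``), excluding air.  Each
    corridor component adjacent to labeled fragments is claimed as blocked
    gallery volume; fragments whose Euclidean end-to-end gap across a shared
    corridor component is at most ``max_gap_mm`` are merged into one label;
    corridor components below ``min_plug_voxels`` are noise, not plugs, and
    are ignored.  Labels are renumbered contiguously.
    """
    if max_gap_mm <= 0:
        raise ValueError("max_gap_mm must be positive")
    labeled = np.ascontiguousarray(labeled)
    filtered = _median3(volume.voxels)
    in_band_raw = np.abs(volume.voxels - frass_level) <= band_halfwidth
    corridor = (
        (np.abs(filtered - frass_level) <= band_halfwidth)
        & ~air_mask
        & (labeled == 0)
    )
    comp, n_comp = ndimage.label(corridor, structure=_structure(26))

    n_in = int(labeled.max())
    uf = _UnionFind(n_in + 1)
    blocked = np.zeros(labeled.shape, dtype=bool)
    claims: list[tuple[np.ndarray, int]] = []  # (comp crop slices, label-set key)
    spacing = volume.spacing

    sizes = np.bincount(comp.ravel(), minlength=n_comp + 1)
    slices = ndimage.find_objects(comp)
    for k, sl in enumerate(slices, start=1):
        if sl is None or sizes[k] < min_plug_voxels:
            continue  # wall/noise specks, not a frass plug
        pad = tuple(
            slice(max(s.start - 2, 0), min(s.stop + 2, dim))
            for s, dim in zip(sl, labeled.shape)
        )
        comp_crop = comp[pad] == k
        lab_crop = labeled[pad]
        touch = ndimage.binary_dilation(comp_crop, structure=_structure(26))
        labs = np.unique(lab_crop[touch & (lab_crop > 0)])
        if len(labs) == 0:
            continue
        if len(labs) > 1:
            # pairwise Euclidean gaps across this plug
            for i in range(len(labs)):
                dt = ndimage.distance_transform_edt(
                    lab_crop != labs[i], sampling=spacing
                )
                for j in range(i + 1, len(labs)):
                    gap = float(dt[lab_crop == labs[j]].min())
                    if gap <= max_gap_mm:
                        uf.union(int(labs[i]), int(labs[j]))
        claims.append((pad, comp_crop, [int(l) for l in labs]))

    # contiguous renumbering of merged labels
    roots = {}
    for lab in range(1, n_in + 1):
        roots.setdefault(uf.find(lab), []).append(lab)
    order = sorted(roots)
    remap = np.zeros(n_in + 1, dtype=np.int32)
    for new, root in enumerate(order, start=1):
        for lab in roots[root]:
            remap[lab] = new
    out_labels = remap[labeled]

    cross6_w = ndimage.generate_binary_structure(3, 1).astype(np.int8)
    cross6_w[1, 1, 1] = 0
    for pad, comp_crop, labs in claims:
        # claim only voxels that look frass-like in the raw volume as well:
        # the median-filtered corridor carries a thin shell of gallery-wall
        # voxels that would fatten the recovered bore.  Isolated shell voxels
        # lack face-adjacent frass support; plug bodies have plenty
        claim = comp_crop & in_band_raw[pad]
        support = ndimage.correlate(
            claim.astype(np.int8), cross6_w, mode="constant"
        )
        claim &= support >= 2
        if not claim.any():
            continue
        merged = {remap[l] for l in labs}
        if len(merged) == 1:
            target = merged.pop()
            crop_out = out_labels[pad]
            crop_out[claim] = target
            blocked[pad] |= claim
        else:
            # plug touches labels that stayed separate: give each voxel to
            # the nearest one
            lab_crop = out_labels[pad]
            dt_idx = ndimage.distance_transform_edt(
                lab_crop == 0, sampling=spacing, return_distances=False, return_indices=True
            )
            nearest = lab_crop[tuple(ind[claim] for ind in dt_idx)]
            lab_crop[claim] = nearest
            blocked[pad] |= claim

    return GalleryMask(labels=out_labels, blocked=blocked, spacing=spacing)


def smooth_mask(mask: GalleryMask, radius_mm: float = 0.5) -> GalleryMask:
    """Morphological closing then opening with a ball, per label.

    Labels are processed independently and never merge; a voxel claimed by
    two smoothed labels stays with the lower label id.
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    if radius_mm == 0:
        return GalleryMask(
            mask.labels.copy(), mask.blocked.copy(), mask.spacing, mask.labels.copy()
        )
    spacing = np.asarray(mask.spacing)
    rad_vox = np.maximum(np.round(radius_mm / spacing).astype(int), 0)
    if (rad_vox <= 1).all():
        # at sub-voxel radii an in-plane-only element would leave z-facing
        # pits open; use the full 26-neighbourhood box
        rad_vox = np.array([1, 1, 1])
        ball = np.ones((3, 3, 3), dtype=bool)
    else:
        zz, yy, xx = np.meshgrid(
            *[np.arange(-r, r + 1) for r in rad_vox], indexing="ij"
        )
        ball = (
            (zz * spacing[0]) ** 2 + (yy * spacing[1]) ** 2 + (xx * spacing[2]) ** 2
        ) <= radius_mm**2 + 1e-9

    out = np.zeros_like(mask.labels)
    pad_n = [int(r) + 1 for r in rad_vox]
    for sl, k in zip(ndimage.find_objects(mask.labels), range(1, mask.n_labels + 1)):
        if sl is None:
            continue
        pad = tuple(
            slice(max(s.start - p, 0), min(s.stop + p, dim))
            for s, p, dim in zip(sl, pad_n, mask.labels.shape)
        )
        crop = mask.labels[pad] == k
        sm = ndimage.binary_closing(crop, structure=ball)
        sm = ndimage.binary_opening(sm, structure=ball)
        if not sm.any():
            sm = crop  # never erase a gallery outright
        dest = out[pad]
        dest[sm & (dest == 0)] = k
    blocked = mask.blocked & (out > 0)
    return GalleryMask(
        labels=out, blocked=blocked, spacing=mask.spacing, unsmoothed=mask.labels.copy()
    )


def segment_volume(
    volume: CTVolume,
    *,
    threshold_low: float = AIR_INTERVAL[0],
    threshold_high: float = AIR_INTERVAL[1],
    connectivity: int = 26,
    max_gap_mm: float = DEFAULT_MAX_GAP_MM,
    frass_level: float = FRASS_LEVEL,
    band_halfwidth: float = FRASS_BAND_HALFWIDTH,
    smooth_radius_mm: float = 0.5,
    min_component_voxels: int = 50,
    seeds=None,
) -> GalleryMask:
    """Full segmentation stage: threshold -> region grow -> bridge -> smooth.

    ``seeds`` (n, 3) voxel indices override the automatic per-component
    seeding.  Interior air is separated from the surrounding air gap with a
    trunk mask before labeling.
    """
    trunk = trunk_mask(volume)
    air = threshold_air(volume, threshold_low, threshold_high) & trunk
    if seeds is None:
        seeds = auto_seeds(air, min_voxels=min_component_voxels)
    if len(seeds) == 0:
        return GalleryMask(
            labels=np.zeros(volume.shape, dtype=np.int32),
            blocked=np.zeros(volume.shape, dtype=bool),
            spacing=volume.spacing,
        )
    labeled = region_grow(air, seeds, connectivity=connectivity)
    bridged = bridge_blockage(
        labeled,
        air,
        volume,
        max_gap_mm=max_gap_mm,
        frass_level=frass_level,
        band_halfwidth=band_halfwidth,
    )
    return smooth_mask(bridged, smooth_radius_mm)
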