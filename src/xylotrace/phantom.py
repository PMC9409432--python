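"""Synthetic wood-segment CT phantoms with known gallery ground truth.

The generator emulates what a clinical multi-slice CT of an infested pine
trunk segment looks like:

* a wood cylinder with concentric annual-ring bands (two-level earlywood /
  latewood attenuation) around a pith that may sit off-centre and drift
  slowly along the axis;
* air-filled larval galleries whose centreline geometry follows the published
  per-class distributions of total length, boring depth and axial extent,
  widening from the entrance hole towards the pupal chamber;
* frass-blocked gallery sections rendered at a wood-like attenuation (the
  frass-feces mixture is radiologically similar to xylem, which is exactly
  what makes real segmentations hard);
* optionally a larva, brighter than the xylem, inside the chamber;
* additive Gaussian scanner noise.

All attenuations are on a Hounsfield-like scale chosen to preserve the
qualitative ordering air < frass ~ wood < larva.  Every random draw flows
from a single seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .reference import (
    BLOCKAGE_FRACTION_RANGE,
    GALLERY_TYPES,
    GROUP_SIZES,
    REFERENCE_SUMMARIES,
    SEGMENT_DIAMETERS_CM,
)
from .types import CTVolume

__all__ = [
    "RingModel",
    "GalleryTruth",
    "GalleryParams",
    "PhantomConfig",
    "GeometryError",
    "PlacementError",
    "generate_centerline",
    "rasterize_tube",
    "generate_phantom",
    "truth_mask",
    "default_fixture_configs",
    "sample_params",
]


class GeometryError(ValueError):
    """Requested gallery geometry cannot be realized (e.g. length too short
    to span the requested depth)."""


class PlacementError(RuntimeError):
    """Could not place the requested number of pairwise-disjoint galleries."""

    def __init__(self, requested: int, placed: int):
        super().__init__(
            f"only {placed} of {requested} galleries could be placed without overlap"
        )
        self.requested = requested
        self.placed = placed


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RingModel:
    """Annual-ring geometry of one trunk segment.

    ``pith_mm`` gives the per-slice (y, x) pith position in mm; the trunk
    boundary is a circle of ``trunk_radius_mm`` around ``center_mm`` (the
    pith need not coincide with the geometric centre).
    """

    pith_mm: np.ndarray  # (nz, 2) -> (y, x) mm per slice
    ring_period_mm: float
    band_attenuations: tuple[float, float]  # (earlywood, latewood)
    trunk_radius_mm: float
    center_mm: tuple[float, float]  # (y, x) of the trunk circle centre
    bark_thickness_mm: float = 0.0
    earlywood_fraction: float = 0.6

    def __post_init__(self) -> None:
        self.pith_mm = np.asarray(self.pith_mm, dtype=float)
        if self.ring_period_mm <= 0:
            raise ValueError("ring_period_mm must be positive")
        if not self.trunk_radius_mm > self.bark_thickness_mm >= 0:
            raise ValueError("need trunk_radius_mm > bark_thickness_mm >= 0")


@dataclass
class GalleryTruth:
    """Ground truth for one synthetic gallery (world coordinates, mm)."""

    type_label: str
    centerline_mm: np.ndarray  # (n, 3) (z, y, x); index 0 = entrance
    radius_profile_mm: np.ndarray  # (n,)
    blocked_intervals_mm: list[tuple[float, float]]  # arc-length ranges
    entrance_index: int = 0
    emergence_index: int = -1
    branch_mm: np.ndarray | None = None  # surface hole first, attachment last
    branch_radius_mm: np.ndarray | None = None
    branch_attach: int | None = None
    larva_present: bool = False
    larva_pose: dict | None = None
    requested: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centerline_mm = np.asarray(self.centerline_mm, dtype=float)
        self.radius_profile_mm = np.asarray(self.radius_profile_mm, dtype=float)
        if len(self.centerline_mm) < 2:
            raise ValueError("centerline needs >= 2 points")
        if np.any(self.radius_profile_mm <= 0):
            raise ValueError("radii must be positive")
        total = self.arc_length_mm()[-1]
        for a, b in self.blocked_intervals_mm:
            if not (0 <= a <= b <= total + 1e-6):
                raise ValueError(f"blocked interval ({a}, {b}) outside [0, {total}]")
        if self.type_label == "Y" and self.branch_mm is None:
            raise ValueError("Y gallery needs a branch polyline")
        if self.type_label in ("C", "S") and self.branch_mm is not None:
            raise ValueError(f"{self.type_label} gallery must not have a branch")

    def arc_length_mm(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.centerline_mm, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length_mm(self) -> float:
        return float(self.arc_length_mm()[-1])

    @property
    def blocked_length_mm(self) -> float:
        return float(sum(b - a for a, b in self.blocked_intervals_mm))


@dataclass
class GalleryParams:
    """Target geometry for one gallery, in mm / mm^3."""

    total_length_mm: float
    boring_depth_mm: float
    vertical_length_mm: float
    entrance_radius_mm: float
    boring_volume_mm3: float
    blockage_fraction: float
    trunk_radius_mm: float
    trunk_center_mm: tuple[float, float]
    entrance_azimuth_rad: float = 0.0
    entrance_z_mm: float = 20.0
    larva_present: bool = False

    def validate(self) -> None:
        if self.total_length_mm <= 0 or self.boring_depth_mm <= 0:
            raise GeometryError("length and depth must be positive")
        if self.total_length_mm < 2.0 * self.boring_depth_mm:
            raise GeometryError(
                f"total length {self.total_length_mm:.1f} mm cannot span depth "
                f"{self.boring_depth_mm:.1f} mm twice (in and out)"
            )
        if self.boring_depth_mm >= self.trunk_radius_mm - 5.0:
            raise GeometryError("boring depth reaches the pith region")
        if not 0 <= self.blockage_fraction < 1:
            raise GeometryError("blockage fraction must be in [0, 1)")


@dataclass
class PhantomConfig:
    """Everything needed to generate one phantom volume deterministically."""

    spacing: tuple[float, float, float] = (0.68, 0.339844, 0.339844)
    n_slices: int = 220
    trunk_diameter_mm: float = 170.0
    counts: dict = field(default_factory=lambda: {"C": 1, "S": 0, "Y": 0})
    #: per-parameter, per-type (mean, sd); defaults derived from the published
    #: summaries in :mod:`xylotrace.reference`
    distributions: dict = field(default_factory=dict)
    blockage_fraction_range: tuple[float, float] = BLOCKAGE_FRACTION_RANGE
    attenuation: dict = field(
        default_factory=lambda: {
            "air": -1000.0,
            "earlywood": -700.0,
            "latewood": -550.0,
            "frass": -620.0,
            "larva": -300.0,
        }
    )
    noise_sd: float = 20.0
    ring_period_mm: float = 4.0
    pith_offset_mm: tuple[float, float] = (3.0, -2.0)
    pith_drift_mm_per_mm: tuple[float, float] = (0.02, -0.015)
    margin_mm: float = 6.0  # air margin around the trunk in-plane
    axial_margin_mm: float = 12.0  # keep galleries off the cut ends
    clearance_mm: float = 6.0  # min wood between two gallery walls
    larva_count: int = 0
    max_placement_tries: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        att = self.attenuation
        wood_lo = min(att["earlywood"], att["latewood"])
        if not (att["air"] < att["frass"] < att["larva"] and att["air"] < wood_lo):
            raise ValueError("attenuation ordering air < frass/wood < larva violated")
        lo, hi = self.blockage_fraction_range
        if not 0 <= lo <= hi < 1:
            raise ValueError("blockage fraction range must lie inside [0, 1)")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("gallery counts must be >= 0")
        if not self.distributions:
            self.distributions = default_distributions()

    @property
    def shape(self) -> tuple[int, int, int]:
        dz, dy, dx = self.spacing
        n_inplane = int(np.ceil((self.trunk_diameter_mm + 2 * self.margin_mm) / dx))
        return (self.n_slices, n_inplane, n_inplane)

    @property
    def trunk_radius_mm(self) -> float:
        return self.trunk_diameter_mm / 2.0


def default_distributions(cv_cap: float = 0.45) -> dict:
    """Per-gallery sampling distributions reconstructed from published
    mean +/- SE summaries.

    The between-gallery SD is ``SE * sqrt(n)`` for the reported group sizes,
    capped at a coefficient of variation of ``cv_cap``: the C class has
    n = 36, and an uncapped back-transformed SD would exceed the mean for
    several parameters, which cannot describe strictly positive gallery
    geometry.  Entrance width gets a tighter 18% cap — the bore diameter is
    set by the larval head capsule, a far less variable trait than gallery
    lengths or volumes.
    """
    caps = {"entrance_width_mm": 0.18}
    dists: dict = {}
    for param, per_type in REFERENCE_SUMMARIES.items():
        dists[param] = {}
        cap = caps.get(param, cv_cap)
        for t, (mean, se) in per_type.items():
            sd = min(se * np.sqrt(GROUP_SIZES[t]), cap * mean)
            dists[param][t] = (mean, sd)
    return dists


# ---------------------------------------------------------------------------
# centerline templates
# ---------------------------------------------------------------------------

_N_TEMPLATE = 600  # samples per template curve


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _max_curvature(pts: np.ndarray) -> float:
    """Maximum discrete curvature (1/mm) of a densely sampled polyline."""
    d = np.diff(pts, axis=0)
    ds = np.linalg.norm(d, axis=1)
    keep = ds > 1e-9
    t = d[keep] / ds[keep, None]
    dt = np.linalg.norm(np.diff(t, axis=0), axis=1)
    mids = 0.5 * (ds[keep][1:] + ds[keep][:-1])
    return float((dt / mids).max()) if len(dt) else 0.0


def _c_template(V: float, D: float, width: float, sep_frac: float, q: float) -> np.ndarray:
    """C-shaped local curve: a tilted half-ellipse.

    Both holes sit at (nearly) the same axial height; the apex reaches depth
    ``D`` and axial offset ``V``.  ``width`` is the tangential half-distance
    between the two holes.  Returns (n, 3) columns (zeta axial, tau
    tangential, delta radial-inward depth).
    """
    s = np.linspace(0.0, 1.0, _N_TEMPLATE)
    phi = np.pi * s
    tau = width * np.cos(phi)
    bump = np.sin(phi) ** q
    delta = D * bump
    zeta = V * bump + sep_frac * V * s  # small same-end offset between holes
    zeta -= zeta.min()
    return np.column_stack([zeta, tau, delta])


def _s_template(V: float, D: float, width: float, q: float) -> np.ndarray:
    """S-shaped local curve: monotone axial run with two opposite bends."""
    s = np.linspace(0.0, 1.0, _N_TEMPLATE)
    zeta = V * s
    tau = width * np.sin(2 * np.pi * s)
    delta = D * np.sin(np.pi * s) ** q
    return np.column_stack([zeta, tau, delta])


def _solve_width(
    make: callable, target_len: float, w_min: float, w_max: float = 80.0
) -> tuple[float, np.ndarray] | None:
    """Find the template width whose arc length matches ``target_len``.

    Arc length is strictly increasing in the width, so plain bisection
    suffices.  Returns None when even ``w_min`` is too long.
    """
    lo, hi = w_min, w_max
    pts_lo = make(lo)
    if _polyline_length(pts_lo) > target_len:
        return None
    pts_hi = make(hi)
    if _polyline_length(pts_hi) < target_len:
        return hi, pts_hi  # saturate: curve as wide as allowed
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _polyline_length(make(mid)) < target_len:
            lo = mid
        else:
            hi = mid
    w = 0.5 * (lo + hi)
    return w, make(w)


def _fit_local_curve(
    type_label: str,
    L: float,
    D: float,
    V: float,
    q: float,
    sep: float,
    rho_min: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Build the local (zeta, tau, delta) curve for one gallery.

    Total length ``L`` and boring depth ``D`` are honoured exactly (arc length
    within well under 1%); the axial extent is reduced below the requested
    ``V`` when the three targets are jointly unreachable — which the published
    class means frequently are for same-end (C/Y) galleries — or when the
    resulting turn would be tighter than ``rho_min`` (a tube cannot bend
    tighter than its own radius without self-overlapping, and its medial axis
    would shortcut such a turn).
    """
    if type_label in ("C", "Y"):
        w_min = 9.0

        def make(w: float, V_: float) -> np.ndarray:
            return _c_template(V_, D, w, sep, q)

    elif type_label == "S":
        w_min = 0.5

        def make(w: float, V_: float) -> np.ndarray:
            return _s_template(V_, D, w, q)

    else:
        raise ValueError(f"unknown gallery type {type_label!r}")

    if L < 2.05 * D:
        raise GeometryError(f"length {L:.1f} mm too short for depth {D:.1f} mm")

    def attempt(V_: float):
        sol = _solve_width(lambda w: make(w, V_), L, w_min)
        if sol is None:
            return None
        _, pts = sol
        if rho_min > 0:
            interior = pts[len(pts) // 25 : -len(pts) // 25]
            if _max_curvature(interior) * rho_min > 1.0:
                return None
        return pts

    pts = attempt(V)
    if pts is not None:
        return pts, V
    if type_label == "S":
        raise GeometryError(
            f"S gallery of length {L:.1f} mm, depth {D:.1f} mm, extent {V:.1f} mm "
            "would turn tighter than its own bore"
        )
    # same-end (C/Y) geometry: the requested axial extent is unreachable at
    # this length (or would force a hairpin tighter than the bore) -> find
    # the largest feasible extent below it
    v_lo, v_hi = 1.0, V
    if attempt(v_lo) is None:
        raise GeometryError(
            f"length {L:.1f} mm cannot realize depth {D:.1f} mm for type {type_label}"
        )
    for _ in range(40):
        v_mid = 0.5 * (v_lo + v_hi)
        if attempt(v_mid) is None:
            v_hi = v_mid
        else:
            v_lo = v_mid
    return attempt(v_lo), v_lo


def _local_to_world(
    local: np.ndarray,
    trunk_center: tuple[float, float],
    trunk_radius: float,
    azimuth: float,
    z0: float,
) -> np.ndarray:
    """Map (zeta, tau, delta) local gallery coordinates to world (z, y, x) mm.

    tau is an azimuthal arc offset measured at the trunk surface; delta is
    depth below the surface towards the trunk axis.
    """
    zeta, tau, delta = local.T
    theta = azimuth + tau / trunk_radius
    rho = trunk_radius - delta
    cy, cx = trunk_center
    return np.column_stack([z0 + zeta, cy + rho * np.sin(theta), cx + rho * np.cos(theta)])


def _radius_profile(
    L: float, r_entrance: float, volume_target: float, n: int
) -> np.ndarray:
    """Linear taper from the entrance bore to the pupal-chamber end, scaled so
    the tube volume matches ``volume_target`` (chamber end widest)."""
    k = 3.0 * volume_target / (np.pi * L)
    disc = 4.0 * k - 3.0 * r_entrance**2
    if disc <= 0:
        r_end = r_entrance
    else:
        r_end = (-r_entrance + np.sqrt(disc)) / 2.0
    r_end = float(np.clip(r_end, max(1.1, 0.9 * r_entrance), 8.0))
    return np.linspace(r_entrance, r_end, n)


def _blocked_intervals(
    arc_mm: np.ndarray,
    fraction: float,
    radii: np.ndarray,
    rng: np.random.Generator,
    max_piece_mm: float = 22.0,
    min_gap_mm: float = 8.0,
    tail_free_mm: float = 12.0,
    entrance_cap_mm: float | None = None,
) -> list[tuple[float, float]]:
    """Place frass plugs totalling ``fraction`` of the tube *volume*.

    Plugs go where larvae actually pack frass: first right at the entrance
    hole, then ahead of the pupal chamber, then (rarely needed) mid-gallery.
    Individual plugs are capped in arc length so blockage bridging with the
    default gap limit always reconnects the air fragments; the volume target
    can therefore fall short for extreme draws, never overshoot.
    """
    s = np.asarray(arc_mm)
    L = float(s[-1])
    if fraction <= 0 or L <= tail_free_mm + 2:
        return []
    r2 = np.asarray(radii) ** 2
    w = np.concatenate([[0.0], np.cumsum(0.5 * (r2[1:] + r2[:-1]) * np.diff(s))])

    def share(a: float, b: float) -> float:
        return float(np.interp(b, s, w) - np.interp(a, s, w))

    def grow(a: float, b_cap: float, want: float) -> float:
        """End point b <= b_cap such that share(a, b) == want (or saturated)."""
        if share(a, b_cap) <= want:
            return b_cap
        lo, hi = a, b_cap
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if share(a, mid) < want:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    target = fraction * w[-1]
    a1 = float(rng.uniform(2.5, 6.0))  # leave a seedable air stub at the hole
    a2 = 0.60 * L + float(rng.uniform(0.0, 0.06 * L))
    a3 = 0.34 * L + float(rng.uniform(0.0, 0.04 * L))
    e_cap = np.inf if entrance_cap_mm is None else entrance_cap_mm
    caps = {
        "entrance": (a1, min(a1 + max_piece_mm, a3 - min_gap_mm, e_cap)),
        "chamber": (a2, min(a2 + max_piece_mm, L - tail_free_mm)),
        "middle": (a3, min(a3 + max_piece_mm, a2 - min_gap_mm)),
    }
    intervals: list[tuple[float, float]] = []
    remaining = target
    for name in ("entrance", "chamber", "middle"):
        if remaining <= 1e-9:
            break
        a, b_cap = caps[name]
        if b_cap <= a + 0.5:
            continue
        b = grow(a, b_cap, remaining)
        remaining -= share(a, b)
        intervals.append((float(a), float(b)))
    return sorted(intervals)


def generate_centerline(
    type_label: str, params: GalleryParams, rng: np.random.Generator
) -> GalleryTruth:
    """Generate the ground-truth geometry of a single gallery.

    The centerline starts and ends on the trunk surface; C and Y galleries
    keep both holes at (nearly) the same axial height, S galleries at opposite
    axial ends.  Y galleries get one branch leaving the main path on its
    entrance side and surfacing next to the entrance hole.
    """
    if type_label not in GALLERY_TYPES:
        raise ValueError(f"type_label must be one of {GALLERY_TYPES}")
    params.validate()

    L, D, V = params.total_length_mm, params.boring_depth_mm, params.vertical_length_mm
    q = float(rng.uniform(1.0, 1.3))
    sep = float(rng.uniform(0.05, 0.18))

    def to_world(local_pts: np.ndarray) -> np.ndarray:
        return _local_to_world(
            local_pts,
            params.trunk_center_mm,
            params.trunk_radius_mm,
            params.entrance_azimuth_rad,
            params.entrance_z_mm,
        )

    # the cylinder mapping contracts tangential arcs at depth, so solve the
    # template length against the target iteratively in world space
    main_volume = params.boring_volume_mm3 * (0.85 if type_label == "Y" else 1.0)
    rho_min = 1.4 * float(np.sqrt(main_volume / (np.pi * L)))
    L_adj = L
    for _ in range(6):
        local, V_eff = _fit_local_curve(type_label, L_adj, D, V, q, sep, rho_min)
        pts = to_world(local)
        realized = _polyline_length(pts)
        if abs(realized - L) <= 2e-3 * L:
            break
        L_adj *= L / realized
    radii = _radius_profile(L, params.entrance_radius_mm, main_volume, len(pts))

    branch = branch_r = None
    attach = None
    attach_arc = None
    if type_label == "Y":
        # a short, straight side exit near the entrance end: it leaves the
        # main bore on its shallow side (axial height decays slower than
        # depth along the segment, so it never grazes the diving main arm)
        # and is bored at the entrance-hole calibre
        attach = int(rng.uniform(0.20, 0.30) * len(local))
        a = local[attach]
        hole = np.array(
            [0.5 * a[0], local[0, 1] + float(rng.uniform(10.0, 14.0)), 0.0]
        )
        t = np.linspace(0.0, 1.0, 200)[:, None]
        line = (1 - t) * a + t * hole
        branch = _local_to_world(
            line,
            params.trunk_center_mm,
            params.trunk_radius_mm,
            params.entrance_azimuth_rad,
            params.entrance_z_mm,
        )[::-1]  # stored surface-hole first, attachment last
        branch_r = np.full(
            len(branch), params.entrance_radius_mm * float(rng.uniform(0.95, 1.05))
        )
        seg_main = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        attach_arc = float(seg_main[:attach].sum())

    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    realized_L = float(seg.sum())
    truth = GalleryTruth(
        type_label=type_label,
        centerline_mm=pts,
        radius_profile_mm=radii,
        blocked_intervals_mm=_blocked_intervals(
            np.concatenate([[0.0], np.cumsum(seg)]),
            params.blockage_fraction,
            radii,
            rng,
            entrance_cap_mm=None if attach_arc is None else attach_arc - 6.0,
        ),
        branch_mm=branch,
        branch_radius_mm=branch_r,
        branch_attach=attach,
        larva_present=params.larva_present,
        requested={
            "total_length_mm": L,
            "boring_depth_mm": D,
            "vertical_length_mm": V,
            "vertical_length_realized_mm": V_eff,
            "entrance_radius_mm": params.entrance_radius_mm,
            "boring_volume_mm3": params.boring_volume_mm3,
            "blockage_fraction": params.blockage_fraction,
        },
    )
    if params.larva_present:
        arc = truth.arc_length_mm()
        i = int(np.searchsorted(arc, arc[-1] - 0.5 * radii[-1] * 6))
        i = min(max(i, 1), len(pts) - 2)
        axis = pts[min(i + 5, len(pts) - 1)] - pts[max(i - 5, 0)]
        axis = axis / (np.linalg.norm(axis) + 1e-12)
        truth.larva_pose = {
            "center_mm": pts[i].tolist(),
            "axis": axis.tolist(),
            "half_length_mm": 9.0,
            "radius_mm": float(0.6 * radii[i]),
        }
    return truth


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _decimate(pts: np.ndarray, radii: np.ndarray, step_mm: float = 0.6):
    """Resample a dense polyline to roughly uniform segment length."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(arc[-1] / step_mm), 2)
    s = np.linspace(0.0, arc[-1], n + 1)
    out = np.column_stack([np.interp(s, arc, pts[:, k]) for k in range(3)])
    r = np.interp(s, arc, radii)
    return out, r, s


def _capsule_paint(
    pts: np.ndarray,
    radii: np.ndarray,
    arcs: np.ndarray,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
):
    """Mark voxels whose centre lies within the (varying-radius) capsule union
    around the polyline.  Returns (indices (m, 3), arc position per voxel,
    truncated flag)."""
    spacing = np.asarray(spacing, float)
    shape_arr = np.asarray(shape)
    flat_all, arc_all, margin_all = [], [], []
    truncated = False
    for i in range(len(pts) - 1):
        p0, p1 = pts[i], pts[i + 1]
        r0, r1 = radii[i], radii[i + 1]
        rmax = max(r0, r1)
        lo_mm = np.minimum(p0, p1) - rmax
        hi_mm = np.maximum(p0, p1) + rmax
        lo = np.floor(lo_mm / spacing).astype(int)
        hi = np.ceil(hi_mm / spacing).astype(int) + 1
        if np.any(hi <= 0) or np.any(lo >= shape_arr):
            truncated = True
            continue
        if np.any(lo < 0) or np.any(hi > shape_arr):
            truncated = True
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape_arr)
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        centers = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3) * spacing
        d = p1 - p0
        dd = float(d @ d)
        if dd == 0:
            t = np.zeros(len(centers))
        else:
            t = np.clip((centers - p0) @ d / dd, 0.0, 1.0)
        proj = p0 + t[:, None] * d
        dist = np.linalg.norm(centers - proj, axis=1)
        rad = r0 + t * (r1 - r0)
        inside = dist <= rad
        if not inside.any():
            continue
        idx = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)[inside]
        flat_all.append(np.ravel_multi_index(idx.T, shape))
        arc_all.append(arcs[i] + t[inside] * (arcs[i + 1] - arcs[i]))
        margin_all.append(rad[inside] - dist[inside])
    if not flat_all:
        return np.empty((0, 3), int), np.empty(0), truncated
    flat = np.concatenate(flat_all)
    arc = np.concatenate(arc_all)
    margin = np.concatenate(margin_all)
    # per voxel keep the arc position of the deepest-containment segment
    order = np.lexsort((-margin, flat))
    flat, arc = flat[order], arc[order]
    first = np.concatenate([[True], flat[1:] != flat[:-1]])
    flat, arcpos = flat[first], arc[first]
    idx = np.stack(np.unravel_index(flat, shape), axis=1)
    return idx, arcpos, truncated


def rasterize_tube(
    centerline_mm: np.ndarray,
    radius_profile_mm,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Rasterize a tube (capsule union around a polyline) into a boolean mask.

    A voxel is set when its centre lies within the local tube radius of the
    polyline.  A tube leaving the grid is truncated with a warning.
    """
    pts = np.atleast_2d(np.asarray(centerline_mm, float))
    radii = np.broadcast_to(np.asarray(radius_profile_mm, float), (len(pts),)).copy()
    if np.any(radii < min(spacing)):
        raise ValueError("tube radius below one voxel")
    if len(pts) == 1:
        pts = np.vstack([pts, pts])
        radii = np.concatenate([radii, radii])
    dpts, drad, arcs = _decimate(pts, radii)
    idx, _, truncated = _capsule_paint(dpts, drad, arcs, shape, spacing)
    if truncated:
        warnings.warn("tube extends beyond the volume grid; mask truncated")
    mask = np.zeros(shape, dtype=bool)
    if len(idx):
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return mask


# ---------------------------------------------------------------------------
# parameter sampling and full phantom generation
# ---------------------------------------------------------------------------


def _trunc_normal(rng, mean, sd, lo, hi, max_tries=200):
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def sample_params(
    type_label: str, config: PhantomConfig, rng: np.random.Generator
) -> GalleryParams:
    """Draw one jointly feasible parameter set for a gallery of a given type."""
    dist = config.distributions
    R = config.trunk_radius_mm

    def draw(name, lo_frac=0.4, hi_frac=2.2):
        mean, sd = dist[name][type_label]
        return _trunc_normal(rng, mean, sd, lo_frac * mean, hi_frac * mean)

    for _ in range(80):
        L = draw("total_length_mm")
        D = draw("gallery_depth_mm")
        V = draw("vertical_length_mm")
        width = draw("entrance_width_mm", 0.6, 1.6)
        vol = draw("boring_volume_mm3", 0.45, 2.0)
        if L < 2.1 * D or D > R - 8.0:
            continue
        frac = float(rng.uniform(*config.blockage_fraction_range))
        c = (config.shape[1] - 1) * config.spacing[1] / 2.0
        return GalleryParams(
            total_length_mm=L,
            boring_depth_mm=D,
            vertical_length_mm=V,
            entrance_radius_mm=width / 2.0,
            boring_volume_mm3=vol,
            blockage_fraction=frac,
            trunk_radius_mm=R,
            trunk_center_mm=(c, c),
        )
    raise GeometryError(f"could not draw feasible parameters for type {type_label}")


def _ring_volume(config: PhantomConfig, ring: RingModel) -> np.ndarray:
    """Render the ringed wood cylinder (no galleries, no noise)."""
    nz, ny, nx = config.shape
    dz, dy, dx = config.spacing
    att = config.attenuation
    early, late = att["earlywood"], att["latewood"]
    vol = np.full(config.shape, att["air"], dtype=np.float32)
    ys = np.arange(ny) * dy
    xs = np.arange(nx) * dx
    X, Y = np.meshgrid(xs, ys)
    cy, cx = ring.center_mm
    r_center = np.hypot(Y - cy, X - cx)
    trunk2d_template = r_center <= ring.trunk_radius_mm
    for z in range(nz):
        py, px = ring.pith_mm[z]
        r_pith = np.hypot(Y - py, X - px)
        phase = np.mod(r_pith / ring.ring_period_mm, 1.0)
        slab = np.where(phase < ring.earlywood_fraction, early, late).astype(np.float32)
        vol[z][trunk2d_template] = slab[trunk2d_template]
    return vol


def _make_ring_model(config: PhantomConfig, rng: np.random.Generator) -> RingModel:
    nz = config.n_slices
    dz = config.spacing[0]
    c = (config.shape[1] - 1) * config.spacing[1] / 2.0
    oy, ox = config.pith_offset_mm
    sy, sx = config.pith_drift_mm_per_mm
    z_mm = (np.arange(nz) - nz / 2.0) * dz
    pith = np.column_stack([c + oy + sy * z_mm, c + ox + sx * z_mm])
    return RingModel(
        pith_mm=pith,
        ring_period_mm=config.ring_period_mm,
        band_attenuations=(config.attenuation["earlywood"], config.attenuation["latewood"]),
        trunk_radius_mm=config.trunk_radius_mm,
        center_mm=(c, c),
    )


def _truth_polylines(truth: GalleryTruth):
    """(points, radii, arcs) for main path and, if present, the branch."""
    out = [(truth.centerline_mm, truth.radius_profile_mm, truth.arc_length_mm())]
    if truth.branch_mm is not None:
        seg = np.linalg.norm(np.diff(truth.branch_mm, axis=0), axis=1)
        arcs = np.concatenate([[0.0], np.cumsum(seg)])
        out.append((truth.branch_mm, truth.branch_radius_mm, arcs))
    return out


def _paint_truth(
    truth: GalleryTruth, config_shape, spacing, inside_trunk
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel indices of one gallery (clipped to the trunk) and a boolean
    per-voxel blocked flag derived from the true blocked arc intervals."""
    all_idx, all_blocked = [], []
    for path_i, (pts, radii, _) in enumerate(_truth_polylines(truth)):
        dpts, drad, arcs = _decimate(pts, radii, step_mm=0.5)
        idx, arcpos, _ = _capsule_paint(dpts, drad, arcs, config_shape, spacing)
        if not len(idx):
            continue
        keep = inside_trunk[idx[:, 0], idx[:, 1], idx[:, 2]]
        idx, arcpos = idx[keep], arcpos[keep]
        blocked = np.zeros(len(idx), dtype=bool)
        if path_i == 0:
            for a, b in truth.blocked_intervals_mm:
                blocked |= (arcpos >= a) & (arcpos <= b)
        all_idx.append(idx)
        all_blocked.append(blocked)
    if not all_idx:
        return np.empty((0, 3), int), np.empty(0, bool)
    idx = np.vstack(all_idx)
    blocked = np.concatenate(all_blocked)
    flat = np.ravel_multi_index(idx.T, config_shape)
    _, first = np.unique(flat, return_index=True)
    return idx[first], blocked[first]


def truth_mask(
    truths: list[GalleryTruth],
    config: PhantomConfig,
    ring: RingModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize ground-truth galleries into (labels, blocked) arrays.

    Labels follow the order of ``truths`` (1-based); used by tests to compare
    recovered masks against the exact voxel-level truth.
    """
    nz, ny, nx = config.shape
    dy = config.spacing[1]
    ys = np.arange(ny) * dy
    xs = np.arange(nx) * config.spacing[2]
    X, Y = np.meshgrid(xs, ys)
    cy, cx = ring.center_mm
    inside2d = np.hypot(Y - cy, X - cx) <= ring.trunk_radius_mm
    inside = np.broadcast_to(inside2d, config.shape)
    labels = np.zeros(config.shape, dtype=np.int16)
    blocked = np.zeros(config.shape, dtype=bool)
    for k, truth in enumerate(truths, start=1):
        idx, blk = _paint_truth(truth, config.shape, config.spacing, inside)
        labels[idx[:, 0], idx[:, 1], idx[:, 2]] = k
        bidx = idx[blk]
        blocked[bidx[:, 0], bidx[:, 1], bidx[:, 2]] = True
    return labels, blocked


def _min_polyline_distance(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    return float(cKDTree(a).query(b, k=1)[0].min())


def _gallery_points(truth: GalleryTruth) -> np.ndarray:
    pts = [truth.centerline_mm]
    if truth.branch_mm is not None:
        pts.append(truth.branch_mm)
    return np.vstack(pts)


def generate_phantom(
    config: PhantomConfig,
) -> tuple[CTVolume, list[GalleryTruth], RingModel]:
    """Generate one wood-segment phantom with ground truth.

    Galleries are placed with azimuthally jittered entrance holes, never on
    the cut ends, and are rejection-resampled until pairwise disjoint with a
    configured wall clearance.  Gaussian noise is added last.
    """
    rng = np.random.default_rng(config.seed)
    ring = _make_ring_model(config, rng)
    vol = _ring_volume(config, ring)

    dz = config.spacing[0]
    z_hi = config.n_slices * dz - config.axial_margin_mm
    att = config.attenuation

    order = [t for t in GALLERY_TYPES for _ in range(config.counts.get(t, 0))]
    rng.shuffle(order)
    n_larvae = min(config.larva_count, len(order))

    placed: list[GalleryTruth] = []
    placed_pts: list[np.ndarray] = []
    for gi, t in enumerate(order):
        ok = False
        for _ in range(config.max_placement_tries):
            params = sample_params(t, config, rng)
            params.entrance_azimuth_rad = float(rng.uniform(0, 2 * np.pi))
            params.larva_present = gi < n_larvae
            # the realized axial extent never exceeds the requested one, so
            # clamp the request to what fits between the cut-end margins
            avail = z_hi - config.axial_margin_mm - 10.0
            if avail < 10.0:
                raise PlacementError(len(order), len(placed))
            params.vertical_length_mm = min(params.vertical_length_mm, avail)
            z_span = params.vertical_length_mm + 10.0
            params.entrance_z_mm = float(
                rng.uniform(config.axial_margin_mm, z_hi - z_span)
            )
            try:
                cand = generate_centerline(t, params, rng)
            except GeometryError:
                continue
            cpts = _gallery_points(cand)
            rmax_c = float(cand.radius_profile_mm.max())
            clear = True
            for prev, ppts in zip(placed, placed_pts):
                rmax_p = float(prev.radius_profile_mm.max())
                need = rmax_c + rmax_p + config.clearance_mm
                if _min_polyline_distance(ppts, cpts) < need:
                    clear = False
                    break
            if clear:
                placed.append(cand)
                placed_pts.append(cpts)
                ok = True
                break
        if not ok:
            raise PlacementError(len(order), len(placed))

    labels, blocked = truth_mask(placed, config, ring)
    vol[(labels > 0) & ~blocked] = att["air"]
    vol[blocked] = att["frass"]

    for truth in placed:
        if truth.larva_present and truth.larva_pose:
            _paint_larva(vol, labels, blocked, truth, config, att["larva"])

    if config.noise_sd > 0:
        vol += rng.normal(0.0, config.noise_sd, size=vol.shape).astype(np.float32)

    return CTVolume(vol, config.spacing), placed, ring


def _paint_larva(vol, labels, blocked, truth, config, larva_att) -> None:
    """Render an ellipsoidal larva inside the pupal chamber (brighter than
    wood), leaving an air ring so the gallery stays connected."""
    pose = truth.larva_pose
    center = np.asarray(pose["center_mm"])
    axis = np.asarray(pose["axis"])
    hl, rad = pose["half_length_mm"], pose["radius_mm"]
    spacing = np.asarray(config.spacing)
    lo = np.maximum(np.floor((center - hl) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center + hl) / spacing).astype(int) + 1, config.shape)
    zz, yy, xx = np.meshgrid(*[np.arange(lo[k], hi[k]) for k in range(3)], indexing="ij")
    pts = np.stack([zz, yy, xx], -1).reshape(-1, 3) * spacing - center
    along = pts @ axis
    perp = np.linalg.norm(pts - along[:, None] * axis, axis=1)
    inside = (along / hl) ** 2 + (perp / rad) ** 2 <= 1.0
    idx = np.stack([zz, yy, xx], -1).reshape(-1, 3)[inside]
    k = (labels[idx[:, 0], idx[:, 1], idx[:, 2]] > 0) & ~blocked[
        idx[:, 0], idx[:, 1], idx[:, 2]
    ]
    idx = idx[k]
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = larva_att


def default_fixture_configs(seed: int = 0) -> list[PhantomConfig]:
    """The five-segment reference fixture: 43 complete galleries (36 C, 3 S,
    4 Y) spread over five trunk segments with the published diameters."""
    counts_per_volume = [
        {"C": 8, "S": 1, "Y": 0},
        {"C": 7, "S": 1, "Y": 1},
        {"C": 7, "S": 0, "Y": 2},
        {"C": 7, "S": 1, "Y": 0},
        {"C": 7, "S": 0, "Y": 1},
    ]
    seeds = np.random.SeedSequence(seed).generate_state(5) % (2**31)
    configs = []
    for diam_cm, counts, s in zip(SEGMENT_DIAMETERS_CM, counts_per_volume, seeds):
        configs.append(
            PhantomConfig(
                trunk_diameter_mm=diam_cm * 10.0,
                counts=counts,
                seed=int(s),
            )
        )
    return configs
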