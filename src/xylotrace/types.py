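"""Shared containers for volumes, masks, centerlines and per-gallery metrics.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)`` with ``z`` the trunk (axial) direction;
* voxel indices are 0-based; world coordinates are ``index * spacing`` in mm,
  with no origin offset;
* all lengths are mm, all volumes mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CTVolume",
    "GalleryMask",
    "Centerline",
    "GalleryMetrics",
    "METRIC_COLUMNS",
]


@dataclass
class CTVolume:
    """A 3D attenuation grid with physical voxel spacing.

    Attenuation is on a Hounsfield-like relative scale (air around -1000,
    xylem between roughly -700 and -550); no absolute calibration is implied.
    """

    voxels: np.ndarray  # (nz, ny, nx)
    spacing: tuple[float, float, float]  # (dz, dy, dx) in mm

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass
class GalleryMask:
    """Labeled gallery voxels plus the frass-blocked sub-mask.

    ``labels`` holds 0 for background and k >= 1 for gallery k.  ``blocked``
    marks voxels attributed to a gallery through frass-blockage bridging; it is
    always a subset of ``labels > 0``.
    """

    labels: np.ndarray  # integer array, same shape as the source volume
    blocked: np.ndarray  # bool array, same shape
    spacing: tuple[float, float, float]
    #: pre-smoothing labels (same ids); fine sub-voxel measurements sample
    #: these to avoid the slight bore dilation of morphological smoothing
    unsmoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.blocked = np.asarray(self.blocked, dtype=bool)
        if self.labels.shape != self.blocked.shape:
            raise ValueError("labels and blocked must have identical shapes")
        if np.any(self.blocked & (self.labels == 0)):
            raise ValueError("blocked voxels must carry a gallery label")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def label_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass
class Centerline:
    """An ordered 3D polyline (mm, world coordinates) through a gallery.

    ``points_mm`` runs from the entrance hole to the emergence hole.  Y-shaped
    galleries carry the extra limb in ``branch_mm``, attached to the main path
    at index ``branch_attach``.
    """

    points_mm: np.ndarray  # (n, 3) in (z, y, x) mm
    branch_mm: np.ndarray | None = None  # (m, 3) from attachment to surface
    branch_attach: int | None = None
    entrance_index: int = 0
    emergence_index: int = -1

    def __post_init__(self) -> None:
        self.points_mm = np.asarray(self.points_mm, dtype=float)
        if self.points_mm.ndim != 2 or self.points_mm.shape[0] < 2:
            raise ValueError("centerline needs at least two 3D points")
        if self.branch_mm is not None:
            self.branch_mm = np.asarray(self.branch_mm, dtype=float)

    @property
    def arc_length_mm(self) -> np.ndarray:
        """Cumulative arc length from the entrance, one value per point."""
        seg = np.linalg.norm(np.diff(self.points_mm, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_arc_mm(self) -> float:
        return float(self.arc_length_mm[-1])

    @property
    def branch_length_mm(self) -> float:
        if self.branch_mm is None or len(self.branch_mm) < 2:
            return 0.0
        seg = np.linalg.norm(np.diff(self.branch_mm, axis=0), axis=1)
        return float(seg.sum())

    @property
    def has_branch(self) -> bool:
        return self.branch_mm is not None and len(self.branch_mm) >= 2

    def reversed(self) -> "Centerline":
        n = len(self.points_mm)
        attach = None if self.branch_attach is None else n - 1 - self.branch_attach
        return Centerline(
            points_mm=self.points_mm[::-1].copy(),
            branch_mm=None if self.branch_mm is None else self.branch_mm.copy(),
            branch_attach=attach,
            entrance_index=0,
            emergence_index=-1,
        )


#: column order of the per-gallery metrics table (the standard seven gallery
#: parameters, in the order they are conventionally reported).
METRIC_COLUMNS = [
    "entrance_width_mm",
    "gallery_depth_mm",
    "vertical_length_mm",
    "blockage_length_mm",
    "blockage_volume_mm3",
    "total_length_mm",
    "boring_volume_mm3",
]


@dataclass
class GalleryMetrics:
    """The seven morphometric parameters of one gallery, plus its type."""

    entrance_width_mm: float
    gallery_depth_mm: float
    vertical_length_mm: float
    blockage_length_mm: float
    blockage_volume_mm3: float
    total_length_mm: float
    boring_volume_mm3: float
    type_label: str = "?"
    label: int = 0
    branch_length_mm: float = 0.0
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        vals = [getattr(self, c) for c in METRIC_COLUMNS]
        if any(v < 0 for v in vals):
            raise ValueError(f"negative metric in {self}")
        if self.blockage_volume_mm3 > self.boring_volume_mm3 * (1 + 1e-9):
            raise ValueError("blockage volume exceeds boring volume")
        if self.blockage_length_mm > self.total_length_mm * (1 + 1e-9):
            raise ValueError("blockage length exceeds total length")

    def as_row(self) -> dict:
        row = {"label": self.label, "type": self.type_label}
        row.update({c: getattr(self, c) for c in METRIC_COLUMNS})
        row["branch_length_mm"] = self.branch_length_mm
        return row
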