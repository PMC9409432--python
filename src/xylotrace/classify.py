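"""C / S / Y gallery typing from centerline topology and hole placement.

The typology follows the field convention for pine-sawyer galleries:

* **Y** — the centerline branches to a third surface hole;
* **C** — no branch, entrance and emergence holes at the same axial end of
  the gallery (small axial hole separation relative to the vertical extent);
* **S** — no branch, holes at opposite axial ends.

A gallery with fewer than two surface holes (larva still boring, or a
gallery truncated by the cut ends of the segment) is *incomplete* and is
excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import Centerline

__all__ = ["TypeCall", "classify_gallery", "DEFAULT_SAME_END_RATIO"]

#: axial hole separation / vertical extent at or below which the two holes
#: count as being at the "same end" (C rather than S)
DEFAULT_SAME_END_RATIO = 0.35


@dataclass
class TypeCall:
    """A gallery type decision with its evidence."""

    label: int
    type_label: str  # C, S, Y or incomplete
    branch_count: int
    axial_separation_mm: float
    separation_ratio: float

    def __post_init__(self) -> None:
        if self.type_label == "Y" and self.branch_count < 1:
            raise ValueError("Y requires at least one branch")
        if self.type_label in ("C", "S") and self.branch_count != 0:
            raise ValueError(f"{self.type_label} must have no branch")


def classify_gallery(
    centerline: Centerline | None,
    vertical_length_mm: float,
    same_end_ratio: float = DEFAULT_SAME_END_RATIO,
    label: int = 0,
) -> TypeCall:
    """Assign C, S or Y from a measured centerline.

    A branched centerline is Y regardless of hole placement.  Otherwise the
    axial separation of the two surface holes, relative to the gallery's
    vertical extent, separates C (same end) from S (opposite ends).  The
    decision is invariant to the orientation of the centerline.
    """
    if centerline is None:
        return TypeCall(label, "incomplete", 0, 0.0, 0.0)
    sep = abs(float(centerline.points_mm[-1, 0] - centerline.points_mm[0, 0]))
    ratio = sep / vertical_length_mm if vertical_length_mm > 0 else 0.0
    if centerline.has_branch:
        return TypeCall(label, "Y", 1, sep, ratio)
    if ratio <= same_end_ratio:
        return TypeCall(label, "C", 0, sep, ratio)
    return TypeCall(label, "S", 0, sep, ratio)
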