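"""Published reference statistics for *Monochamus alternatus* galleries.

Field measurements of pine-sawyer larval galleries in *Pinus densiflora*
report, per gallery shape class (C, S, Y), the mean +/- standard error of the
seven standard gallery parameters, from 43 complete galleries found in five
trunk segments (36 C-shaped, 3 S-shaped, 4 Y-shaped).  These summaries drive
two things in this package:

* the default sampling distributions of the synthetic phantom generator, and
* the summary-statistics ANOVA reconstruction used as a cross-check of the
  statistics module.

Group sizes are not printed alongside the summaries; they are reconstructed
from the reported shape-class percentages (83.72% / 6.97% / 9.3% of 43),
giving n = (36, 3, 4).
"""

from __future__ import annotations

__all__ = [
    "GALLERY_TYPES",
    "GROUP_SIZES",
    "REFERENCE_SUMMARIES",
    "SEGMENT_DIAMETERS_CM",
    "BLOCKAGE_FRACTION_RANGE",
]

GALLERY_TYPES = ("C", "S", "Y")

#: complete galleries per shape class in the reference survey
GROUP_SIZES = {"C": 36, "S": 3, "Y": 4}

#: mean +/- SE per shape class; keys match the metrics table columns
REFERENCE_SUMMARIES = {
    "entrance_width_mm": {"C": (2.90, 0.44), "S": (3.10, 0.26), "Y": (2.81, 0.27)},
    "gallery_depth_mm": {"C": (29.51, 8.90), "S": (36.44, 5.93), "Y": (33.11, 10.17)},
    "vertical_length_mm": {"C": (47.68, 16.78), "S": (51.10, 16.48), "Y": (42.60, 10.10)},
    "blockage_length_mm": {"C": (25.73, 17.10), "S": (38.29, 8.69), "Y": (30.52, 21.84)},
    "blockage_volume_mm3": {"C": (806.59, 777.51), "S": (952.73, 296.72), "Y": (558.21, 423.15)},
    "total_length_mm": {"C": (79.16, 25.77), "S": (108.73, 17.35), "Y": (88.49, 29.04)},
    "boring_volume_mm3": {"C": (2988.01, 274.9), "S": (3669.26, 794.4), "Y": (2530.80, 705.0)},
}

#: diameters of the five scanned trunk segments, cm
SEGMENT_DIAMETERS_CM = (17.5, 18.2, 16.4, 16.1, 17.0)

#: frass-blocked fraction of total gallery volume observed across galleries
BLOCKAGE_FRACTION_RANGE = (0.07, 0.36)
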