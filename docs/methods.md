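# Methods

`xylotrace` reconstructs and measures the larval galleries that wood-boring
beetles (the pine sawyer *Monochamus alternatus* in the motivating use case)
excavate inside trunk xylem, from X-ray CT volumes of trunk segments. This
note records the models, the measurement definitions, the synthetic-data
design, and the numerical choices, in enough detail to judge what a passing
test suite does and does not demonstrate.

## The measurement problem

A CT scan of an infested trunk segment shows galleries as air-filled tunnels
(attenuation far below xylem), except where the larva has packed them with a
frass–feces mixture whose attenuation is practically that of wood. A larva,
when present, is brighter than xylem. The analysis must (i) segment each
gallery as one object even across frass plugs, (ii) extract a centerline,
(iii) produce the seven standard gallery parameters, (iv) type each gallery
as C-, S- or Y-shaped, and (v) compare parameters across types with one-way
ANOVA and Duncan's multiple range test.

### Parameter definitions

| parameter | definition used here |
|---|---|
| entrance width | bore diameter at the entrance hole, measured as the equivalent diameter of the gallery cross-section perpendicular to the centerline just below the surface, extrapolated to the hole along the bore taper |
| gallery (boring) depth | absolute difference between the pith-centred radius of the entrance hole and the gallery's radially most extreme point (innermost for inward galleries, outermost for outward ones) — the concentric-circle construction on annual rings reduces to this radial difference |
| vertical length | axial (trunk-direction) extent of the gallery voxels |
| blockage length | total arc length of centerline intervals running through the frass-blocked sub-mask (branch arm included for Y galleries, minus the junction neighbourhood the main path already covers) |
| blockage volume | blocked voxel count x voxel volume |
| total length | centerline arc length from the centre of the entrance hole to the centre of the emergence hole (main path only for Y galleries; the branch is reported separately, not summed) |
| boring volume | gallery voxel count x voxel volume, blocked voxels included |

"Vertical length" has no established operational definition in the field
literature; the axial extent is this package's reading, and it is the one
quantity here whose definition is a genuine convention rather than a
derivation.

## Segmentation

1. **Trunk mask.** Per slice, the convex hull of the wood boundary
   (attenuation > −800). For circular trunk sections the hull seals gallery
   holes and entrance notches, so interior air separates cleanly from the
   air surrounding the segment. The chord drawn across a 3–10 mm surface
   hole undercuts the true circle by well under a voxel.
2. **Air threshold.** Attenuation in [−1100, −850] (a Hounsfield-like band
   around air), intersected with the trunk mask.
3. **Region growing.** Seeded flood fill (default 26-connectivity; automatic
   seeding takes the deepest interior voxel of every air component of at
   least 50 voxels; user seed lists override).
4. **Blockage bridging** replaces the manual slice-by-slice curation of
   blocked sections that an operator would do in an interactive tool. A
   *frass corridor* is computed as attenuation within ±40 of the frass level
   (−620) on a median-filtered volume; the separable 3-voxel median
   suppresses single-voxel noise without inventing intermediate values at
   material interfaces (a linear filter would wrap every gallery wall and
   every ring boundary in a spurious in-band shell). Corridor components of
   at least 40 voxels adjacent to labeled fragments are claimed as blocked
   gallery volume — restricted to voxels that are frass-like in the raw
   volume too, which strips the one-voxel wall shell — and fragments whose
   Euclidean end-to-end gap across a shared plug is at most `max_gap_mm`
   (default 30 mm) merge into one label. Cross-gallery merges are prevented
   by the corridor itself (sound wood is never in-band), not by the gap cap.
   The operation is idempotent.
5. **Smoothing.** Morphological closing then opening per label (default
   0.5 mm, which at this anisotropic voxel pitch is the full 26-neighbour
   box), labels never merging.

## Centerline and morphometry

Per gallery: 3D thinning (with a one-voxel-dilation retry, because thinning
of slab-like regions a few z-slices thick can collapse entirely), a weighted
26-adjacency graph over skeleton voxels, pruning of terminal spurs shorter
than 3x the local tube radius (surface-reaching endpoints protected), then
the longest geodesic path between surface-reaching endpoints. Skeletons of
open tubes retract from the ends by about one tube radius, so each end is
extended to the centroid of its surface opening — which is precisely the
"centre of the hole" the length definition anchors to. A cubic smoothing
spline resampled at 0.15 mm steps gives the final polyline. A third
surface-reaching endpoint contributes the Y branch, attached to the main
path at its junction.

The pith axis is estimated per slice by a coarse-to-fine search (down to
0.05 mm steps) for the centre minimising the within-radius-bin variance of
wood attenuation — i.e. maximising ring concentricity; slices without ring
contrast are flagged and interpolated. Recovery on phantoms is well under
one voxel, including off-centre and axially drifting piths.

Entrance width is read from bore cross-sections perpendicular to the
centerline: the binary gallery indicator (pre-smoothing — morphological
smoothing dilates the bore by a fraction of a voxel) is sampled trilinearly
on a 0.1 mm grid and thresholded at 0.5, which puts the boundary at the
half-level surface; the equivalent diameter of the section component the
centerline runs through is the width. Sections in open air are exact and
anchor the estimate; sections through frass claims carry a roughly constant
wall uncertainty and only inform the taper slope. Five sections one mm apart
are fitted with a line over arc position and extrapolated to where the depth
profile reaches the surface (the path itself starts at the opening centroid,
which already sits a millimetre or two inside the hole). Blockage-interval
boundaries are likewise located sub-voxel, by interpolating the
blocked-proximity profile along the centerline and trimming the proximity
margin off each run end.

Entrance/emergence disambiguation: the endpoint nearest a blocked interval
is the entrance (frass accumulates at the entrance hole); without blockage
the smaller hole is the entrance. Branched (Y) galleries always use the
opening-width rule, because when the plugged arm happens to be the shorter
(branch) arm, blockage proximity along the main path points at the wrong
end.

## The synthetic phantom

The generator emulates the study conditions of a published CT survey of
*M. alternatus* galleries in *Pinus densiflora*:

* **Scanner geometry.** In-plane pixel pitch 0.339844 mm (the printed
  effective pixel size), axial spacing 0.68 mm emulating slice thickness.
  Phantoms default to 220 slices (~15 cm of trunk): galleries sit at
  distinct azimuths and overlap freely in z, so a full 100 cm segment adds
  volume but no information at desk scale. The five-volume reference fixture
  uses the five published segment diameters (17.5, 18.2, 16.4, 16.1,
  17.0 cm).
* **Attenuation model** (Hounsfield-like): air −1000, earlywood −700,
  latewood −550, frass −620, larva −300; Gaussian noise SD 20 added last.
  The scale preserves the qualitative ordering air < frass ≈ wood < larva
  without claiming real calibration. Rings are a two-level square wave
  (period 4 mm, earlywood fraction 0.6) around a pith that sits a few mm
  off-centre and drifts slowly along the axis. A continuous ring ramp would
  sweep through the frass band and poison the bridging corridor, so the
  two-level model is a deliberate choice, not a simplification of
  convenience.
* **Gallery geometry.** C (and Y main) paths are tilted half-ellipse loops:
  entrance and emergence holes at nearly the same axial height, apex at the
  target boring depth; S paths run monotonically between opposite axial
  ends with two opposite bends. Total length and boring depth are honoured
  exactly (a width parameter is solved by bisection, iterated in world
  space because the cylinder mapping contracts tangential arcs at depth);
  the axial extent yields when the three targets are jointly unreachable.
  They frequently are: same-end holes force arc length ≥ ~1.8x the axial
  extent, which the published C-class means violate, so realized C vertical
  extents fall below the published ones. No turn is allowed tighter than
  1.4x the mean tube radius — a tube bent tighter than its bore
  self-overlaps and its medial axis shortcuts the turn — and draws that
  cannot satisfy this are rejected and resampled.
* **Bore profile.** Radius tapers linearly from the entrance (half the
  sampled entrance width) to an end radius solved so the tube volume matches
  the sampled boring volume (capped at 8 mm); the wide end doubles as the
  pupal chamber. Y branches are short straight side exits near the entrance
  end, bored at entrance-hole calibre, leaving the main arm on its shallow
  side.
* **Sampling distributions.** Per-type means come from the published
  mean ± SE summaries; between-gallery SDs are reconstructed as SE·sqrt(n)
  with the published group sizes (36, 3, 4), capped at 45% CV — the n = 36
  back-transform would otherwise exceed the mean for several parameters,
  which cannot describe strictly positive geometry — and at 18% CV for
  entrance width, a head-capsule-constrained trait far less variable than
  lengths or volumes. Draws are truncated to positive, jointly feasible
  ranges.
* **Blockage.** Each gallery's blocked volume fraction is drawn uniformly
  from the observed 7–36% band and realized as frass plugs placed where
  larvae actually pack frass: at the entrance hole (starting 2.5–6 mm in,
  so the air stub at the hole stays seedable), ahead of the pupal chamber,
  and only if needed mid-gallery; single plugs are capped at 22 mm of arc so
  default-gap bridging always reconnects the fragments. Plug placement hits
  the volume-fraction target through the r² arc weighting of the tapered
  bore; the greedy construction can fall short for extreme draws, never
  overshoot.
* **Placement.** Entrance azimuths are uniform, never on the cut ends;
  candidate galleries are rejection-resampled until every pair of tubes
  keeps ≥ 6 mm of wood between walls. Identical config + seed reproduces the
  volume bit for bit.
* **Completeness.** Fixture galleries are complete (adult emerged): the
  emergence hole is open and no larva is rendered. Larva rendering (an
  ellipsoid in the chamber, brighter than wood, with an air ring keeping the
  gallery connected) is exercised in unit tests.

### What the phantom does not emulate

Beam hardening, scatter, reconstruction artifacts, bark texture, knots,
moisture gradients, cracks, and partial-volume blur at material interfaces.
Real frass is inhomogeneous and its attenuation band is wider than the
rendered one. Passing recovery tests therefore demonstrate the pipeline's
geometric and topological correctness under realistic noise and blockage,
not robustness to every artifact of field CT data; the corridor parameters
in particular are tunable surrogates for an operator's judgement, not values
inferred from real scans.

## Statistics

One-way fixed-effects ANOVA is computed either from raw per-gallery values
or, exactly equivalently, from per-group (n, mean, SE) summaries (the
within-group sum of squares rebuilt from sd = se·sqrt(n)); the two paths
agree to floating-point precision, which is itself a test invariant. Edge
cases: all values identical gives F = 0, p = 1; zero within-group variance
with unequal means gives p = 0.

Duncan's new multiple range test orders the k group means and tests every
span of p consecutive means against q*(p, df_w, (1−alpha)^(p−1)) ·
sqrt(MSW/n_h), with n_h the harmonic mean of the span's group sizes,
stepping down from the full range and never testing inside an accepted span.
Studentized-range quantiles come from `scipy.stats.studentized_range` (a
numerical integration of the standard definition). Letters are read off the
homogeneous spans, which are contiguous in the ordered means by
construction. With k = 2 the decision coincides with the pooled-t LSD; on
the same data Duncan rejects at least every pair Tukey's HSD rejects.

The published per-type summary table is reproduced from summaries alone with
group sizes (36, 3, 4), reconstructed from the reported shape-class
percentages since the counts themselves are not printed. For the
boring-volume column this yields F = 0.42, p = 0.66 under the SE reading of
the ± values. The printed ± values cannot be SEs and SDs at once: the SE
reading reproduces the boring-volume F/p but not the entrance-width p; the
discrepancy is inherited from the source and left unresolved, and only the
boring-volume cell is used as a quantitative anchor. The implementation
uses df_within = N − k = 40 (the printed "df = 2,42" is off by the group
count; p rounds to 0.66 either way).

## Problem sizes and tolerances

The reference fixture is five ~15 cm phantom segments holding 43 complete
galleries (36 C, 3 S, 4 Y) — the composition of the published survey — at
full in-plane resolution (~550² × 220 voxels per volume). Pith search
evaluates every 8th slice; skeletons are computed per gallery on padded
bounding boxes. On the fixture, per-gallery recovery against voxel-level
ground truth is required to ≤ 10% for lengths, widths and depths and ≤ 15%
for volumes, type calls must match exactly, and segmentation must recover
exactly one label per true gallery with Dice ≥ 0.95 on the small noiseless
configuration. Simulation-based checks (ANOVA type-I error 0.05 ± 0.01) use
10⁴ vectorized replicates.

## Known limitations

* The longest-geodesic rule can make a Y gallery's true entrance arm the
  "branch" when the side exit's path is marginally longer; total length then
  measures branch-hole to emergence. The equal-calibre-holes assumption
  keeps the entrance-width measurement consistent under this ambiguity, and
  type calls are unaffected.
* Entrance width on smoothed thin bores (< ~2 mm radius) reads up to ~7%
  low because smoothing erodes the stub where the tube meets the surface.
* The generator cannot jointly satisfy the published C-class total length
  and vertical extent under same-end hole geometry (see above); vertical
  extent is the sacrificed quantity, and no quantitative anchor reads it.
* Galleries touching the cut ends of the segment ("incomplete") are excluded
  from measurement rather than partially measured, mirroring the survey's
  use of complete galleries only.
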