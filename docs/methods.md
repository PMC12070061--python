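# Methods

`axonquant` quantifies fluorescence micrographs of developing sensory
ganglia and cultured neurons: ganglion area, nerve outgrowth and width,
explant axon intersection profiles, neurite branch-order complexity,
two-channel intensity measures, and immunoblot densitometry.  Because real
confocal data of this kind are rarely shareable, the package ships a
seeded synthetic-scene generator whose exact ground truth backs every
measurement with an oracle.  This note records the models, the parameters
that matter, and the numerical choices.

## Coordinate and calibration conventions

Rasters are indexed `(y, x)` (stacks `(z, y, x)`); `x` is the column and
`y` the row, growing downward.  A single in-plane calibration
`pixel_size_um` converts pixels to micrometres (in-plane pixels are
assumed isotropic); stacks carry a `z_step_um`.  All geometry returned by
the library (polylines, trees, profiles) is in micrometres.  Embedded TIFF
calibration metadata is ignored in favor of explicit arguments, since
files in practice often carry stale or absent calibration.

## Synthetic scenes

**Arbor growth.**  A neurite is a persistent random walk: fixed 2 µm
steps, heading diffusing by `turn_sd_deg` (default 3°) per step, total
arclength drawn from a truncated normal `segment_len_um` (default
45 ± 10 µm, floored at a quarter of the mean).  Side branches arise as a
Poisson process along the arclength with rate `branch_prob_per_um`
(default 0.02 /µm); a child leaves at 25–55° to its parent and carries
order parent + 1, capped at `max_order` (≤ 3).  An event landing exactly
on a neurite's final walk point is discarded — it would be a pure tip
kink, indistinguishable from curvature, not a branch.  Explant axons are
single-primary arbors rooted on the core-disk boundary, headed radially;
nerve scenes are a rectangular trunk ending in a fan of straight terminal
branches whose *axial* extents are the requested tip depths.

**Rendering.**  Strokes are sampled at quarter-pixel arclength steps,
splatted bilinearly, and convolved once with a Gaussian of
σ = √(line σ² + PSF σ²) (defaults 1.0 and 0.4 µm), so a straight line
peaks at `amplitude` (default 120) and total rendered intensity is
proportional to arclength.  Noise is optional Poisson shot noise (gain)
plus Gaussian read noise (default sd 5 on a background of 10; peak SNR
≈ 24), then quantization to uint16.  One `numpy` Generator seeded from
`GrowthParams.seed` drives each scene; sub-draws happen in documented
FIFO order, so scene and truth stay paired and bit-reproducible.

**Resolvability.**  Measurements that count structures can only be exact
when structures are separated at the rendering scale.  When
`min_separation_um` is set, trees are resampled until: every edge is at
least twice that long; non-adjacent edges never pass closer than it; and
edges sharing a node diverge at an effective opening angle of at least
20° over their first ~16 µm.  The validation suites use 7 µm ≈ 3× the
rendered full width at half maximum.  What passing tests under these
conditions shows is that the *measurement* stages are correct on
resolvable material; it does not certify behavior on densely fasciculated
or out-of-focus real data, where structures genuinely merge.  The
generator also does not emulate uneven illumination, autofluorescence
texture, chromatic shift, or 3-D depth attenuation.

## Ridge detection

Curvilinear centerlines are extracted with the classic second-derivative
line-point criterion: Gaussian derivatives at scale
σ = w/(2√3) + 0.5 px (w = expected line width), line points where the
principal Hessian eigenvalue is strongly negative and the sub-pixel
profile maximum falls inside the pixel, then hysteresis linking into
polylines.  Contrast thresholds are user-facing intensity values mapped
to curvature units through the bar-line response
2hu·exp(−u²/2σ²)/(√2π σ³), u = w/2.  Defaults, when no thresholds are
given, are the image's 99.5/99.9 percentiles above its median — adequate
for fields dominated by line structure, wrong for images with large
bright blobs (pass explicit thresholds there, as the explant pipeline
does).  Three numerical details matter in practice:

* the discrete derivative kernels have a small nonzero response to a
  constant image; that DC term is measured once and subtracted, so flat
  frames yield zero detections;
* on lines near 45° two adjacent pixels can claim the same sub-pixel
  centerline point; during linking, a neighbor whose sub-pixel position
  lies within 0.75 px of an accepted point is retired, preventing
  zigzag double-tracing (~30% length inflation otherwise);
* the smoothed ridge outlives a physical line end by about one scale
  unit, so chain ends are trimmed where the smoothed amplitude falls
  below half the chain's median — the half-maximum point sits at the
  true endpoint.

Segments split at junctions and are not re-paired across crossings: a
segment is a proxy for an axon, not a reconstruction of one.  Segments
shorter than 3 px are dropped as speckle (configurable).

## Ring-intersection profiling

Counts are computed on the vector polylines: ring r's count is the number
of sign changes of (distance-to-center − r) along each polyline.  A
vertex exactly on a ring counts once iff the sign changes across it;
tangential grazes count zero.  This has an exact independent oracle — the
per-edge quadratic for circle–segment intersection, implemented
separately in `geometry.py` and recorded in explant ground truth — which
is why vector counting is the default.  A raster mode (connected overlap
clusters of the binarized segments with 1-px annuli) is provided for
comparability with pixel-based plugin counting; it can double-count thick
diagonal crossings.  Defaults are 20 rings at 175 µm.  The explant center
is the intensity-weighted centroid of the largest bright component after
*two* Otsu passes — the second pass separates the bright core from its
attached outgrowth, which otherwise drags the centroid tens of µm.

## Terminal-branch profiles

At each multiple of `interval_um` (default 30 µm) from the start anchor
along the scan axis, the full perpendicular intensity profile is sampled
(1 px steps, linear interpolation) and maximal suprathreshold runs are
counted.  Runs separated by gaps under 2 px are merged first (anti-aliased
line interiors can dip below threshold for a single pixel), then runs
shorter than `min_run_px` (default: line width in px, floor 2) are
discarded.  The threshold defaults to Otsu's; the start anchor (the first
branching point) must be supplied — identifying it anatomically is out of
scope.  Replicate profiles are aligned by re-indexing each to its own
anchor and truncating to the shortest common extent; the summary reports
per-distance mean and s.e.m.

## Neurite tracing and branch orders

The seeded suprathreshold component is skeletonized, converted to a graph
(8-connectivity, spurious diagonal triangles removed), loops are broken at
the dimmest skeleton pixel, degree-2 chains are contracted into
path-carrying edges, and leaf chains shorter than 5 px hanging off
junctions are pruned as skeletonization artifacts.  Edge arclengths are
measured on the pixel chain decimated to every 4th pixel, which removes
the staircase bias of 8-connected paths.

Branch-order semantics follow the manual-tracing convention: a primary
neurite leaves the soma; each side path off a primary is one secondary;
side paths off secondaries are tertiary; orders beyond 3 are reported as
an overflow count.  Manual tracing implies a *continuation* rule at each
branch point; here the parent neurite continues into the child minimizing
the turning angle.  This rule is a design choice, not something the
original procedure specifies — ties (a symmetric Y) are resolved
arbitrarily by it.  Turning is measured with chords over up to 14 µm
anchored at the junction, because skeleton geometry within a stroke-merge
zone of a junction is distorted.

Three geometric corrections compensate systematic skeleton biases, each
worth 1–6 µm per structure at the default rendering scale:

* **root snapping** — the skeleton junction nearest the soma can be
  displaced by up to a stroke width; a graph node within 5 µm of the seed
  is preferred over a mid-chain pixel (which would split one primary into
  two);
* **tip extension** — skeletonization retracts about half a stroke width
  from free line ends; tips are marched along the end tangent to the mask
  boundary, then pulled back by 0.4× the local mask half-width (the
  thresholded mask of a line end overshoots the true endpoint by roughly
  that fraction);
* **branch re-anchoring** — the filled wedge at a junction displaces the
  skeleton branch point down the child; the child's clean direction
  (estimated 5–15 µm from the junction) is extrapolated backward onto the
  parent polyline and the distorted lead-in replaced by that chord.

Edges lying entirely within `soma_radius_um` of the root (default 0, i.e.
disabled) are left unordered, so neurites begin at the soma boundary when
a soma disk is present.

## Intensity quantifications

`partition_signal` subtracts a background level (default: the modal
intensity, robust when most of the frame is unlabeled), then splits the
integrated signal between a polygon ROI and its complement.  Both
percent-of-total fractions and the mean-outside/mean-inside ratio are
reported; `core_fraction` is defined as `1 − axon_fraction` so the two
sum to 1 exactly in floating point.  `per_cell_coloc` thresholds the mask
channel per z-slice (Otsu by default), keeps components of at least
`min_area_px`, and averages the measure channel within each; slices whose
measure channel's 99th percentile falls below `min_measure_level` are
excluded — the operational form of "insufficient staining", since no
quantitative exclusion rule exists for the manual procedure.  Spot
counting is single-scale Laplacian-of-Gaussian blob detection; spots
closer than about 2σ merge (a resolution limit, stated, not worked
around).

Gel densitometry interpolates a straight baseline through the profile
values at two anchors flanking each band, using the median over ±4
samples at each anchor (single-sample noise would tilt the baseline),
subtracts it, and integrates by the trapezoidal rule.  The *total* band
area is clipped at zero; clipping pointwise would rectify noise into a
systematic positive bias of several percent.  Areas can be normalized to
a designated loading-control band.

## Statistics

`compare_groups` wraps the standard two-sample tests (paired/unpaired t,
Wilcoxon signed-rank, Mann–Whitney).  `auto` chooses parametric vs rank
by Shapiro–Wilk at α = 0.05 per group (per paired-difference for paired
designs) — a stated convention, since mixed test usage in this field
rarely documents a rule.  Degenerate inputs (zero variance everywhere;
all-zero paired differences) are reported with `degenerate=True` instead
of raising.  Multiple comparisons use Holm–Šídák step-down, the default
of the graphing software this workflow typically feeds.  Summaries report
mean, s.e.m. (absent for n = 1) and n per condition, plus a long-form
export for violin plots.

## Validation problem sizes

The shipped validation suites use: 20 explants (1024² px at 2 µm/px, 10
axons each) for ring-profile equivalence; 200 neurons (512² px at
0.5 µm/px) for branch-order recovery; 12 nerve scenes (≤ 7 terminal
branches) for profile exactness; a 3 × 4 width × length grid for ridge
length fidelity; 100 random images for conservation; 20-cell fields for
colocalization; 10 gel profiles; and 100 two-cohort repetitions
(n = 15/group, branch probabilities 0.03 vs 0.015 /µm) for the
effect-direction check.  These sizes keep the whole validation run in a
few minutes on one CPU while leaving the statistical margins comfortable.

## Known limitations

* The ridge detector estimates centerlines only — no per-point width, no
  multi-scale σ selection, no 3-D detection.
* Tracing is fully automatic; there is no interactive path editing, and
  heavily overlapping arbors (below the resolvability scale above) will
  merge or drop branches.
* The branch continuation rule is a convention; different conventions
  relabel orders on symmetric junctions.
* Percentile-based ridge threshold defaults misbehave on images dominated
  by bright non-line structure; pass explicit contrasts there.
* The nerve generator ramifies at a single point with straight branches;
  real nerves bifurcate progressively, so its truth count function is
  exact only for the generated geometry.
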