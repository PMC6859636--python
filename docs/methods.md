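# Methods

`rootpcj` reconstructs root system architecture from binary images in which
soil hides parts of every root, and then measures standard root phenotype
traits. This note records the models and procedures implemented, the
parameters that matter, the design choices made where the design was open,
and what the synthetic test bed does and does not establish.

## Imaging model and preprocessing

The expected input is a photograph of roots pressed against a transparent
container wall: bright, roughly curvilinear structures of a few pixels'
width on a darker soil background, with speckle from reflections and soil
texture, and with stretches of every root hidden where soil lies between
root and wall. Preprocessing is conventional: grayscale conversion
(Rec. 601 luma), a 3×3 median then a 3×3 gaussian filter (order and window
are knobs; the defaults favor impulse removal first), automatic
between-class-variance (Otsu) thresholding with the polarity switchable via
`invert`, optional background flooding with hole filling (4-connected
background against 8-connected foreground, preserving duality), and removal
of 8-connected components below `speck_min_px` (default 20 px).

Note that a 3×3 median filter erases structures thinner than about 3 px
running diagonally; root images should be captured (or rescaled) so roots
are at least 3–4 px wide if median filtering is enabled.

`edge_continuity` reports, per border side, whether the border row/column
contains a run of **more than four** consecutive foreground pixels (read
strictly: five or more). This is only the trigger an acquisition rig would
use to decide that adjacent views need stitching; stitching itself is out
of scope.

## Thinning

Skeletons come from the classical two-subiteration thinning algorithm of
Zhang and Suen. A foreground pixel P1 with neighbor ring P2..P9 (north,
then clockwise) is deleted when `2 <= N(P1) <= 6`, `S(P1) == 1`, and the
two sub-pass products vanish (`P2*P4*P6 = P4*P6*P8 = 0` in pass A;
`P2*P4*P8 = P2*P6*P8 = 0` in pass B). Decisions are made on the image as it
stood at the start of each sub-pass (mark-then-delete), borders are
zero-padded, and iteration stops when a full A+B round deletes nothing, so
the output is a deterministic fixed point.

The implementation is vectorized (shifted-array arithmetic); the test suite
checks it pixel-for-pixel against an independently coded per-pixel
reference on random masks. One property is deliberately *not* enforced:
true Zhang–Suen output is only approximately unit-width. Certain staircase
configurations leave an occasional 2×2 foreground block (on synthetic root
masks, well under 1% of skeleton pixels, confined to junction clusters). A
cleanup pass could remove them, but would silently diverge from the
published algorithm and from the reference oracle, so the blocks are kept
and documented instead. Downstream stages do not assume strict unit width.

## Feature points

A skeleton pixel is classified by partitioning its eight neighbor cells
into 8-connected groups (adjacency between the neighbor cells themselves):

* one group of one or two mutually adjacent neighbors — **endpoint**;
* two groups — interior arc pixel;
* three or more groups — **bifurcation**.

This reading makes the endpoint and bifurcation rules complementary. The
historical phrasing of the bifurcation rule ("more than one neighbor, and
the neighbors are connected") contradicts its own intent — it would mark
every two-neighbor endpoint a bifurcation — and is kept only behind
`literal_bifurcation=True` for comparison. The suite verifies the
classification against a brute-force flood-fill oracle on all 256 neighbor
configurations.

## Progressive corrosion labeling

Arcs (maximal bifurcation-free skeleton paths) each receive one serial
number by consuming the skeleton from its endpoints inward:

1. endpoints are queued in raster order with fresh serials 1..|M|;
2. a FIFO frontier erases pixels and propagates its serial to unlabeled
   neighbors;
3. junction pixels stop every wave and restart each outgoing branch with a
   fresh serial; the junction itself keeps a reserved marker label (−1);
4. waves meeting head-on along one arc (an isolated line is seeded from
   both of its ends) have their serials unified;
5. regions with no endpoint seed — pure cycles, junction-locked arcs — are
   swept from their raster-first pixel;
6. serial classes are compacted to 1..K in raster order.

A **junction** here is any skeleton pixel with three or more skeleton
neighbors (graph degree ≥ 3). This is deliberately the same definition an
independent graph decomposition uses (delete degree-≥3 nodes, count
components), so the label map is exactly checkable: the 3×3 bifurcation
rule above is a local classifier and disagrees with graph degree on some
junction-cluster pixels, and using degree for arc splitting keeps the
labeling and its oracle consistent. The conservation law `arc pixels +
junction pixels = skeleton pixels` holds exactly.

## Segment matching

Arcs are summarized by least-squares fits (solved by QR factorization of
the Vandermonde design, the numerically stable equivalent of the normal
equations). Features per arc: the overall degree-1 line angle, in degrees
within (−90, 90], and a tip derivative per end, the d(row)/d(col) slope of
a degree-1 fit over the `deriv_window` (default 5) pixels nearest that end.
Per-arc abscissa is the coordinate axis with the greater extent along the
arc, so near-vertical roots stay single-valued.

A candidate tip pair must pass three gates (defaults `d1=4, d2=10, d3=50,
d4=0.2`):

1. **line-slope gate** — angular difference of the two line angles at most
   `max(d1, d2) = 10°`. As printed, the rule ("difference < d1 and at the
   same time > d2") is unsatisfiable for d1 < d2; it is read as a
   transposition. The literal conjunction survives behind
   `strict_slope_gate` and, by construction, matches nothing.
2. **tip-derivative gate** — the mismatch of the two facing tip tangents,
   at most `d3`, compared as folded inclination angles in degrees. Raw
   dy/dx differences were tried first and blow up on near-vertical roots
   (one 5-px tip window is exactly vertical while its partner reads slope
   ≈ 5, producing an unbounded difference between two nearly parallel
   tips); the angular form is bounded, symmetric, and keeps the published
   threshold meaningful across orientations.
3. **joint-refit gate** — a single degree-`fit_degree` (default 3)
   polynomial is refit through the union of both arcs' pixels; its summed
   squared loss divided by the number of pixels must not exceed `d4`. The
   per-pixel normalization makes 0.2 scale-comparable across arc lengths
   (a raw sum of 0.2 would be unattainable for any arc longer than a few
   pixels, since rasterization alone contributes ≈ 1/12 px² per pixel).

The proximity rule then resolves the surviving candidates: each segment
pair is reduced to its nearest gate-passing end combination, all candidates
are sorted by tip distance (ties broken by ids, for determinism), and pairs
are accepted greedily while both tips are unused. Each tip joins at most
once; a segment may still be continued at both of its ends. Only true
skeleton endpoints are eligible tips — an arc end abutting a junction is
anchored there and is never re-joined.

Arcs of at most `tiny_px` (default 10; a documented alternative preset of
30 trades recall for speed on large images) pixels are excluded from
matching, and those dangling at no more than one junction are erased from
the skeleton in **one** cleanup pass before matching, after which features
and labels are recomputed. The single pass matters: erasure iterated to a
fixed point progressively dissolves the junction cluster where thick roots
overlap near the collar and merges arcs belonging to different roots.
Erasing dangling prongs is also what re-exposes matchable tips at blunt
stump ends, where thinning leaves a 1–2 px fork. Tiny arcs wedged between
two junctions carry connectivity and are never erased.

## Gap bridging

A matched tip pair is bridged with an odd-degree Hermite curve (default
quintic, `join_degree=5`; 3 and 1 supported): position and first derivative
are matched at both tips and the second derivative is zero there, so the
bridge leaves each stump tangentially and straightens mid-gap. The curve is
solved on a normalized abscissa (the dominant axis between the tips,
rescaled to [0, 1]) for conditioning, sampled at 4 points per pixel, and
rasterized into an 8-connected path running exactly from tip to tip; when
both tip derivatives equal the chord slope the quintic degenerates to the
straight chord. Tip windows that are vertical in the bridge axis, or
steeper than slope 5, fall back to the chord slope to keep the bridge
bounded. The symbolic closed form (solved independently with a computer
algebra system) is the oracle in the tests.

Repair output: the repaired mask is the union of the input mask with each
bridge dilated to the mean local root width measured at its two anchor
points (`skeleton_only_bridges` gives 1-px bridges); the overlay colors
original foreground gray, bridges green, and arcs chained into one root by
the joins in a shared color.

## Phenotype traits

With a scalar calibration `mm_per_px` (default 0.1 — a typical close-range
rig; the checkerboard distortion model it replaces is out of scope):

* **RTN** — endpoints of the repaired skeleton outside `collar_radius`
  (default 25 px) of the collar. The collar is the centroid of the topmost
  skeleton cluster (roots grow downward from the seed) or an explicit
  coordinate. The radius covers the junction web where thick roots overlap
  before separating (with default widths and angular spacing, roots 2–4 px
  wide separating at ≥ 10° clear each other within ~23 px).
* **RTL** — skeleton pixel count × calibration (the literal "total number
  of pixel points" reading); `diagonal_weighted=True` counts diagonal
  steps as √2 for metric accuracy.
* **RTW** — at every skeleton pixel, the number of foreground mask pixels
  crossed by a unit-step march perpendicular to the local tangent (total
  least-squares direction of skeleton pixels within a ±5 px window),
  averaged and scaled.
* **REL** — (max − min) occupied image column × calibration.
* **REA** — angle between the degree-1 fits of the two longest arcs,
  folded into [0, 180); undefined (None) below two arcs.
* `relative_error(measured, actual)` — `100·|actual − measured|/measured`,
  one decimal. The *measured* (in-image) value is the denominator; that is
  the convention under which the published in-soil vs washed-root
  validation errors recompute. Of the fifteen published cells, ten
  recompute exactly under this convention; the other five do not follow
  from their printed value pairs under either denominator choice and are
  stored with `printed_error_pct: None` as misprints rather than chased.
* Aging regressions: the published polynomials RTN(d), RTW(d), RTL(d) and
  the extension-length model (published under the symbol RTET, aliased to
  REL here since no other trait of that name exists) are bundled and
  evaluated with Horner's rule. They are descriptive fits; they
  extrapolate poorly outside the 0–14 day aging range, as any cubic does.

## Synthetic test bed

The generator emulates the imaging geometry, not photorealism. Defaults —
chosen once as the package's study conditions — are: a 320×320 px frame at
0.1 mm/px; a collar at (8, center); per system 3–8 roots; departure angles
spread evenly over ±50° from vertical with ±2° jitter (so adjacent roots
separate within a couple dozen pixels); center lines `col(r) = c0 +
tan(θ)·Δr + q·Δr²` with curvature |q| ≤ 4·10⁻⁴ px⁻¹ (a root turns only
gently over its 130–200 px length, the regime where the degree-3 matching
model is well specified — the curvature knob exists precisely to probe
model mismatch); widths 2–4 px drawn as stamped disks. Occlusion punches
circular patches of 5–15 px through exactly one root at arc positions
30–80% along it, at least 25 arc-px from other gaps on the same root and
clear of the collar. Noise is Bernoulli speckle on the background (and
mild gaussian texture on grayscale input). Everything is driven by
`numpy.random.default_rng` seeds recorded in the truth object, so scenes
regenerate exactly on any platform.

A gap counts as *rejoined* when a bridge's two anchor tips map (nearest
center line, within half a root width + 4 px of skeletonization slack) to
the same root with the gap between their arc positions; any other bridge
is a *wrong join*. Under the defaults, 50 seeded systems give a rejoin
rate of ≈ 0.98–1.00 and no wrong joins; the residual misses are borderline
gate failures (a long curved arc pair whose joint per-pixel loss lands
just above d4, a curled thinning stump whose tip tangent misses d3), not
systematic errors. On clean systems, RTN and REL recover exactly and RTL
within ~4% (thinning retracts each tip by roughly half a root width).

What passing these tests does *not* show: robustness to uneven
illumination, to roots thinner than the median window, to dense root mats
where arcs from different roots run parallel within the gate tolerances,
or to occlusions at junctions (the generator avoids them by default; a
flagged mode places them for stress testing). The gates' published
thresholds were tuned on real maize imagery; on other species or optics
they are the first knobs to revisit.

## Numerical choices and degenerate inputs

* Least squares via `numpy.linalg.lstsq` (QR); rank-deficient designs fall
  back to an axis swap, then to a reduced degree, with a warning.
* All queues FIFO, all scans raster-order, all ties broken by ids: every
  stage is bit-deterministic for identical inputs.
* Empty images: every trait returns 0 (REA: None); empty skeletons yield
  empty feature sets and label maps; `binarize` of a constant image
  returns all-background rather than failing.
* Coordinates are 0-based (row, col), origin top-left, rows increasing
  downward (the direction of gravity); masks serialize as 0/255 8-bit PNG.
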