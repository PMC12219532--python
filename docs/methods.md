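# Methods

This note documents the models, conventions and numerical choices behind
`orgspat`, and what its synthetic validation does and does not establish.

## Inputs and conventions

One analysis covers one cell: binary rasters per class (cell outline,
nucleus, mitochondria, ER, glycogen, lipid droplets) on a common grid, plus
an optional registered ratio image. Rasters are 0-based and row-major;
x is the column index, y the row index, y grows downward. All physical
distances are pixel values multiplied by `pixel_size_nm` (default 5 nm,
the SEM pixel pitch). Float-valued mask inputs are treated as segmentation
probability maps and binarized at a confidence threshold (default 0.90) at
load time; everything downstream is strictly binary.

Ratio values are opaque scaled ¹³C/¹²C numbers whose natural-abundance
(terrestrial) background is the constant 102. The constant is used as
given; no conversion to atom-percent-excess is attempted because the scale
factor of the input data is not defined here. (The conventional
natural-abundance ratio would be ≈112 per 10⁴ carbon atoms; the discrepancy
between that convention and the 102 constant is noted, not resolved.)

## Mask preprocessing

Order: hole filling → class-specific morphology → overlap resolution →
labeling → size exclusion. The ordering of hole filling versus morphology
is not externally constrained; this implementation fixes fill → morphology
and documents it.

- Hole filling applies to cell and mitochondria masks (configurable):
  background regions not connected to the image border become foreground.
- ER masks are eroded 4× with the 3×3 square structuring element,
  smoothing segmentation noise; LD masks are dilated 2× with the 3×3
  diamond (4-neighbourhood cross). Each step is individually switchable
  because the erosion destroys structures thinner than ~9 px.
  At image borders the outside counts as background (scipy convention).
- Overlap resolution first removes everything outside the cell outline,
  then walks the priority order nucleus, mitochondria, ER, glycogen, LD: a
  contested pixel is kept by the earliest class. The operation is
  idempotent and the identity on disjoint in-cell stacks. The cytosol
  compartment is cell − nucleus − mitochondria − LD; ER and glycogen
  remain part of cytosol at this resolution.
- Components are labeled with 8-connectivity; ids are assigned 1..K in
  raster-scan order of each object's first pixel so labelings are
  reproducible.
- Size exclusion removes components strictly below the class threshold
  (defaults: ER 500, mitochondria 5000, glycogen 500, LD 5000 px);
  thresholds are read as minimum viable object sizes, so an object of
  exactly the threshold area is kept. Thresholds are configurable, and
  scaled-down analyses (see below) scale them with object area.

## Isotope quantification

Conditioning is floor-then-smooth by default: values below 102 reset to
102, then a 17×17 mean filter (85 nm at 5 nm/px, matching the ~80 nm
lateral resolution of the ion image). The two steps nearly commute because
the floor touches only rare pixels; the alternative order is exposed in
`condition_ratio`. The mean filter uses nearest-value (replicate) edge
padding so cell-edge regions are not darkened toward zero.

Enrichment is always an arithmetic mean of conditioned pixels: per object,
per class (pooled class pixels, i.e. pixel-weighted over objects), and per
cell (all pixels inside the cell outline). Smoothing attenuates the means
of structures thinner than the 17 px window (ER especially); the bias is
monotone in structure width and is part of the method, not corrected.
Binning into enrichment categories uses half-open intervals
[eᵢ, eᵢ₊₁) with everything below the first edge in category 0 and the last
edge closing the top bin.

## Morphometry

Perimeter is a pixel count: object pixels with at least one of their 8
neighbours outside the object (image borders count as outside). Circularity
is `4πA/P² · (1 − 0.5r)²` with `r = P/(2π) + 0.5`, evaluated exactly as
written. The perimeter-dependent correction term grows with P, so scores
are not confined to [0, 1] and are not clipped; they are comparative shape
scores, not isoperimetric quotients. Centroids are unweighted means of
pixel centers, scaled to nm.

The ranked-volume fit sorts volumes ascending, assigns ranks k = 1..n and
fits `log v_k = log a + b·k` by least squares; r² is reported on the log
scale. The linearised fit is exact for noiseless exponential inputs and
numerically stable; a nonlinear linear-space refit is available via
`space="linear"`. All-equal inputs return b = 0 with r² defined as 0.

## Contact sites

For every perimeter pixel of every object, a (2m+1)×(2m+1) region of
interest centred on it is scanned; perimeter pixels of *other* objects at
Euclidean centre-to-centre distance ≤ m are contacting pixels (m = 2 px =
10 nm by default, covering the 5–10 nm contact regime; m is configurable).
Distance comparisons use squared integer offsets, so threshold decisions
are exact, and the scan provably equals the brute-force all-pairs
computation (`find_contacts_bruteforce`, kept as an independent oracle with
its own grouping code).

Contacting pixels of one object pair are grouped into discrete sites:
pixels are connected when 8-adjacent on the same object or linked by a
within-range cross-object pair. A site in which either object contributes
exactly one contacting pixel is discarded as segmentation noise. (Pure
union-side 8-connectivity would split one physical contact into two sites
whenever a background column separates the objects, and would let a
single-pixel-pair touch survive the noise filter; the pair-link grouping
plus per-side filter avoids both.)

Contact fractions divide an object's contacting pixels per partner class by
its perimeter pixel count. A pixel contacting two partner classes counts
toward both classes; the total contact fraction uses the union of
contacting pixels and therefore never exceeds 1. The contact class of an
object is its closest partner (smallest minimum pixel distance); exact ties
break toward the larger contacting-pixel count and then a fixed class
priority (ER > LD > glycogen > mitochondria), both documented and
deterministic.

## Networks and spatial randomness

Organelle centroids (nucleus excluded; contact-site and nuclear-envelope
point lists, where present, are removed before construction) form an
undirected radius graph with edges at centroid distance ≤ 500 nm — ties at
exactly the radius are edges. A KD-tree accelerates the query but the edge
set equals all-pairs thresholding. Communities are connected components,
size-classed isolated (1), 1to3 (2–3), 4to10 (4–10), 10+ (≥ 11).
Connectivity is the fraction of nodes with degree ≥ 1; first-neighbour
proportions report, per source class, the share of nodes with at least one
neighbour of each target class (a node can count toward several targets).

The CSR test compares the observed mean nearest-neighbour distance of n
points against complete spatial randomness. The expected value under CSR is
the Clark–Evans closed form `0.5/√λ` with intensity `λ = n/area`, the area
being the axis-aligned bounding box `(max_x−min_x)(max_y−min_y)` of the
observed points; no edge correction is applied. `R = observed/expected`
(< 1 clustered, > 1 dispersed). The z-score comes from 1000 Monte-Carlo
replicates — "1000 simulations per point pattern", i.e. 1000 simulated
patterns of n uniform points each, not 1000 per individual point, since the
z-score needs a distribution of pattern-level means. The observed bounding
box is reused for every replicate rather than re-fit; the tests are run
per organelle class per cell. Degenerate (collinear) inputs raise rather
than being patched around.

Because the simulation window is the observed bounding box, the null
distribution is mildly mis-centred (mean z ≈ +0.3 at n = 100) and the
two-sided |z| > 2 rate under CSR sits near 5.5–6% rather than the nominal
4.6%. This is a property of the bounding-box convention itself; the
calibration suite verifies the rate stays within 3–7%, using 1000 CSR
replicates so the binomial noise of the estimate is small against that
band.

## Synthetic scenes

The generator emulates the anatomy the pipeline targets, with exact ground
truth: a convex (elliptical) cell covering ~64% of the canvas, one nucleus
disc (15% of cell area), elliptical mitochondria with axis ratios 1–3,
curvilinear ER ribbons (smoothed random walks dilated to 13 px width, i.e.
65 nm — wide enough to survive the standard 4× erosion, as real tubule
cross-sections do), glycogen depots built from overlapping ~8 px (40 nm)
granule discs so each depot is one connected component, and LD discs.
Placement is rejection sampling with a configurable retry cap and a 3 px
separation margin; infeasible packings fail loudly, naming the class.

Default full-scale conditions: 896×896 px at 5 nm/px; 10 mitochondria,
6 ER, 6 glycogen, 3 LD; area fractions nucleus 0.15, mitochondria 0.13,
ER 0.045, glycogen 0.05, LD 0.05 (realized within ±20% of target, and sized
so every object clears the standard size-exclusion thresholds). Enrichment
offsets over the 102 background: nucleus 15, mitochondria 30, ER 20,
glycogen 60, LD 10, with additive Gaussian noise (sd 5) clipped at the 102
floor. Planted contact pairs are axis-aligned square pads whose facing
edges sit at an exact pixel gap g, giving a minimum centre distance of
exactly g+1 and an extended multi-pixel contact zone (curved shapes at a
gap touch at a single pixel pair, which the noise filter would correctly
discard).

The noise model is a stand-in: the true per-pixel distribution of scaled
ion-count ratios is not specified by the data source, so additive Gaussian
with a hard floor is used. The generator reproduces geometry and mean
enrichment exactly but does not emulate SEM texture, ion-counting
statistics, registration error, or segmentation-model failure modes —
passing tests establish algorithmic correctness on known ground truth, not
robustness to real-world segmentation noise.

## Problem sizes in the test and acceptance runs

The validation suite runs scenes at 448×448 px with proportionally reduced
object counts and size thresholds (objects are ~4× smaller in area than at
full scale, thresholds ER/glycogen 125 px, mitochondria/LD 1250 px);
contact-search fuzzing uses 128×128 px fields of small blobs; CSR
calibration uses 1000 patterns of n = 100 points with 1000 Monte-Carlo
replicates each. These sizes were chosen so the full suite completes in a
few minutes while every check (oracle equality, exact recovery, binomial
calibration bands) retains its force; none of the checked properties
depends on absolute scene scale.

## Known limitations

- Strictly 2-D: no 3-D stacks, tomogram morphometry or 3-D contact
  surfaces (externally measured volumes can still be fed to the ranked
  fit).
- Perimeter is a count, not a geometric length; circularity inherits the
  verbatim correction term and is comparative only.
- The CSR expectation uses no edge correction, and the bounding-box window
  makes the test slightly conservative toward dispersion (documented
  above).
- Touching organelles of one class merge into one labeled object; no
  watershed splitting is attempted.
- The benchmark scores with an empty prediction (or empty truth) define
  precision = recall = F = 0 to avoid undefined divisions.
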