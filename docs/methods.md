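# Methods

## Scope and coordinate conventions

`polarscore` quantifies receptor polarization and migration phenotypes of
single cells in already-2D multichannel fluorescence images (any upstream
projection or background handling is the acquisition pipeline's business;
images are consumed as-is and intensities are never rescaled on read, since
the clustering statistic's pixel selection is rank-based but other
thresholds are not). Images are indexed 0-based as (row, col) with pixel
centers at integer coordinates; the only (x, y) surface is the track CSV
boundary, where x = col and y = row. This conversion happens in exactly one
module (`io`) to keep axis conventions from leaking.

## Cell detection

Detection is a classical threshold-and-components scheme: Gaussian
smoothing (σ = 1 px), global Otsu threshold, binary hole filling,
8-connected labeling, then filters on area (default 200–10000 px), solidity
(≥ 0.7) and border contact (excluded by default). Defaults assume cells of
roughly 15–20 px radius, i.e. lymphocytes at high-magnification confocal
sampling (~0.15 µm/px); all are exposed. Touching cells are **rejected by
the solidity filter, not split**: the per-cell statistics are defined for
singly detected cells, and a watershed split would manufacture boundaries
the statistic is sensitive to. Detection may run on any channel or on the
pixelwise channel sum (default), so a cell dim over most of one channel's
membrane is still found.

A global variance-based threshold has a known failure mode when the
foreground fraction is very small and a sparse very-bright class exists
(e.g. a membrane-dominant stain with tight caps and almost no cytosolic
signal): the threshold jumps to the bright class. The polarity classifier
is therefore routinely run on pre-computed (e.g. ground-truth or curated)
masks, which the API accepts everywhere; the clustering-index pipeline runs
detection on stains with appreciable cytosolic signal, where Otsu operates
in its valid regime.

Each region's outer boundary is traced at pixel resolution with
Moore-neighbor tracing (clockwise on screen, starting at the
topmost-then-leftmost boundary pixel, Jacob's stopping criterion). The
traced closed path — not a sub-pixel iso-contour — is the geometry the
perimeter reference of the clustering index is defined on; holes are
ignored because membrane receptors live on the outer boundary. Ellipse
axes and elongation come from second central moments; elongation (major /
minor) is the shape readout for uropod-elongation phenotypes.

## The clustering index

Per cell and channel: select n = max(2, round(0.10 · area)) brightest
pixels (ties broken by intensity then (row, col) order — fully
deterministic), and let *Dα* be their mean pairwise Euclidean distance.
Two reference configurations of the same n points normalize it:

* **Packed bound S_l**: n lattice points filling, row-major, a square block
  of side ⌈√n⌉ with unit spacing; for n = 100 this is exactly a 10 × 10
  pixel square. The block is a *reference* configuration, not a strict
  lower bound: exhaustive search shows slightly more compact lattice
  clusters exist for n ∈ {7, 10, 11, 12} (e.g. n = 7: 1.497 vs the block's
  1.564), which is one reason the index may slightly exceed 1; such values
  are flagged, never clipped.
* **Perimeter bound S_u**: n points at equal arclength along the traced
  outer contour (arclength via step lengths 1 and √2), snapped to contour
  vertices with an order-insensitive tie rule (earliest vertex within 1e-6
  of the minimal circular distance; collisions advance to the next unused
  vertex). Placement is deterministic — no Monte-Carlo scatter — so the
  bound is a fixed property of the cell's geometry.

The index ci = (S_u − Dα)/(S_u − S_l) is 1 when the selected pixels *are*
the packed block and 0 when they *are* the perimeter placement; both
identities hold to 1e-9 by construction and are asserted in the test suite.
The normalization direction follows the labeling of the packed
configuration as the fully-clustered end and the perimeter scatter as the
unclustered end; any alternative published variant can be swapped by
replacing one function. ci is invariant under image translation and 90°
rotations and unchanged when all coordinates are scaled (Dα, S_l, S_u all
scale linearly). Cells smaller than 20 px or with a boundary shorter than
n steps are reported with reason codes, not dropped silently.

## Trailing-edge localization

The rear axis of a cell is the unit vector from its geometric centroid
toward the intensity-weighted centroid of a uropod reference channel
(CD44 by default); offsets below 0.5 px are treated as "no defined axis"
and the cell is excluded with a reason code. Alternatives: the opposite of
a matched track's net motion, or a user-supplied axis. A marker is
**trailing-edge localized** when its rear-half-plane signal fraction
(split through the geometric centroid, perpendicular to the axis; pixels
exactly on the line count half to each side, making
rear_fraction(axis) + rear_fraction(−axis) = 1) reaches the threshold,
default 0.6. The half-plane rule is the simplest reproducible
operationalization of "localized at the trailing edge"; a rear-sector
variant was deliberately left out. Threshold sensitivity on synthetic
data: rear-capped cells (κ = 8 surface stain, low cytosolic signal) sit
near rear fraction 0.8 and front-capped cells near 0.2, so any threshold
in roughly (0.25, 0.75) separates the two populations perfectly; 0.6 was
chosen to demand genuine rear dominance while tolerating cytosolic
dilution.

## Track metrics

A track is an ordered (frame, x, y) sequence with physical frame interval
dt (s) and pixel size. Reported per cell: path length, net displacement,
elapsed time (frame span × dt — gap-aware), mean speed (path length /
elapsed time, the single per-cell "velocity" number), directionality ratio
(net / path ∈ [0, 1]), signed turning angles, and the endpoint rebased to
the origin for rose plots. Stationary tracks (zero path) are rejected
rather than given an arbitrary directionality. Condition summaries are
mean ± SEM (SEM undefined at n = 1, reported as NaN). Frame interval and
pixel size have no defaults on the CLI: guessing units silently is worse
than requiring them.

## Two-group comparison

Per-cell values are compared with a normality-branched scheme: Shapiro-Wilk
per group at α = 0.05 (a constant group is assigned normality p = 0,
i.e. treated as non-normal); if both groups pass, a two-sided
equal-variance Student's t-test (Welch behind a flag), otherwise a
two-sided Mann-Whitney U — exact U-distribution enumeration when the
smaller group has ≤ 8 values and there are no ties, normal approximation
with tie correction otherwise. The branch is auditable: both normality
p-values, the test name and both n's are always reported. Extreme
separations can underflow the p-value to 0; it is clamped to the smallest
positive float so p ∈ (0, 1] holds. No multiple-testing correction is
applied by default (single planned contrasts); Benjamini-Hochberg is
available behind a flag for multi-channel tables. Comparisons pool cells
across fields within a condition; per-experiment hierarchical modeling is
out of scope and should be layered on top where experiment structure
exists.

## Synthetic micrographs

Each synthetic cell is an ellipse (semi-axes ~13–21 px by default,
T-cell-scale at ~0.15 µm/px) carrying, per channel: a flat cytosolic level
(nonspecific antibody signal, default 40 counts), and a membrane term
whose angular density around the outline is von Mises,
∝ exp(κ·cos(θ − μ)), normalized to angular mean 1 so total membrane signal
is κ-independent; κ = 0 is a uniform ring, κ = 8 a tight cap. Radially the
membrane is Gaussian (sd = half the membrane width, default 1.25 px)
peaked one membrane-width *inside* the outline — the PSF-blurred image of
a thin membrane whose ground-truth mask is drawn at the cell's outer
envelope. Field background is flat (8 counts); noise is Poisson on the
expected intensity plus additive Gaussian read noise (sd 2, ~2% of the
default membrane amplitude 80). Cells are placed by rejection sampling
with a minimum gap (default 10 px) and never touch.

Two rendering choices matter for how the statistic behaves and were made
deliberately. First, the radial *Gaussian* membrane profile (rather than a
hard-edged band) is what gives the clustering index a continuous response
to κ: with a hard band, the rank-based top-decile set degenerates to the
same angular window for every κ once modulation exceeds noise, and the
index saturates; with a blurred profile the brightest-decile region trades
angular extent against radial depth continuously, so mean ci rises
strictly across κ ∈ {0, 1, 2, 4, 8} (roughly 0.18, 0.66, 0.76, 0.83, 0.89
at defaults, Spearman ρ ≈ 0.98 between per-cell ci and κ). Second, the
inward peak offset keeps threshold detection from systematically dilating
masks by the blur margin, so ground-truth agreement of the detector is a
property of the geometry, not of a rendering artifact.

Tracks are persistent random walks: heading evolves by a wrapped-normal
turn with E[cos(turn)] = persistence (sd = √(−2 ln p); p = 0 draws a fresh
uniform heading each step), step length is speed·dt with mean-one
lognormal jitter (sd 0.3), so the generator's speed parameter is
recoverable from mean speed. All randomness — placement, stains, noise,
tracks — flows from a single seed through one generator; reruns are
byte-identical.

The benchmark ("wt_like" κ_CD44 = 4 vs "mutant_like" κ_CD44 = 1, equal
LFA-1 κ = 1, 10 fields × 20 cells per condition, with matched track sets)
mirrors a polarized-versus-polarization-defective contrast qualitatively.
What the generator does **not** emulate: realistic PSF convolution beyond
the radial blur, intensity heterogeneity within one cell's cap,
non-elliptical or multipolar shapes (an optional two-cap variant can be
built from the per-channel stain map), touching cells, photobleaching,
time-lapse image sequences, and uneven illumination. Passing tests
therefore demonstrate correctness of the measurement pipeline under a
controlled camera model, not robustness to every real-world artifact;
on real data the detector's parameters (and, for difficult stains,
externally curated masks) carry that burden.

## Numerical and degenerate-input choices

* Top-decile ties: higher intensity first, then (row, col) lexicographic —
  identical images always give identical scores.
* Perimeter snapping tie rule: earliest vertex within 1e-6 of the minimal
  circular arclength distance, so float summation order cannot flip a
  choice; collisions advance cyclically, guaranteeing n distinct points.
* Regions with < 3 pixels cannot be traced and are skipped with a warning;
  regions with area < 20 or boundary shorter than n are reported with
  reason codes.
* A constant detection image raises (no threshold definable); zero
  surviving components is a warning plus an empty mask, not an error.
* Collinear regions get elongation = ∞ rather than a division error.
* Half-pixel rule on the polarity split line makes the complement identity
  exact to 1e-12 in floating point.
* Label masks are relabeled to a contiguous 1..K on read, preserving label
  order.

## Problem sizes in the checks

The property suite uses 100 cells per κ level for parameter recovery, 200
cells per condition for the contrast and the polarity classifier, 10 fields
× 20 cells for segmentation recovery, exhaustive enumeration up to
n_a + n_b = 12 for the Mann-Whitney oracle, and ≥ 50 randomized point sets
or regions (n ≤ 200) per distance oracle — sizes at which every estimate
above is stable across seeds while the whole suite stays fast enough to run
on every change.
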