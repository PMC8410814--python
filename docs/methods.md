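# Methods

This note documents the models and procedures implemented in
`nodeglia`, the parameter choices that matter, what the synthetic-data
generator does and does not emulate, and the design decisions taken
where the underlying experimental protocols leave the computation
under-specified.

## Contact calling

A microglia–node contact is defined at pixel level: at least one
microglia-positive pixel overlapping or adjacent to at least one
node-positive pixel.  Adjacency is a parameter:

- `full` (default): overlap or 8-neighbourhood in 2D / 26 in 3D.
  Diagonal neighbours count because at typical lateral sampling
  (~0.2 µm/px) the PSF spans several pixels, so a corner-to-corner
  configuration is not optically distinguishable from an edge-sharing
  one.
- `face`: overlap or 4-neighbourhood in 2D / 6 in 3D, for
  sensitivity analyses.

The rule is symmetric in its two arguments and monotone under dilation
of either mask; both properties are tested, and the implementation is
checked exhaustively against brute-force pair enumeration on all 512
microglia patterns of a 3×3 neighbourhood.

Per-field quantification counts labelled nodal structures (connected
components of the node mask, 8/26-connectivity by default) and the
fraction contacted.  Two evaluation modes exist because confocal
z-series are routinely scored on their central plane with the rest of
the stack used only for visual confirmation: `middle_plane` (default)
evaluates structures and contacts on the central z-plane; `full_stack`
evaluates in 3D.  A field with zero nodal structures has an undefined
percentage; it is flagged and excluded from aggregation rather than
scored 0.

Aggregation is mean-of-means: per-field percentages are averaged per
animal, then per-animal means per condition.  The s.e.m. uses the n−1
denominator over animals; a condition with a single animal reports
s.e.m. 0 together with an explicit `n1_flag`.

## Contact stability over movies

A contact time series is an ordered boolean vector (≥ 2 frames, no
gaps; recordings with dropped timepoints are split into gap-free
segments rather than interpolated, because run lengths are
length-sensitive).  Metrics: percentage of frames with contact, and
the longest run of consecutive frames in a given state (0 when the
state never occurs).  The run scanner is validated exhaustively
against enumeration on all series up to length 12 and on 10⁴ random
longer series.

For mask movies, the same contact rule is applied frame by frame.
Frames must be registered beforehand; misregistration is not
detectable from the masks themselves and is the caller's
responsibility (an explicit, documented contract — registration is out
of scope here).

## Tip trajectories

Tracked tips are ordered (x, y[, z]) pixel coordinates with a voxel
size and frame interval.  All metrics operate on the origin-relative
trajectory (t₀ position subtracted, so every track starts at (0, 0)):

- per-step Euclidean distances, converted to µm;
- total path length (sum of steps);
- mean instantaneous velocity, reported in µm/min regardless of the
  acquisition interval (velocity scales linearly with voxel size and
  inversely with frame interval — unit consistency is tested);
- mean distance from origin over all frames after t₀.

Tracks are 2D by default (tips are typically tracked on maximum
intensity projections); 3D coordinates are accepted, with z scaled by
the axial voxel size.  Single-frame tracks are rejected at
construction rather than silently scored.

## Ramification and surveillance indices

The ramification index of a binarized 2D cell mask is

    R = (perimeter / area) / (2 · √(π / area)),

the perimeter-to-area ratio normalized by that of a circle of equal
area: analytically 1 for a disk, larger for branched shapes.  On
rasters the perimeter estimator matters: counting boundary-pixel edges
overestimates diagonal boundaries by up to √2 and pushes a digital
disk to R ≈ 1.27.  The Crofton-formula estimator (4 directions) is
therefore the default; the estimator used is recorded with every
value, and the boundary-count variant remains available for
compatibility with edge-counting scripts.  A radius-100 digital disk
scores within 5% of 1, and the discretization error decreases
monotonically with radius (tested over radii 10–100).

The surveillance index subtracts frame n−1 from frame n of a
binarized single-cell movie: pixels newly gained are process extension
(PE), pixels newly lost are process retraction (PR), and
S = Σ (PE + PR) over all frame pairs.  PE and PR are disjoint per pair
by construction.  A pixel toggling off-then-on across three frames
contributes to two different pairs and is counted twice — the sum runs
over frame pairs, which is the natural reading of the definition; this
interpretation is stated here because a per-pixel-lifetime count would
differ.  S is reported raw and per frame pair (movies of different
lengths are otherwise incomparable); normalization to the control-group
mean applies to the raw sum.

Both indices are computed on 2D maximum-intensity projections; 3D
masks must be projected first.

## Myelination and phenotype

The myelination index is area(myelin ∩ axon) / area(axon) inside a
user-supplied region of interest (excluding somas and white-matter
tracts; ROI geometry is never inferred).  No dilation is applied to
the axon mask before intersection.  The lesion unremyelinated fraction
is area(lesion \ myelin) / area(lesion).  Both are invariant to
padding outside the ROI, and the myelinated plus unmyelinated axon
fractions sum to 1 exactly.

Marker positivity (IGF1, iNOS, …) has no standard intensity criterion
— historically it is scored visually — so the package uses an explicit
recorded rule: a microglia-positive cell is marker-positive when its
mean marker intensity exceeds k × the field background median
(default k = 2).  The fraction is monotone non-increasing in k
(tested).  Contact-by-phenotype cross-tabulations are emitted as
pooled and per-animal 2×2 count tables; conditional-independence
testing on them is delegated to standard statistics tooling.

## Binarization

The reference workflows binarized channels manually in ImageJ.  For
reproducibility this package substitutes an explicit rule — Otsu's
threshold by default, or a fixed value — recorded in output metadata.
Otsu on a constant image raises (the threshold is undefined).  Objects
smaller than `min_object_px` (default 4 px in 2D, 8 voxels in 3D) are
removed to suppress shot-noise specks; the salt-noise growth test on
the surveillance index quantifies why this cleanup matters.  Movies are
thresholded with a single value computed on the whole movie so that
frame-to-frame differences reflect morphology, not threshold jitter.

## Synthetic-microscopy generator

The generator emulates the statistical structure the analysis assumes,
with exact ground truth:

- **Geometry.**  Axons are near-horizontal polylines; nodes are bright
  puncta (default radius 3 px ≈ 0.6 µm at 0.193 µm/px) spaced along
  them; one microglial cell (soma disk + straight processes, 3 px
  wide) sits at the field center with one process routed to each node
  and a few decoy processes elsewhere.
- **Constructive contact truth.**  A node in contact has a process
  pixel overlapping its raster.  A node out of contact has every
  microglia pixel carved out of a clearance zone (4 px from the node
  center beyond its radius), leaving a ≥ 2-px background gap that PSF
  blur and thresholding cannot close at the validated SNR.  The
  requested initially-contacted fraction is honoured exactly
  (`round(fraction × n_nodes)` nodes), not sampled.
- **Contact dynamics.**  Per node, a two-state Markov chain with
  per-frame attach probability a and detach probability q, giving the
  analytic stationary contact fraction a/(a+q) and geometric run
  lengths as oracles.
- **Tip motion.**  Free tips follow an isotropic Gaussian walk with
  per-axis step σ px; confined tips add a pull κ toward an anchor
  (discrete Ornstein–Uhlenbeck), with per-axis stationary variance
  σ²/(1−(1−κ)²) as a closed-form oracle.  Defaults (σ = 1.5 px,
  κ = 0.5) put free-tip excursions in the low-µm range over a 10-min
  movie at 30-s frames, matching the scale on which process tips are
  tracked; each contacted node contributes one confined tip and two
  free tips, mirroring the convention of tracking the contacting tip
  plus two randomly chosen non-contacting tips per movie.
- **Optics and noise.**  Hard binary rasters (no anti-aliasing, so
  ground-truth adjacency is unambiguous) are blurred with a Gaussian
  PSF and corrupted with Poisson shot noise at a photon gain plus
  Gaussian read noise — the standard fluorescence noise model.
  Defaults: 0.193 µm/px, 0.5 µm z-step, 30-s frames (10-min frames
  are typical for in vivo spinal-cord imaging and can be configured).
  Acquisition SNR is a free parameter, not a claim about any
  instrument: the `high_snr_params()` preset (PSF σ 0.8 px, 500
  photons, read noise 0.005) is the level at which mask recovery is
  essentially lossless (Jaccard ≥ 0.97 against clean rasters) and is
  what the recovery validations use; the fixture generator also emits
  a deliberately degraded level (Jaccard < 0.5) as a negative control.
- **Determinism.**  All randomness flows from one integer seed through
  a single generator; identical seeds give byte-identical outputs.

What the generator does *not* emulate — and what passing its tests
therefore does not show about real data: realistic microglial
morphogenesis and chemotaxis, anisotropic or depth-dependent PSFs,
autofluorescence and bleed-through, sample drift (inputs are assumed
registered), and segmentation ambiguity from overlapping cells.  The
validations demonstrate that the *measurement* pipeline is correct
given adequate segmentation, not that segmentation of any particular
dataset is adequate.

## Problem sizes and numerical choices

Validation runs use 256×256 px fields with 20 nodes, ~50 fields per
recovery experiment, 10⁴-replicate Monte-Carlo ensembles for scalar
expectations, and 10³–10⁴ series for run-length checks — sizes at
which Monte-Carlo standard errors are a few per mil, far inside the
asserted tolerances, while the whole suite stays interactive.
Stationary-variance checks for the confined walk use 1500-frame tracks
with a 500-frame burn-in.  Percentages are reported on the 0–100
scale; fractions on 0–1.  Coordinates are 0-based, axis order
(t, z, y, x), ROI bounds half-open; µm conversions happen only at the
reporting layer.

## Known limitations

- Thresholding is global (Otsu or fixed); adaptive segmentation of
  unevenly illuminated real data is out of scope.
- The contact rule inherits segmentation errors at single-pixel
  resolution; sub-pixel contact geometry is not modelled.
- Tip detection and tracking are not automated — tracks are inputs
  (manual or from other tools), matching how such data are produced.
- Image registration is assumed done; only the masks are analysed.
- Inferential statistics (mixed models, multiple-comparison
  procedures) are deliberately delegated to dedicated tools; this
  package stops at per-animal / per-condition summary tables.
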