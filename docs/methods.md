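# Methods

This note records the models behind each stage, the parameters that
matter, and the design choices made where the underlying procedure admits
more than one reading.

## Tissue phantoms

Every stage is validated against synthetic phantoms with complete ground
truth, so the package needs no external data.  A phantom emulates a thin
tissue section: spherical cells truncated to a z-slab (default 9 × 200 ×
200 voxels), radii drawn uniformly from 4.5–6.5 voxels, each with a
concentric nucleus (radius fraction 0.55) and a membrane shell 1.5 voxels
thick.  Placement is rejection sampling with the single hard constraint
that **nuclei never overlap** (membranes may touch — that is the point of
the spillover model); the well-separated "easy" fixture adds a minimum
center spacing of three cell radii.  Where spheres overlap, voxels are
assigned by scaled distance (argmin of dist/radius), giving touching cells
a well-defined shared boundary ridge.  Cell types carry fixed marker
profiles (default three types at 200 a.u. on their own marker, 5 a.u.
off-target) with a per-cell log-normal variation of CV 0.1 so that
recovery correlations are meaningful.

Rendering follows the acquisition layout: every cycle re-images the
nuclear stain (1000 a.u.) and the membrane reference (500 a.u.) alongside
two marker channels; blank cycles carry noise only.  An optional Gaussian
blur (σ 0.7 voxels) emulates optical spread; Poisson noise is applied to
the non-negative intensities and Gaussian read noise (σ 5 a.u. on the
dense fixture) is added last.  Fixture seeds are fixed constants
(`phantoms.DEFAULT_SEEDS`).

What the phantoms deliberately do **not** emulate: realistic optics (PSF),
autofluorescence spectra, tile boundaries, chromatic shifts, or biological
marker co-expression structure.  Passing tests therefore demonstrate
algorithmic correctness and statistical calibration under a controlled
forward model, not performance on any particular instrument's data.

## Segmentation

The contrast image is (1 − membrane_scaled) × nuclear_scaled.  Channels
are scaled to [0, 1] with a robust percentile window (0.1th–99.5th,
clipped) rather than plain min–max: under Poisson noise a single hot voxel
otherwise sets the range and flattens the membrane-ridge contrast to a
tenth of its noiseless depth, destroying seed detection.

The low-pass filter is a hard spherical mask in normalised frequency
space: a component with per-axis frequencies `f_i` (units of Nyquist) is
kept when `sqrt(mean_i f_i²) ≤ cutoff`, so `cutoff = 1` is the identity
and the DC term (image mean) always survives.  The default cutoff is 0.2:
the internuclear spacing of densely packed cells is ~5–6 voxels and a
cutoff of 0.15 under this normalisation removes wavelengths below ~7.7
voxels — exactly the structure that separates adjacent nuclei.  The
filter shape and cutoff are configuration, not dogma; `segment_stack`
exposes both.

Seeds are local maxima of the filtered contrast separated by at least
`min_distance` (default 5 ≈ the expected cell radius); no additional
Gaussian smoothing is applied by default because the low-pass already is
the smoothing.  The watershed floods the Sobel gradient magnitude from the
seeds within a foreground mask (Otsu threshold on scaled nuclear + scaled
membrane, closed with radius 1).  Regions below `min_size` (default 40
voxels) merge into the neighbour with the longest shared boundary, or drop
if isolated.  Ties everywhere are broken by voxel scan order (z, y, x
ascending), so the pipeline is bit-deterministic.  Segmentation is
volumetric (3-D) throughout; the thin-slab phantoms are still genuinely
3-D (9 planes).

Quantification is mean intensity per channel over each cell's voxels
(integral / size); centroids are unweighted voxel means; per-cycle totals
over the marker channels feed the homogeneity gate.  The benchmark scores
a mask against true centers: % nuclei found (centers inside any region),
% singlets (center-containing regions with exactly one center), and
% unlabeled regions.

## Spillover compensation and gating

The spill coefficient from cell *j* into neighbour *i* is `c · b_ij /
B_j`: the fraction of *j*'s total boundary (including faces to background
— physically, the fraction of its membrane) facing *i*, scaled by one
global coefficient `c` (default 0.3, valid range [0, 0.5)).  Columns of S
sum to 1, so the forward model conserves per-marker totals exactly, and
strict diagonal dominance guarantees invertibility.  Boundaries are voxel
face adjacencies (6-connectivity).  The forward model used by the phantom
generator and the inverse used by `compensate` are built by the same code,
so inverse-identity holds by construction to solver precision (~1e-14).
Negative compensated intensities (possible under noise) are clamped to 0
and flagged per cell; totals are conserved before clamping — note that
clamping itself can only raise a marker's total, which is why conservation
is stated pre-clamp.

Cleanup gating runs three sequential gates: (1) nuclear-stain density
(nuclear / size) within a window AND profile homogeneity
(var/mean² of per-cycle totals) below a maximum; (2) all blank-cycle
channels below a maximum; (3) size within a window.  Thresholds are
explicit configuration; `GateConfig.from_reference_table` derives density
and size windows from percentiles (default 1st–99th) of a trusted
reference population, mirroring how such gates are set interactively.

## Interaction statistics

Graph: 2-D Delaunay triangulation of cell centers, edges longer than a
cutoff removed (default 3 × median edge length, which prunes convex-hull
spanning edges).

For types A, B: `observed_AB = N_AB / E` (the Beta mean), and the expected
frequency is built from incident-edge frequencies.  Two conventions are
implemented because the phrase "frequency of edges incident to a type"
admits both:

* **half-edge (default)** — `f_A` = degree mass of type A / 2E, expected
  `2 f_A f_B` heterotypic and `f_A²` homotypic.  These expectations sum to
  1 over unordered pairs and centre the log odds at 0 under random label
  arrangement, which is what makes the permutation-null calibration and
  the binomial test meaningful.
* **edge** (`incident_mode="edge"`) — `f_A` = share of edges with ≥ 1
  endpoint of type A, expected `f_A · f_B`.  The most literal reading, but
  the expectations then sum to more than 1 and every pair is biased toward
  apparent avoidance under the null (measured bias ≈ −0.24 heterotypic /
  −0.81 homotypic at three balanced types); it is kept for comparability,
  not for inference.

When node-type counts are available the default expectation additionally
carries the without-replacement finite-size correction (`n/(n−1)`
heterotypic, `(n_A−1)/n_A · n/(n−1)` homotypic), which removes the
residual O(1/n_A) homotypic bias visible on small populations.  Pairs with
`N_AB = 0` report a −∞ sentinel; an optional pseudocount (default 0) is
exposed rather than silently imputed.

Significance: one-sided lower-tail p = P(X ≤ N_AB), X ~ Binomial(E,
expected) — exact up to 10⁴ trials, continuity-corrected normal above
(agreement ~1e-3 at the handover for balanced probabilities, ~5e-3 for
strongly skewed ones).  BH step-up q-values over the unordered pairs;
q < 0.05 flags avoidance and q > 0.95 attraction.  This sidedness
convention is what makes the dual-threshold rule coherent.

Cross-condition comparison: two-sample t-tests on per-sample counts
normalized by each sample's total edges, BH across pairs; zero-variance
ties report p = 1 and are flagged.  The χ deviation statistic is
`sqrt(Σ z²)` of a matrix z-scored against a reference condition's mean
and SD (zero-SD elements excluded and counted) and applies identically to
count and log-odds matrices.  `interaction_change_summary` reports
per-pair Δcount, Δlog-odds and Δ(frequency sum), plus the OLS R² of the
two co-distributions — the diagnostic separating abundance-driven from
affinity-driven interaction changes.

The attraction planter (`plant_interactions`) places cells on a jittered
grid and greedily swaps type labels (preserving type counts) until the
measured log odds of the target pairs reach their targets.  Note a
geometric constraint: `observed_AB` cannot exceed the fraction of edges
available between the two populations, so a +1 log-odds target is only
attainable for minority pairs (e.g. 15%/15% types); for abundant pairs the
requested observed frequency would exceed what any spatial arrangement can
produce, and the planter warns with the achieved value.

## i-niches

Compositions are unweighted neighbour-type fractions of the first-tier
ring (the index cell excluded from its own ring).  Cells with fewer than
`min_neighbors` (default 3) neighbours after pruning are excluded from
clustering — a two-cell ring makes the fraction vector degenerate — and
reported.  K-means runs on the raw fraction vectors (squared-Euclidean,
no transform), `n_init` 10 restarts, mandatory seed; niche ids are ordered
by decreasing abundance.  K defaults to 100 to match full-scale practice
but is configurable since phantoms are far smaller.  Niche profiles are
mean marker expression of index cells of a chosen type; empty niches are
masked, never imputed.  Niches with > 90% of index cells in one
anatomical compartment are flagged compartment-specific.

The niche-dependence test compares nested linear models `marker ~ type`
vs `marker ~ type + niche`, both as one-hot categorical factors with
intercept, via the partial F statistic
`((RSS_r − RSS_f)/Δdf) / (RSS_f/df_f)`.  Niche enters as a *predictor*:
the alternative reading (niche as the response) does not define a test of
marker-on-niche dependence and is treated as a wording slip.  Degrees of
freedom come from matrix ranks, so aliased levels are detected and
reported rather than silently absorbed.  Marker values for profiles and
tests are compensated, gated intensities; z-scaling is display-only.

Cell-type labels are a pluggable input (phenotype clustering proper is an
upstream concern): external labels are validated and passed through, and a
baseline K-means typer on standardized marker space (clusters named by
their top marker) is provided as plumbing for the phantoms.

## Problem sizes and numerical notes

The test-suite and acceptance-script simulations use: 200-cell dense and
40-cell easy phantoms for segmentation; a 400-cell two-type phantom for
compensation; 2000 cells × 1000 label permutations for the null
calibration; 20 planting replicates for attraction power; 20 seeds × 300
index cells for niche recovery; 1000 null simulations at n = 800 and 200
power simulations at n = 5000 for the F-test.  These sizes give the
calibration checks (type-I within [0.03, 0.07], power ≥ 0.9) comfortable
Monte-Carlo resolution while the whole suite runs in well under a minute
per stage.

Determinism: fixed seeds give bit-identical phantoms, stacks and masks.
Known limitations: the ±3 SE permutation-null check on the mean log odds
is intrinsically tight — the estimator retains a Jensen-type bias of order
1/(2 N_AB) that does not shrink with more permutations, so for small
homotypic pairs the measured ratio sits at a nonzero fraction of the band
and can occasionally brush it on unlucky phantom draws; the drift model
is a rigid per-cycle translation (no rotation or scaling); the FCS writer
emits minimal FCS 3.0 (float data, one parameter per marker plus
cell_id/x/y/size) and is not a general cytometry library.
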