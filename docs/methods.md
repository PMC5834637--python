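# Methods

This note documents the models behind `pengcensus`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic
experiments do and do not demonstrate.

## Colony point process

Nests are generated by a clustered point process with a hard core:
sub-colony (parent) centres are uniform over the island extent, each
parent receives a Poisson number of nests (mean `nests_per_subcolony`),
and offspring are displaced isotropically with a Gaussian scale
`cluster_radius`. Candidate positions are accepted by dart throwing only
if they lie inside the extent and at least `hardcore` metres from every
accepted nest; an exhausted attempt budget raises an explicit
`InfeasibleLayoutError` rather than silently truncating the colony.

Defaults: `hardcore = 0.7 m`, `cluster_radius = 3 m`,
`nests_per_subcolony = 150`, eight sub-colonies on a 200 × 160 m extent,
artifact intensity 0.005 m⁻². The nest-spacing values are stand-ins — no
quantitative point-process parameters are available for the study system —
chosen so that the synthetic nearest-neighbour (NN) distance distributions
are unimodal and well separated from the Poisson artifact field: at these
settings the nest 1-NN median is ≈0.8 m against an artifact median of
≈6 m. The extent and artifact intensity encode an island that is mostly
barren rock with colonies covering a few percent of the surface, which is
what makes an NN-based filter effective in the first place. All values are
configurable.

Coordinates are world metres with y increasing north; rasters are
row-major with row 0 at the northern edge and use the pixel-centre
convention for world↔pixel conversion (the centre of pixel (0,0) sits half
a pixel inside the origin corner).

## Rendering and detection

Nests render as isotropic Gaussian blobs (σ = 0.15 m, unit amplitude);
artifacts use the identical appearance by default — the worst case for a
detector, so that separation must come from spatial structure, not
appearance. Additive Gaussian pixel noise (σ = 0.05) is applied last.
Requesting a blob smaller than one pixel at the chosen ground sample
distance (default 0.05 m/px) is an error.

The detector is a classical difference-of-Gaussians operator (inner scale
= expected blob σ, outer scale 1.6×) with local-maxima extraction and a
threshold on the response normalised so an isolated unit-amplitude blob
scores 1 (closed form: a Gaussian blob of scale s filtered at scale t
keeps amplitude s²/(s²+t²)). It deliberately stands in for the original
neural point detector, whose trained weights are not reproducible; what
matters to every downstream stage is the contract — scored point
detections with confusable, spatially unstructured false positives — and
that is preserved. The detector is tuned for recall (default threshold
0.25); precision is the spatial filter's job.

Rasters are processed as 512 × 512 tiles. Tiles partition the raster
exactly (pixel sums are conserved; trailing tiles are smaller rather than
padded). The tiled detection path reads a read-only halo (4 outer DoG
scales) from the parent raster around each tile so the filter response at
seams equals the full-raster response; peaks are assigned to the tile
containing their centre, and residual near-duplicates are merged to their
score-weighted centroid, iterated to a fixed point so merging is
idempotent.

## Nearest-neighbour spatial filter

A detection is retained iff at least `m` other detections (default
`m = 2`) lie within radius `r`. The neighbourhood is always evaluated
against the full, unfiltered detection set in a single pass: iterating the
rule to a fixed point would progressively erode colony edges, so the
pipeline applies it exactly once.

Choosing `r` is the module's central design decision. Three methods are
provided:

- `fixed`: `r` supplied verbatim.
- `quantile`: `r` = the q-th percentile (default 90) of k-NN distances.
- `mixture-crossover` (default): the log k-NN-distance distribution is
  read as a two-component mixture — a structured colony component and an
  unstructured component from the sparse false-positive field. Both modes
  are located on a kernel-smoothed density and `r` is their log-midpoint
  (geometric mean), which is the density crossover when the two log-scale
  components have comparable spread. `k` is tied to `m` so the fitted
  statistic is exactly the one the rule thresholds. A parametric
  alternative (lognormal colony component against a Rayleigh-type law for
  the unstructured field) was evaluated and rejected: the colony
  component's heavy right tail — sparse cluster edges — breaks the
  lognormal fit and pulls the crossover inside the colony mode, rejecting
  10–20% of true nests. The mode-midpoint form is robust to that tail.

Degenerate inputs (all distances identical, or no second mode) fall back
to a fixed default (`r = 1.5 m`) with a warning. Distances are Euclidean
in world metres, so rules are invariant to the raster's ground sample
distance. At the defaults the filter rejects ≥90% of artifact detections
while losing ≤2% of true nests (typically <1%); both rates are
re-measured, not assumed, in the test suite.

## Ground-count protocol and precision classes

Each counting unit is counted three times; the triple is accepted iff
every count lies within 5% of the triple's mean (boundary inclusive;
all-zero triples accepted). On failure the unit is split into two halves —
nests allocated binomially, since the protocol gives no arity — and the
halves are counted recursively up to `max_depth`, beyond which the unit is
flagged unresolved. The accepted estimate is the mean of the three
agreeing counts rounded half-up: the protocol does not specify which count
is kept, and the mean is unbiased under symmetric error. Observer error is
a truncated normal on the count scale with relative standard deviation
`cv` (default 0.03) and multiplicative bias (default 1); the protocol
itself only ever asserts the 5% agreement rule, so `cv` is a free
simulation parameter.

Precision classes map relative half-widths to labels: ≤5% → N1, ≤10% → N2,
≤50% → N4; anything worse is an explicit error.

## Calibration and error propagation

Automated counts are calibrated per site by ordinary least squares of
manual validation counts on detected counts, with residual scale
√(RSS/(n−2)) (zero when n = 2). The island estimate is the fitted value at
the island's detected total, floored at zero; its relative uncertainty is
the t-based prediction-interval half-width divided by the estimate, which
feeds the N-class assignment.

Validation plots in the synthetic survey combine one quadrat per
sub-colony — six cluster radii wide, so each plot includes the sparse
cluster edge and therefore the filter's edge losses at the island's own
rate — with a grid of 15 m quadrats over the occupied extent and one empty
background plot. Whole-sub-colony plots remove the bias that dense-core
plots would leave (the regression would never see the isolated nests the
filter rejects); the grid plots widen the regression's leverage, which
matters because the island total sits far above the plot range.

Error propagation is Monte Carlo: per replicate each island's count is
redrawn independently with its class half-width h, read either as 1.96
standard deviations of a normal (`normal95`, default: σ = h·c/1.96) or as
the half-width of a uniform; draws are truncated at zero, replicate totals
are summed, and the CI is the empirical 2.5/97.5 percentile range. The
point estimate remains the deterministic sum. The published interval's
construction is not specified, so exact endpoint reproduction is not
claimed; under `normal95` the synthetic half-width lands within a few
percent of the published one, and both interpretations are offered side by
side as sensitivity modes. Independence across islands is assumed — a
documented limitation, not a finding.

## Cross-sensor calibration and area change

Offsets between sensors are per-band mean differences over a
comparable-pixel mask (default: all pixels; cloud/sea masking is out of
scope) and are removed by subtraction — exact in the noiseless case,
contraction of residual band means under noise. Guano classification is a
pluggable slot; the default is a nearest-class-mean discriminant on the
reflectance vector configured from class spectra, equivalent to the linear
discriminant under equal covariances and priors. Fine masks or polygons
are reduced to the 30 m analysis grid by majority coverage (threshold 0.5,
configurable), which is approximately area-preserving and idempotent on
the target grid; epoch comparison reports per-epoch area, pairwise ratios,
and gained/lost/stable cell counts. The band mapping between sensors is
supplied explicitly via config.

## What the synthetic experiments show — and what they do not

Passing the suite demonstrates that the pipeline's stages are individually
correct against oracles (brute-force NN scans, closed-form regression and
propagation checks, exact noiseless round trips) and that, under the
stated generative model, the end-to-end chain recovers island totals with
sub-percent mean error and well-calibrated CI coverage (93–97% over
synthetic archipelagos). It does not demonstrate performance on real
imagery: real orthomosaics have vignetting, terrain shadow, walking birds
and mosaicking seams that the Gaussian-blob renderer does not emulate, and
real false positives are only approximately spatially random. The
detector, in particular, is a stand-in; only its contract is faithful.

## Problem sizes and numerical choices

Simulated study islands hold ≈1,200 nests on a 4,040 × 3,240-pixel raster;
recovery experiments use ten islands, coverage experiments 400
archipelagos at 2,000 Monte-Carlo replicates each, and the published-table
propagation 100,000 replicates — sizes chosen so the full analysis re-runs
in minutes on a laptop while keeping Monte-Carlo error well inside every
tolerance asserted. All randomness flows from a single run seed fanned out
to per-stage substreams by hashing seed + stage name, so any stage can be
re-run in isolation with identical results; CI endpoints are rounded to
integers after percentile extraction, point totals are integer sums, and
presentation percentages are rounded from the exact ratio.
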