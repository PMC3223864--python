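# Methods

## Model and assumptions

A developmental process sampled at ordered time points traces a piecewise-
linear path through gene-expression space: centroids `X_1 .. X_t` joined
by segment vectors `v_i = X_{i+1} − X_i`.  The model summarizes that path
by a single unit vector `e` (the developmental state line) chosen so that

1. `e` lies in the span of the segments,
2. `e` makes the **same** angle θ with every segment, and
3. cos θ is maximal among all such equal-angle vectors.

Condition 2 is what preserves temporal structure: each training centroid
projects to a position whose consecutive gaps are `‖v_i‖·cos θ`, so both
the order of the time points and the ratios of consecutive inter-centroid
distances survive the projection exactly.  Condition 3 picks the unique
representative (information loss is minimized by stretching the projected
gaps as far as the equal-angle constraint allows).

The assumptions a user accepts with this model:

- **The sampling order is correct.**  The fit is driven entirely by the
  declared order; a shuffled order produces a meaningless line.
- **A single line is enough.**  Strongly curved or branching processes
  are summarized, not captured; the line is a one-dimensional scale, not
  a trajectory reconstruction.
- **Projection is blind orthogonally.**  A sample whose displacement from
  the trajectory is perpendicular to the segment span projects exactly
  onto its anchor's position, so "no shift on the line" never implies "no
  change of state".
- **Expression units are the caller's responsibility.**  Projection is a
  plain dot product with no centering or rescaling; lines and the samples
  scored on them must share preprocessing.  All normalization in the CLI
  is explicit opt-in (`none` default, `log2`, `log2+quantile`).

## Fitting: closed form and degeneracies

With unit segments `u_i` as columns of `U` and `G = UᵀU`, solving
`G c = 1` and normalizing `U c` yields the equal-angle maximizer, with
`cos θ = 1/√(1ᵀG⁻¹1)`; coefficients are reported on the raw segments
(`e = Σ a_i v_i`, `a_i = c_i/(‖Uc‖·‖v_i‖)`).  The closed form is exact,
deterministic and O(n·t² + t³); a generic constrained optimizer is kept
in the test suite purely as an independent cross-check.  Because
`cos θ > 0` by construction, the line always points forward in time — no
sign heuristic is needed (asserted defensively).  Larger projection
values therefore always mean *later* developmental positions in this
package.

Degenerate inputs are handled explicitly rather than silently:

- **Zero-length segments** (consecutive duplicate centroids): error by
  default, naming the time pair; an opt-in `merge` policy drops the later
  duplicate with a warning (silent removal would change t and the
  coefficient indexing).
- **Linearly dependent segments** with rank < t−1: error advising removal
  of redundant time points, *except* segments that are exactly collinear
  and co-oriented, which legitimately reduce to the two-point case
  (straight trajectory, cos θ = 1).
- **t = 2**: the line is the normalized single segment, cos θ = 1.

Numerical tolerances (all configurable at the call sites that use them):
unit norm within 1e−10; equal-angle residual within 1e−8; Gram rank
threshold 1e−10 relative to the largest eigenvalue; ratio guard — a
consecutive-gap ratio whose denominator gap is below 1e−12 of the total
trajectory length is reported as NaN (and flagged for PCA columns), since
a near-zero gap makes the ratio arbitrarily large.

## Replicates, projection and display conventions

Per-time-point centroids are the arithmetic mean of replicate columns
(median is available but non-canonical).  Projection of arbitrary samples
is the raw dot product; *centered* positions subtract the raw position of
the first training centroid, which is the display convention used
throughout (origin = earliest training time point).  Angles between lines
are reported in [0°, 180°] without folding, so opposing directions are
distinguishable from orthogonal ones.  Differentiation coordinates are
simply the pair of centered projections on two lines, each computed on
the table restricted to that line's own gene set.

Gene matching across datasets is exact string identity after stripping
quotes/whitespace; no probe-to-gene mapping is attempted, and
`harmonize_genes` (default minimum overlap 0.5 of the smaller table)
guards against accidental platform mismatches.  Cross-platform scoring
requires the caller to pre-map identifiers.

## Diagnostics

`distance_table` compares per-gap distances and consecutive-gap ratios in
full space, on the line, and on PCA components computed from the
time-point centroids (mean-centered SVD; each component's sign fixed so
its largest-magnitude loading is positive, since PC signs are otherwise
arbitrary).  The line's ratio columns must equal the space columns to
1e−8 relative — the model's central invariant — while PC columns
generally break it on curved trajectories.

`order_concordance` scores a projection against a known sample order with
Kendall's tau (tau-b tie convention) plus a strict "perfect order" flag.

`leave_out_robustness` refits the line under sets of removed time points
(default: all singletons, pairs and triples of interior points) and
re-projects a fixed test set on each reduced line's own centered scale.
The empty removal set is bit-identical to the full fit.  Endpoint
removals change both the modeled time range and the origin, and
measurably inflate test-position variance relative to interior removals —
the practical reading is that sampling the extremes of the developmental
window matters most.

## Synthetic data: what it emulates and what it does not

The generator builds trajectories with exact, known geometry: prescribed
segment lengths and pairwise turn angles (Gram–Schmidt construction in a
canonical frame, then a Haar-random rotation so no test can rely on
axis-aligned coordinates), baseline expression drawn per gene from
N(8, 1) — the scale of log2 microarray intensities — and isotropic
Gaussian replicate noise.  Default study conditions: 3 replicates per
time point, noise SD 0.5, segment lengths of order 1–3, turn angles
10–90°.  External samples are displaced from an anchor centroid along the
true line direction and/or into the orthogonal complement of the segment
span, which makes the orthogonal-blindness property testable by
construction.  All randomness flows from one integer seed through a
single generator.

Real expression data differ in ways the generator deliberately omits:
correlated gene noise, probe/batch effects, heteroscedastic intensity-
dependent variance, and platform-specific distributions.  Passing tests
therefore demonstrate the *geometry* of the method — order and ratio
preservation, recovery under isotropic noise, displacement behaviour —
not robustness to real microarray artifacts.

## Problem sizes

Test and acceptance runs use desk-scale instances chosen to exercise the
mathematics rather than production volume: trajectories of 3–50 genes and
3–8 time points (200 instances for the ratio-preservation sweep, 100 for
the optimizer cross-check), 20 seeds per noise level for recovery curves,
and 40–80 genes for the displacement, robustness and angle scenarios.
The closed form is O(n·t² + t³), so behaviour is independent of scale
beyond numerical conditioning.

## Published-figure reconstruction

The published per-gap distances of the 5-point ovary development course
(118.62, 105.49, 114.97, 104.52) and the pairwise angles between the
liver, lung and ovary lines (72.27°, 91.52°, 87.79°) are used as
*generating inputs* to synthetic trajectories, and the pipeline is
required to reproduce the derived quantities (the distance-ratio row
1.12 / 0.92 / 1.10, and the recovered angles).  Absolute distances from
the original accession-level matrices are not reproduced: they depend on
the original (unstated) preprocessing, and re-deriving them would require
downloading and re-normalizing the raw series, which is out of scope.

## Known limitations

- One line per process: no branching, no curvature, no pseudotime graph.
- No statistical test is attached to group separations of projected
  positions; the package reports positions, means and variances only.
- Identifier harmonization is exact-match; probe-level cross-platform
  comparisons need external mapping.
- The robustness protocol varies which time points are present, not
  replicate-level resampling; replicate noise sensitivity is addressed by
  the recovery curves in the synthetic module instead.
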