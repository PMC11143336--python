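# Methods

## The model

A plate-reader run yields, per well, OD readings y_0 … y_n at strictly
increasing times x_0 … x_n (hours). The region between the piecewise-linear
interpolant of these points and the time axis is treated as a plane figure;
its centroid (x̄, ȳ) and area A summarize when and how much optical mass the
culture produced. The figure decomposes exactly into n trapezoidal strips
(one per sampling interval), so the centroid is computed as the area-weighted
mean of closed-form strip centroids — no quadrature error beyond the
piecewise-linear representation of the data itself. For a strip on
[x_{j−1}, x_j] with heights y_{j−1}, y_j:

    A_j  = (y_{j−1} + y_j)/2 · (x_j − x_{j−1})
    x̄_j = x_{j−1} + (x_j − x_{j−1})(y_{j−1} + 2 y_j) / (3 (y_{j−1} + y_j))
    ȳ_j = (y_j + y_{j−1}² / (y_{j−1} + y_j)) / 3

ȳ_j is algebraically the textbook trapezoid-centroid height
(y_{j−1}² + y_{j−1}y_j + y_j²)/(3(y_{j−1}+y_j)); the tests cross-check the
two forms against each other and against a dense-grid double-integration
oracle that computes A and the first moments Q_y = ∬x dA, Q_x = ∬y dA by the
midpoint rule on a refined grid. The oracle shares no code with the strip
path and its error vanishes quadratically in the refinement, which the
suite verifies.

The Centroid Index of treated curve i against the uninfected control is

    CI_i = 1 − (x̄_i ȳ_i) / (x̄_ctrl ȳ_ctrl)

and the comparison metrics are the per-curve Virulence Index
VI = 1 − AUC(treated)/AUC(control) and the maximum specific growth rate
μmax = max over sliding windows of the least-squares slope of ln(OD) vs
time.

### Assumptions and semantics

- OD values entering the centroid must be nonnegative: the centroid of a
  signed region is not what the index means. Negative post-blank readings
  are clamped to 0 (not dropped), keeping grids aligned and areas
  nonnegative.
- CI is origin-dependent through x̄. Times are used exactly as given in the
  input file; `rezero_time` subtracts each curve's first time point when the
  user wants the origin at inoculation. Nothing is re-zeroed silently.
- A treated curve with zero total area has no centroid; its CI is defined as
  exactly 1, the continuous limit of the index and the biologically intended
  "complete lysis" score. A control with zero area or zero coordinate
  product makes the index undefined and raises an error rather than
  returning ±∞.
- Strips with zero height at both ends have zero area and an undefined
  centroid; they are excluded from the weighted sums. Exclusion is the
  unique consistent choice since their weight is zero.
- CI ≤ 1 always; CI < 0 exactly when the treated coordinate product exceeds
  the control's. Scaling both curves' ODs by a common factor leaves CI
  unchanged; scaling only the treated curve down strictly increases it.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| μmax window | 5 points | — | sliding log-linear fit length; 5 points ≈ 1 h at 15-min sampling, long enough to average read noise, short enough to stay inside the exponential phase |
| μmax OD floor | 0.01 | OD | readings at or below this are excluded before taking logs (ln 0 guard; near-blank readings are dominated by noise) |
| ranking tie tolerance | 5×10⁻³ | index units | index values equal to two decimals share a rank and are flagged as ties, mirroring the convention of reporting indices to two decimals |
| grid tolerance | 10⁻⁹ h | hours | two time grids closer than this everywhere are treated as identical |
| table precision | 4 decimals | — | CSV outputs round indices to 4 decimals: two more than the reporting convention, so downstream ranking does not create spurious ties |

Replicates: the default policy computes metrics per replicate and reports
mean ± SD per condition, preserving variance information; curve-first
averaging (`aggregate_replicates`, pointwise mean or median) is available
when a single representative curve per condition is wanted. Multiple
control wells are always aggregated (pointwise mean) before index
computation, because the index takes a single control centroid.

## Synthetic data

The generator emulates the assay geometry the package targets: 96 h of
incubation sampled every 15 min (385 points), inoculation at OD 0.1, a
logistic uninfected control (default carrying capacity 1.0 OD, rate
0.25 h⁻¹ — a slow-growing psychrophile scale). Treated wells follow a
phenomenological lysis shape: logistic growth to the lysis onset,
exponential OD decay, and optionally a logistic regrowth toward a fraction
of the carrying capacity — continuous at both junctions and bounded by
[0, k]. Measurement noise is additive zero-mean Gaussian, clamped at 0,
with a seeded generator.

Two purpose-built pairs exercise the discrimination claims:

- **area-matched pair** — a curve and its time-reflection about the grid
  midpoint. The strip areas of the reflection are the same multiset, so the
  two members have identical AUC (areas are accumulated with exact `fsum`
  summation, making the equality bit-level); only the timing of the mass
  differs. VI cannot separate the members; CI strictly penalizes the
  late-mass one.
- **μmax twin pair** — two curves sharing a bit-identical exponential
  segment, diverging afterwards (plateau vs continued slower rise). Their
  μmax values are identical to machine precision whenever a full fitting
  window lies in the shared segment, while their centroids differ.

What the generator does **not** emulate: phage population kinetics (no
ODE model of adsorption/burst), multiplicative or drifting plate-reader
noise, condensation artifacts, well-edge effects, or non-uniform sampling.
Passing tests therefore demonstrate the *metric's* mathematical behavior on
curves with realistic shapes, not instrument-level robustness on any
particular dataset.

## Numerical choices

- All sums are plain double-precision accumulations except areas, which use
  exact (`math.fsum`) summation of the per-strip areas; at plate scale
  (≤ ~400 points per curve) the oracle comparisons confirm double precision
  is ample, and `fsum` makes the area identical across the centroid and
  area-under-curve code paths and invariant under strip reordering.
- `align_time_grids` in `interpolate` mode resamples both curves onto the
  union of their time points inside the overlap of their ranges. Linear
  interpolation leaves a piecewise-linear curve unchanged as a geometric
  object, so centroids and areas are preserved exactly for curves already
  linear between their samples.
- Degenerate inputs: zero-area treated curve → CI 1 (logged); zero-area or
  zero-product control → error; all-zero strips → skipped; μmax with no
  window above the OD floor → "not estimable" error rather than a fake 0.
- CSV writing uses `%.17g` floats and round-trip parsing, so a
  write/read cycle reproduces a plate bit-exactly in both layouts.

## Problem sizes

The test suite and the acceptance script run everything at the native assay
scale (385-point grids): 200-curve oracle-equivalence ensembles,
100-pair discrimination ensembles, and a 1000-pair bound/sign ensemble —
each completes in seconds because the centroid computation is vectorized.

## Known limitations

- CI compares coordinate *products*, so a treatment trading a smaller ȳ for
  a larger x̄ can score the same as one doing the reverse; the individual
  centroids are therefore always reported next to the index.
- CI's dependence on the time origin is inherent to x̄; comparisons are only
  meaningful between curves sharing an origin convention (the tool enforces
  a shared grid and never shifts origins silently).
- The μmax estimator assumes log-linear growth inside some window; strongly
  non-exponential growth yields a best-window slope that is a summary, not
  a mechanistic rate.
- No smoothing is applied before centroid computation: denoising would
  silently shift x̄ and ȳ. Noise enters the index roughly in proportion to
  its effect on the strip areas.
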