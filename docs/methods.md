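# Methods

## The pipeline

A symmetric N×N matrix is reduced to topology in four stages:

1. **Conversion.** Correlation matrices are mapped entrywise through 1 − C
   (diagonal forced to 0); distance and generic matrices pass through
   unchanged.  Because every later stage depends only on the ordering of the
   off-diagonal entries, any strictly monotone decreasing function of C
   (e.g. arccos C, the spherical angle) yields identical results; 1 − C is
   used for simplicity.
2. **Order complex.** The K = N(N−1)/2 upper-triangle entries are sorted
   ascending; ties are broken lexicographically by vertex pair (i, j), so
   the filtration is total and deterministic even on degenerate input.  The
   filtration may also be built descending (`order="descending"`) for raw
   similarity input, since the direction of the ordering changes the curves.
3. **Betti curves.** For each step j, graph G_j (the first j edges) is
   completed to its clique complex and β_i(G̃_j) recorded, i = 0..max_dim.
   Step j maps to edge density j/K.
4. **Integral signature.** BiAUC = Σ_j β_i on the native per-step grid — a
   plain integer sum, invariant under shifts and rescalings of the weights.

## Computing Betti curves

β_0 is maintained by a union-find sweep over the edge list.  For i ≥ 1 the
curves are extracted from the persistence barcode of the flag filtration,
computed once per matrix.  Because the filtration ends at the complete
graph, every (q+1)-subset of vertices is eventually a q-simplex, entering at
the step of its latest edge; no clique testing is needed.  Dimension-p
intervals are obtained by reducing the coboundary block in reverse
filtration order (anti-transpose construction): one GF(2) column per
p-simplex, rows indexed by its (p+1)-dimensional cofaces with the earliest
coface as the pivot position.  A column that retains a pivot pairs a birth
p-simplex with its death coface; β_p(j) is then a difference of cumulative
birth and death counts.  Columns are Python integers used as bitsets, so a
column addition is a single XOR; the column count equals the number of
p-simplices (4 005 edges at N = 90) rather than the combinatorially many
(p+1)-simplices, which is what makes 90-vertex dimension-1 curves run in
~0.2–0.4 s.  Coefficients are GF(2) throughout, the standard choice for
flag-complex persistence.  Within-step ordering of simplices cannot affect
the per-step Betti numbers, so the lexicographic refinement is purely a
determinism device.

Dimensions 2 and 3 require enumerating all subsets of size up to max_dim+2;
they are gated by a vertex cap (default 120) and raise an explicit capacity
error beyond it.  Default max_dim is 1, since the integral signatures use
only β_0 and β_1.

An independent oracle, `brute_force_betti`, recomputes Betti numbers of an
explicit graph by enumerating cliques and taking GF(2) boundary-matrix
ranks (β_i = dim ker ∂_i − rank ∂_{i+1}), with no code shared with the
persistence path; the test suite requires exact agreement at every
filtration step on hundreds of random instances in dimensions 0–3.

## Reference ensembles

All samplers draw from decorrelated SeedSequence sub-streams of the user
seed (stream ids: euclidean 1, sphere 2, hyperbolic 3, random symmetric 4,
random correlation 5, modular 6), so adding replicates or strata never
perturbs existing draws.  Replicate seeds in sweeps are derived from the
master seed via a spawn key encoding (geometry, dim, radius, replicate) and
kept below 2^31.

- **RM** — i.i.d. Uniform(0,1) strict upper triangle, mirrored, zero
  diagonal.  Any continuous entry law is equivalent under the pipeline's
  monotone invariance; uniform is the simplest.
- **RC** — Pearson correlation of n independent standard-Gaussian series of
  the given length.
- **EG** — uniform samples in the unit hypercube [0,1]^dim, Euclidean
  distances.
- **SG** — normalized isotropic Gaussians on the unit sphere S^(dim−1);
  `dim` is the *ambient* dimension, so a length-T series analogy maps to
  dim = T, aligning the spherical model with the correlation geometry of
  length-T series.  Geodesic distance arccos⟨x,y⟩ with the inner product
  clamped to [−1,1]; the chordal option returns plain Euclidean distances
  (relation: chordal = 2 sin(geodesic/2)).
- **HG** — a direction uniform on the sphere and a radial coordinate
  r ∈ [0, R], placed at Poincaré norm (cosh r − 1)/(2 + cosh r); distances
  by the Poincaré-ball metric arccosh(1 + 2‖u−v‖²/((1−‖u‖²)(1−‖v‖²))).

### The hyperbolic radial law

The default radial law is the area-corrected quasi-uniform distribution of
hyperbolic random-graph models, density ∝ sinh r on [0, R], with the
closed-form inverse CDF r = arccosh(1 + u(cosh R − 1)).  The choice is
deliberate and matters in high ambient dimension.  A volume-uniform draw in
the Euclidean ball B^dim_R (radius CDF (r/R)^dim, available as
`radial_law="ball"`) concentrates all radii within a relative O(1/dim) of R;
at dim = 400 the resulting cloud is metrically indistinguishable from a
sphere sample, and its Betti signatures sit on top of SG/RC rather than in
the near-zero-cycle regime that characterizes hyperbolic clouds.  With the
quasi-uniform law the O(R) radial spread dominates the O(1/√dim) angular
fluctuations, the distance ordering is governed by the additive radial
terms (tree-like structure), and β_1 stays at zero across the tested radii
— the "hyperbolic character" — while B0AUC falls from ~97 000 at R = 0.01
toward the random-correlation level (~14 000) at R = 10, reproducing the
flatter β_0 decay of small radii.  Two further laws are available for
comparison: `"uniform"` (norm uniform on [0, R]) and `"sinh_n"` (the true
hyperbolic volume element sinh^(dim−1) r, numerically inverted in log
space), the latter concentrating like the ball law in high dimension.  No
single radial law can make B1AUC both vanish at small R and grow to the
correlation level at large R: within the flat small-R regime the distance
ordering is scale-invariant, so the law's shape — not R — fixes the
radial/angular balance there.

### Modular systems

`modular_time_series(m, n_series=90, length=400, noise_sd=0.01)` draws m
independent standard-Gaussian base series and tiles them cyclically so that
columns i, j are copies iff i ≡ j (mod m) (the tail block reuses the first
base series; module sizes differ by at most one).  Independent Gaussian
noise of standard deviation `noise_sd` is added to **every** column —
originals included — since adding it only to copies would single out one
column per module arbitrarily.  Base series have unit standard deviation,
so `noise_sd` is also the relative noise amplitude; 0.01 is the default for
"small-amplitude" noise and is recorded in sweep output.  As noise_sd → 0
the correlation matrix has numerical rank m.

## Sweeps, separability, defaults

Signature sweeps default to 90 vertices, 100 replicates per stratum,
hyperbolic radii {0.01, 0.05, 0.1, 0.5, 0.7, 1, 10}, and dims as powers of
two from 4 to 2^15 — log-scale coverage of the series-length axis; the grid
is configurable.  Sweep tables carry a `dim_kind` column separating ambient
manifold dimension (EG/SG/HG) from series length (RC/modular).  Tables are
written in a canonical sort order with deterministic formatting, so reruns
with the same master seed are byte-identical; a cache path makes sweeps
resumable (existing rows are reused, only missing rows computed).  Timings
go to the logging channel, not the tables, to keep outputs reproducible.

Separability trains a linear SVM (C = 1) on (B0AUC, B1AUC), z-scored on the
training half only, with balanced 50/50 splits.  The reported accuracy
averages 20 random splits (a single split of 100-point strata has high
variance; `repeats=1` gives the strict single-split protocol).  The pair is
ordered canonically before splitting so that swapping labels cannot change
the result.

## What the synthetic ensembles do and do not show

The reference ensembles are exactly the study conditions: high-symmetry
constant-curvature manifolds sampled i.i.d., and stationary white-noise
time series.  Real connectivity data differ in ways the ensembles do not
model — autocorrelated and nonstationary series, inhomogeneous sampling on
an unknown (possibly non-constant-curvature) manifold, measurement noise,
and concatenation across subjects.  Passing tests therefore certify the
pipeline and the comparative geometry of the reference models, not any
claim that a matching real dataset *is* spherical or hyperbolic; low-rank
modular structure alone moves signatures through the hyperbolic region, as
the modularity sweep demonstrates.

## Numerical choices and edge cases

- Symmetry validated to 1e-12; inner products clamped to [−1, 1] before
  arccos; arccosh arguments floored at 1.
- Tied weights are legal: the lexicographic tie-break makes curves well
  defined, and CSV round-trips preserve curves exactly unless rounding
  creates new ties.
- Correlation matrices are validated to unit diagonal and entries in
  [−1, 1]; zero-variance series raise an error naming the offending column;
  non-positive prices raise an error naming the row/column.
- Problem sizes in the validation suite: exact checks run at oracle scale
  (7–30 vertices); stochastic geometry checks run at the study conditions
  n = 90, dim/length = 400 with 20 curve replicates, 100 signatures per
  stratum for the SVM, and 10 modularity replicates over
  m ∈ {1, 2, 5, 10, 45, 90}.

## Known limitations

- Homology dimensions above 3 are out of scope; dimensions 2–3 are
  practical only for modest vertex counts (combinatorial clique growth).
- Only complete filtrations (every pair weighted) are supported; sparse or
  thresholded inputs are not.
- The hyperbolic sampler covers the Poincaré ball model only, and its
  radial law is an approximation — exact uniform sampling from the
  hyperbolic volume in high ambient dimension degenerates to a sphere (see
  above), which is a property of the geometry, not of the implementation.
- Real-data ingestion expects a generic delimited time-series or matrix
  file; acquisition-specific preprocessing (parcellation, detrending,
  ticker selection) is the user's responsibility.
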