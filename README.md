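# bettisig

Integral Betti signatures of symmetric matrices, with random, Euclidean,
spherical and hyperbolic reference ensembles.

## What problem this solves

Connectivity matrices — Pearson correlations of fMRI regional time series,
climate station temperatures, stock log-returns — are routinely interpreted
as noisy images of points on some hidden low-dimensional manifold.  A basic
question is what the *curvature* of that manifold looks like: flat
(Euclidean), positively curved (spherical) or negatively curved
(hyperbolic).  `bettisig` answers it comparatively, using topology rather
than differential geometry, so that the answer depends only on the *ordering*
of the matrix entries and is therefore invariant under any strictly monotone
transformation of the measured values.

## The method

Given an N×N symmetric matrix M read as edge weights of the complete graph,
the **order complex** is the nested graph sequence

    G_0 ⊆ G_1 ⊆ … ⊆ G_K,   K = N(N−1)/2,

obtained by inserting edges one at a time in ascending weight order
(correlation matrices are first converted by the monotone map 1 − C).  Each
graph G_j is completed to its **clique (flag) complex**, whose p-simplices
are the (p+1)-cliques, and the **i-th Betti curve** is the sequence of Betti
numbers β_i over the filtration: β_0 counts connected components, β_1
independent loops, β_2 enclosed voids.  The **integral Betti signature** is
the area under each curve on the native step grid,

    BiAUC = Σ_j β_i(G̃_j),

a two-number summary (B0AUC, B1AUC) per matrix.  Observed matrices are
placed against reference ensembles: i.i.d. random symmetric matrices (RM),
white-noise correlation matrices (RC), and geodesic distance matrices of
uniform samples on the unit hypercube (EG), the unit sphere (SG) and the
Poincaré ball of hyperbolic space at sampling radius R (HG).  A linear SVM
on (B0AUC, B1AUC) quantifies which reference geometries are distinguishable,
and a modular copied-series simulator probes the low-rank confound that can
mimic hyperbolic geometry.

Betti curves are computed by persistence of the flag filtration, implemented
in-package as an anti-transposed GF(2) coboundary reduction with bitset
columns (and validated against an independent brute-force boundary-rank
oracle), so a 90-vertex matrix takes a fraction of a second at homology
dimension 1.

## Worked example

```python
from bettisig import random_correlation, betti_of_matrix, integral_signature

C = random_correlation(90, length=400, seed=7)     # white-noise correlations
bc = betti_of_matrix(C, max_dim=1)                 # Betti curves of 1 - C
sig = integral_signature(bc, geometry_label="RC", ambient_dim_or_length=400)
print("B0AUC =", sig.b0_auc)
print("B1AUC =", sig.b1_auc)
```

prints

```
B0AUC = 8546
B1AUC = 75319
```

with the β_1 curve peaking at 178 loops around edge density 0.11 — the
signature region typical of spherical geometry, which white-noise
correlation matrices share (Pearson correlation is a normalized inner
product, so 1 − C orders pairs exactly like the spherical angle arccos C).
An fMRI correlation matrix would be analysed the same way from file:

```bash
bettisig betti --input roi_timeseries.csv --input-type timeseries --out-dir results/
bettisig sweep --geometries RM,RC,EG,SG,HG --dims 400 --replicates 100 --out sweep.csv
bettisig separate --signatures sweep.csv --dim 400 --out accuracy.csv
```

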