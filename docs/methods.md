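# Methods

## Model

`icmsim` simulates an ICM spheroid as point-like cells in unbounded 3-space.
The state of cell *i* is a position **x**ᵢ, a radius rᵢ and an expression
type εᵢ ∈ {N₊G₊, N₋G₋, N₊G₋, N₋G₊} (undifferentiated before the fate
stage). Three processes act:

1. **Mechanics.** Overdamped motion, dxᵢ/dt = Σ_k F_{i,k}, with a
   Morse-type pair force that is repulsive below contact distance rᵢ+r_k
   (limited compressibility), adhesive between contact and the cutoff σrᵢ,
   and zero beyond. Defaults F₀ = 1, a = 0.6, σ = 4. The cutoff condition
   d < σrᵢ depends on the radius of the cell the force acts on, so for
   unequal radii the field is deliberately non-reciprocal in the band
   between σrᵢ and σr_k; `symmetrise_cutoff=True` switches to
   d < σ·min(rᵢ, r_k) (the pair interacts reciprocally or not at all).
2. **Growth.** dr/dt = k(r\* − r) with k = 1, r\* = 1. The update uses the
   exact exponential flow of this linear ODE, so radii match the closed
   form for any step size and never exceed r\*.
3. **Division.** A cell with r ≥ 0.95 r\* divides with constant hazard
   1.0 per unit time (per-step probability 1 − e^{−hazard·dt}); the hazard
   law is a modelling choice, since only "stochastic and radius-dependent"
   is constrained, and both knobs (`div_threshold_frac`, `div_rate`) are
   configuration. Division conserves volume exactly: both daughters get
   radius r·2^{−1/3}; the mother keeps its position and the daughter is
   offset by a uniformly random direction scaled by `delta_frac`·r_new
   (default 0.1, "small against the radius"). Divisions within a step are
   processed in cell-id order for determinism, and the time axis is in
   arbitrary model units — only cell-count-indexed snapshots are meaningful.

**Initialisation.** n₀ cells with radii uniform in [2^{−1/3}, 1]·r\*
(desynchronising the division clock), positions uniform in a ball sized for
volume fraction 0.4, then 200 force-only relaxation steps with per-step
displacement capped at 0.25 r\*. Note an equilibrium property of this
force law: with range σr ≈ 4 and cell spacing ≈ 1.6, dozens of neighbours
lie within the adhesive tail, so the packing compresses until deep pairwise
overlaps (maximum overlap fraction ≈ 0.7) balance the aggregate adhesion.
That compression is part of the model, not a relaxation failure; full force
balance takes ≈ 1000 capped steps, while 200 steps suffice for stable
growth runs.

**Numerics.** Explicit Euler with dt = 0.002 and a hard guard that aborts
if any per-step displacement exceeds r\*. Interior pressure grows with
spheroid size under the long-range cutoff; dt = 0.01 becomes unstable past
roughly 300 cells, while dt = 0.002 is stable through the 1041-cell stage
with a comfortable margin. Forces are evaluated by a numba-compiled kernel
over a cached candidate-pair list (search radius σr\* plus a margin of 1.0,
rebuilt whenever accumulated drift reaches half the margin or the cell
count changes); the tests assert that this path reproduces the plain
all-pairs computation. Coincident centres (undefined force direction) are
resolved by a seeded tiny random separation.

## Fate dynamics

Fates are assigned i.i.d. from a proportion vector p₀ when the population
first reaches t₀ ∈ {200, 300, 400} cells (configurable), independent of
position. At division both daughters draw their type from the mother's
daughter-type distribution under one of four nested hypotheses:

* H1: identity (strict heredity).
* H2: N₊G₊ → N₋G₊ with probability `q_pp_to_np`.
* H3: H2 plus N₋G₋→N₊G₊, N₊G₊→N₊G₋ and N₊G₋→N₋G₊. Two readings of this
  edge set circulate; the default follows the wider one, and the preset
  `H3_methods` provides the narrower variant (H2 plus N₊G₋→N₋G₊ only).
  Neither is privileged.
* H4: H3 plus the reverse flux N₋G₊→N₊G₋, closing the N₊G₋↔N₋G₊ exchange.

Switches are applied independently per daughter by default. The
`forced_asymmetric` flag instead switches exactly one (coin-flipped)
daughter with the total switch probability — the "asymmetric division"
reading — and the expected-daughter matrix is adjusted accordingly so the
deterministic flow stays consistent with the sampler.

Because all fates share one constant division rate, expected counts obey
dn/dt = λ(Dᵀ − I)n with D[i][j] = 2·(daughter distribution), and
proportions obey dp/dt = λ(Dᵀ − 2I)p. Reparametrising time by
s = ln(cell count) cancels λ, so proportions between two population sizes
are connected by exp((Dᵀ − 2I)·ln(n_to/n_from)). This flow is used
forwards (`propagate_proportions`), backwards (`back_solve_t0`, which
refuses — rather than clips — any inverse that leaves the probability
simplex), and inside `fit_transition_rates`, which always back-solves p₀ to
match the t₁ targets exactly and fits the free switch probabilities to the
t₂ targets by bound-constrained least squares (L-BFGS-B, deterministic
multi-start; the fit of the next-simpler hypothesis is embedded as a start,
so added complexity can only reduce the residual). A pure branching-process
sampler (`simulate_lineage_proportions`) provides the stochastic
counterpart with no mechanics.

The experimental proportion vectors live in unpublished supplementary
material, so the package's defaults, p(t₁) = (0.15, 0.10, 0.40, 0.35) and
p(t₂) = (0.07, 0.05, 0.35, 0.53) in order (N₊G₊, N₋G₋, N₊G₋, N₋G₊), are
synthetic stand-ins chosen to mirror the qualitative trend (a strong rise
of N₋G₊ between the two stages). Users supply their own measured vectors
for real comparisons.

## Neighbourhood statistics

Cells are neighbours iff they share a 3D Delaunay edge of the cell-centre
cloud. Raw Delaunay on a convex cloud yields some long sliver edges at the
hull; the default is unfiltered, with an optional `max_edge_length` filter.
The composition row of centre type j pools the full neighbour multiset of
all type-j cells (a cell adjacent to two type-j centres counts twice); a
per-cell-mean variant exists for sensitivity analysis. Same-type enrichment
is diagonal composition minus the global type proportion. ψ is printed for
scalar means, so its application to whole matrices is an aggregation
choice: entrywise |s̄−m̄|/m̄ averaged over the 16 (centre, neighbour)
entries, with zero-denominator entries excluded and reported, recorded in
the output metadata. Rank-sum comparisons use the two-sided
Wilcoxon–Mann–Whitney test (normal approximation with tie correction,
checked against the exact permutation distribution in the tests) on
per-replicate composition entries; the Bonferroni factor defaults to the
number of comparisons actually performed (16 when all entries are defined)
and is configurable and logged.

## Spatial analysis

Per organoid, cell distances to the organoid centre of mass (unweighted)
are sorted and split into 10 equal-count bins (equal-width optional);
per-bin type proportions are averaged across organoids with their SD. For
density maps each organoid is normalised — centred, scaled so the median
absolute deviation of cell-to-centre distances equals 1 (MAD rather than SD
for outlier robustness) — and rotated by the minimal rotation taking the
target type's centre of mass onto the positive x-axis. The rotation is
defined up to a residual spin about x, so only distance-based statistics
are exactly equivariant under rigid motion of the input; tests assert
equivariance on radial profiles. Pooled binary labels (1 = target type) are
smoothed onto a regular grid by Gaussian Nadaraya–Watson averaging
(bandwidth 0.3 normalised units, spacing 0.25 by default; kernel choice
recorded in the map metadata), giving presence values in [0, 1]. The rim
enrichment score is the mean target proportion in the outer three bins
minus the inner three.

## Synthetic data generator

`synthetic` emulates microscopy-derived per-cell tables: positions by
rejection-sampled minimum-separation packing in a ball (volume fraction
0.30 by default — random sequential addition jams near 0.38), fates by
competitive-seed clustering: `n_seeds` seed cells take types drawn from the
target proportions and every cell adopts its nearest seed's fate with
probability `clustering_strength`, otherwise drawing i.i.d. At strength 0
this reduces exactly to i.i.d. assignment (the random-mixing null); at
strength 1 fates form contiguous Voronoi patches. `rim_bias` tilts the
i.i.d. branch linearly in the radial quantile. Two consequences worth
noting: with few seeds, per-organoid type proportions at high clustering
fluctuate at patch scale (the target holds in expectation); and because
per-bin proportions are compositional, rim-biasing one type necessarily
core-shifts the remainder. The generator reproduces the geometry and label
structure the analyses need but none of the imaging-derived artefacts of
real data (segmentation errors, intensity thresholds, nucleus shape), so
passing tests validate the analysis machinery, not organoid biology.

## Problem sizes

The test-suite simulations use 20 repetitions per fate-assignment count for
the clustering comparisons (rank-sum against shuffled-fates nulls remains
decisive at that size) and 100 repetitions for lineage-only Monte Carlo,
which is cheap without mechanics. Full-scale studies (100 mechanical
repetitions per hypothesis and t₀) run through `icmsim simulate`, which
writes resumable per-repetition snapshots with derived seeds
(base + repetition index).

## Known limitations

* No pressure feedback on growth and no fate-dependent mechanics, motility
  or adhesion — deliberately: the model isolates division + heredity. It
  therefore cannot produce the sorted core/rim architecture of the 48 h
  stage, and proportions under H1 are a martingale rather than tracking
  the observed N₋G₊ increase.
* The division law (threshold + constant hazard) is one simple choice
  consistent with a radius-dependent stochastic process; time units are
  arbitrary and only cell-count-indexed snapshots are comparable across
  parameterisations.
* The deep equilibrium overlaps implied by the σr = 4 adhesive tail mean
  cell "radius" should be read as an interaction scale, not a hard sphere.
* 2D neighbourhood analysis and contact-area edge weighting are out of
  scope.
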