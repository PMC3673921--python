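# Methods

## Data model

All computation starts from a binary incidence matrix whose rows are
replicate samples keyed by an estuary > site > replicate hierarchy and whose
columns are taxa. Abundances are accepted on input and thresholded at
"any count > 0 is presence", since every statistic here is incidence-based.
Taxa observed nowhere are retained and reported (they never affect richness,
which is computed on observed taxa); all-zero replicates are legal
observations — an empty core is data — and count toward sample totals in
rarefaction and α. Site identifiers are scoped to their estuary.

## The additive partition

For a site with replicate richnesses r_1..r_n and pooled richness γ-site:
α = mean(r_i), β-site = γ-site − α, and β-conn = γ-estuary − γ-site, where
γ-estuary pools every sample in the estuary. γ values are observed union
richness: the random accumulation of all T samples converges to the union at
t = T, so the partition is exact rather than estimated, and α, β-site are
carried as exact rationals so the two additive identities hold to equality.
An optional mode computes γ at a common rarefied t for designs with unequal
replication; it is off by default because it replaces an identity with an
estimate. Per-site SD of replicate richness uses the n−1 denominator.

## Rarefaction

Expected richness at t of T samples is computed exactly from per-taxon
incidence counts T_j:

    E[S_t] = Σ_j [1 − C(T−T_j, t) / C(T, t)]

with binomial coefficients in log space (stable past T = 100). The
Monte-Carlo random-accumulation curve (mean running richness over seeded
random sample orderings) is retained both because field practice reports it
and because it is an independent oracle for the analytic curve; the suite
checks agreement within three standard errors. Extrapolation beyond T is
refused: accumulation is reported at the samples actually taken, with the
caller warned rather than given a model-based extrapolation.

## Dissimilarity and distances

Jaccard dissimilarity 1 − |a∩b|/|a∪b| is computed on pooled compositions:
a unit's composition is the union of its member samples, the only choice
consistent with how γ-site and γ-estuary are defined (a frequency-threshold
composition — presence in ≥ a given fraction of members — is available
behind a flag). Two empty compositions are an error, not a 0.

Environmental distance is Euclidean on z-scored variables (population SD;
variables in these tables span four orders of magnitude, so standardisation
is the default, configurable). Missing variables are handled strictly —
drop the incomplete column with a warning — with an optional
pairwise-complete mode that rescales each pair's distance by √(p/p_complete).
Spatial distance is planar Euclidean or haversine great-circle km (Earth
radius 6371 km). |Δβ-conn| matrices are plain absolute differences.

Shore complexity is implemented as (equal-area-circle circumference) /
(shoreline length). The verbal definition in the source database's
documentation reads in the opposite order, but its anchors (1 = simple,
< 0.1 = complex) and all published values ≤ 0.45 are only consistent with
this orientation, which the isoperimetric inequality bounds in (0, 1].
Closure index is mouth width / shoreline length. Shell-hash cover is classed
0% → none, (0, 5]% → rare, > 5% → present.

## Inference

The Mantel statistic is the Pearson (or Spearman-on-midranks) correlation of
the vectorized upper triangles; the null permutes rows and columns of one
matrix simultaneously; p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1) for the
one-tailed "greater" alternative (|r| two-sided), with ties at r_obs counted
into the tail. Defaults — Pearson, one-tailed, 9999 permutations — are
package choices (field reports rarely state them) and are configurable; both
r and r² are reported since connectivity studies commonly print r². The test
is implemented in-package so that an explicit numpy Generator seed gives
bit-reproducible p-values; the suite cross-checks r and p against
scikit-bio's independent implementation and against full enumeration at
n = 4. Tests are skipped with a warning below n = 4 units, where the
permutation null is degenerate.

Spearman and Kruskal–Wallis (tie-corrected, chi-square reference) come from
scipy; Holm adjustment from statsmodels and is off by default. A pairwise
Mann–Whitney follow-up with Holm correction is provided as an extension for
locating which groups differ after a significant Kruskal–Wallis.

PCA is an eigendecomposition of the correlation matrix with eigenvalues
clipped at zero, variance fractions summing to one over all axes, and a
deterministic sign convention (each axis's largest-magnitude loading is
positive). The collinearity screen reports every variable pair with
|Spearman ρ| above a threshold (default 0.8, pairwise-complete); *which*
member of a redundant cluster to drop is left to the analyst — for the
built-in estuary table the shipped exclusion list (shore length, catchment
area, river discharge) reflects that choice, and the ordination worked
example reproduces its published variance fractions (41%/22%/78% over three
axes) only on the screened table.

## Synthetic metacommunities

The generator is a Bernoulli occupancy model on an environmental gradient:
species optima μ_j ~ U(gradient); site environments x_i ~ U(gradient),
shrunk toward their estuary mean by homogenisation h; each site accesses a
uniform random subset of round(c·P) of the P-species pool (connectivity c);
occupancy probability q_ij = π · p_max · exp(−(x_i′−μ_j)²/2σ²) for
accessible species, with independent Bernoulli draws per replicate. Defaults
mirror a nine-estuary survey: 9 × 10 sites × 10 replicates, P = 120,
gradient (0, 1), niche breadth σ = 0.3 (niches cover about a third of the
gradient, so sites share many but not all species), p_max = 0.9 (even a
perfectly matched species misses some cores), π = 0.4, c = 0.8, h = 0.
Closed forms E[α] = Σ q, E[γ at t] = Σ(1−(1−q)^t) make the generator an
analytic oracle for the partition pipeline.

What it does *not* emulate: abundance structure, spatial autocorrelation of
occupancy within sites, dispersal kernels, temporal dynamics, and
detection/misidentification error. Passing tests therefore demonstrate
correctness of the statistical machinery under independent Bernoulli
incidence, not robustness to those real-data features. Site coordinates lie
on a line with random spacing and are independent of the environment unless
the spatial-gradient flag orders sites by environment (for studying
space–environment confounding).

### Dial responses are unimodal, by design

E[β-site] per species is 1−(1−q)^t − q, which vanishes at q = 0 and q = 1
and peaks between: both extreme patchiness and saturation homogenise
replicates. Likewise the accessible-pool gap behind β-conn,
P[(1−(1−c)^S) − c] for S sites, peaks near S(1−c)^{S−1} = 1 (c ≈ 0.3 at
S = 6): past that threshold further fragmentation shrinks the regional pool
itself and β-conn falls — the reversal the stress-response framework
predicts for heavily degraded systems. Parameter-recovery tests therefore
check the monotone branch between moderate disturbance and full
saturation/connectivity (π ∈ [0.5, 1], c ∈ [0.4, 1], five grid values,
twenty seeds each), where monotonicity is the model's own closed-form
prediction.

## Pipeline

All randomness flows from one top-level seed fanned out per stage via
`numpy.random.SeedSequence`, and the run log records versions, seed and
options without timestamps, so a rerun with the same config is
byte-identical. A stage failure aborts with a stage-named error and removes
partial outputs. Estuaries with fewer than four sites are excluded from
within-estuary Mantel tests with a logged warning.

## Problem sizes and calibration checks

The suite validates: exact-vs-enumeration rarefaction on all subset sizes of
matrices up to 12 samples; the additive identities on 1000 random
metacommunities; Mantel type-I error at α = 0.05 within the binomial 99%
interval over 1000 null simulations (15 units, 999 permutations); and the
dial-response monotonicity above. These sizes were chosen as the smallest
that give the calibration checks adequate resolution.

## Known limitations

* γ-estuary uses the observed union; with very low per-species detection it
  underestimates the accessible pool, which is why β-conn reverses under
  extreme fragmentation (see above).
* The Mantel permutation count, not an analytic null, bounds the smallest
  attainable p at 1/(n_perm+1); below seven units the discrete null is
  coarse.
* The pairwise-complete environmental-distance mode is a heuristic rescaling,
  not an imputation; strict mode is the default for reproducibility.
* Spearman p-values use the t approximation, inaccurate below ~10 pairs with
  heavy ties.
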