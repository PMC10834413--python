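# Methods

This note documents the statistical model, the numerical choices behind
the sampler, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
option existed.

## Model

Occupancy of point *i* (lake *j*) in year *t* is a latent Bernoulli
state `z_ijt` with logit-linear probability
`logit(psi_ijt) = x_ijt' beta + w_ij + gamma_j`. Detections on visit
*k* are `y_ijkt ~ Bernoulli(p_ijkt z_ijt)` with
`logit(p_ijkt) = v_ijkt' alpha`; a detection is impossible at an
unoccupied point, and false positives are assumed negligible (surveyors
are trained to distinguish the target from related taxa). The closure
period is the calendar year: repeated surveys within a year are visits
*k* of the same season, which is what lets the model separate
non-detection from absence. Occupancy states are conditionally
independent across years given the effects — there is no explicit
colonization/extinction dynamic; the time-since-infestation covariate
carries the systematic trend.

`w` is one spatial random field over all survey points with the
exponential kernel `sigma2 * exp(-phi d)`, approximated by a
Nearest-Neighbor Gaussian Process. Because the prior on `phi` is
bounded so the effective range (~3/phi) stays below the within-lake
scale, cross-lake correlation is negligible and a single field spanning
all lakes behaves as independent within-lake fields. The unstructured
lake intercepts `gamma_j` absorb the between-lake resolution; both are
needed because a single vague spatial term cannot distinguish the two
resolutions.

### Priors

| parameter | prior | rationale |
|---|---|---|
| beta, alpha | N(0, 2.72) | near-uniform on the probability scale after inverse-logit (verified by a test: KS distance of inverse-logit draws from U(0,1) is ~0.013) |
| phi | U(3/(X_max/2), 1/W_min) | X_max = max within-lake inter-point distance, W_min = largest minimum within-lake nearest-neighbor distance, recomputed per dataset; keeps the spatial term within-lake |
| sigma2 | U(0.001, 10) | weakly informative; bounds prevent confounding with the intercept and unreasonable logit-scale magnitudes |
| sigma2_lake | Inv-Gamma(0.1, 0.1) | vague; the lake intercepts are not confounded with the overall intercept |

### Covariates and their units

Occupancy level (per point-year; all per-point values are medians across
surveys, since between-survey variation in, e.g., depth is mostly
positional measurement error):

- depth (m, median across visits; analysis restricted to points
  strictly shallower than 9.14 m = 30 ft);
- time since first infestation (years, from lake metadata);
- boat-travel distance to the nearest access (m);
- nearest-access type (private = 1, public = 0; left unscaled);
- numbers of public and private accesses within 1 km by water;
- fetch (m): longest connected in-water chord through the point over 36
  equally spaced bearings (18 undirected lines); islands truncate a
  chord because fetch proxies uninterrupted wind run over water;
- depth × fetch, the product of the two standardized main effects
  (not re-standardized — the convention of standard occupancy software).

Detection level (per visit): overall plant density and Characeae
density — sums of coverage-proportion midpoints (ordinal 0/1/2/3 →
0, 0.125, 0.5, 0.875) over non-target taxa and non-target Characeae
respectively — and day of year (1-based ordinal date). All quantitative
columns are centered/scaled with statistics computed over the analysis
set after the depth filter and deduplication; the statistics are stored
with the design so predictions for new years reuse them.

Repeat observations within 10 m of one another (GPS error across
surveys, far below any grid spacing) are a single point: single-linkage
clustering within lake at 10 m, canonical location = cluster centroid.

## Sampler

Pólya-Gamma augmentation makes every logit-linear update conjugate, so
the sampler is a Gibbs scheme with exact conditional draws:

1. `z_ijt`: forced to 1 where any visit detected the species; otherwise
   Bernoulli with `P(z=1|rest) = psi q / (psi q + 1 - psi)` where `q` is
   the product of per-visit `(1-p)`. Point-years with no visits reduce
   to `psi` exactly.
2. `beta`, `gamma_j`: Gaussian conditionals given PG draws
   `omega_r ~ PG(1, eta_r)` at every point-year.
3. `w_i`: sequential (Gauss-Seidel) draws from the NNGP full
   conditionals, combining the point's own kriging factor with the
   factors of every location that lists it as a neighbor.
4. `alpha`: PG-conjugate update using only visits at point-years with
   current `z = 1` (visits at unoccupied points carry no information
   about detection).
5. `phi`, `sigma2`: random-walk Metropolis on the logit of the
   rescaled parameter within its uniform bounds (with the Jacobian), so
   proposals never leave the support. Proposal scales adapt toward a
   0.44 acceptance rate during burn-in only, preserving the stationary
   distribution afterwards. For `sigma2` no refactorization is needed:
   the kriging weights depend only on `phi`, and the conditional
   variance scales linearly in `sigma2`.
6. `sigma2_lake`: conjugate inverse-Gamma.

The PG(1, z) sampler is Devroye's exact alternating-series rejection
method (`PG(1,z) = J*(1, z/2)/4`), validated against the closed-form
mean `tanh(z/2)/(2z)` and the variance 1/24 at z = 0. All kernels are
numba-compiled and consume a single `numpy` `Generator`; per-chain
generators are spawned deterministically from the master seed, so runs
are bit-for-bit reproducible.

Correctness of the whole scheme is checked two independent ways: on a
five-point toy instance the MCMC marginals of `beta` and `alpha` match
a brute-force 2-D grid posterior with `z` summed out analytically
(means agree to ~0.01 with posterior sds ~1), and with all data removed
the sampler reproduces its priors (a direct invariance test).

### Numerical choices

- NNGP ordering: lexicographic by (x, y); an alternative (y, x)
  ordering is exposed for robustness checks.
- Neighbor covariances get a 1e-8 diagonal jitter on the correlation
  scale (configurable); a non-positive conditional variance after
  jitter is floored at the jitter value rather than crashing.
- NNGP exactness: with m ≥ n−1 the factorized density equals the dense
  multivariate normal to < 1e-8 (tested at n = 20).
- Retained draws per chain = floor((n_iter − burn_in)/thin); the
  production preset (3 × 250,000, burn-in 25,000, thin 50) retains
  13,500 draws. The desk preset is 3 × 20,000 / 5,000 / 10.
- Split-chain R-hat (each chain halved) rather than the classic
  two-chain form; verified against an independent reference
  implementation to 1e-6. Convergence rules: ≤ 1.02 for nonspatial
  parameters, < 1.05 for spatial ones (`w`, `phi`, `sigma2`).
- Exact distance ties in nearest-access lookup break to the smaller
  access id.
- Visibility-graph edge admission tests segments against the polygon
  buffered by 1 µm: boundary-snapped accesses can sit a few ulps
  outside the polygon after projection, and the buffer makes the
  predicate robust without admitting paths over land.
- Degenerate inputs: all-detected or none-detected datasets fit with a
  warning (weak identification), disconnected "lakes" are rejected at
  polygon merge, duplicate coordinates are rejected by the NNGP
  builder (deduplication must run first).

## Prediction and triage

Per point and posterior draw, `psi = inverse-logit(x'beta + w + gamma)`
with the time covariate standardized by the stored training scaling;
the surface reports the posterior median and central 95% interval. The
per-lake mean occupancy is summarized draw-wise (average over points
within each draw, then quantiles) so its interval is a genuine
posterior interval for the lake mean.

Lakes are triaged into four classes by crossing the posterior mean of
the lake-mean occupancy with its 95% CI width: class 4 (mean < 0.010,
width ≤ 0.05 — low and certain), class 1 (mean > 0.349, width > 0.12 —
high but uncertain), class 3 (mean < 0.160 — low-to-moderate), class 2
(otherwise). The mean boundaries follow the observed class envelopes of
the motivating analysis and the width tiers were set so the rule is
total over the unit square and separates the published exemplar lakes;
the rule is a monitoring triage heuristic layered on the model output,
not a model quantity, and both axes are configurable.

Effect translations: a logit-scale coefficient `b` changes probability
by at most `|b|/4` per standard deviation (maximum logistic
derivative), reported in percent to one decimal. The detection
intercept maps to detection probability at scaled-mean covariates via
the inverse logit; +2 SD of both density covariates gives the
"abundant vegetation" detection scenario (0.534 − 2·0.348 − 2·0.165 →
~38%).

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
multiple lakes (circles, ellipses, one with an island) in a projected
plane, 65 m survey grids clipped to the water polygon, a depth field
increasing with distance from shore (0.035 m/m + N(0, 0.3 m) noise, so
lake centers exceed the 9.14 m cutoff and exercise the filter),
shoreline accesses of both types, staggered first-infestation years,
and 3 survey years with 1–2 visits drawn in a June–September window.
Rake tables for non-target taxa come from per-point latent propensities
cut into the ordinal scale, with Characeae a component of the total so
the two density covariates covary positively, as they do structurally
in real rake data.

Crucially, the generator *runs the real predictor code*: fetch,
boat-travel distances and design standardization are computed by the
same `geo`/`covariates` modules the analysis uses, and the latent field
is drawn from the exact dense GP, not the NNGP — so fitting tests the
NNGP approximation rather than a self-fulfilling identity. True
coefficients sit on the standardized scale: occupancy
(−0.5 intercept, depth −1.6, time +1.7, distance −1.1, access type
+0.9, accesses −0.2/−0.05, fetch +0.25, depth × fetch −0.55) and
detection (0.534, −0.348, −0.165, +0.034), i.e. detection is ~63% per
visit at mean covariates. The variance components are sigma2 = 1.0 and
sigma2_lake = 0.5: with only five lakes a lake-level variance of the
magnitude real multi-lake datasets suggest is unidentifiable, so the
desk scenario uses moderate values for which the recovery study is
informative; variance-component recovery is not asserted.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: real bathymetry and shoreline
complexity, boater-traffic structure behind access risk, temporal
abundance dynamics within a season, GPS measurement error (deduplication
is tested on dedicated fixtures instead), misidentification (false
positives), and preferential sampling of the littoral grid.

## Problem sizes and presets

The desk scenario is 5 lakes × ~140 retained points × 3 years
(~2,100 point-years, ~3,000 visits). The recovery study in the test
suite fits it with the desk preset (3 × 20,000 iterations); the
acceptance script uses 3 × 8,000 with burn-in 2,000 and thin 10, which
the split R-hat diagnostics show is adequate for the nonspatial
parameters at this data size. Analysis drivers use the same reduced
preset so a full end-to-end run stays in the minutes range on a laptop
CPU.

## Known limitations

- Detection covariates are limited to the three available ones; depth
  affects only occupancy, so the model cannot separate "deeper = less
  occupied" from "deeper = harder to sample".
- The four-class triage rule's width tiers are a heuristic; different
  monitoring goals may warrant different cuts.
- One NNGP spans all lakes; with the bounded `phi` prior this is
  equivalent to independent within-lake fields, but pathological
  geometries (lakes closer together than their own diameters) would
  weaken that argument.
- The sampler is single-threaded; chains run sequentially. The
  production preset (250k iterations on thousands of points) is an
  overnight job rather than an interactive one.
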