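# Methods

This note documents the statistical models and procedures implemented in
`perturbkit`, the assumptions behind them, the parameters that matter, what
the synthetic-data generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Hierarchical Bayesian TMT differential expression

### Observation model

Reporter-ion intensities of an 11-plex TMT experiment are first expressed as
log2 ratios to the plex's pooled *global-mix* channel, one ratio per PSM and
non-mix channel. PSMs with a non-positive mix or channel intensity are
dropped (counted and logged). Shared peptides are razor-assigned to the
candidate protein with the most distinct peptides. For a ratio `y` of
protein `p` under label `l` (a (plex, channel) pair):

    y = beta[p, l] + b[l] + eps,    eps ~ Normal(0, sigma_p^2)

with priors

    beta[p, l]  ~ Normal(0, nu_p^2)         per-protein expression scale
    b[l]        ~ Normal(0, tau^2)          label bias, pooled over proteins
    sigma_p^2   ~ InvGamma(2, 0.5)          reporter noise per protein
    nu_p^2      ~ InvGamma(2, 0.5)
    tau         ~ half-Normal(0, 0.5)

The zero-centred bias prior resolves the beta/b identifiability: a shift
common to all proteins at one label is attributed to the label, because
paying for it once through `tau` is cheaper than paying for it in every
protein's `beta`. This identification only works if the `beta` prior scale
is informative, which is why `nu_p^2` is learned rather than fixed wide: the
pooled mass of unchanging proteins pins the per-label consensus. The scale
is per protein (not global) because expression parameters are a mixture —
most proteins flat, some strongly changing — and a single Gaussian scale
would collapse onto the flat majority and push real effects into the noise
variance.

Proteins observed with a single PSM per (protein, label) group have zero
within-group degrees of freedom, so their `sigma_p` and `nu_p` are not
separately identifiable (only the sum is). Such proteins share a pooled
noise variance `sigma_0^2`, drawn conjugately each sweep from the
within-group residuals of all proteins (an empirical-Bayes step; the pooled
posterior is extremely concentrated, so the plug-in approximation is
negligible).

### Sampler

A blocked Gibbs sampler with two collapsed updates:

1. `b | y, sigma, nu, tau` with `beta` integrated out — each group mean is
   marginally `Normal(b_l, sigma_p^2/n + nu_p^2)`, so the update is
   conjugate. Collapsing removes the slow random walk between `b` and the
   per-label mean of `beta`.
2. `(sigma_p^2, nu_p^2) | y, b` with `beta` integrated out — a joint
   Metropolis step on the log scales (3 inner iterations per sweep, proposal
   sd `~2.4*sqrt(2/df)` clipped to [0.05, 0.8]). Collapsing removes the
   coupling through `beta` that otherwise makes the variance split mix
   slowly for low-information proteins.
3. `beta | b, sigma, nu, y` — conjugate, drawn last so every reported draw
   comes from its exact full conditional.
4. `tau | b` — random-walk Metropolis on `log tau`.

Defaults: 5 chains, 2,000 sweeps, 25% burn-in (the production-scale 500k
steps is a configuration choice, not the default). Convergence is assessed
with the Gelman–Rubin statistic for every `beta`, `b` and `sigma`, threshold
1.05. Only running moments are stored, so memory is independent of chain
length.

### Differences, replicate combination, effect sizes

Drug-induced differential expression is `beta[treated] - beta[control]`
formed **per draw** (respecting posterior correlation; the global-mix
denominator cancels algebraically, so rescaling any plex leaves these
differences unchanged). Technical replicates are combined by averaging point
estimates and adding credible-interval extents in quadrature
(`h = sqrt(sum h_r^2)/R`), after which they contribute a single distribution.
Biological replicates are combined by Bayesian updating (precision-weighted
Gaussian product).

Cohen's d between the treated and control posteriors uses

    d = |mu_T - mu_C| / sqrt((sd_T^2 + sd_C^2)/2)

where the sds are the **single-replicate** posterior spreads (the combined
sd times `sqrt(n)`, i.e. the harmonic-mean variance of the per-replicate
posteriors). This is the classic Cohen's-d convention — a population sd,
not a standard error — and it is the scale presupposed by the
replicate-count threshold table {6: 1.50, 5: 1.75, 4: 2.25, 3: 3.38}
(α = 0.05, power 0.8), which is an n-per-group two-sample power analysis.
Using the combined (shrinking) sds instead would make d grow as `sqrt(n)`
and the fixed table meaningless. Replicate counts outside the table fall
back to a noncentral-t inversion (`min_detectable_effect`, bisection to
1e-6). A protein is selected if any time point in any fraction exceeds its
threshold.

Time-course p-values for proteins with heterogeneous replicate availability
are computed per availability stratum and pooled into a **single**
Benjamini–Hochberg pass.

## FRET screens and EC50 estimation

Pixelwise FRET/CFP ratios are computed on background-subtracted,
flat-field-normalised images over a cell mask (CFP pixels above the residual
background median plus `k*sigma`, `k = 3`, spread estimated as 1.4826·MAD).
Per sensor and time point, measurements are scaled to [0, 1] and fit with
the two-parameter logistic `y = 1/(1 + exp(-k(x - m)))` on the log10 dose
axis (linear mode available; zero-dose wells are excluded from log fits).
R² is computed against the per-dose replicate medians. Fits are kept iff
the EC50 lies inside the (closed) dose range and R² > 0.75; kept EC50s are
summarised by their median.

Because the fit has fixed asymptotes 0 and 1, the scaling extremes enter the
estimate directly; scaling therefore uses the extremes of the **per-dose
replicate medians** rather than the raw points, so a single noisy excursion
at a plateau cannot stretch the whole curve. (Raw-extreme scaling remains
available in `scale_unit_interval`.) The fit itself uses all pooled points;
initialisation is `m` = median log-dose and `k` signed by the
Spearman(dose, value) trend, with 3 jittered restarts before a fit is marked
non-convergent.

With multiplicative measurement noise of CV 5% this estimator has an
intrinsic EC50 spread of roughly 6–8% for a mid-range, moderately steep
sensor — the recovery claims in the test suite are stated for the screen
conditions below, not for arbitrary panels (a sensor with EC50 near the edge
of the dose series is biased by plateau truncation, and duplicate wells
roughly double the spread).

## Differential Spearman networks and block models

Per replicate and condition, every protein pair's edge value is the Spearman
correlation of the two temporal profiles (average ranks for ties;
pairwise-complete time points with a minimum overlap of 3). With N
replicates per condition this gives 2N edge values per pair; a two-sided
pooled-variance t-test (Welch and Fisher-z variants available) contrasts the
two N-sized groups, and pairs with `-log10 p > 2` (p < 1%) form the
difference network. No edge-level multiple-testing correction is applied by
default, matching the raw-p retention rule; BH is available.

Nodes are clustered with a non-degree-corrected Bernoulli stochastic block
model: profile log-likelihood `(1/2) * sum_rs m_rs log(m_rs/(n_r n_s))`
(directed block counts, halved to count undirected edges once; 0·log 0 = 0),
fitted by greedy agglomeration from singletons followed by single-node move
refinement, best of `n_restarts` random orders, with the block count chosen
by the penalised score `LL - (B(B+1)/2) log E`. On an 8-node two-clique
graph this reproduces the exhaustive-search optimum; the implementation is
deliberately simple and exact-oriented rather than scalable.

## Time-course significance and translocation calling

Per-entity temporal significance uses a spline F-test: a natural cubic
spline of time (default df = 3, knots at quantiles of the unique times,
boundary knots included) plus intercept versus intercept-only, pooling
replicates as repeated observations:

    F = [(RSS0 - RSS1)/(df1 - df0)] / [RSS1/(n - df1)]

The null distribution comes from permuting time labels within each
replicate, independently per entity (so that the resulting p-values are
independent across entities), `p = (1 + #{F* >= F})/(B + 1)`, default
B = 1,000. BH q-values are computed from the step-up definition.

Candidate translocations are proteins whose PCA-denoised replicate-mean
profiles in two subcellular fractions are anticorrelated below r < -0.8.
Denoising reconstructs each fraction's entity × time matrix from the fewest
principal components reaching 90% explained variance. Two deliberate
choices:

- **Denoising uses the full entity population.** On a matrix restricted to
  significantly changing proteins, one component reaches the variance target
  and forces every profile onto a single blended shape, distorting the
  correlations; the full population spreads variance over enough components
  for a faithful basis.
- **Only significantly changing proteins are evaluated.** Pearson r is
  scale-free, so between two near-flat noise profiles it is meaningless and
  produces spurious ±1 calls. `translocation_pipeline` therefore gates the
  correlation screen on a per-fraction permutation spline F-test
  (BH q < 0.05 in at least one fraction).

A protein is reported once, with its most negative fraction-pair r.

Cross-omic merge and filter rules operate on provided tables: proteins with
time-course q < 1% are merged with genes at q < 1% and max |log2FC| > 0.5;
differentially expressed genes require q < 0.05 and |log2FC| >= 1 at one or
more time points (inclusive); ontology terms require dispensability < 0.1
and q < 5% (strict).

## Imaging quantifiers

- Background: provided value, low percentile (default 5th) or histogram
  mode; spread via median/MAD. Masks threshold at the residual background
  level plus `k*sigma` (default k = 3; the threshold constant is a shipped
  default, not a measured value).
- Apoptotic fraction: `100 * |caspase mask| / |nuclear mask|` in pixel
  counts (an intensity-weighted variant is available behind a flag).
- Filipin: sum of corrected intensity over the above-background mask.
- Enzyme kinetics: OLS slope of summed well intensity over the 0–1 h window
  (inclusive endpoints, overridable), reported per hour with linear R²;
  replicate summaries as mean ± SD.
- FRAP: bleach-ROI trace divided by an equally sized remote ROI and rescaled
  to a prebleach mean of 1; any multiplicative factor common to both ROIs
  (photofading) cancels exactly. The exponential recovery fit
  `c + m(1 - exp(-(t - t0)/tau))` is an optional extension.

## Synthetic-data generators

Each generator is a pure function of (parameters, seed); RNG streams are
derived per stage from the global seed so stage outputs are independent of
call order. The no-noise limit of every generator satisfies its stated
closed form exactly. Study-scale defaults:

- **TMT**: 300 proteins, 1 + Poisson(2) peptides each, 3 fractions × 3
  series (A/B/C, the interleaved 15-point time course) × 3 biological
  replicates; label biases Normal(0, 0.3²) per channel; reporter noise
  Normal(0, 0.25²) per PSM and channel; whole-series dropout with
  probability 0.1 per (protein, fraction, series); 25% of proteins receive a
  saturating effect `e(t) = e_max (1 - 2^(-t/6h))` with `e_max ~ N(0, 1)`
  (or fixed magnitude on request). The global-mix channel is the linear mean
  of the ten non-mix true intensities and carries its label bias but **no
  per-PSM noise**: the pooled mix aggregates every time point, so its read
  noise is far below the per-channel noise, and a noisy shared denominator
  would make the independence-assuming model's difference CIs conservative.
- **FRET screen**: 12-dose geometric series 0.343–100 µM, sextuplicate
  wells, sensors with EC50 log-uniform 4–15 µM, logistic slope 4–6 per
  decade (Hill ≈ 1.7–2.6), amplitude equal to the baseline ratio, linear
  onset saturating at 30 min; out-of-range sensors at 300 µM. Multiplicative
  log-normal noise of the requested CV.
- **Fraction time course**: logistic-in-log-time ramps of amplitude 1 for
  translocators (exact negation in the destination fraction), single-bump
  profiles for temporal changers, i.i.d. Gaussian noise per replicate
  (default sd 0.1).
- **Network panel**: pairs of proteins with within-pair correlation ±0.9
  (vehicle/treated), all other entries independent; a non-PSD correlation
  matrix fails loudly rather than being projected.
- **Kinetics, FRAP, apoptosis images**: saturating product formation
  `F(t) = Fmax(1 - exp(-rate·t/Fmax))` with `Fmax = 100·rate·1h` (linear to
  well under 1% over the first hour); shared-photofade FRAP traces; disc
  cells with exact mask-pixel ground truth and a multiplicative illumination
  gradient.

What the generators do **not** emulate: peptide-level systematic effects
(ionisation efficiency, missed cleavages, isobaric co-isolation
interference), between-replicate biological variance beyond measurement
noise, cell-shape or texture realism beyond discs, chromatographic or
spectral structure, and real screens' plate/edge effects. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated models, not robustness to every artefact of real data.

## Numerical choices and degenerate inputs

- All reported posterior sds are floored at 1e-3.
- Identical MCMC chains yield R-hat 1.0 by convention (zero within-chain
  variance guard).
- Degenerate constant vectors scale to 0.5 with a flag instead of dividing
  by zero; a diverged logistic midpoint maps to a clipped EC50 and is
  removed by the dose-range filter.
- The closed dose interval keeps a fit with EC50 exactly at a boundary dose.
- An even number of kept EC50s summarises as the mean of the central pair.
- t-tests on identical samples report t = 0, p = 1.
- BH is implemented from the step-up definition and is stable under input
  permutation.
- Problem sizes in the test suite (e.g. 300-protein TMT recovery at 5 × 2,000
  MCMC sweeps, 1,000-entity null calibration at 200 permutations) are the
  package's desk-scale defaults for synthetic studies.

## Known limitations

- The hierarchical model is a faithful reconstruction of the stated
  ingredients (ratiometric global-mix design, pooled label bias, MCMC with
  Gaussian posterior summaries); the original method's exact generative
  model is not public, so parameter-level agreement with it cannot be
  claimed.
- The d-threshold table is shipped as overridable defaults: a standard
  noncentral-t inversion reproduces its ordering but not its exact values
  (e.g. n = 3 gives ≈ 3.07, not 3.38).
- The SBM is a simple Bernoulli variant with an MDL-like penalty, not a
  degree-corrected or nested model.
- The Edge-style time-course test is a spline-F permutation stand-in
  delivering the same interface (per-entity p-values), not a reimplementation
  of the optimal discovery procedure.
- EC50 estimates inherit the bias of the fixed-asymptote fit for sensors
  whose sigmoid is truncated by the dose range; the range filter removes the
  worst cases but near-edge sensors remain less accurate.
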