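# Methods

This note documents the statistical procedures implemented in `mitecomm`,
the defaults they ship with, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Data model

A survey is a pair of tables: a sample × species matrix of non-negative
integer counts (individuals per soil core) with a plot/treatment label per
sample, and a sample × environment table with five continuous variables —
vegetation cover `VegCovr` (%), soil moisture `H` (%), soil temperature
`Ts` (°C), `pH`, and penetration resistance `RPs` (MPa). Counts are
validated as integers (fractional abundances are rejected, not rounded:
the data are counted individuals); `VegCovr` and `H` must lie in [0, 100],
`pH` in [0, 14], `RPs ≥ 0`. Species and sample identifiers are opaque
strings; row/column order of input files is preserved, and every statistic
downstream is invariant to sample order.

## Frequency, constancy, DD4

Within a plot of `P` samples, a species present in `p` of them has
frequency `F = 100·p/P` (presence/absence only). Constancy bands follow
the conventional accidental → euconstant ladder; because the conventional
band edges ("5.0–15.0", "15.1–30.0", …) leave values such as 15.05
unassigned, the implementation uses half-open intervals that partition
[0, 100] exactly: F1 [0, 5), F2 [5, 15], F3 (15, 30], F4 (30, 50],
F5 (50, 100]. Every representable F maps to exactly one class.

The dispersal-rate statistic between plots a and b is

    DD4 = (2W / (A + B)) · ((A − B) / (A + B − W)),

with `A = Σ F_a`, `B = Σ F_b` over all species and
`W = Σ min(F_a, F_b)` over the *rare* species. Since `W ≤ min(A, B)`,
both factors are ≤ 1 in magnitude, hence `|DD4| ≤ 1`; the statistic is
antisymmetric in the pair and zero for identical frequency vectors.
Degenerate denominators (`A + B = 0`, or `A + B = W`, possible only when
every species is rare and fully shared) are defined as `DD4 = 0` with a
warning. Reported values are `|DD4|` with the sign kept as metadata.

Three readings of "rare" are supported (`rare_scope`): a species counts
toward `W` if it is classified F1/F2 in **both** plots (default,
conservative), in **either** plot, or in the **pooled** classification of
the mean frequency. Frequencies enter on the 0–100 percent scale.

## Rarefaction

Sample-based rarefaction uses the exact analytic (Mao Tau) form

    τ(n) = S_obs − Σ_j C(N − N_j, n) / C(N, n),

the expected richness of a uniformly random subset of `n` of the `N`
samples, where `N_j` is the number of samples containing species j.
Binomial coefficients are evaluated with exact integer arithmetic
(`math.comb`), so the curve is exact up to one floating division per term;
τ(1) equals mean per-sample richness and τ(N) the observed richness by
construction. The test suite verifies equality with exhaustive subset
enumeration for N ≤ 8.

## Ordination

**Bray–Curtis.** `d(i,j) = Σ|x_i − x_j| / Σ(x_i + x_j)` over species,
optionally after `ln(x+1)`; pairs of two empty samples are defined as 0
with a warning. The `ln(x+1)` transform is stated for the CCA path; for
internal consistency it is also the default on the Bray–Curtis /
NMDS / ANOSIM path, controllable by flag.

**NMDS.** Kruskal stress-1,
`sqrt(Σ(d̂ − f(d))² / Σ d̂²)` with a monotone disparity function `f`
fitted by isotonic regression (Kruskal's primary tie treatment: embedded
distances are sorted within blocks of tied observed dissimilarities).
Minimisation is by SMACOF (Guttman transform) alternated with the isotonic
refit. Defaults: k = 2 dimensions, 20 starts (start 0 is the
classical-scaling configuration, the rest random Gaussians), 300
iterations, convergence tolerance 1e−7 on the stress decrement. The best
configuration is returned centered and rotated to principal axes;
non-convergence is flagged, not raised.

**ANOSIM.** All `M = n(n−1)/2` off-diagonal dissimilarities are ranked
once (average ranks on ties);
`R = (mean between-group rank − mean within-group rank)/(M/2) ∈ [−1, 1]`.
The null distribution randomly relabels samples; every permutation p-value
in the package uses the add-one convention
`p = (1 + #{perm ≥ obs}) / (1 + n_perm)`, so p ≥ 1/(1+n_perm) > 0.

**CCA.** The (transformed) community matrix is chi-square
double-standardized, `Q = (P − r cᵀ)/sqrt(r cᵀ)` with row/column mass
vectors r, c; total inertia is `‖Q‖²_F`. Constraints are standardized to
zero mean/unit variance, centered under the row weights, scaled by
`sqrt(r)`, and `Q` is projected onto their span by least squares; the SVD
of the fitted part gives the canonical axes (eigenvalues = squared
singular values, constrained inertia their sum; axis percentages are of
constrained inertia). Samples that are empty after the transform are
dropped with a warning (their row weight would be undefined), as are
all-zero species columns. Species–axis correlations are plain Pearson
correlations between the `ln(x+1)` species vectors and the canonical site
scores, with a |r| ≥ 0.5 highlight helper; the definition of
"correlated with an axis" is not fixed by convention, and this is the
simplest reproducible choice.

Per-constraint VIFs are `1/(1 − R²)` from the row-weighted regression of
each constraint on the others (single constraint → 1, exact collinearity
→ +inf). The model-level permutation test permutes the rows of the
constraint matrix against the fixed standardized community (a random
re-pairing of environment with samples) and compares pseudo-F
`(CI/q)/((TI − CI)/(n − q − 1))`; per-axis tests condition on the
preceding canonical axes by residualizing both sides on them. Forward
selection adds, at each step, the candidate whose additional constrained
inertia has the lowest permutation p (ties broken by pseudo-F) under
permutation of the reduced-model residuals, stopping at `alpha_add`
(default 0.05). The default permutation count for the full CCA model test
is 9999.

## Indicator species

For species i and site-group set G (single plots, and all plot pairs when
`max_combo_size = 2`): specificity `A = mean abundance in G (pooled) /
(pooled mean + Σ means of the remaining groups)`, fidelity `B = fraction
of G's samples containing i`, `IndVal = 100·A·B`. Over singleton sets the
specificities of a species sum to 1. An alternative all-singletons
denominator is available by flag. Significance comes from randomly
reallocating samples among groups, with the species' maximum IndVal over
candidate sets as the permutation statistic (the same statistic as
observed). The characteristic-species rule retains (species, set) pairs
with IndVal > 25 % and p < 0.05; both thresholds are configurable, and the
full table is always exposed so softer readings remain recoverable.
Default n_perm = 999.

## Abundance and richness models

Per-sample abundance (row sum) and richness (occupied species count) are
modelled as Poisson with log link over a 15-model candidate set: intercept
only, each single predictor (plot factor and the five covariates),
the plot factor plus each covariate, and three two-covariate combinations.
Covariates are screened beforehand by iterative VIF exclusion (threshold
3; the highest-VIF covariate is dropped until all pass, ties keeping the
earlier-declared column). A Gaussian random site intercept can be added;
with one site per plot it is confounded with the treatment factor, so its
variance estimate routinely hits the boundary, in which case the fit
collapses to the plain GLM — the variance component still counts toward
K, so the treatment-only model has K = 6 (intercept + 4 contrasts +
variance). The random-intercept marginal likelihood uses a Laplace
approximation: damped Newton to the joint (β, u) mode (tolerance 1e−8,
≤ 200 iterations), `log det` correction from the u-block of the Hessian,
and a bounded scalar search over log σ².

Ranking uses `AIC = −2LL + 2K` by default — the variant that reproduces
the published arithmetic exactly — with the small-sample
`AICc = AIC + 2K(K+1)/(n−K−1)` behind a flag. Δi and Akaike weights
`w_i = exp(−Δi/2)/Σ exp(−Δ/2)` follow, with Δi < 2 flagged competitive.
Treatment contrasts are reported against the control on the
linear-predictor scale (`CG−X = −β_X`), with single-step adjusted p-values
from the max-|z| multivariate-normal distribution over the contrast family
(the quasi-Monte-Carlo CDF is seeded for reproducibility). Environment
variables get a one-way ANOVA (between-plot df, MS, F, p) and Tukey HSD
comparisons with studentized-range 95 % limits; all-constant groups raise
an error naming the variable rather than emitting an undefined F.

Poisson overdispersion of abundance is deliberately not corrected
(no negative-binomial or zero-inflated response models); the candidate
family is kept as designed.

## Synthetic generator

The generator emulates the study design: 5 plots (control CG and
treatments A–D) × 50 cores, a 30-species pool, and per-plot environment
Gaussians truncated to each variable's legal range by resampling.
Printed per-plot extremes anchor the environment calibration
(VegCovr: A 75.96 ± 8.74, C 57.28 ± 8.59; Ts: C 17 ± 1.62, D 14.7 ± 1.74;
pH: B 4.55 ± 1.22, C 5.05 ± 0.42; H: A 69 ± 6.82, C 61.5 ± 5.9;
RPs: B 1.39 ± 0.14, A 1.30 ± 0.13); the unprinted plot/variable
combinations are interpolated between those extremes.

Counts follow an occupancy-thinned log-linear model: species s is present
in a sample of plot p with probability `occ(s, p)` (zero outside the
plot's species set), and a present species contributes `1 + NB(μ − 1, k)`
individuals with `log μ = baseline_s + offset_p + β_veg·z(VegCovr) +
β_ts·z(Ts)` (z-scores against the across-plot mixture moments; k = 2 by
default, overdispersed as field counts of aggregated soil fauna are, with
Poisson as the k → ∞ switch). The `1 +` shift makes per-sample presence
equal the occupancy parameter exactly, so the constancy structure is
controlled directly and expected totals are analytic; plot offsets are
solved (Brent root-finding at spec construction) so expected per-plot
totals hit the published abundances — D 584 ≫ CG 50, B 52, with the
residual 477 of the 1163 grand total split evenly between A and C, a
split the source tables do not determine. Species sets give richness
CG 5, B 7, A 16, C 18, D 26; only plot D has occupancies above 0.3
(one euconstant, one constant species), mirroring the reported constancy
contrast. Environmental responses are planted only on a few species for
`VegCovr` and `Ts` — the two variables reported as meaningful — and the
other variables are pure noise channels.

Each plot draws from an independent random stream keyed by the plot's
rank in sorted label order, so outputs are reproducible bit-for-bit from
`(spec, seed)` and independent of plot-tuple ordering.

What the generator does **not** emulate: spatial autocorrelation among
cores, temporal dynamics (single sampling date), species-level
environmental niches beyond two linear responses, and any
abundance–environment feedback. Passing recovery and calibration tests
therefore show that the estimators work under independent, log-linear,
occupancy-thinned sampling — not that field data satisfy those
assumptions.

## Problem sizes and reproducibility

Simulation-based checks use scaled problem sizes chosen as the package's
own test design: permutation-null calibration runs 1000 simulations of a
5 × 10-sample, 12-species exchangeable community at n_perm = 199 (an
attainable α = 0.05 grid); coefficient recovery 200 seeds at 5 × 20
samples; forward-selection recovery 50 seeds; indicator recovery 100
seeds at the study's 50 cores per plot, where the planted exclusive
species is euconstant. The end-to-end pipeline derives one seed per stage
from the master seed with a fixed counter scheme
(`SeedSequence([master, stage_counter])`), so adding stages never
perturbs earlier streams and whole-pipeline reports hash identically
across reruns.

## Known limitations

* The printed DD4 formula bounds the statistic by 1; published values
  above 1 therefore cannot arise from this implementation, and no attempt
  is made to reverse-engineer an alternative scaling.
* Per-axis CCA permutation tests use reduced-model residual permutation,
  an approximation whose finite-sample behaviour is less studied than the
  model-level test (which is calibrated in the suite).
* The Laplace approximation can be inaccurate for tiny group counts with
  large variance components; in the intended one-site-per-plot design the
  component is boundary-collapsed anyway.
* NMDS is a local optimizer; multiple starts mitigate but do not eliminate
  the risk of sub-global stress.
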