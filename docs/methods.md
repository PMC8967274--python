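# Methods

This note documents the statistical model, the simulation that stands in
for the greenhouse experiment, the numerical choices in the sampler and the
derived quantities, and the limits of what the test suite demonstrates.

## Performance curve

Performance (scaled relative growth rate, RGR) at daytime temperature `x`
is a peak-normalized Kumaraswamy kernel on the support `(lower, upper)`:

    z    = (x - lower) / (upper - lower)
    k(z) = z^(a-1) (1 - z^a)^(b-1)
    P(x) = stretch * k(z) / k(z*),     z* = ((a-1)/(ab-1))^(1/a)

and `P(x) = 0` outside the support. The kernel family is flexible enough to
capture the left-skewed curves typical of plant growth (slow rise from the
cold limit, steep collapse at the hot limit). Peak normalization was chosen
because it makes `stretch` the maximum performance and yields the thermal
optimum in closed form, `T_opt = lower + (upper - lower) z*` — both directly
testable against grid oracles. An interior maximum requires `a > 1` and
`b > 1`; validation enforces both (with `b = 1` the kernel is monotone and
the optimum degenerates to the upper limit, which would also break the
invariant that the breadth endpoints lie strictly inside the support).

## Hierarchical model and priors

The likelihood is defined on genotype-level mean RGR, scaled by the grand
mean (so the response has mean 1) and with temperature centered on the
unweighted mean of the distinct daytime treatments:

    y_i ~ Normal(P(x_i; theta_{pop(i)}), sigma)   truncated below at 0.

The zero-truncated Normal matches the preprocessing, which truncates
dieback (negative RGR) to zero before averaging. Each population's
parameters live in an unconstrained space

    (c, log w, log(a-1), log(b-1), log s)

with `lower = c - w/2`, `upper = c + w/2`. The support midpoint `c` rather
than `lower` is deliberate: translation of the support is the posterior's
softest direction, and making it a coordinate axis materially improves
mixing. Each coordinate is partially pooled across populations through a
Gaussian hyper-distribution `theta_pj ~ Normal(mu_j, tau_j^2)`.

Priors are weakly informative and anchored on the observed design rather
than hard-coded temperatures: the hyper-mean of `c` is centered on the
middle of the treatment span with sd half the span; `log w` on 1.5x the
span (critical limits typically extend beyond the tested range); `log(a-1)`
and `log(b-1)` on values giving `a ~ 2.5`, `b ~ 3.5`; `log s` on the
observed scaled maximum. Hyper-variances get conjugate Inv-Gamma(3, 0.5)
priors; the residual sd gets a Half-Normal(0.5) prior on the scaled-RGR
scale. A floor of 1e-4 (scaled units) is added to sigma inside the
likelihood so that noise-free data (used by end-to-end recovery tests) keep
the posterior proper.

## Sampler

Sampling is adaptive Metropolis-within-Gibbs, exploiting that populations
are conditionally independent given hyper-parameters and sigma:

- componentwise Gaussian random-walk updates of each transformed
  coordinate, proposed for all populations at once and accepted per
  population (target acceptance 0.44, Robbins-Monro scale adaptation);
- four joint random-walk updates per sweep from a per-population empirical
  covariance learned online during warmup (target acceptance 0.23) — these
  traverse the ridge along which support limits trade off against shape
  parameters;
- conjugate Gibbs draws of the hyper-means and hyper-variances;
- a log-scale random-walk update of sigma.

Adaptation runs only during warmup, so retained draws come from a fixed
Markov kernel with the correct stationary distribution. Chains are
independent streams spawned from one seed; the retained draw count is
exactly `chains x iterations x (1 - warmup_fraction)` (4 x 4000 x 0.5 =
8000 under the default settings). R-hat and bulk ESS are computed with
ArviZ per parameter; fits warn above R-hat 1.01 and flag non-convergence
above 1.05, returning draws either way. The raw support/shape coordinates
are weakly identified by design (only six distinct temperatures constrain
each curve) and their R-hat can sit above 1.05 at moderate chain lengths
even when the scientifically-used functionals (`T_opt`, `T_breadth`,
`stretch`) mix well; the diagnostics report makes this visible rather than
hiding it. `MCMCConfig.max_tree_depth` is accepted and recorded for
interface compatibility with tree-based samplers but has no effect here.

The posterior predictive p-value simulates replicate observations from the
truncated-Normal likelihood for a subsample of at most 500 draws (inverse-
CDF sampling) and reports `mean 1[y_rep > y_obs]` overall and per
population; values near 0.5 indicate adequate fit.

## Derived quantities

`T_opt` is analytic. `T_breadth` evaluates the curve on `grid_n = 100`
equally spaced points spanning the draw's own support and takes, on each
side of the optimum, the grid point whose performance is closest to
`level = 0.5` of the maximum; the two support endpoints are excluded as
candidates (they have zero performance, and their inclusion could violate
`lower < breadth_lo`). The grid spans the support rather than the data
range because performance is identically zero outside it. An optional
`refine` flag replaces the snapped endpoints by Brent root-finding; it is
off by default so that reported breadths correspond to the 100-point grid
convention. Posterior summaries (mean, equal-tailed 2.5/97.5 percentiles)
are always computed from per-draw derived values, never by deriving from
summarized parameters — the tests assert the order explicitly because the
two differ for nonlinear functionals. Critical thermal limits are exported
in the summary tables but not analyzed downstream: with treatments spanning
10-45 degC the limits extrapolate beyond the design and are reported for
completeness only.

## Range contrasts and cline models

For each posterior draw the invasive among-population average of a derived
parameter is subtracted from the native average; the contrast is summarized
by its posterior mean and equal-tailed 95% credible interval and called
significant when the interval excludes zero.

Cline models regress population posterior means (a two-stage approach;
posterior uncertainty in the response is not propagated) on a predictor
(latitude, MAT, or TS), a range indicator, and optionally their
interaction. Native is the reference level, so the range coefficient is the
invasive offset. Four families are fitted: `T_opt ~ latitude`,
`T_opt ~ MAT`, `T_breadth ~ latitude`, `T_breadth ~ TS`. The interaction
and no-interaction models are compared by AIC computed as
`-2 loglik + 2(k+1)` — the Gaussian constant is kept and the residual
variance is counted as a parameter, so values are comparable to mainstream
statistical software. Selection takes the strict minimum even when the AIC
difference is small; exact ties go to the fewer-parameter model. A
significant interaction in a selected full model is labelled "divergent
clines"; a significant predictor effect without interaction, "parallel
cline". Per-range sub-models (`response ~ predictor` within each range)
localize any cline. Degenerate constant responses are handled by reporting
zero slopes, p-values of 1, and the adjusted-R-squared formula value
`1 - (n-1)/(n-k-1)` (which is negative, as adjusted R-squared can be).

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
with defaults mirroring the motivating experimental design: 18 native + 13
invasive populations, 3 genotypes per population, six day/night regimes
(10/0, 20/10, 25/15, 30/20, 40/30, 45/35 degC), two clones per genotype per
regime plus two extra 45/35 clones per genotype — 1302 cuttings in total —
with establishment failure (p = 25/1302) and accidental damage
(p = 26/1277) rates chosen so the expected audit trail matches that design;
a fixture mode pins the counts exactly by sampling without replacement.
Observation noise is additive on the RGR scale (sd 0.02/day by default,
about 15% of the peak rate, in line with clonal growth assays), so the
implied RGR of an established cutting is exactly `P(day_temp) + eps` — the
forward model conjugate to the analysis likelihood. Outside the support the
expectation is zero and negative draws become dieback records, later
truncated by preprocessing; damaged cuttings get an arbitrary negative
implied RGR.

Ground truth curves default to `lower = -5`, `upper = 50` degC, `a = 2.5`,
`b = 3.5`, peak RGR 0.15/day (optimum near 23.5 degC). In cline mode the
optimum shifts linearly with MAT (default 0.15 degC per degC, plus seeded
population scatter, 0.8 degC sd) by translating both limits, and breadth
scales linearly with TS by stretching the support about the optimum — both
constructions are exact, so noiseless truths regress with exactly the
configured slopes. Climate is generated as latitude bands (native 33-61,
invasive 50-58 degrees) with MAT falling and TS rising in latitude in the
native range and TS falling in the narrow invasive band.

What the generator does not emulate: chamber/tray effects and round
replication structure (clones are pooled per genotype x temperature, as in
the analysis), night-temperature physiology (night temperature is carried
as metadata only; the curve's axis is daytime temperature), genotype-level
curve variation (the model fits population curves), spatial autocorrelation
of climate, and any real geography beyond monotone trends. Passing tests
therefore demonstrate correctness of the estimator under the model's own
assumptions plus the stated observation model — not robustness to chamber
effects or model misspecification beyond the truncation/averaging mismatch
the pipeline itself introduces.

## Problem sizes in tests and the acceptance script

Fits inside the test suite and acceptance script use reduced sampler
settings chosen once as the smallest sizes at which the checks are stable:
2 chains x 2000 iterations for 12-population recovery fits, 2 x 1500 for
posterior-predictive checks, 2 x 900 for the 50-dataset credible-interval
calibration suite, and the full 4 x 4000 arithmetic on a small dataset
where the draw count itself is the quantity under test. The calibration
suite uses 5-population datasets; pooled coverage of the 95% interval is
required to land in 90-99%, leaving room for Monte Carlo error at these
sizes.

## Known limitations

- The likelihood treats genotype means as zero-truncated Normal; strictly,
  an average of per-clone truncated values is not truncated Normal. The
  residual sd absorbs most of the mismatch and posterior predictive
  p-values on pipeline data sit near 0.5, but sigma should be read as a
  dispersion parameter, not a per-clone measurement sd.
- Critical thermal limits extrapolate beyond the treatment range and are
  prior-sensitive; they are exported, not analyzed.
- Cline regressions ignore posterior uncertainty in the population means;
  with 31 populations the dominant error is among-population scatter, but
  slopes for poorly-estimated parameters will be mildly attenuated.
- The sampler is random-walk based; for much larger designs (hundreds of
  populations) a gradient-based sampler would scale better.
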