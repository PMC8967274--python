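# thermperf

Hierarchical Bayesian thermal performance curves (TPCs) for clone-growth
experiments, with native-vs-invasive range contrasts and climatic cline
tests.

## The problem

A common design for measuring plant thermal physiology grows clonal cuttings
of many genotypes from many populations under a handful of day/night
temperature regimes, and scores relative growth rate (RGR) — the change in
total stem-plus-branch length per unit initial length per day,

```
RGR = (stem_out - stem_in) / (stem_in * days)
```

From RGR-versus-temperature data one wants, for every population, a thermal
performance curve: its **thermal optimum** `T_opt` (temperature of maximum
performance), its **thermal performance breadth** `T_breadth` (span of
temperatures sustaining at least 50% of maximum performance), and its
critical thermal limits (where performance reaches zero). Comparing these
between a species' native and introduced ranges, and regressing them on
latitude, mean annual temperature (MAT), and temperature seasonality (TS),
asks whether invading populations evolved new thermal niches or carried
their ancestral tolerance with them.

`thermperf` implements the full analysis as a tested, reusable pipeline:

1. **synthetic_data** — seeded simulation of the experiment (populations,
   genotypes, clone replicates, regimes, establishment failure, accidental
   damage, dieback at temperature extremes, optional true climatic clines).
2. **preprocess** — RGR, auditable quality filters, genotype means, scaling.
3. **tpc_model** — the Kumaraswamy-kernel curve and its hierarchical
   Bayesian fit with convergence diagnostics and posterior predictive
   checks.
4. **tpc_derive** — `T_opt`, `T_breadth`, and posterior summaries per draw.
5. **inference** — posterior range contrasts and AIC-compared cline models.
6. **cli / pipeline** — a `thermperf` command tying the stages together.

## The model

Performance at temperature `x` follows a peak-normalized Kumaraswamy kernel.
With critical limits `lower < upper` and `z = (x - lower)/(upper - lower)`:

```
k(z)  = z^(a-1) * (1 - z^a)^(b-1)                 0 < z < 1
z*    = ((a - 1)/(a b - 1))^(1/a)                 kernel mode (a, b > 1)
P(x)  = stretch * k(z)/k(z*)   inside (lower, upper),  else 0
```

so `stretch` is the maximum performance and
`T_opt = lower + (upper - lower) z*` in closed form. Observed scaled
genotype-mean RGR is modelled as `y ~ Normal(P(x), sigma)` truncated below
at zero, with each population's five parameters partially pooled through
Gaussian hyper-distributions on an unconstrained scale. Sampling is by an
adaptive Metropolis-within-Gibbs scheme (componentwise and joint
adaptive-covariance random-walk updates per population, conjugate updates
for hyper-parameters); R-hat and effective sample size are reported via
ArviZ, and model fit via the posterior predictive p-value
`P(y_rep > y_obs)` (≈0.5 indicates adequate fit). See `docs/methods.md`.

## Worked example

```python
from thermperf import MCMCConfig, SimConfig
from thermperf.synthetic_data import simulate_experiment
from thermperf.preprocess import preprocess
from thermperf.tpc_model import fit_tpc
from thermperf.tpc_derive import derive_draws
from thermperf.inference import cline_analysis, range_contrast

cfg = SimConfig(n_native_pops=6, n_invasive_pops=6, truth_mode="cline",
                noise_sd=0.01, seed=42)
climate, truths, records = simulate_experiment(cfg)
clean, report, means, scaled = preprocess(records)
draws, diag = fit_tpc(scaled, MCMCConfig(chains=2, iterations_per_chain=2000, seed=1))
per_draw = derive_draws(draws)
contrast = range_contrast(per_draw, "t_opt")
```

This prints (via the obvious `print` calls):

```
cuttings: 504 -> established 493 -> final 481 (19 dieback truncations)
               t_opt  t_breadth
INV01          23.73      30.16
INV02          23.98      29.28
INV03          23.75      28.64
INV04          23.86      28.65
T_opt contrast (native - invasive): -0.827 degC [-1.276, -0.368], significant=True
T_opt ~ MAT: final model reduced, beta1=0.160 (p=0.019), AIC=30.75
  native-range slope 0.173 (p=0.098)
```

Reading the output: the filter audit shows how many cuttings survived
establishment and damage exclusions and how many negative-growth (dieback)
records were truncated to zero. Each population gets a posterior-mean
thermal optimum (degC) and 50%-of-maximum breadth (degC). The range contrast
is the posterior distribution of (native mean − invasive mean); here the
simulation placed a true `T_opt` cline on MAT, and because the simulated
invasive range is cooler on average than the native range the contrast is
genuinely negative and its 95% credible interval excludes zero. The cline
report compares models with and without a range-by-predictor interaction by
AIC: the reduced (no-interaction) model wins, with the fitted slope of
`T_opt` on MAT close to the simulated truth of 0.15 degC per degC.

The same analysis runs from the shell:

```
thermperf init-config cfg.yaml
thermperf all --config cfg.yaml --outdir out
```

which writes `experiment.csv`, `genotype_means.csv`, `posterior_draws.csv`,
`derived_summary.csv`, `contrasts.json`, `clines.csv`, and a `manifest.json`
recording seeds and artifact paths; re-running with the same configuration
reproduces every output bit-for-bit.

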