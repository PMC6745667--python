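# spatmort

Narrower confidence intervals for mortality rates when all you know is
*where* the deaths and survivals happened.

## The problem

Species-level tree mortality rates from repeated forest-plot censuses
are classically treated as binomial: of `n` individuals alive at the
first census, `k` survive to the second, every individual is assumed to
share the same survival probability `k/n`, and the instantaneous rate is

    λ̂ = (ln n − ln k) / Δt        [per year]

with Δt the mean census interval in years.  The equal-probability
assumption is clearly false — mortality risk is spatially structured by
gaps, pathogens, flooding, soil — and it is *conservative*: the binomial
is the maximum-variance model for a fixed mean.  If individual survival
probabilities `p_1, …, p_n` differ, the number of survivors follows the
**Poisson binomial** distribution, whose variance `Σ p_i (1 − p_i)` is
strictly smaller than the mean-matched binomial variance
`n p̄ (1 − p̄)`.  Any defensible estimate of individual-level risk
therefore buys narrower confidence intervals.

`spatmort` estimates those individual probabilities from the spatial
pattern alone:

1. **Bandwidth selection.**  Besag's `L(r) = sqrt(K(r)/π)` (Ripley's K
   with isotropic edge correction on a rectangular window) is computed
   for the dead subset, the surviving subset and the full pattern; the
   relative aggregation curves `A_dead(r)` and `A_surv(r)` compare each
   subset with the whole, and the species bandwidth σ is the shorter of
   the distance maximizing `A_dead` and the distance minimizing
   `A_surv`.
2. **Probability map.**  Leave-one-out Gaussian kernel densities of
   surviving and dead neighbours give
   `p̂_i = D1_i / (D1_i + D0_i)`; values are clamped to
   [0.0001, 0.9999] and the whole vector is shifted on the logit scale
   until the Poisson binomial mode equals the observed survivor count.
3. **Bootstrap.**  10,000 independent Bernoulli resamples of the map
   give the distribution of `λ*`; the 2.5% and 97.5% quantiles are the
   95% CI.  The binomial baseline runs the identical machinery with
   constant `p_i = k/n`, and the headline statistic is the relative
   width reduction `(W_b − W_Pb) / W_b`.

## Worked example

Simulate three synthetic species (300 stems each, patchy survival:
patches of survival probability 0.98 or 0.2 on a 200 × 200 m plot,
5-year interval) and analyze them:

```sh
spatmort simulate --species 3 --n 300 --seed 42 --out demo_census.csv
spatmort run --census demo_census.csv --window 0 200 0 200 \
             --reps 2000 --seed 42 --out demo_results.csv
```

```text
species_id   n  k_obs  sigma  lambda_binomial  lambda_poibin    w_b   w_pb  improvement
    sp0000 300    239 6.1523           0.0455         0.0455 0.0227 0.0151       0.3351
    sp0001 300    259 1.1719           0.0294         0.0294 0.0178 0.0023       0.8696
    sp0002 300    244 8.6914           0.0413         0.0413 0.0222 0.0165       0.2581
```

Per species: `sigma` is the selected kernel bandwidth in metres;
`lambda_binomial` and `lambda_poibin` are the yearly mortality rates
under the two models (identical by construction — the map's mode is
rescaled to the observed count); `w_b`/`w_pb` are the 95% CI widths and
`improvement = (w_b − w_pb)/w_b`, e.g. a 33.5% narrower interval for
sp0000.  The same computation is available programmatically through
`spatmort.read_census`, `spatmort.run_batch` and the lower-level
functions (`k_function`, `select_sigma`, `kernel_densities`,
`rescale_to_mode`, `bootstrap_ci`, …).

The census CSV needs columns
`species_id, x, y, status, date0, date1` (status 1 = alive at recensus,
0 = dead; dates as decimal years or ISO-8601).

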