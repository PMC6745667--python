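# Methods

## Model

Each individual `i` of a species is a Bernoulli trial: alive (`x_i = 1`)
or dead (`x_i = 0`) at the second census.  The survivor count
`K = Σ x_i` of `n` independent but *non-identically* distributed trials
follows the Poisson binomial distribution with parameters
`p_1, …, p_n`.  Its mean is `Σ p_i` and its variance `Σ p_i (1 − p_i)`,
which is bounded above by the mean-matched binomial variance
`n p̄ (1 − p̄)` with equality iff all `p_i` are equal — heterogeneity in
individual risk always *reduces* uncertainty in the aggregate outcome.

The yearly mortality rate is `λ = (ln n − ln k) / Δt`.  Per-individual
census-interval lengths are collapsed to the species mean Δt, the
standard convention in forest-plot demography; `k = 0` maps to an
infinite rate.  Inference is a parametric bootstrap: the fitted vector
`p̂` is the "alternative world", survivor counts `k*` are drawn as
independent Bernoulli outcomes from it, and the 95% CI for λ is the
2.5%/97.5% quantile pair of the implied `λ*` distribution.  The
binomial baseline is the same machinery with constant `p_i = k/n`
(equivalent to bootstrapping the raw binary observations).  Model
comparison uses the relative width reduction `(W_b − W_Pb) / W_b`.

## Poisson binomial computation

Two PMF paths are implemented and continuously cross-checked:

* exact `O(n²)` convolution recursion (the test oracle);
* the DFT-CF evaluation — characteristic function sampled at the
  `n + 1` unit roots `C^l`, `C = exp(2πi/(n+1))`, inverted by FFT —
  the production path.  Observed agreement with the oracle is ~1e-15
  at `n = 1000`, far inside the 1e-8 bound the tests assert.  Negative
  round-off masses are clipped to zero and the table renormalized.

The mode (`k̂`, the central estimate of the survivor count) breaks
exact ties toward the smaller `k`, i.e. the higher mortality rate —
a deterministic, mildly conservative convention.  Tie detection uses a
1e-12 absolute tolerance so that floating-point noise in the FFT path
cannot flip a genuine tie.

## Probability map

Leave-one-out Gaussian kernel densities of survivors and dead at each
point (`g(d, σ) = exp(−d²/2σ²)`, unnormalized — only the ratio
matters) give `p̂_i = D1_i / (D1_i + D0_i)`.  Excluding the focal
individual keeps the map strictly smoother than the data and gives the
correct limits, both of which are tested:

* σ → ∞: every `p̂_i` tends to the leave-one-out survivor fraction
  `(k − x_i)/(n − 1)` (the binomial world, maximally conservative);
* σ → 0 (or an isolated point): densities vanish and the same
  leave-one-out fraction is substituted explicitly (threshold 1e-300 on
  the total density).

Raw probabilities are clamped to [0.0001, 0.9999] (configurable), then
rescaled so the map's Poisson binomial mode equals the observed
survivor count.  The rescaling family is an additive shift `c` on the
logit scale — the minimal monotone one-parameter family that preserves
the ordering and spatial structure of the map — solved by bisection on
`c ∈ [−50, 50]` (the mode is non-decreasing in `c`), with re-clamping
after the shift.  `c` is reported as `scale_param`.  Clamping must
precede the shift because the logit is undefined at 0 and 1.  In the
rare case where clamping makes the exact target mode unreachable the
closest achievable mode is returned with a warning.

## Bandwidth selection

`K(r)` uses the estimator `area/(m(m−1)) Σ_{i≠j} e_ij 1(d_ij ≤ r)` with
Ripley's isotropic edge correction; for rectangles the in-window circle
fraction has a closed form (two nearest edges, with the corner-overlap
term), valid for `r` up to half the shorter side.  The default distance
grid is 513 equally spaced values from 0 to a quarter of the shorter
window side.  The implementation was validated against an independent
reference (`spatial::Kfn` in R agrees exactly after accounting for its
`n²` versus our `n(n−1)` denominator) and against the CSR expectation
`K(r) = πr²` by simulation.

The species bandwidth is
`σ = min(argmax_r A_dead(r), argmin_r A_surv(r))` with
`A_sub = (L_sub − L_all)/L_all`, searching only `r > 0` where the curve
is defined (`L_all > 0`; subsets need ≥ 2 points), ties toward smaller
`r`, floored at half the grid spacing.  Species with no usable curve on
either side (all dead or all alive) are degenerate and get a binomial
point estimate only.

**Known limitation.**  For Bernoulli-thinned, uniformly placed points
on a patch mosaic, the *expected* `A_dead(r)` is maximal as `r → 0+`
(the patch-type covariance peaks at lag zero), and the empirical argmax
is dominated by the closest dead pairs: single pairs at small `r`
produce large spikes in `L_dead` exactly where `L_all` is small.  In
practice the selector tracks the nearest-dead-pair scale rather than
the patch scale.  On sparse patterns the two coincide to within a
factor of ~2 about half of the time (simulation: ~0.49 success over
patch scales {5, 10, 20} at 50 seeds each, with ~30-stem species on
windows of 10 patches per side, survival 0.98/0.1 and patch fractions
0.8/0.2); on dense patterns σ collapses toward the grid floor, which
over-fits the map and makes the Poisson binomial intervals
optimistically narrow.  The selection rule is kept as stated because it
is the method's definition; users with prior knowledge of the relevant
interaction scale should prefer a fixed σ (the `sigma` override in
`AnalysisConfig` / `--sigma` on the CLI).

## Synthetic data

* `coin_mixes` — two-point mixtures of biased coins constrained to an
  identical expected head count (default 135 of 300, the homogeneous
  regime at p = 0.45, a moderate ±0.2 mixture, and an extreme
  0.02/0.98 mixture); one coin may take an intermediate value so the
  mean constraint holds exactly.
* `coin_table` — a 20 × 15 unit grid of coins with no / patchy /
  gradient spatial structure in the true head probability; with no
  structure the fitted map (σ = 1.25) leaves the Poisson binomial and
  binomial PMFs nearly identical (max difference < 0.02), while patchy
  structure concentrates the Poisson binomial.
* `species_landscape` — uniform positions on a rectangular plot; square
  blocks of side `patch_scale` are assigned survival regimes by a
  seeded draw, statuses are Bernoulli; all-dead/all-alive draws are
  redrawn up to 10 times and then flagged degenerate.  The recorded
  `p_true` yields the true rate `(ln n − ln Σ p_true)/Δt` for coverage
  and recovery experiments.

What these generators deliberately do *not* emulate: inhibition between
stems (real trees cannot be arbitrarily close — precisely the feature
whose absence breaks small-`r` behavior of the bandwidth selector),
habitat covariates, within-species Δt variation (generated constant),
and multi-census histories.  Passing tests on these landscapes shows
the estimation machinery is correct under the stated model, not that
the spatial model captures real forest mortality.

## Batch experiment conditions

`spatmort.experiments` fixes the study conditions used by the tests and
`scripts/acceptance.py`:

* *central-estimate agreement*: 200 species, `n ~ U{20..500}`,
  200 × 200 window, patch scale 20, per-species regime pair drawn from
  U[0.5, 0.99] in equal proportions, Δt = 5 yr.  Because rescaling pins
  the map's mode to the observed count, rates from `k_obs` and from
  `k̂` correlate at r = 1.0 whenever the target mode is reachable.
* *CI-width reduction*: 200 species, n = 300, patch scale 40, regimes
  0.98/0.2 with fractions 0.8/0.2, Δt = 5 yr, 2,000 bootstrap
  replicates per model; mean improvement ≈ 70% under these strongly
  segregated conditions.
* *coverage*: 1,000 censuses drawn from a known two-level probability
  vector (n = 200, 120 × 0.9 and 80 × 0.4), analyzed with the true
  vector rescaled to each realized count, 2,000 replicates; observed
  coverage ≈ 94–95%.

Per-species RNG seeds are derived as `crc32(master_seed:species_id)`,
so results for one species never depend on which other species are in
the batch.  Bootstrap quantiles interpolate linearly between order
statistics; draws with `k* = 0` map to `λ* = +∞` and are retained, so
an upper bound is reported as infinite whenever ≥ 2.5% of draws lose
every individual, rather than being silently truncated.

## Caveats on the headline statistics

The near-perfect central-estimate agreement is a property of the
rescaling construction, not evidence that the map is right.  The
CI-width reduction depends on σ: data-driven σ on a *homogeneous*
landscape still yields apparent improvements of 0.5–0.9 by fitting
noise (the σ ~ 0 over-fitting regime), whereas a flat kernel recovers
the binomial answer.  Width reductions should therefore be read as
conditional on the probability map being a faithful description of the
risk surface.
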