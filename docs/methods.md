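# Methods

`polyspace` quantifies a single question: how large is the *usable* space
of sequence variants of a gene, and how quickly does an evolving
population exhaust it?  Once the space is exhausted, mean dissimilarity to
any ancestor stops growing and sequence divergence stops carrying
information about elapsed time.  This note records the models, the
estimators, the numerical choices, and what the synthetic experiments do
and do not show.

## Sequence spaces in log10

A gene of length `L` over `k` monomers has at most `k^L` variants, and the
probability of hitting one given variant by blind permutation is
`(1/k)^L`.  Both are carried exclusively as log10 values (`4^120 ≈
10^72.2` overflows every native float), and the two functions are exact
negations of each other by construction.  `L = 0` is accepted as the
identity case (one empty sequence, probability 1) so that algebraic
property tests have an anchor.

## Exhaustion accounting

Neutral accounting equates the target variant count with the number of
mutant copies produced:

* **unlimited doubling** — `k^L = μ · N0 · 2^n`, so
  `n = log2(k^L / (μ N0))`.  For `L = 120`, `k = 4`, `μ = 2.54e-10`,
  `N0 = 1`: `n = 271.87`, i.e. 272 generations, under four days at a
  20-minute generation time.
* **constant Ne** — `k^L = μ · Ne · n`, so `n = k^L / (μ Ne)`.  For
  `Ne = 2e8`: `n ≈ 3.48e73` generations ≈ `1.32e69` years.

Two interpretive points, both deliberate: the accounting treats the space
size itself as the target on the left-hand side (the polymorphism level θ
of neutral theory is not separately modelled), which is how the worked
regime calculations above are posed; and the 20-minute default generation
time is an inference from the day/year conversions those calculations
imply rather than a stated constant.  Counts that exceed float range are
carried as (mantissa, base-10 exponent) pairs and formatted to 3
significant figures.  The deterministic accounting is intentional: no
coupon-collector correction for re-drawing already-seen variants is
applied.

## The effective space

Purifying selection narrows each site to an allowed set of nucleotides;
the per-site sets and frequencies observed in a reference alignment form
the *polymorphism profile* (gaps rejected — indels are out of scope; `U`
is normalised to `T` so RNA and DNA references interoperate).

* **Effective length `Le`** — the count of sites whose allowed set has at
  least two states.  Sites are treated independently: covariation between
  sites (e.g. paired stems of structured RNAs) is real but unmodelled, and
  output metadata flags this (`epistasis_modelled: false`).  Because
  epistasis only removes combinations, the independent-site space is an
  upper bound on the true effective space.
* **Effective base `ke`** — an effective-alphabet (perplexity) measure of
  how many alternatives a variable site really explores under
  transition/transversion bias κ.  The single-generation kernel mutates a
  site with probability μ and, given a mutation, picks the transition with
  probability κ/(κ+2) and each transversion with 1/(κ+2).  Restricting
  this symmetric kernel to an allowed set (rejected proposals keep the
  state) preserves symmetry, so its *stationary* law is uniform on the
  allowed set for every κ — a stationary-based measure cannot see the
  bias.  `ke` is therefore defined on mutational-timescale accessibility:
  from each allowed origin, weight the origin and its transition partner
  by κ and each allowed transversion by 1, normalise, take the Shannon
  entropy, average over origins, exponentiate, and average (in log) over
  variable sites.  This yields the limits the measure is meant to have:
  `ke = |allowed|` at κ = 1, `ke → 2` for a fully free site as κ → ∞
  (the transition pair), strictly decreasing in κ in between, and
  `1 ≤ ke ≤ k` always, hence `Le·log10(ke) ≤ L·log10(k)`.

With the default κ = 4 (a typical prokaryotic Ti/Tv ratio) and the
default synthetic profile (120 nt, 50 variable sites, 4 states each),
`ke ≈ 3.3` and the space shrinks from `10^72.2` to `10^25.9`.

## Forward simulation

A population of gene copies (default 200) evolves in discrete
generations: birth–death demography first (each copy duplicates with
probability `duplication_rate`, dies with probability `extinction_rate`;
the population is capped at `population_size` by uniform down-sampling
and rescued from total extinction by keeping one uniformly chosen
pre-step copy), then per-site independent Bernoulli(μ) mutation through
the κ-biased kernel with proposals outside a site's allowed set rejected.
Rejection — rather than lethal selection — is the simplest implementation
of purifying constraint; it reduces the effective substitution rate on
constrained sites, which is intended.  At most one hit per site per
generation; divergence is substitution-only Hamming fraction.  A single
seeded `numpy` generator drives each run, so runs are bit-reproducible;
ensembles use `seed + replicate`.

Two demographic regimes matter in practice.  With
`duplication_rate = extinction_rate = 0` the copies are independent and
the diverged-site count is exactly binomial around the matrix-power
expectation of the (restricted) kernel — this is the regime in which the
simulator is validated against the Jukes–Cantor discrete closed form
`D(t) = (3/4)(1 − (1 − 4μ/3)^t)` and its Kimura two-parameter analogue.
With turnover the copies share genealogy: the population mean wanders
around the expectation with a correlation time of the order of the
coalescent time, and the within-population SD reflects the genealogy, not
the binomial.  Note that with equal birth and death rates the population
size random-walks *downward* under a pure cap (excursions above are
clipped, excursions below are free); holding a population near carrying
capacity requires `duplication_rate > extinction_rate`.

Simulations throughout the analysis scripts and tests use a scaled
per-generation substitution probability of order `1e-3` so that
saturation happens within a few thousand generations; the analytic
calculators use the measured bacterial rate `2.54e-10`.  Divergence
dynamics depend on μt (and on rate ratios), so the scaling changes the
time axis, not the shape.

## Plateau and critical times

* **Plateau `D∞`** — mean of the trajectory's mean divergence over the
  terminal 20 % of samples, accepted as a steady state when the OLS slope
  over the window is statistically indistinguishable from zero at 95 %,
  *or* when the fitted total drift across the window is below 2 % of the
  window mean.  Slope standard errors are Newey–West (HAC,
  `maxlags = window/5`): under birth–death genealogy the window residuals
  are strongly autocorrelated and iid-error slope tests reject genuinely
  stationary windows.  The drift fallback covers the regime where even
  HAC lags are shorter than the wander's correlation time.  A zero
  plateau (μ = 0) is reported as "not saturated" rather than a
  degenerate estimate.  For demographic runs, the plateau should be
  estimated on an ensemble-mean trajectory
  (`ensemble_mean_trajectory`); a single wandering run carries
  irreducible uncertainty of the order of its coalescent fluctuations.
* **tcrit50 / tcrit90** — the trajectory is first smoothed with an
  isotonic (monotone non-decreasing) regression — the expectation is
  monotone, so monotone smoothing suppresses Monte-Carlo jitter without
  biasing the crossing — then the first crossing of `0.5·D∞` (resp.
  `0.9·D∞`) is located by linear interpolation between samples.  On
  analytic saturating curves `D∞(1 − e^{−rt})` the estimators recover
  `ln 2 / r` and `ln 10 / r` within 2 % across three decades of `r`.
* **Years** — conversion from generations multiplies by an explicit
  generation time (minutes) over a Julian year (525 960 min).  It is
  opt-in: published million-year critical times for specific organisms
  presuppose generation times and ecological rates that are not part of
  this package's inputs, so no default is offered.

## Steady state and the collapse of the clock

* **Steady-state distribution** — per-copy divergences to the ancestor
  pooled over post-tcrit90 snapshots, as a 30-bin histogram on [0, 1].
  Stationarity is part of the contract: snapshots separated by at least
  `tcrit90/2` must agree within a total-variation tolerance.  The
  scientific bound is 0.1, but the sampling-noise floor of the TV
  statistic between two n-copy histograms exceeds 0.1 for n ≲ 400 at 30
  bins, so the default tolerance is `max(0.1, Cauchy–Schwarz noise
  bound)`; callers with large snapshots can (and the acceptance property
  test does) enforce 0.1 explicitly.
* **Time–divergence correlation** — Pearson correlation between
  generation and divergence across ≥ 20 replicate trajectories pooled per
  time window, measured across the ensemble because the claim concerns
  how well time can be inferred from divergence.  Near 1 in the linear
  range, near 0 past saturation.
* **Revisitation** — the probability that two independent lineages of the
  same gene meet within a divergence threshold.  The Monte-Carlo
  estimator simulates replicate pairs and reports the binomial standard
  error; by default only the terminal generation is sampled, so with a
  horizon past saturation it targets the stationary meeting probability
  (explicit `sample_generations` scan a path, and "min over time" then
  applies).  The exact reference, tractable for any length, uses
  per-site stationary laws (uniform on allowed sets) and a
  Poisson-binomial convolution of mismatch probabilities; the two routes
  agree on enumerable spaces.

## Synthetic reference data

The generator emulates a 5S-rRNA-like reference set: default 120 nt, 42 %
of sites variable (nearest-integer allocation, i.e. 50 of 120), allowed
sets of configurable size containing the ancestor state, uniform truth
frequencies, optional GC bias, RNA output with `U`.  The truth profile is
returned alongside, and at depth ≥ 1000 the observed profile equals the
truth exactly.  The 0.42 default places the free-variable-site plateau at
`0.75 × 50/120 ≈ 0.31` — the regime of published 5S analyses — but the
generator does not model secondary-structure covariation, lineage
structure among references, or real 5S base composition; passing tests
demonstrate internal consistency of the machinery, not properties of the
real gene.

## Problem sizes

Default experiment scales — 120 nt, 100–200 copies, 4000–6000
generations, ensembles of 8–30 replicates, 2×10⁴–2×10⁵ Monte-Carlo pairs
— were chosen so each analysis step completes in seconds while keeping
Monte-Carlo standard errors at the third decimal of divergence.  All are
parameters, not constants.

## Known limitations

Independent sites (no epistasis, no stem covariation); no indels, no
horizontal transfer, no recombination, no fitness landscape beyond
allowed-set rejection; deterministic exhaustion accounting (no stochastic
coverage correction); plateau certification on a single demographic run
is noise-limited, as discussed above.
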