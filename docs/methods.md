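# Methods

## Model

The package implements an age-dependent multistate Cormack–Jolly–Seber
(CJS) model for annually resighted, nestling-marked birds. Because every
individual is ringed in the nest, its age — and therefore its age class:
juvenile (< 2 years), subadult (2–6, inclusive), adult (> 6) — is known
at every occasion, so the "multistate" structure reduces to
deterministic ageing and the only latent process is alive/dead.
Conditional on first capture, for individual *i* and interval *t*:

- survival: `logit(phi[i,t]) = beta[x(i,t)] + eps[t]`, with
  `eps[t] ~ Normal(0, sigma^2)` a year effect shared by all individuals;
- detection: an alive bird is seen at occasion *t* with probability
  `p[x(i,t)]`; dead birds are never seen; death is absorbing.

Apparent survival confounds death with permanent emigration; the package
does not attempt to separate them. The age class of an interval is the
class at the interval's *start* occasion; detection at occasion *t* uses
the class at *t*. The year effect enters survival only — detection is
time-constant (by class or fully shared), which also avoids the classic
confounding of the final survival and detection parameters under fully
time-varying *p*; a fully time-dependent *p* is deliberately not offered.

The `eps` term is indexed by calendar year and shared across individuals
(a temporal random effect, not individual frailty): that is the reading
consistent with annual survival series and with standard CJS practice,
and it is what the generator produces and the sampler fits.

## Likelihood and cross-checks

Each history's probability, conditional on being alive at first capture
(which contributes no factor), is computed by a two-state forward
recursion over occasions: the alive mass survives and is observed or
missed; the dead mass absorbs the complement and can only be missed.
Three independent routes to the same quantity are kept and tested
against each other to 1e-12:

1. a pure-Python per-history recursion (`history_loglik`), the readable
   reference;
2. a compiled (numba) whole-dataset kernel used by both fitters —
   roughly 30× faster than a vectorised numpy evaluation, which is what
   makes the replicate studies below affordable;
3. a brute-force enumeration over all death intervals
   (`enumerate_history_probs`), guarded at 2^11 patterns, whose
   probabilities must sum to one.

The m-array (releases × first-recapture occasion) gives a fourth route:
for parameters tied across age classes the multinomial m-array
likelihood differs from the individual-history likelihood only by the
parameter-free multinomial coefficient, and the tests verify that the
difference is constant across parameter points to 1e-10. The m-array
likelihood deliberately *refuses* class-varying parameters: once rows mix
individuals with different future class trajectories the m-array is no
longer sufficient, so offering it would be wrong, not conservative.
Impossible events return `-inf` rather than raising, so optimisers and
samplers can reject them.

## Inference

**Maximum likelihood** (fixed effects, `eps = 0`): Nelder–Mead from four
fixed starting points, each polished by BFGS, on the logit scale;
standard errors by delta method from a central finite-difference Hessian
(step 1e-4). Estimates with |logit| > 10 are flagged as boundary cases.
Datasets in which no bird is ever seen after first capture are rejected
as non-identifiable.

**Bayesian fit**: adaptive Metropolis-within-Gibbs on the marginal
likelihood (no data augmentation — the forward recursion integrates the
latent states exactly, so the state space stays small and mixing is not
throttled by imputed death times). One scalar random-walk update per
parameter per iteration: each `beta`, each `logit p`, each `eps[t]`, and
`log sigma` (the sigma step needs no data likelihood, only the `eps`
prior). Proposal scales adapt by Robbins–Monro toward 44% acceptance
with step `min(0.1, it^-0.6)` and freeze at the end of burn-in, keeping
the post-burn-in chain properly Markovian. Priors: Normal(0, 10²) on
logit-scale effects, Uniform(0, 10) on sigma, `eps | sigma ~ Normal(0,
sigma²)`. Chains start from overdispersed seeded draws (effects ~
Normal(1.5, 1) on the logit scale, sigma ~ Uniform(0.1, 1)), redrawn up
to 100 times if the posterior is not finite. The default protocol is 3
chains × 150,000 iterations, burn-in 5,000 (pre-thinning), thin 3.

Sampler correctness is established two ways: on a tiny two-parameter
problem the chain means must match a fine-grid numerical integration of
the posterior within 0.01, and on simulated studies the posterior must
recover the generating parameters and deliver nominal interval coverage
(see below).

**Diagnostics**: the classic (non-split) multi-chain Gelman–Rubin
statistic, `Rhat = sqrt(var+ / W)` with `var+ = ((n-1)/n) W + B/n`, with
the conventional convergence rule Rhat ≤ 1.1; and an
autocorrelation-based effective sample size using Geyer's initial
positive-sequence truncation (chain-averaged autocovariances, paired
sums, stop at the first negative pair).

**Summaries** report posterior mean, sd and the 2.5/97.5 percentiles per
parameter plus derived quantities computed draw-by-draw (never from
plug-in means): class survival `invlogit(beta)`, class resighting
probability, and the annual survival series `invlogit(beta + eps[t])`.
Percentiles use order statistics (`inverted_cdf`) rather than
interpolation so that intervals commute exactly with monotone transforms
such as the inverse logit.

## Synthetic data

The generator emulates the target study design: 227 birds marked as
nestlings (entering at age 0 with a certain detection at marking) over
the 34 occasions 1987–2020, cohorts uniform over all but the final year
(per-year marking counts are not published; a bird marked at the last
occasion carries no survival information), class survival 0.907 / 0.958
/ 0.924, resighting 0.88, and year effects with sigma = 0.3 on the logit
scale — a moderate value giving visible interannual wiggle; the scale is
a configuration knob, not an empirical claim. Birds never resighted
after marking are retained. Trend series are linear-plus-Gaussian-noise
with optional clipping at zero.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about field data: heterogeneous or time-varying
detection (e.g. feeding-station closures), transience or emigration
distinct from death, tag loss, uneven marking effort, and autocorrelated
breeding series. The trend test's permutation null assumes exchangeable
years, which real temporal series can violate.

## Trend tests

Productivity is chicks fledged divided by pairs, year by year (a zero
pair count is an error, reported with its year). Spearman's rho is the
Pearson correlation of midranked values — valid under ties, unlike the
`6*sum(d^2)` shortcut — and inference is by permutation: exact
enumeration of all n! permutations for n ≤ 8, otherwise seeded
Monte-Carlo with the add-one rule `(b+1)/(m+1)` (which cannot report
zero); the classic t approximation is available for comparison. Tests
are two-sided.

## Problem sizes and numerical choices

The replicate experiments use scaled designs chosen to exercise every
age class while keeping the full suite quick to run: recovery studies
use 15 occasions (so adults are observed for several intervals) with
2,000 individuals for the MLE (tolerance ±0.02) and 300 for the Bayesian
fit (±0.05; 3 chains × 15,000 iterations); interval coverage is measured
over 100 replicate studies at 2 chains × 3,000 iterations each, pooling
the three class survivals and the resighting rate (expected ≈95%,
accepted 89–99%). All randomness flows from explicit integer seeds;
identical configuration and seed reproduce byte-identical datasets and
chains.

## Known limitations

- Single study area; no spatial structure, no multi-site movement.
- No dead-recovery or known-fate data; no Jolly–Seber abundance or
  recruitment estimation; no model-selection machinery (DIC/WAIC).
- The sampler is single-threaded by design; very long chains on large
  datasets simply take proportionally longer.
- The exclusion flag on histories is carried through I/O but no
  exclusion rule is applied; callers decide.
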