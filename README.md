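# gypaetus

Age-structured capture–mark–recapture survival analysis for long-lived
raptors, built around the design of a long-term bearded vulture
(*Gypaetus barbatus*) ringing programme in the Pyrenees: birds ringed in
the nest, resighted each winter at feeding stations and territories, with
survival varying by plumage age class and by year.

The package is for population ecologists who need, from Python:

- encounter-history data handling (MARK-style `.inp` and long CSV, m-array
  reduction, validation);
- the **age-dependent Cormack–Jolly–Seber (CJS) model** with a shared year
  random effect on survival;
- fitting by **maximum likelihood** (fixed effects) and by **Bayesian
  MCMC** (adaptive Metropolis-within-Gibbs on the marginal likelihood),
  with Gelman–Rubin and effective-sample-size diagnostics;
- a **synthetic-data generator** that reproduces the study's structure, so
  every stage is testable without access to the (request-only) field data;
- **Spearman permutation trend tests** for breeding series (productivity =
  chicks fledged / pairs, and pair counts).

## The model

For individual *i* in interval *t*, apparent survival φ and resighting
probability *p* follow

    logit(φ_i,t) = β_x(i,t) + ε_t,   ε_t ~ Normal(0, σ²)
    P(detected at t | alive at t) = p_x(i,t)

where *x(i,t)* is the age class — juvenile (age < 2), subadult (2–6) or
adult (> 6) — which is deterministic because every bird's birth year is
known. The likelihood of each history, conditional on first capture,
marginalises the latent alive/dead process with a two-state forward
recursion; a brute-force enumeration over death times and a multinomial
m-array likelihood serve as independent cross-checks. Priors for the
Bayesian fit: Normal(0, 10²) on each logit-scale effect, Uniform(0, 10)
on σ.

## Worked example

```python
import gypaetus as g

cfg = g.SimulationConfig(
    design=g.StudyDesign(tuple(range(1990, 2002))),  # 12 occasions
    n_individuals=200, seed=5,
)
dataset = g.simulate_dataset(cfg)
spec = g.ModelSpec(p_structure="constant", random_year_effect=True)
mcmc = g.McmcConfig(n_iterations=6000, burn_in=2000, thin=2, n_chains=3, seed=9)
chains = g.run_mcmc(dataset, spec, mcmc)
summary = g.summarize_posterior(chains)
print(summary.table.loc[["survival_juvenile", "survival_subadult",
                         "survival_adult", "p", "sigma"]].round(3))
```

prints

```
                    mean     sd   q2.5  q97.5   rhat       ess
quantity
survival_juvenile  0.927  0.016  0.892  0.956  1.004   843.989
survival_subadult  0.946  0.012  0.920  0.968  1.007   809.061
survival_adult     0.902  0.034  0.831  0.962  1.001  1401.117
p                  0.899  0.011  0.876  0.921  1.000  2109.871
sigma              0.256  0.222  0.015  0.812  1.044   129.563
```

Each `survival_*` row is the posterior of invlogit(β) for one age class —
the mean annual survival probability, with its 95% credible interval —
and `p` is the winter resighting probability; the generating values were
0.907/0.958/0.924 and 0.88, all inside their intervals. `rhat` below 1.1
on every row (and on every sampled parameter) indicates the three chains
converged. The annual series invlogit(β + ε_year) is in the same table
under `survival_<class>_<year>`.

The `examples/` directory holds one short script per capability
(`simulate_study.py`, `fit_mle.py`, `fit_mcmc.py`, `trend_analysis.py`);
each prints the numbers it computes and what they mean. A thin CLI wraps
the same functions:

```sh
gypaetus simulate --seed 1 --out-dir run/
gypaetus fit --data run/dataset.inp --out-dir run/fit/
gypaetus trend --series run/productivity.csv
```

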