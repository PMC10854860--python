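"""Maximum-likelihood fit of the fixed-effects age-dependent CJS model.

Simulates a large study without year effects, then recovers the three
age-class survival probabilities and the resighting rate by maximising
the forward-recursion likelihood. The printed standard errors come from
a finite-difference Hessian via the delta method.
"""

import gypaetus as g

cfg = g.SimulationConfig(
    design=g.StudyDesign(tuple(range(1987, 2002))),  # 15 occasions
    n_individuals=2000,
    sigma_year=0.0,
    seed=77,
)
dataset = g.simulate_dataset(cfg)
spec = g.ModelSpec(p_structure="constant", random_year_effect=False)
result = g.fit_mle(dataset, spec)

print(result.to_frame().round(4).to_string())
print(f"log-likelihood: {result.loglik:.2f}  converged: {result.converged}")
print("truth: survival 0.907 / 0.958 / 0.924, p 0.88 — estimates should "
      "fall within a couple of SEs of these")
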