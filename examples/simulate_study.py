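"""Draw a synthetic ringing study and look at its raw structure.

The default configuration mimics a long-term bearded vulture
monitoring programme: 227 nestling-marked birds over the 34 annual
occasions 1987-2020, age-class survival 0.907/0.958/0.924, winter
resighting probability 0.88, and a shared year effect (sd 0.3 on the
logit of survival).
"""

import numpy as np

import gypaetus as g

cfg = g.default_study(seed=1)
dataset = g.simulate_dataset(cfg)

det, first, _ = dataset.to_arrays()
print(f"individuals: {dataset.n_individuals}")
print(f"occasions:   {dataset.design.n_occasions} "
      f"({dataset.design.first_year}-{dataset.design.occasion_years[-1]})")
print(f"total detections: {det.sum()}")
singletons = int((det.sum(axis=1) == 1).sum())
print(f"never resighted after marking: {singletons} birds")

ma = g.build_m_array(dataset)
print(f"m-array releases: {int(ma.releases.sum())}, "
      f"never seen again: {int(ma.never_seen_again.sum())}")

# The m-array row sums always equal the releases: that identity is the
# multinomial structure the CJS likelihood factorises over.
assert np.array_equal(ma.recaptures.sum(axis=1) + ma.never_seen_again,
                      ma.releases)
print("m-array row-sum identity holds")
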