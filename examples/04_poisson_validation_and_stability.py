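"""Validate ranked feature calls against independent reads, and score
attribution stability across model instances.

First: the motif-centre Poisson test — for each predicted feature, count
validation ChIP reads in a window around its midpoint and test enrichment
against the dataset-wide Poisson background in both replicates; report the
pass proportion as weaker features are added, next to a random-position
baseline.  Second: the feature-stability estimator on binary masks.
Runtime: a few minutes (the end-to-end recovery pipeline trains a model).
"""

import numpy as np

from diffcnn.evaluation import stability_estimator
from diffcnn.experiments import run_feature_recovery

res = run_feature_recovery(seed=7, n_regions_per_class=300, reg_epochs=40,
                           top_n=50)
print(f"{res['n_features']} ranked down-class feature calls")
print(f"top-50 calls overlapping a planted site: {res['top_overlap']:.0%} "
      f"(chance ~ {res['chance_overlap']:.0%})")
curve, base = res["pass_curve"], res["baseline_curve"]
print("\nPoisson pass proportion (both replicates P < 0.05):")
for n in (10, 50, 100, len(curve)):
    if n <= len(curve):
        print(f"  top {n:4d}: ranked {curve[n - 1]:.2f}   random {base[n - 1]:.2f}")

# stability estimator anchors on synthetic masks
identical = np.zeros((10, 500, 300))
identical[:, :, 50:75] = 1.0
rng = np.random.default_rng(0)
random = np.zeros((10, 500, 300))
starts = rng.integers(0, 276, size=(10, 500))
for m in range(10):
    for r in range(500):
        random[m, r, starts[m, r]:starts[m, r] + 25] = 1.0
print("\nstability estimator anchors:")
print(f"  identical masks: phi = {stability_estimator(identical).phi:.3f}")
print(f"  random masks:    phi = {stability_estimator(random).phi:.3f}")
print("phi near 1 = models agree on where the feature is; near 0 = the "
      "selected windows are unrelated across model instances.")
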