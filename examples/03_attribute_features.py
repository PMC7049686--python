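"""Locate planted co-factor sites by nucleotide-level attribution.

Trains a small deep classifier briefly, then attributes the down-binding
logit with all three methods (mutagenesis, integrated gradients,
gradient x input) and checks how often the strongest 25 nt window of each
region overlaps the known planted site.  A random window would overlap
about 8% of the time.  Runtime: about a minute.
"""

import numpy as np

from diffcnn.attribution import (gradient_times_input, importance_from_map,
                                 integrated_gradients, mutation_map,
                                 strongest_window)
from diffcnn.experiments import default_deep_spec, study_config, train_fixed_epochs
from diffcnn.models import HeadSpec, build_deep_cnn
from diffcnn.synthetic import generate_dataset
from diffcnn.training import SequenceDataset

dataset = generate_dataset(study_config(150, seed=7))
sd = SequenceDataset.from_synthetic(dataset)
X = sd.encode(300)
head = HeadSpec("class", "classification", tuple(sd.class_names))
graph = build_deep_cnn(default_deep_spec(), [head], rng=np.random.default_rng(1))
train_fixed_epochs(graph, "class", X, sd.y_class, epochs=25,
                   learning_rate=3e-3, batch_size=64, seed=2)

down = sd.class_names.index("down_t0")
sites = {r.identifier: r.true_sites for r in dataset.regions}
sample = [i for i in range(len(sd))
          if sd.y_class[i] == down and sites[sd.ids[i]]][:30]


def hits_site(call):
    return any(call.start < e and s < call.end
               for (s, e, _) in sites[call.region_id])


methods = {
    "mutagenesis": lambda i: importance_from_map(
        mutation_map(graph, X[i], "class", down, sd.ids[i])),
    "integrated_gradients (64 steps)": lambda i: integrated_gradients(
        graph, X[i], "class", down, steps=64, region_id=sd.ids[i]),
    "gradient_x_input": lambda i: gradient_times_input(
        graph, X[i], "class", down, sd.ids[i]),
}

print(f"strongest-window overlap with the planted co-factor site "
      f"over {len(sample)} down-class regions (chance ~ 8%):")
for name, attribute in methods.items():
    frac = np.mean([hits_site(strongest_window(attribute(i)))
                    for i in sample])
    print(f"  {name:32s} {frac:.0%}")
print("\nEvery method localizes far above chance; the single-step "
      "gradient x input trails the path-integrated methods on this "
      "non-linear model, and the direct classifier used here is the "
      "weakest setting - the serial model of example 04 does better.")

i = sample[0]
region_id = sd.ids[i]
s, e, motif = sites[region_id][0]
call = strongest_window(integrated_gradients(graph, X[i], "class", down,
                                             steps=64, region_id=region_id))
print(f"\nexample region {region_id}: planted {motif} at [{s}, {e}), "
      f"strongest IG window [{call.start}, {call.end})")
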