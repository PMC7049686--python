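"""Train the deep regression trunk, then the serial down-binding classifier.

The deep CNN regresses per-replicate log-RPKM from sequence alone.  A
serial model freezes that trunk and feeds its 8 predicted log-RPKM values
to a small dense classifier for the down-binding task - the regression
task regularizes the classifier, which sees only a few hundred labelled
examples.  Runtime: a couple of minutes on one CPU core.
"""

import numpy as np
from sklearn.model_selection import train_test_split

from diffcnn.evaluation import classification_report, regression_report
from diffcnn.experiments import default_deep_spec, study_config, train_fixed_epochs
from diffcnn.models import HeadSpec, build_deep_cnn
from diffcnn.synthetic import generate_dataset
from diffcnn.training import (SequenceDataset, TrainingConfig,
                              classification_heads, make_serial_graph,
                              train_with_early_stopping)

dataset = generate_dataset(study_config(200, seed=7))
sd = SequenceDataset.from_synthetic(dataset)
X = sd.encode(300)
idx = np.arange(len(sd))
train_idx, test_idx = train_test_split(idx, test_size=0.2,
                                       stratify=sd.y_class, random_state=0)

reg_head = HeadSpec("regression", "regression", tuple(sd.replicate_names))
trunk = build_deep_cnn(default_deep_spec(), [reg_head],
                       rng=np.random.default_rng(1))
print(f"deep trunk: {trunk.n_parameters()} parameters")
train_fixed_epochs(trunk, "regression", X[train_idx], sd.y_reg[train_idx],
                   epochs=60, learning_rate=5e-3, batch_size=128, seed=2)

pred = trunk.predict_logits(X[test_idx], "regression")
tissue_of = np.array([int(n[1]) for n in sd.replicate_names])
rep = regression_report(sd.y_reg[test_idx], pred, sd.replicate_names, tissue_of)
print("\nper-replicate test Pearson R (log RPKM):")
for name in sd.replicate_names:
    print(f"  {name:10s} R={rep.pearson[name]:.2f} Rho={rep.spearman[name]:.2f}")
print("cross-replicate upper bound (same tissue, true values):")
for k, v in rep.cross_replicate.items():
    print(f"  {k:22s} R={v:.2f}")

# serial classifier over the down-binding class set
down_head = classification_heads(sd.class_names, "2task")[0]
to_head = {c: i for i, c in enumerate(down_head.names)}
head_labels = np.array([to_head.get(sd.class_names[c], -1) for c in sd.y_class])
eligible = head_labels >= 0
tr = train_idx[eligible[train_idx]]
te = test_idx[eligible[test_idx]]
tr2, va2 = train_test_split(tr, test_size=0.25, stratify=head_labels[tr],
                            random_state=0)
serial = make_serial_graph(trunk, down_head, (32,), np.random.default_rng(3))
cfg = TrainingConfig(learning_rate=3e-3, batch_size=64, patience=8,
                     max_epochs=40, seed=0)
serial, best_epoch, _ = train_with_early_stopping(
    serial, "down", X[tr2], head_labels[tr2], X[va2], head_labels[va2], cfg)

scores = serial.predict_proba(X[te], "down")
crep = classification_report(head_labels[te], scores, list(down_head.names))
print(f"\nserial down-binding classifier (stopped at epoch {best_epoch}):")
for name in down_head.names:
    print(f"  {name:18s} PR-AUC={crep.pr_auc[name]:.2f} "
          f"recall={crep.per_class_recall[name]:.2f}")
print(f"  macro F1 = {crep.macro_f1:.2f}")
print("PR-AUC above the class prevalence means the trunk's regression "
      "features carry the differential signal.")
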