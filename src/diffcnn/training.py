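"""Dataset assembly, model selection and the regularization modes.

Model selection follows a two-stage early-stopping scheme: a fifth of the
data is held out for test, k-fold cross-validation with patience-based
early stopping is run on the rest, and the mean of the training losses at
the per-fold stoppage points becomes the stopping criterion when the
winning configuration is retrained on the entire cross-validation data
(no validation set is consulted in that final stage).

Four ways of fitting the classifier are provided:

* ``direct`` — train the classifier on the labelled regions only;
* ``transfer`` — copy and freeze the convolution of a trained shallow
  regression model, then select and train only the classifier on top;
* ``serial`` — freeze a trained deep regression model and feed its
  predicted per-replicate log-RPKM vector to a small dense classifier
  (the composite stays differentiable end-to-end, so attribution can
  flow back to the sequence);
* ``parallel`` — one shared trunk with a regression head and one or two
  classification heads, trained by cyclically alternating batches across
  heads; early stopping monitors the classification validation loss only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .genomics import one_hot_encode
from .models import (DeepModelSpec, HeadSpec, ModelGraph, ShallowCNNSpec,
                     build_deep_cnn, build_shallow_cnn,
                     compute_receptive_field, sample_input_length)

__all__ = [
    "TrainingConfig",
    "SearchSpace",
    "TrialResult",
    "SequenceDataset",
    "augment_reverse_complement",
    "split_folds",
    "train_with_early_stopping",
    "train_final_on_all",
    "random_search",
    "build_transfer_model",
    "build_serial_model",
    "train_parallel_multitask",
    "classification_heads",
]


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    patience: int = 3
    max_epochs: int = 30
    seed: int = 0
    folds: int = 3
    test_fraction: float = 0.2
    augment_target: str | None = None  # class to RC-augment (train/val only)

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class SearchSpace:
    """Per-hyper-parameter choice lists for random search; each trial draws
    one value per key (uniformly).  Architecture keys are interpreted by the
    model family, ``learning_rate`` by the optimizer."""

    choices: dict[str, list]
    n_trials: int = 5

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for key, values in self.choices.items():
            if not values:
                raise ValueError(f"empty choice list for {key!r}")

    def sample(self, rng: np.random.Generator) -> dict:
        return {k: v[rng.integers(0, len(v))] for k, v in self.choices.items()}


@dataclass
class TrialResult:
    description: dict
    fold_val_losses: list[float]
    fold_train_losses_at_stop: list[float]

    @property
    def mean_val_loss(self) -> float:
        return float(np.mean(self.fold_val_losses))

    @property
    def mean_train_loss_at_stop(self) -> float:
        return float(np.mean(self.fold_train_losses_at_stop))


@dataclass
class SequenceDataset:
    """Raw sequences with labels and regression targets; one-hot encoding is
    deferred because the input length is itself a hyper-parameter."""

    sequences: list[str]
    y_class: np.ndarray
    y_reg: np.ndarray
    ids: list[str]
    class_names: list[str]
    replicate_names: list[str]

    @classmethod
    def from_synthetic(cls, ds, pseudocount: float = 1.0) -> "SequenceDataset":
        classes = {c: i for i, c in enumerate(ds.class_names)}
        return cls(sequences=[r.sequence for r in ds.regions],
                   y_class=np.array([classes[ds.labels[r.identifier]] for r in ds.regions]),
                   y_reg=np.log(ds.rpkm.loc[[r.identifier for r in ds.regions]]
                                .to_numpy(dtype=np.float64) + pseudocount),
                   ids=[r.identifier for r in ds.regions],
                   class_names=ds.class_names,
                   replicate_names=list(ds.rpkm.columns))

    def __len__(self) -> int:
        return len(self.sequences)

    def encode(self, input_length: int) -> np.ndarray:
        return np.stack([one_hot_encode(s, input_length) for s in self.sequences])


# -- dataset handling --------------------------------------------------


def augment_reverse_complement(X: np.ndarray, y_class: np.ndarray, y_reg: np.ndarray,
                               target_class: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reverse-complement augmentation anchored on one under-represented
    class: every example of ``target_class`` is duplicated as its reverse
    complement (with A,C,G,T channel order, RC of a one-hot matrix is a flip
    of both axes); any other class whose count is below the doubled target
    count is likewise fully duplicated.  Apply to training/validation data
    only — never to the test split."""
    counts = {c: int((y_class == c).sum()) for c in np.unique(y_class)}
    if counts.get(target_class, 0) == 0:
        return X, y_class, y_reg
    m = 2 * counts[target_class]
    dup_classes = [c for c, n in counts.items() if c == target_class or n < m]
    mask = np.isin(y_class, dup_classes)
    X_rc = X[mask][:, ::-1, ::-1]
    return (np.concatenate([X, X_rc]),
            np.concatenate([y_class, y_class[mask]]),
            np.concatenate([y_reg, y_reg[mask]]))


def split_folds(y_class: np.ndarray, config: TrainingConfig,
                ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Hold out ``test_fraction`` of the data (stratified by class), then
    split the remainder into ``folds`` disjoint stratified folds.  Returns
    (test indices, list of fold index arrays); deterministic under seed."""
    idx = np.arange(len(y_class))
    cv_idx, test_idx = train_test_split(idx, test_size=config.test_fraction,
                                        stratify=y_class, random_state=config.seed)
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=config.seed)
    folds = [cv_idx[val] for _, val in skf.split(cv_idx, y_class[cv_idx])]
    return np.sort(test_idx), [np.sort(f) for f in folds]


# -- single-head training loops ----------------------------------------


def _loss_and_grad(kind: str, out: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    if kind == "classification":
        return nn.cross_entropy_grad(out, y)
    return nn.mse_grad(out, y)


def _epoch(graph: ModelGraph, head: str, X: np.ndarray, y: np.ndarray,
           opt: nn.Adam, batch_size: int, rng: np.random.Generator) -> float:
    kind = graph.head_spec(head).kind
    order = rng.permutation(len(X))
    total, n_batches = 0.0, 0
    for i in range(0, len(order), batch_size):
        b = order[i:i + batch_size]
        out = graph.forward(X[b], head, train=True)
        loss, dout = _loss_and_grad(kind, out, y[b])
        if not np.isfinite(loss):
            raise FloatingPointError("training loss diverged (non-finite)")
        opt.zero_grad()
        graph.backward(dout, head)
        opt.step()
        total += loss
        n_batches += 1
    return total / max(n_batches, 1)


def evaluate_loss(graph: ModelGraph, head: str, X: np.ndarray, y: np.ndarray,
                  batch_size: int = 256) -> float:
    kind = graph.head_spec(head).kind
    out = graph.predict_logits(X, head, batch_size)
    return _loss_and_grad(kind, out, y)[0]


def train_with_early_stopping(graph: ModelGraph, head: str,
                              X_train: np.ndarray, y_train: np.ndarray,
                              X_val: np.ndarray, y_val: np.ndarray,
                              config: TrainingConfig,
                              ) -> tuple[ModelGraph, int, float]:
    """Patience-based early stopping on the validation loss.

    Stops after ``patience`` epochs without improvement, restores the
    best-validation weights, and returns ``(graph, best_epoch, training
    loss at the best epoch)`` — the training loss feeds the second-stage
    stopping criterion.
    """
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(graph.parameters(), lr=config.learning_rate)
    best_val, best_epoch, best_train, best_state = np.inf, 0, np.inf, graph.get_state()
    bad = 0
    for epoch in range(1, config.max_epochs + 1):
        train_loss = _epoch(graph, head, X_train, y_train, opt, config.batch_size, rng)
        val_loss = evaluate_loss(graph, head, X_val, y_val)
        if val_loss < best_val:
            best_val, best_epoch, best_train = val_loss, epoch, train_loss
            best_state = graph.get_state()
            bad = 0
        else:
            bad += 1
            if bad >= config.patience:
                break
    graph.set_state(best_state)
    return graph, best_epoch, best_train


def train_final_on_all(graph: ModelGraph, head: str, X: np.ndarray, y: np.ndarray,
                       criterion: float, config: TrainingConfig) -> ModelGraph:
    """Second-stage training on the full cross-validation data: run until
    the running (per-epoch mean) training loss drops to the criterion or
    ``max_epochs`` is reached; no validation data is consulted."""
    if not np.isfinite(criterion) and criterion < 0:
        raise ValueError("criterion must be finite or +inf")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(graph.parameters(), lr=config.learning_rate)
    for _epoch_no in range(1, config.max_epochs + 1):
        train_loss = _epoch(graph, head, X, y, opt, config.batch_size, rng)
        if train_loss <= criterion:
            return graph
    warnings.warn(f"stopping criterion {criterion:.4g} not reached within "
                  f"{config.max_epochs} epochs (last loss {train_loss:.4g})",
                  stacklevel=2)
    return graph


# -- cross-validated selection over graph factories ---------------------


def _augmented(X, y_class, y_reg, head_kind, class_names, config):
    """Apply RC augmentation (if configured) and pick the head's targets."""
    if config.augment_target is not None and head_kind == "classification" \
            and config.augment_target in class_names:
        target = class_names.index(config.augment_target)
        X, y_class, y_reg = augment_reverse_complement(X, y_class, y_reg, target)
    return X, (y_class if head_kind == "classification" else y_reg)


def cv_select_and_train(factories: list[tuple[dict, "callable", int]],
                        dataset: SequenceDataset, head: HeadSpec,
                        config: TrainingConfig,
                        ) -> tuple[TrialResult, ModelGraph, np.ndarray]:
    """Evaluate candidate graph factories by mean CV validation loss, then
    retrain the winner on all CV data with the mean-stoppage-loss criterion.

    Each factory is ``(description, make(rng) -> ModelGraph, input_length)``.
    Ties break towards the earlier factory.  Returns the winning trial, the
    final trained graph and the held-out test indices (the test split is
    never augmented and never seen during selection or final training).
    """
    y_class, y_reg = dataset.y_class, dataset.y_reg
    test_idx, folds = split_folds(y_class, config)
    cv_idx = np.setdiff1d(np.arange(len(dataset)), test_idx)

    encoded: dict[int, np.ndarray] = {}

    def encode(L: int) -> np.ndarray:
        if L not in encoded:
            encoded[L] = dataset.encode(L)
        return encoded[L]

    trials: list[tuple[TrialResult, int]] = []
    best_pos, best_loss = -1, np.inf
    for i, (desc, make, input_length) in enumerate(factories):
        X = encode(input_length)
        val_losses, stop_losses = [], []
        try:
            for f, val_fold in enumerate(folds):
                train_fold = np.setdiff1d(cv_idx, val_fold)
                Xt, yt = _augmented(X[train_fold], y_class[train_fold],
                                    y_reg[train_fold], head.kind,
                                    dataset.class_names, config)
                Xv, yv = _augmented(X[val_fold], y_class[val_fold],
                                    y_reg[val_fold], head.kind,
                                    dataset.class_names, config)
                graph = make(np.random.default_rng([config.seed, i, f]))
                graph, _, stop_loss = train_with_early_stopping(
                    graph, head.name, Xt, yt, Xv, yv, config)
                val_losses.append(evaluate_loss(graph, head.name, Xv, yv))
                stop_losses.append(stop_loss)
        except FloatingPointError:
            continue
        trial = TrialResult(desc, val_losses, stop_losses)
        trials.append((trial, i))
        if trial.mean_val_loss < best_loss:
            best_pos, best_loss = len(trials) - 1, trial.mean_val_loss
    if not trials:
        raise RuntimeError("all trials diverged")

    winner, factory_i = trials[best_pos]
    _, make, input_length = factories[factory_i]
    X = encode(input_length)
    Xa, ya = _augmented(X[cv_idx], y_class[cv_idx], y_reg[cv_idx],
                        head.kind, dataset.class_names, config)
    final = make(np.random.default_rng([config.seed, factory_i, config.folds]))
    final = train_final_on_all(final, head.name, Xa, ya,
                               winner.mean_train_loss_at_stop, config)
    return winner, final, test_idx


def random_search(space: SearchSpace, dataset: SequenceDataset, head: HeadSpec,
                  config: TrainingConfig, family: str = "shallow",
                  ) -> tuple[TrialResult, ModelGraph, np.ndarray]:
    """Random hyper-parameter search over ``space`` for a single-head model.

    Input length handling follows the family rules: for the shallow CNN it
    is drawn from the ``input_length`` choices; for the deep CNN it is
    derived from the sampled architecture's receptive field, expanded by a
    uniform factor of up to two and clipped to the 200–2000 nt bounds.
    """
    rng = np.random.default_rng(config.seed)
    factories = []
    for t in range(space.n_trials):
        params = space.sample(rng)
        lr = params.pop("learning_rate", config.learning_rate)
        if family == "shallow":
            spec = ShallowCNNSpec(**params)
        elif family == "deep":
            spec = DeepModelSpec(**params, input_length=200)
            rf = compute_receptive_field(spec)
            spec = replace(spec, input_length=sample_input_length(rf, rng))
        else:
            raise ValueError(f"unknown family {family!r}")
        build = build_shallow_cnn if family == "shallow" else build_deep_cnn
        desc = {"trial": t, "spec": spec, "learning_rate": lr}

        def make(g, spec=spec, build=build):
            return build(spec, [head], rng=g)

        factories.append((desc, make, spec.input_length))
    return cv_select_and_train(factories, dataset, head, config)


# -- regularization modes ----------------------------------------------


def classification_heads(class_names: list[str], mode: str) -> list[HeadSpec]:
    """Head layout for the multitask modes: in 2-task mode one down-binding
    head over {down classes, non_differential}; in 3-task mode additionally
    an up-binding head over {up classes, non_differential} (the
    non-differential class is shared between the two)."""
    down = tuple(c for c in class_names if c.startswith("down_")) + ("non_differential",)
    up = tuple(c for c in class_names if c.startswith("up_")) + ("non_differential",)
    heads = [HeadSpec("down", "classification", down)]
    if mode == "3task":
        heads.append(HeadSpec("up", "classification", up))
    elif mode != "2task":
        raise ValueError(f"unknown multitask mode {mode!r}")
    return heads


def build_transfer_model(regression_graph: ModelGraph, dataset: SequenceDataset,
                         head: HeadSpec, config: TrainingConfig,
                         fc_size_choices: list[tuple[int, ...]] = [(16,), (32,), (32, 16)],
                         dropout_choices: list[float] = [0.0, 0.1],
                         ) -> tuple[TrialResult, ModelGraph, np.ndarray]:
    """Transfer regularization for the shallow CNN: the convolution of a
    trained regression model is copied and frozen, and model selection runs
    over the classifier that follows it.  The input length is inherited from
    the regression model."""
    if regression_graph.family != "shallow":
        raise ValueError("transfer mode expects a trained shallow CNN")
    base_spec: ShallowCNNSpec = regression_graph.spec
    conv: nn.Conv1d = regression_graph.trunk.layers[0]

    factories = []
    for fc_sizes in fc_size_choices:
        for dropout in dropout_choices:
            spec = replace(base_spec, fc_sizes=tuple(fc_sizes), dropout=dropout)

            def make(g, spec=spec):
                graph = build_shallow_cnn(spec, [head], rng=g)
                new_conv: nn.Conv1d = graph.trunk.layers[0]
                new_conv.w.data[...] = conv.w.data
                new_conv.b.data[...] = conv.b.data
                new_conv.freeze()
                return graph

            factories.append(({"fc_sizes": tuple(fc_sizes), "dropout": dropout},
                              make, spec.input_length))
    return cv_select_and_train(factories, dataset, head, config)


class _FrozenGraphLayer(nn.Layer):
    """Wraps a frozen trained graph (trunk + one head) as a single layer so
    it can serve as the feature extractor of a composite model.  Always runs
    in evaluation mode; gradients still flow through to the input."""

    def __init__(self, graph: ModelGraph, head: str):
        self.graph = graph
        self.head = head
        graph.freeze()

    def params(self):
        return self.graph.parameters()

    def forward(self, x, train=False):
        return self.graph.forward(x, self.head, train=False)

    def backward(self, dout):
        return self.graph.backward(dout, self.head)


def make_serial_graph(regression_graph: ModelGraph, head: HeadSpec,
                      hidden_sizes: tuple[int, ...],
                      rng: np.random.Generator) -> ModelGraph:
    """Compose a frozen regression trunk with a small dense classifier on
    its predicted log-RPKM vector; end-to-end differentiable."""
    n_targets = regression_graph.head_spec("regression").size
    layers: list[nn.Layer] = [_FrozenGraphLayer(regression_graph, "regression")]
    size_in = n_targets
    cls_layers: list[nn.Layer] = []
    for width in hidden_sizes:
        cls_layers += [nn.Dense(size_in, width, rng=rng), nn.ReLU()]
        size_in = width
    cls_layers.append(nn.Dense(size_in, head.size, rng=rng))
    return ModelGraph(nn.Sequential(layers), {head.name: (head, nn.Sequential(cls_layers))},
                      regression_graph.spec, family="serial")


def build_serial_model(regression_graph: ModelGraph, dataset: SequenceDataset,
                       head: HeadSpec, config: TrainingConfig,
                       hidden_choices: list[tuple[int, ...]] = [(16,), (32,), (32, 16)],
                       ) -> tuple[TrialResult, ModelGraph, np.ndarray]:
    """Serial regularization: select (over 1–2 hidden layers) and train the
    dense classifier that reads the frozen deep regression model's output."""
    if "regression" not in regression_graph.heads:
        raise ValueError("serial mode needs a graph with a 'regression' head")
    factories = []
    for hidden in hidden_choices:
        def make(g, hidden=tuple(hidden)):
            return make_serial_graph(regression_graph, head, hidden, g)
        factories.append(({"hidden": tuple(hidden)}, make,
                          regression_graph.input_length))
    return cv_select_and_train(factories, dataset, head, config)


# -- parallel multitask training ----------------------------------------


def _head_targets(head: HeadSpec, dataset: SequenceDataset,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(eligible indices, per-example class indices within the head's class
    set) for one classification head."""
    name_to_head = {c: i for i, c in enumerate(head.names)}
    labels = np.array([name_to_head.get(dataset.class_names[c], -1)
                       for c in dataset.y_class])
    idx = np.nonzero(labels >= 0)[0]
    return idx, labels


def train_parallel_multitask(spec: DeepModelSpec, dataset: SequenceDataset,
                             config: TrainingConfig, mode: str = "2task",
                             val_idx: np.ndarray | None = None,
                             train_idx: np.ndarray | None = None,
                             ) -> tuple[ModelGraph, int]:
    """Train a shared deep trunk with a regression head and one (2-task) or
    two (3-task) classification heads by alternating batches cyclically
    (regression → down → up).  The early-stopping criterion is the summed
    validation cross-entropy of the classification heads only; the auxiliary
    regression loss never triggers a stop.  Returns (graph, best epoch)."""
    cls_heads = classification_heads(dataset.class_names, mode)
    heads = [HeadSpec("regression", "regression", tuple(dataset.replicate_names))] + cls_heads
    graph = build_deep_cnn(spec, heads, rng=np.random.default_rng(config.seed))

    all_idx = np.arange(len(dataset))
    if train_idx is None or val_idx is None:
        tr, va = train_test_split(all_idx, test_size=0.2,
                                  stratify=dataset.y_class, random_state=config.seed)
        train_idx = tr if train_idx is None else train_idx
        val_idx = va if val_idx is None else val_idx

    X = dataset.encode(spec.input_length)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(graph.parameters(), lr=config.learning_rate)

    # per-task training arrays; classification heads see only the examples
    # whose label belongs to their class set, RC-augmented if configured
    task_data: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "regression": (X[train_idx], dataset.y_reg[train_idx])}
    val_tasks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for h in cls_heads:
        idx, labels = _head_targets(h, dataset)
        tr = np.intersect1d(idx, train_idx)
        Xh, yh = X[tr], labels[tr]
        if config.augment_target in h.names:
            Xh, yh, _ = augment_reverse_complement(
                Xh, yh, np.zeros((len(yh), 1)), h.names.index(config.augment_target))
        task_data[h.name] = (Xh, yh)
        va = np.intersect1d(idx, val_idx)
        val_tasks[h.name] = (X[va], labels[va])

    order = ["regression"] + [h.name for h in cls_heads]
    bs = config.batch_size

    def batches_for(task):
        Xa, ya = task_data[task]
        perm = rng.permutation(len(Xa))
        return [(Xa[p], ya[p]) for p in
                (perm[i:i + bs] for i in range(0, len(perm), bs))]

    def val_loss():
        return sum(evaluate_loss(graph, name, Xv, yv)
                   for name, (Xv, yv) in val_tasks.items())

    best_val, best_state, best_epoch, bad = np.inf, graph.get_state(), 0, 0
    n_steps_per_epoch = max(1, int(np.ceil(len(train_idx) / bs)))
    iters = {name: iter([]) for name in order}

    for epoch in range(1, config.max_epochs + 1):
        for step in range(n_steps_per_epoch * len(order)):
            task = order[step % len(order)]
            try:
                xb, yb = next(iters[task])
            except StopIteration:
                iters[task] = iter(batches_for(task))
                xb, yb = next(iters[task])
            kind = graph.head_spec(task).kind
            out = graph.forward(xb, task, train=True)
            loss, dout = _loss_and_grad(kind, out, yb)
            if not np.isfinite(loss):
                raise FloatingPointError("training loss diverged (non-finite)")
            opt.zero_grad()
            graph.backward(dout, task)
            opt.step()
        vl = val_loss()
        if vl < best_val:
            best_val, best_state, best_epoch, bad = vl, graph.get_state(), epoch, 0
        else:
            bad += 1
            if bad >= config.patience:
                break
    graph.set_state(best_state)
    return graph, best_epoch
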