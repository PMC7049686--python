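"""Predictive metrics, the motif-centre Poisson test and the cross-model
feature-stability estimator.

The Poisson test asks whether validation ChIP reads are enriched in a fixed
window (500 nt by default) centred on each predicted feature, against a
Poisson background whose rate is the dataset-wide average read density
(a MACS-style local rate is available as an option); a feature passes when
the upper-tail P value is below alpha in both validation replicates.

The stability estimator quantifies agreement of binary feature masks across
model instances trained with identical data and hyper-parameters: treating
every position of a region as a selectable feature, it equals 1 when all
models select identical masks and has expectation ~0 for independent
uniform-random selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import (average_precision_score, confusion_matrix,
                             f1_score, precision_recall_curve, recall_score)

from .attribution import DEFAULT_WINDOW, FeatureCall
from .genomics import ReadIndex

__all__ = [
    "ClassificationReport",
    "RegressionReport",
    "PoissonTestResult",
    "StabilityResult",
    "classification_report",
    "regression_report",
    "poisson_upper_tail",
    "poisson_motif_test",
    "pass_proportion_curve",
    "stability_estimator",
    "stability_experiment",
]


# -- classification / regression ---------------------------------------


@dataclass
class ClassificationReport:
    class_names: list[str]
    pr_curves: dict[str, tuple[np.ndarray, np.ndarray]]  # precision, recall
    pr_auc: dict[str, float]            # NaN for classes absent from truth
    confusion: np.ndarray
    per_class_recall: dict[str, float]
    macro_f1: float


@dataclass
class RegressionReport:
    replicate_names: list[str]
    pearson: dict[str, float]
    spearman: dict[str, float]
    cross_replicate: dict[str, float] = field(default_factory=dict)


def classification_report(y_true: np.ndarray, scores: np.ndarray,
                          class_names: list[str]) -> ClassificationReport:
    """One-vs-rest PR curves and PR-AUC per class, confusion matrix from
    the argmax prediction, per-class recall and macro-averaged F1.

    ``scores`` may be probabilities or logits — only the ranking within
    each column and the row argmax are used.
    """
    n_classes = len(class_names)
    labels = np.arange(n_classes)
    y_pred = scores.argmax(axis=1)
    curves, aucs, recalls = {}, {}, {}
    for c, name in enumerate(class_names):
        truth = (y_true == c).astype(int)
        if truth.sum() == 0:
            aucs[name] = float("nan")
            recalls[name] = float("nan")
            continue
        precision, recall, _ = precision_recall_curve(truth, scores[:, c])
        curves[name] = (precision, recall)
        aucs[name] = float(average_precision_score(truth, scores[:, c]))
        recalls[name] = float(recall_score(truth, (y_pred == c).astype(int),
                                           zero_division=0))
    return ClassificationReport(
        class_names, curves, aucs,
        confusion_matrix(y_true, y_pred, labels=labels),
        recalls,
        float(f1_score(y_true, y_pred, labels=labels, average="macro",
                       zero_division=0)))


def regression_report(y_true: np.ndarray, y_pred: np.ndarray,
                      replicate_names: list[str],
                      tissue_of_replicate: np.ndarray | None = None,
                      ) -> RegressionReport:
    """Per-replicate Pearson R and Spearman Rho; optionally the
    between-replicate same-tissue correlations of the true values, reported
    as the expected upper bound of model performance."""
    pearson, spearman = {}, {}
    for j, name in enumerate(replicate_names):
        if np.std(y_true[:, j]) == 0 or np.std(y_pred[:, j]) == 0:
            pearson[name] = spearman[name] = float("nan")
            continue
        pearson[name] = float(stats.pearsonr(y_true[:, j], y_pred[:, j]).statistic)
        spearman[name] = float(stats.spearmanr(y_true[:, j], y_pred[:, j]).statistic)
    cross = {}
    if tissue_of_replicate is not None:
        for t in np.unique(tissue_of_replicate):
            cols = np.nonzero(tissue_of_replicate == t)[0]
            for a in range(len(cols)):
                for b in range(a + 1, len(cols)):
                    key = f"{replicate_names[cols[a]]}~{replicate_names[cols[b]]}"
                    cross[key] = float(stats.pearsonr(y_true[:, cols[a]],
                                                      y_true[:, cols[b]]).statistic)
    return RegressionReport(replicate_names, pearson, spearman, cross)


# -- motif-centre Poisson test -----------------------------------------


@dataclass
class PoissonTestResult:
    feature: FeatureCall
    counts: tuple[int, int]
    lam: tuple[float, float]
    p_values: tuple[float, float]
    passed: bool


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam); defined as 1 at k = 0 (a window with
    no reads can never pass)."""
    if k <= 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def _local_lambda(reads: ReadIndex, chrom: str, centre: int, window: int,
                  global_rate: float) -> float:
    """MACS-style local rate: max of the global rate and the rates measured
    in 1 kb / 5 kb / 10 kb windows around the feature, scaled to ``window``."""
    rates = [global_rate]
    for span in (1000, 5000, 10000):
        k = reads.count(chrom, centre - span // 2, centre + span // 2)
        rates.append(k / span)
    return max(rates) * window


def poisson_motif_test(features: list[FeatureCall],
                       reads_rep1: ReadIndex, reads_rep2: ReadIndex,
                       region_lengths: dict[str, int],
                       window: int = 500, alpha: float = 0.05,
                       lambda_mode: str = "global",
                       ) -> list[PoissonTestResult]:
    """Test read enrichment around each feature midpoint in two validation
    replicates.

    Per replicate, ``k`` counts reads within the ``window`` nt interval
    centred on the feature midpoint and ``lambda`` is the expected count
    under the background rate (total reads / total region span, times the
    window; optionally the MACS-style max-of-local-rates).  A feature passes
    when the upper-tail P value is below ``alpha`` in both replicates.
    """
    if lambda_mode not in ("global", "local"):
        raise ValueError(f"unknown lambda mode {lambda_mode!r}")
    span = sum(region_lengths.values())
    results = []
    for feat in features:
        centre = (feat.start + feat.end) // 2
        lo, hi = centre - window // 2, centre + window - window // 2
        counts, lams, ps = [], [], []
        for reads in (reads_rep1, reads_rep2):
            rate = reads.total_reads / span if span else 0.0
            lam = (rate * window if lambda_mode == "global"
                   else _local_lambda(reads, feat.region_id, centre, window, rate))
            k = reads.count(feat.region_id, lo, hi)
            counts.append(k)
            lams.append(lam)
            ps.append(poisson_upper_tail(k, lam) if reads.total_reads else 1.0)
        results.append(PoissonTestResult(feat, (counts[0], counts[1]),
                                         (lams[0], lams[1]), (ps[0], ps[1]),
                                         ps[0] < alpha and ps[1] < alpha))
    return results


def pass_proportion_curve(results: list[PoissonTestResult]) -> np.ndarray:
    """For features sorted from strongest to weakest, the fraction of the
    top-n features passing the test, for n = 1..N."""
    passed = np.array([r.passed for r in results], dtype=float)
    return np.cumsum(passed) / np.arange(1, len(passed) + 1)


def random_baseline_features(features: list[FeatureCall],
                             region_lengths: dict[str, int],
                             rng: np.random.Generator,
                             window: int = DEFAULT_WINDOW) -> list[FeatureCall]:
    """Chance baseline: each feature's window is re-drawn uniformly at
    random within its region (scores and order preserved)."""
    out = []
    for feat in features:
        L = region_lengths[feat.region_id]
        start = int(rng.integers(0, L - window + 1))
        out.append(FeatureCall(feat.region_id, start, start + window,
                               feat.score, feat.class_index, feat.rank))
    return out


# -- feature-selection stability ---------------------------------------


@dataclass
class StabilityResult:
    phi: float
    per_region: np.ndarray
    n_models: int
    n_regions: int
    mask_width: int
    n_excluded: int = 0


def _phi_region(masks: np.ndarray) -> float:
    """Stability of one region's masks (models x positions binary).

    Treating each position as a feature selected by k = mask-width of the
    d positions, the score is 1 - mean_f s2_f / (kbar/d * (1 - kbar/d)),
    with s2_f the unbiased sample variance of the selection indicator of
    position f across models.  1 iff all masks are identical; expectation
    ~0 for independent uniform selections.
    """
    M, d = masks.shape
    kbar = masks.sum(axis=1).mean()
    denom = (kbar / d) * (1 - kbar / d)
    if denom == 0:
        return float("nan")
    s2 = masks.var(axis=0, ddof=1)  # per-position sample variance
    return float(1.0 - s2.mean() / denom)


def stability_estimator(masks: np.ndarray | list[np.ndarray]) -> StabilityResult:
    """Feature-stability score over regions.

    ``masks`` is (models x regions x positions) binary, or a list of
    (models x positions) arrays when regions differ in length.  Regions
    with a degenerate denominator (every position selected) are excluded
    and counted.
    """
    if isinstance(masks, np.ndarray):
        if masks.ndim != 3:
            raise ValueError("expected a (models, regions, positions) array")
        per_region_masks = [masks[:, r, :] for r in range(masks.shape[1])]
    else:
        per_region_masks = list(masks)
    if per_region_masks and per_region_masks[0].shape[0] < 2:
        raise ValueError("stability needs at least 2 models")
    widths = {int(m.sum(axis=1).max()) for m in per_region_masks}
    phis = np.array([_phi_region(m.astype(float)) for m in per_region_masks])
    ok = phis[np.isfinite(phis)]
    return StabilityResult(float(ok.mean()) if ok.size else float("nan"),
                           phis, per_region_masks[0].shape[0],
                           len(per_region_masks), max(widths) if widths else 0,
                           int(np.isnan(phis).sum()))


def masks_from_features(features_per_model: list[list[FeatureCall]],
                        region_lengths: dict[str, int],
                        region_ids: list[str],
                        window: int = DEFAULT_WINDOW) -> list[np.ndarray]:
    """Binary masks (one per region, models x positions) from each model's
    strongest-window feature calls."""
    calls = [{c.region_id: c for c in model_calls}
             for model_calls in features_per_model]
    masks = []
    for rid in region_ids:
        d = region_lengths[rid]
        m = np.zeros((len(features_per_model), d))
        for j, per_model in enumerate(calls):
            c = per_model[rid]
            m[j, c.start:c.end] = 1.0
        masks.append(m)
    return masks


def stability_experiment(train_model, attribute_model, X: np.ndarray,
                         ids: list[str], n_models: int = 10,
                         window: int = DEFAULT_WINDOW,
                         ) -> StabilityResult:
    """Train ``n_models`` instances with identical data and hyper-parameters
    but different initialization seeds, attribute the sampled regions with
    each, select one strongest window per region, and score mask agreement.

    ``train_model(seed) -> graph`` and
    ``attribute_model(graph, x, region_id) -> AttributionTrack`` keep this
    generic across model types and attribution methods (a Table-3-style grid
    is a loop over those two callables).
    """
    from .attribution import strongest_window as _sw
    features_per_model = []
    for seed in range(n_models):
        graph = train_model(seed)
        calls = [_sw(attribute_model(graph, x, rid), window)
                 for x, rid in zip(X, ids)]
        features_per_model.append(calls)
    lengths = {rid: X.shape[2] for rid in ids}
    masks = masks_from_features(features_per_model, lengths, ids, window)
    return stability_estimator(masks)
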