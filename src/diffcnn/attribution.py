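"""Nucleotide-level attribution and sliding-window feature ranking.

Three attribution methods, all evaluated on the raw pre-softmax logit of a
chosen class (never on probabilities):

* in-silico mutagenesis — a mutation map of every single-base substitution,
  summarised per nucleotide by the (negated) sum of logit changes, so a
  positive score means the reference base supports the class;
* integrated gradients — gradients averaged along a straight path from a
  reference input to the example, scaled by their difference, averaged over
  one or more references (an all-zero reference or a panel of background
  regions);
* gradient × input — the single-step, zero-reference special case of
  integrated gradients.

A sliding window (25 nt by default, matching the stability mask width)
locates the strongest feature per region; features are ranked dataset-wide
from strongest to weakest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MutationMap",
    "AttributionTrack",
    "FeatureCall",
    "mutation_map",
    "importance_from_map",
    "integrated_gradients",
    "gradient_times_input",
    "completeness_check",
    "completeness_report",
    "strongest_window",
    "rank_features",
    "ensemble_attribution",
    "attribute_dataset",
]

DEFAULT_WINDOW = 25


@dataclass
class MutationMap:
    """effects[i, b]: change of the class logit when position i is
    substituted by base b (0 at the reference base and at padded columns)."""

    effects: np.ndarray  # (L, 4)
    reference_output: float
    region_id: str = ""
    class_index: int = 0


@dataclass
class AttributionTrack:
    scores: np.ndarray  # (L,)
    region_id: str = ""
    class_index: int = 0
    method: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("attribution scores must be finite")


@dataclass
class FeatureCall:
    """A ranked, scored window locating the strongest feature of a region."""

    region_id: str
    start: int  # region-relative, half-open window [start, end)
    end: int
    score: float
    class_index: int = 0
    rank: int | None = None


def _logit(graph, x: np.ndarray, head: str, class_index: int) -> float:
    return float(graph.predict_logits(x[None], head)[0, class_index])


def mutation_map(graph, x: np.ndarray, head: str, class_index: int,
                 region_id: str = "", batch_size: int = 256) -> MutationMap:
    """Mutation map over all 3L single-base substitutions, evaluated in
    batched forward passes; all-zero (padded) columns are skipped."""
    if class_index >= graph.head_spec(head).size:
        raise ValueError(f"class index {class_index} out of range for head {head!r}")
    L = x.shape[1]
    ref_out = _logit(graph, x, head, class_index)
    variants, where = [], []
    col_sums = x.sum(axis=0)
    ref_base = x.argmax(axis=0)
    for i in range(L):
        if col_sums[i] == 0:
            continue
        for b in range(4):
            if b == ref_base[i]:
                continue
            v = x.copy()
            v[:, i] = 0.0
            v[b, i] = 1.0
            variants.append(v)
            where.append((i, b))
    effects = np.zeros((L, 4))
    if variants:
        V = np.stack(variants)
        out = graph.predict_logits(V, head, batch_size)[:, class_index]
        for (i, b), o in zip(where, out):
            effects[i, b] = o - ref_out
    return MutationMap(effects, ref_out, region_id, class_index)


def importance_from_map(mm: MutationMap, method_label: str = "mutagenesis",
                        ) -> AttributionTrack:
    """Per-nucleotide importance: minus the sum of logit changes over the
    three alternative bases, so mutations that lower the class logit give
    the reference base a positive score."""
    scores = -mm.effects.sum(axis=1)
    return AttributionTrack(scores, mm.region_id, mm.class_index, method_label)


def _zero_reference(x: np.ndarray) -> np.ndarray:
    return np.zeros_like(x)[None]


def integrated_gradients(graph, x: np.ndarray, head: str, class_index: int,
                         steps: int = 512, references: np.ndarray | None = None,
                         region_id: str = "", batch_size: int = 256,
                         ) -> AttributionTrack:
    """Integrated gradients on the pre-softmax logit.

    For each reference x', gradients are evaluated at
    ``x' + (s/steps)(x - x')`` for s = 1..steps, averaged, and multiplied by
    ``x - x'``; per-nucleotide scores sum the 4 base channels and the final
    track is the mean over references.  ``references=None`` uses a single
    all-zero reference.  Interpolation proceeds in continuous input space
    (interior points are not one-hot), which is well defined because the
    network maps real-valued inputs.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    refs = _zero_reference(x) if references is None else np.asarray(references)
    if refs.shape[1:] != x.shape:
        raise ValueError("reference shape does not match the input")
    alphas = np.arange(1, steps + 1) / steps
    tracks = np.zeros(x.shape[1])
    for ref in refs:
        diff = x - ref
        points = ref[None] + alphas[:, None, None] * diff[None]
        grads = graph.input_gradients(points, head, class_index, batch_size)
        attr = diff * grads.mean(axis=0)
        tracks += attr.sum(axis=0)
    scores = tracks / len(refs)
    return AttributionTrack(scores, region_id, class_index, "integrated_gradients",
                            {"steps": steps, "n_references": len(refs)})


def gradient_times_input(graph, x: np.ndarray, head: str, class_index: int,
                         region_id: str = "") -> AttributionTrack:
    """Channel-sum of x ⊙ ∇f(x) on the pre-softmax logit — identical to
    integrated gradients with a zero reference and a single step."""
    grad = graph.input_gradients(x[None], head, class_index)[0]
    return AttributionTrack((x * grad).sum(axis=0), region_id, class_index,
                            "gradient_x_input")


def completeness_check(graph, x: np.ndarray, head: str, class_index: int,
                       steps: int, references: np.ndarray | None = None,
                       degenerate_tol: float = 1e-9) -> float:
    """Summation-to-delta: relative deviation of the summed attribution from
    f(x) - mean_ref f(x').  Returns NaN when the denominator is degenerate
    (such regions are excluded from aggregate reports)."""
    refs = _zero_reference(x) if references is None else np.asarray(references)
    track = integrated_gradients(graph, x, head, class_index, steps, refs)
    fx = _logit(graph, x, head, class_index)
    fref = float(np.mean(graph.predict_logits(refs, head)[:, class_index]))
    delta = fx - fref
    if abs(delta) < degenerate_tol:
        return float("nan")
    return abs(track.scores.sum() - delta) / abs(delta)


def completeness_report(graph, X: np.ndarray, head: str, class_index: int,
                        references: np.ndarray | None = None,
                        step_counts: tuple[int, ...] = (16, 64, 128, 256, 512),
                        ) -> dict[int, dict[str, float]]:
    """Aggregate max/mean summation-to-delta deviation over a region sample
    for each step count; degenerate regions are counted but excluded."""
    report = {}
    for steps in step_counts:
        devs = np.array([completeness_check(graph, x, head, class_index, steps,
                                            references) for x in X])
        ok = devs[np.isfinite(devs)]
        report[steps] = {"max": float(ok.max()) if ok.size else float("nan"),
                         "mean": float(ok.mean()) if ok.size else float("nan"),
                         "n_degenerate": int(np.isnan(devs).sum())}
    return report


def strongest_window(track: AttributionTrack, window: int = DEFAULT_WINDOW,
                     ) -> FeatureCall:
    """The length-``window`` interval with the maximal score sum (stride 1);
    ties break to the leftmost start."""
    scores = track.scores
    if len(scores) < window:
        raise ValueError(f"track length {len(scores)} shorter than window {window}")
    sums = np.convolve(scores, np.ones(window), mode="valid")
    start = int(sums.argmax())  # argmax returns the first (leftmost) maximum
    return FeatureCall(track.region_id, start, start + window,
                       float(sums[start]), track.class_index)


def rank_features(tracks: list[AttributionTrack], window: int = DEFAULT_WINDOW,
                  ) -> list[FeatureCall]:
    """One strongest-window call per region, sorted from strongest to
    weakest score; ties break deterministically by region identifier."""
    calls = [strongest_window(t, window) for t in tracks]
    calls.sort(key=lambda c: (-c.score, c.region_id))
    for rank, call in enumerate(calls, start=1):
        call.rank = rank
    return calls


def _single_track(graph, x, head, class_index, method, region_id, **kwargs):
    if method == "mutagenesis":
        return importance_from_map(mutation_map(graph, x, head, class_index,
                                                region_id, **kwargs))
    if method == "integrated_gradients":
        return integrated_gradients(graph, x, head, class_index,
                                    region_id=region_id, **kwargs)
    if method == "gradient_x_input":
        return gradient_times_input(graph, x, head, class_index, region_id)
    raise ValueError(f"unknown attribution method {method!r}")


def ensemble_attribution(graphs: list, x: np.ndarray, head: str, class_index: int,
                         method: str = "mutagenesis", region_id: str = "",
                         **kwargs) -> AttributionTrack:
    """Arithmetic mean of the per-model attribution tracks (models trained
    on different folds of the data)."""
    if not graphs:
        raise ValueError("need at least one model")
    tracks = [_single_track(g, x, head, class_index, method, region_id, **kwargs)
              for g in graphs]
    mean = np.mean([t.scores for t in tracks], axis=0)
    return AttributionTrack(mean, region_id, class_index, f"ensemble_{method}",
                            {"n_models": len(graphs)})


def attribute_dataset(graphs: list, X: np.ndarray, ids: list[str], head: str,
                      class_index: int, method: str = "mutagenesis",
                      mode: str = "all_data", fold_of: np.ndarray | None = None,
                      **kwargs) -> list[AttributionTrack]:
    """Attribute every region under one of three model-usage modes:
    ``all_data`` (single model, first in the list), ``ensemble`` (mean over
    all models) or ``held_out`` (each region attributed only by the model
    that excluded it during training; ``fold_of[i]`` indexes that model)."""
    tracks = []
    for i, (x, rid) in enumerate(zip(X, ids)):
        if mode == "all_data":
            tracks.append(_single_track(graphs[0], x, head, class_index,
                                        method, rid, **kwargs))
        elif mode == "ensemble":
            tracks.append(ensemble_attribution(graphs, x, head, class_index,
                                               method, rid, **kwargs))
        elif mode == "held_out":
            if fold_of is None:
                raise ValueError("held_out mode needs fold_of")
            tracks.append(_single_track(graphs[int(fold_of[i])], x, head,
                                        class_index, method, rid, **kwargs))
        else:
            raise ValueError(f"unknown attribution mode {mode!r}")
    return tracks
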