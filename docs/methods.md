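# Methods

## The model

The package addresses a supervised regulatory-genomics problem: given DNA
regions bound by a principal TF across several tissues, per-replicate
binding intensities (RPKM) and per-region differential-binding labels,
learn models whose nucleotide-level attribution locates the *co-factor*
sites that drive the tissue-specific differences.

Two CNN families operate on one-hot encoded sequence (4×L, base order
A,C,G,T; sequences are centred, zero-padded symmetrically with the extra
base of padding on the right, or centre-cropped; ambiguous bases become
all-zero columns; L is bounded to 200–2000 nt).

**Shallow CNN.** One convolution (ReLU) over the one-hot input, then the
per-filter global max-pool concatenated with the global average-pool
(2·n_filters features), then fully connected layers into the head(s).
The average-pool alongside the max matters for perturbation-based
attribution when a motif occurs more than once in a region: with max-only
pooling, mutating one instance is masked by the other.

**Deep CNN.** `n_pool` pooling blocks — convolution → batch-norm → ReLU →
1×1 bottleneck convolution (linear or ReLU, `round(ratio·channels)` ≥ 1
output channels; omitted when the bottleneck is off) → dropout →
max-pool(stride = width = `pool_width`) — followed by `n_dil` dilated
convolution blocks whose outputs are concatenated channel-wise onto the
running representation (hyper-residual; additive residuals are not used),
ending in a linear 1×1 convolution and global average pooling per head.
The dilation rate of block *j* is `min(base · growth^j, max_dilation)`
(defaults 2, ×2, cap 4). Convolutions use "same" padding so the spatial
length before global pooling is exactly `floor(L / pool_width^n_pool)`;
pooling drops a trailing remainder shorter than its window. With the
bottlenecks on, the total convolution count is `2·n_pool + 2·n_dil + 1`
(each block's main + 1×1 conv, plus the output conv): the full-size
3-pool/7-dilation configuration counts 21.

**Receptive field.** `RF = 1 + Σᵢ (kᵢ−1)·dᵢ·Πⱼ<ᵢ sⱼ` over conv and pool
layers in order (1×1 convolutions contribute nothing); for the shallow CNN
it is simply the filter width. Deep-model input lengths are drawn
uniformly from [RF, 2·RF] and clipped to [200, 2000]; shallow input
lengths are free hyper-parameters.

Classification heads always expose pre-softmax logits separately from
probabilities; every attribution method operates on logits.

## Training and model selection

A fifth of the data is held out for test (stratified); 3-fold stratified
CV with patience-based early stopping runs on the rest. Per trial the mean
training loss at the per-fold stoppage points is recorded, and the winner
(lowest mean validation loss, ties to the earlier trial) retrains on the
full CV data until its running epoch-mean training loss reaches that
criterion — no validation data is consulted in the final stage, and a
warning is emitted if the criterion is not reached by `max_epochs`.

Losses: cross-entropy for classification, MSE on `log(RPKM + 1)` (natural
log; the pseudocount guards zeros and is configurable) for regression.
Optimizer: Adam. Reverse-complement augmentation duplicates every example
of the anchor (rarest down) class as its reverse complement — a flip of
both one-hot axes — and fully duplicates any other class whose count is
below the doubled anchor count; it applies to training and validation
folds only, never to the test split.

Regularization modes for the small classification task:

* **direct** — the deep classifier trained on labels alone (the
  over-parameterized baseline expected to overfit);
* **transfer** (shallow) — the convolution of a trained regression model
  is copied and frozen; selection runs only over the classifier on top;
  the input length is inherited;
* **serial** (deep) — the trained regression model is frozen whole and its
  N-vector of predicted log-RPKM feeds a small dense classifier (1–2
  hidden layers chosen by selection); the composite is differentiable end
  to end, so attribution reaches the sequence;
* **parallel** — one trunk with a regression head plus one (2-task) or two
  (3-task) classification heads; batches alternate cyclically
  (regression → down → up), every batch updating trunk + that head; the
  early-stopping criterion sums the classification heads' validation
  cross-entropy only, so regression deterioration never stops training.
  In 3-task mode the down head's class set is {down per tissue,
  non-differential} and the up head's {up per tissue, non-differential},
  with non-differential examples served to both.

Freezing is absolute (frozen parameters are skipped by the optimizer and
verified bit-identical in tests), and every entry point is bitwise
reproducible from its seed on one device.

The layers themselves are NumPy with hand-derived backward passes
(float32; losses accumulate in float64), validated against central finite
differences for every layer type. Batch-norm uses running statistics in
evaluation mode, which keeps the evaluated network piecewise-linear in its
input — relevant for attribution.

## Attribution

* **Mutagenesis**: effects(i,b) = logit(x with base b at i) − logit(x),
  batched over all 3L substitutions; padded columns are skipped.
  Per-nucleotide importance is −Σ_{b≠ref} effects(i,b), so a positive
  score means the reference base supports the class. The optional
  DeepBind-style map rescaling is not applied by default; raw logit deltas
  are kept.
* **Integrated gradients**: per reference x′, the gradient of the logit is
  averaged at x′ + (s/steps)(x−x′) for s = 1..steps, multiplied by
  (x−x′), channel-summed, and finally averaged over references (a single
  all-zero reference, or a panel such as non-differential regions without
  planted sites). Interpolation happens in continuous input space;
  interior points are not one-hot, which is well defined because the
  network maps real-valued inputs. Gradient×input is exactly the
  single-step zero-reference special case and is implemented so the two
  coincide to machine precision.
* **Completeness (summation-to-delta)**: |Σ attribution − (f(x) −
  mean_ref f(x′))| / |f(x) − mean_ref f(x′)|, reported per step count
  {16, 64, 128, 256, 512}. It is identically zero for affine models. A
  relative deviation is meaningless when the prediction barely differs
  from the reference, so the bundled study treats regions with
  |f(x) − f(x′)| < 1 nat as degenerate: they are screened out before the
  50-region sample is drawn, and their count is reported. On the
  benchmark model the max deviation at 512 steps is a few percent at
  most.
* **Feature calls**: the strongest length-25 window (sum of scores, stride
  1, leftmost tie-break), one per region, ranked dataset-wide descending
  with region-identifier tie-break. Ensemble attribution averages
  per-model tracks; held-out mode attributes each region only with the
  model that excluded it.

## Validation

**Motif-centre Poisson test.** Per replicate, k = reads in the window
centred on the feature midpoint; λ = (total reads / total region span) ×
window by default, or the MACS-style max of the global rate and the
1/5/10 kb local rates; P = upper-tail Poisson P(X ≥ k), defined as 1 at
k = 0; a feature passes with P < 0.05 in both replicates. The
pass-proportion curve reports the passing fraction of the top-n ranked
features for every n, next to a baseline that re-draws each feature's
position uniformly within its region (averaged over 10 draws to de-noise
the small-n prefix). Read positions are single-base anchors (midpoints by
convention, declared in metadata). The 500 nt default window matches
kilobase-scale peaks; studies on 300 nt synthetic regions use 100 nt,
keeping the window:region ratio, because a 500 nt window would cover the
entire region and make the test position-blind.

**Stability estimator.** For each region, each model's 25 nt mask is a
selection of k of the d positions; Φ_region = 1 − (mean over positions of
the unbiased sample variance of the selection indicator across models) /
(k̄/d · (1 − k̄/d)), averaged over regions. Φ = 1 iff all models select
identical masks; for independent uniform placements its expectation is
≈0 (slightly positive, ~0.005 for 25 nt masks in 300 nt regions, because
edge positions are selected less often than interior ones). Regions where
the denominator degenerates (every position selected) are excluded and
counted. The stability experiment trains n models with identical data and
hyper-parameters but different initialization seeds and scores their
strongest-window masks.

## The synthetic benchmark

The generator emulates a three-tissue differential ChIP-seq study with
replicate counts (2, 2, 4). Background sequence is i.i.d. uniform ACGT
(an optional first-order Markov background is out of scope of the default
null). Every region gets one anchor-motif instance at a uniform position;
differential-destined regions also get one co-factor instance (non-
overlapping), drawn from the PWM of the activity pattern their class
requires: pattern {t} produces up-binding in t, pattern
{all tissues}∖{t} produces down-binding in t. Default motifs are 7-mers
with consensus probability 0.98 per position (~1.8 bits/position — a
strong, well-defined core site). Sharpness matters: at 0.85–0.95 a
planted instance is statistically indistinguishable from background
near-matches in a 300 nt region (verified with an exact-PWM-score
oracle), which would make ground-truth recovery ill-posed rather than
hard.

RPKM for replicate r of tissue t is
`base_region · effect(t) · exp(N(0, σ_rep))` with `base_region =
10 · exp(N(0, 0.4))` and effect = `cofactor_effect` (default 4) where the
region's co-factor is active, else 1. Labels are re-derived from the
simulated table by a fold-change rule standing in for count-based
differential testing: the tissue with the largest |log fold| of its mean
against the other tissues' mean sets the class if that fold exceeds the
threshold (default 1.5×), else non-differential. Under default noise
(σ_rep = 0.3) about 94% of regions receive their constructed class — the
residual disagreement emulates the label noise of real differential
calls. `cofactor_effect = 1.0` is the explicit null (labels become pure
threshold false positives).

Validation reads (two replicates, 50 000 reads each by default) are 80%
signal — positions Normal(site centre, σ = 15 nt), clipped to the region
— distributed across all planted co-factor sites, plus 20% uniform
background. Each region is written as its own FASTA contig so
region-relative and genomic coordinates coincide.

What the generator does **not** emulate: GC bias and repeat structure,
fragment-length/shift artefacts, co-operative or overlapping sites,
diploid variation, and motif families with shared cores. Passing the
end-to-end tests therefore shows the machinery recovers planted signal
under honest noise, not that it meets any particular accuracy on real
ChIP-seq.

## Study problem sizes and numerical choices

The bundled studies run on one CPU core at desk scale, chosen as the
smallest sizes at which the qualitative claims are stable:

* completeness study: 2 100 regions (300/class, 300 nt), the reference
  small deep CNN (2 pool + 2 dilation blocks, channels 64/48/48/48, first
  kernel 8 to cover the motif span, ReLU bottlenecks at ratio 0.5),
  10 epochs, 50 down-class regions, 512 steps;
* feature recovery: 3 500 regions (500/class), regression trunk 40
  epochs (Adam, 5·10⁻³, batch 128), serial classifier with early
  stopping, integrated gradients at 16 steps, top-100 calls scored
  against planted sites, Poisson window 100 nt;
* regularization comparison: 1 400 regions, three training seeds; serial
  regression 50 epochs; direct and parallel with patience 6–8;
* stability comparison: 1 400 regions, 5 models per type, 200 down-class
  regions, gradient×input masks.

Ties everywhere break deterministically (leftmost window, earlier trial,
lexicographic region id). Degenerate cases are defined, not silently
dropped: zero-variance correlation columns and truth-absent PR classes
report NaN; k = 0 Poisson windows have P = 1; all-selected stability
regions and near-reference completeness regions are excluded with counts.

## Known limitations

* The NumPy framework targets clarity and exact gradients, not speed;
  full-size models (21 layers, millions of parameters, 2 kb inputs) are
  out of its intended range.
* The fold-change labeller ignores replicate dispersion, so its false
  positives are exchangeable across regions — convenient for testing,
  simpler than count-based differential calls.
* Uniform background sequence makes motif recovery easier than on real
  genomes; the reported recovery rates are upper bounds in that respect.
* Attribution stability is measured over initialization seeds only; data
  resampling (bootstrap) stability is not implemented.
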