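# Methods

## Protocol

One run simulates K clients holding disjoint labeled datasets, an
unlabeled proxy pool visible to all parties, and a class-balanced test
set. Before any communication each client (i) fits its density-ratio
selector on its private training features and calibrates the selection
threshold on its validation split, and (ii) pretrains its local
classifier on its private data. Then for each of T rounds:

1. the server draws `proxy_batch` proxy IDs without replacement
   (reshuffling when the pool is exhausted);
2. each client predicts on the drawn samples (class index in hard mode,
   softmax vector in soft mode), drops predictions whose density ratio
   is below its threshold, and uploads the rest;
3. the server averages the shared predictions per sample (one-hots are
   reconstructed server-side in hard mode), drops samples with zero
   sharers, drops samples whose ensemble ambiguity 2(1 − max p) exceeds
   τ_server, and broadcasts the survivors — as the averaged simplex
   vector in soft mode, as the one-hot of the ensemble argmax (ties to
   the lowest class index) in hard mode;
4. each client takes a local-training phase (`local_epochs` on private
   data) followed by a distillation phase (`distill_epochs` of
   cross-entropy toward the broadcast targets).

Pretraining before round 1 reflects the two-phase view of the protocol
(train locally first, then share knowledge); without it the first
round would distill the noise of untrained models. The combined
local+distillation objective is realized by the two sequential phases
per round; the epoch ratio `distill_epochs/local_epochs` plays the role
of the mixing weight between private and proxy loss terms.

Kept selection statistics per round: per-client kept counts, survivor
count, samples dropped for having no sharer, p_proxy (the percentage of
drawn IDs surviving both filters; cumulatively, the fraction of the
proxy pool ever used), per-client test accuracy, and exact byte counts.

## Density-ratio estimation (KuLSIF)

The client-side selector estimates w(x) = p_k(x)/u(x) against a uniform
reference density u on the axis-aligned bounding box of the client's
training features, widened by `reference_margin` (default 0.05) of the
per-dimension range; the box concretizes the compact support assumption
and adapts to the client's data. The reference sample size defaults to
n_u = n_k.

The estimator minimizes a regularized least-squares objective over a
Gaussian-kernel RKHS. By the stationarity condition in function space
the minimizer is

    w = Σ_{x_i∈S_k} k(x_i,·)/(n_k β) + Σ_{x_j∈S_u} γ_j k(x_j,·),
    (K_uu + n_u β I) γ = −K_uk 1/(n_k β),

a single symmetric positive-definite solve that is exact over the span
of kernel sections at S_k ∪ S_u (verified in the tests against a
black-box quadratic minimizer to 1e−6 relative). The ridge term β I
keeps the system well conditioned for any β > 0; β defaults to 1e−3,
and the consistency property (error shrinking in n) is exercised with
the schedule β ∝ n^{−0.9}, consistent with the estimator's known
convergence-rate condition. Ratios are not clipped; slightly negative
values can occur in low-density regions and are handled naturally by
the quantile threshold.

The kernel bandwidth defaults to the median heuristic — the median
pairwise distance, subsampled to 1000 points — computed on the client
sample S_k rather than S_k ∪ S_u: the bandwidth should resolve the
length scale of the density being modelled, and mixing in the (much
more dispersed) uniform reference would systematically over-smooth
narrow densities. On the 1-D Gaussian-vs-uniform benchmark this
recovers the closed-form ratio at the mode within a few percent at
n = 5000.

Threshold calibration uses the lower (inverse-CDF) empirical quantile
of the validation ratios, so the threshold is always an attained value;
selection keeps ties (ratio ≥ threshold), so τ_client = 0 shares
everything at or above the validation minimum. Default τ_client = 0.25
and τ_server = 2 follow the standard operating point; τ_server = 2
makes the server filter inert since ambiguity is bounded by
2(1 − 1/C) < 2 — the client-side filter does the work in the default
configuration, and the server filter matters when τ_server is
tightened.

Feature space: ratios are estimated on the raw input features, adequate
for low-dimensional synthetic data. `fit_kulsif` accepts arbitrary
matrices, so a fixed feature map can be applied upstream for
higher-dimensional inputs.

## Classifier

A small fully connected network (default one ReLU hidden layer of
width 32) trained by mini-batch gradient descent (lr 0.05, batch 32) on
cross-entropy, with hard or soft targets. Two deliberate choices:

- **Input standardization**, with per-model feature moments frozen at
  the first fit. Unnormalized blob coordinates (magnitudes up to ~16)
  make fixed-step gradient descent oscillate. FedAvg instead pools the
  first and second moments across clients before training, since
  parameter averaging is only meaningful when all clients share one
  input scaling (analogous to aggregating normalization statistics).
- **Zero-initialized output layer.** With ReLU hidden units this makes
  a model trained on a single class a provably constant predictor of
  that class: off-class output weights and biases only ever accumulate
  non-positive multiples of nonnegative hidden activations, so the
  trained class's logit is maximal at every input. The independent-
  training baseline under strong non-IID therefore scores exactly
  100/C % on a balanced test set, rather than approximately so through
  uncontrolled extrapolation.

## Baselines and ablations

- IndepLearn: local training only; zero bytes.
- No-selection FD: the identical loop with both filters forced open.
- FedAvg: per-round parameter averaging weighted by train-set size;
  requires a homogeneous architecture; exchanges the full parameter
  vector (4 bytes/parameter) per client per round.
- Selector ablation: the density-ratio score is replaced by the
  confidence score max p, or by the negated logit-energy score
  −(−T log Σ exp(z/T)), both quantile-calibrated on validation data the
  same way. Scores are oriented so higher = more in-distribution, and
  AUROC is computed per client against the correctness of that client's
  proxy predictions using the evaluation-only label oracle. The energy
  baseline is the standard score on the classifier's own logits; no
  separate generative model is trained.

On the synthetic benchmark the confidence and energy baselines do not
merely fail to detect OOD samples — they invert (AUROC ≈ 0): a
one-class ReLU model's logit scale grows with distance from its
training data, so max softmax saturates to 1.0 exactly on far OOD proxy
samples while staying below 1 in-distribution. This is the
over-confidence failure mode in its extreme form; on noisy
high-dimensional data the same mechanism typically lands near chance
rather than below it.

## Synthetic data

`make_blobs` draws C isotropic Gaussian classes whose centroids sit on
scaled coordinate axes at pairwise distance ≥ separation × noise_sd
(defaults: C = 10, 100 samples/class, d = 8, separation 8, unit noise).
Partitioning draws a class-balanced test set first (15% by default),
then a stratified proxy pool (15% of each class's remainder, inside the
10–20% convention), then client pools: strong non-IID gives client k
class k mod C (requires K ≥ C), weak non-IID classes {k mod C,
(k+1) mod C}, IID spreads every class round-robin. Each client reserves
20% of its data for validation (the calibration set size is otherwise a
free choice, exposed in config).

What the generator emulates: multi-class structure, severe label-skew
heterogeneity, an unlabeled in-support proxy pool, balanced evaluation.
What it does not: image-like high-dimensional geometry, label noise,
class imbalance, covariate shift between proxy and test distributions,
or underfit local models. Passing results therefore demonstrate the
mechanism — selectors routing knowledge to its owners and suppressing
ambiguity — not performance on any real imaging task; absolute
accuracies here are far above what heterogeneous image benchmarks give.

## Numerical and accounting conventions

- Problem sizes in tests: 1000-sample datasets, 10 clients, 8 rounds,
  100-sample proxy batches; a full run takes well under a second, a
  5-seed comparison a few seconds.
- Wire format: 4-byte floats and IDs; hard prediction = ID + class
  index (8 bytes), soft = ID + C floats (4 + 4C); FedAvg = 4 bytes per
  parameter per direction. `comm_bytes` reproduces the logged totals
  exactly and is the single source of the closed forms.
- Proxy samples with zero sharers in a round are dropped and counted;
  an all-filtered round skips distillation and is logged.
- Argmax ties everywhere break toward the lowest class index.
- Determinism: every stochastic component (generation, partitioning,
  reference sampling, batch shuffling, proxy draws) derives its stream
  from the run seed; repeated runs are bit-identical.

## Known limitations

- The uniform-reference box construction degrades in high dimension
  (volume concentration makes u(x) a poor contrast); use a feature map.
- Confidence/energy ablation conclusions are architecture-dependent in
  the inverted-AUROC direction discussed above.
- FedAvg here is the plain algorithm without client sampling, server
  momentum, or secure aggregation; byte accounting ignores framing
  overhead and compression.
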