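# Methods

## The model

A subject is a bag x = {x₁,…,x_S} of grayscale frames with one label in
{1..K}. The pipeline is φ → G → ψ → θ → softmax:

* **φ, frozen per-image encoder.** Features are extracted once and the
  rest of the model trains on top. This two-phase design makes training
  cheap and means the classifier never sees pixels — only S×d feature
  matrices. Registered production backbones: DenseNet-121 (d=1024),
  ResNet-50 (2048), ViT-16 (1024); they require external pretrained
  weights and a deep-learning runtime, so requesting one raises an
  explicit error rather than downloading anything. Self-contained
  encoders: `tinycnn` (two seeded random stride-2 conv layers + ReLU,
  2×2 average pooling, frozen per-feature normalisation, random
  projection to d) and `identity` (block-average + flatten, for
  exact-arithmetic tests). The frozen normalisation statistics —
  estimated once from 64 seeded speckle calibration images — play the
  role of a pretrained network's frozen batch-norm statistics: without
  them every embedding shares the channel-bias response, all pairwise
  correlations sit near 1, and a correlation-thresholded graph is
  meaningless. `tinycnn` also applies σ=1 Gaussian despeckling, as a
  B-mode display pipeline would.
* **G, correlation graph.** Frames s ≠ r are linked iff the Pearson
  correlation of their raw (un-standardised) embeddings is ≥ τ, default
  τ = 0.995. Degenerate (zero-variance) vectors: correlation is defined
  as 1 for exactly equal vectors, else 0 — deterministic and
  conservative (no edge).
* **ψ, graph encoder** (1 or 2 blocks, hidden dim default 512; tests use
  8–32):
  - *GAT block:* multi-head attention with LeakyReLU(0.2) logits
    e_ij = aᵀ[Wh_i ‖ Wh_j], softmax over the self-loop-augmented
    neighbourhood, head outputs concatenated, ELU output, identity
    residual when input and output dims match. Self-loops are added
    because isolated nodes are common at τ = 0.995 and attention needs a
    non-empty neighbourhood.
  - *GIN block:* u_i = MLP((1+ε)h_i + Σ_{j∈N(i)} h_j) with a two-layer
    ReLU MLP; ε default 0. No self-loops in the adjacency — the (1+ε)
    self term already covers the node itself.
  - *Baselines:* `mlp` applies the same 1- or 2-block row-wise MLP with
    the graph ignored; `max` skips ψ entirely and pools raw features.
* **θ, global max pooling** over nodes, converting the blocks'
  permutation equivariance into invariance of the final scores: the
  diagnosis cannot depend on scan order. This invariance is asserted in
  tests for every encoder kind under random permutations at relative
  tolerance 1e-5 (float64 throughout; observed discrepancies are at
  machine precision).
* **Head:** multinomial logit σ_k(z) ∝ exp(δ_k + β_kᵀz), computed with
  max-subtraction; argmax ties break to the smallest class index so
  reporting is deterministic.

### Training

Cross-entropy, Adam (β = 0.9/0.999), learning rate cosine-annealed per
epoch from `base_lr` to ~0; defaults epochs=100, batch_size=32,
base_lr=1e-3 (benchmarks here use 50 epochs and base_lr=1e-2, which is
comfortable at these feature scales). Feature matrices are z-scored per
dimension on the training set before entering ψ (frozen-embedding
scales are arbitrary; without this, gradients through Glorot-initialised
blocks are starved). The correlation graph is always built on the raw
features. Gradients come from a small in-repo reverse-mode autodiff on
dense numpy arrays; every op composition used by the blocks is checked
against central finite differences in the test suite. Mini-batches
iterate subject-wise (each subject has its own graph); a NaN loss aborts
with a diagnostic rather than training on.

### Balanced splitting

Classes are down-sampled (seeded, without replacement) to the rarest
class size n_min, then n_min is apportioned to train/val/test by
floor-then-largest-remainder on (0.81, 0.09, 0.10), so the three parts
always sum exactly to n_min. On the reference cohort counts
(12,321 / 2,287 / 1,629 / 535) this yields per-class (3605, 401, 445)
for the two-class task and (1753, 195, 216) for the three-class task —
training totals 7,210 and 5,259 — and a four-class test partition of
4 × 54 = 216. Any class with fewer than 3 subjects is rejected; very
small pools can still leave a partition empty (largest-remainder gives
(3, 0, 0) at n_min = 3), which triggers a warning, not silent repair.

### Metrics

accuracy; per class precision = TP/(TP+FP), recall = TP/(TP+FN),
f1 = TP/(TP + 0.5(FP+FN)) (algebraically the harmonic mean of precision
and recall); one-vs-rest ROC with trapezoidal AUC. Undefined ratios
(empty denominator) report 0 with a warning. Repeated experiments
re-split and retrain with derived seeds and report mean ± sd/√n.

## Conformal risk control

Split conformal prediction with three set constructions:

* **APS** conformity score: with labels sorted by descending score and
  r the true label's rank, E = Σ_{r'<r} σ_(r') + u·σ_label, u ~ U(0,1)
  (u fixed at 1 when randomisation is off).
* **RAPS**: E plus λ·max(0, r − k_reg); defaults λ = 0.01, k_reg = 1,
  both exposed — reasonable small-penalty values in the RAPS
  literature.
* **NPS**: uncalibrated baseline — smallest descending-score prefix
  with mass ≥ 1 − α; carries no finite-sample guarantee.

Calibration uses the conservative order statistic: q̂ = the
⌈(n+1)(1−α)⌉-th smallest calibration score, +∞ if the index exceeds n
(forcing full sets). Prediction sets include labels in descending-score
order while the label's own (penalised) cumulative score is ≤ q̂; the
score sequence is nondecreasing in rank, so the first failure stops the
scan. The top-ranked label is always included unless `allow_empty` is
set (published set-size tables have no empty-set category). One uniform
draw per subject is taken from a seeded stream, shared across ranks;
u = 1 reproduces deterministic mode exactly. Under this convention set
membership is exactly "conformity score ≤ q̂", which is what makes the
exchangeability coverage argument go through; the boundary-label
(generalized-quantile) convention found in some expositions differs for
deterministic sets and is not used.

Coverage reporting follows the set-size taxonomy used in practice:
mean set size, plus coverage overall and within the unambiguous
(singleton-set) and ambiguous (multi-label) groups; an empty group
reports NaN. When every set is a singleton, overall coverage equals
classification accuracy by construction.

A note on RAPS vs APS set sizes: the rank penalty shrinks sets only
when the true label concentrates at low ranks — i.e. when scores are
informative, as with a well-trained classifier. For deliberately
uninformative Dirichlet(1,…,1) scores the penalty inflates the
calibration quantile as much as the test scores and the ordering can
reverse slightly; the ordering test therefore uses sparse
Dirichlet(0.5) scores, the calibrated analogue of a confident
classifier.

## Synthetic data: what it emulates, and what it does not

`gen_grouped_subjects` emulates the statistical shape the pipeline
assumes, not B-mode physics:

* **Grouped acquisition** — group size uniform on (2, 12) by default
  (real per-subject frame counts vary; the true distribution of the
  reference cohort is not public, so this is a placeholder).
* **Class-graded liver texture** — multiplicative speckle
  (template × Rayleigh factor with unit mean, clipped to [0,1]).
  Liver mean brightness is 0.35 + class_effect·0.03·(k−1) plus
  N(0, 0.03) subject jitter, so `class_effect` is the between-class
  shift in units of the subject-level brightness SD; coarse-blob
  contrast (Gaussian-filtered field, centred so it never shifts the
  mean) also grows with the class. With class_effect = 3 the
  per-subject mean-intensity AUC is ≈ Φ(3/√2) ≈ 0.983 by the
  two-Gaussian closed form; the measured value is 0.987.
* **Shared speckle within a subject** — speckle is determined by the
  scatterer configuration, not re-drawn per frame, so liver shots of
  one subject share a single realization remixed with a fresh one in
  proportion `motion` (default 0.05, probe-motion decorrelation). This
  is what makes same-organ embedding correlations clear τ = 0.995
  (measured liver–liver edge density ≈ 0.97 under `tinycnn`) while
  cross-organ pairs never do (0 such edges measured).
* **Distractor frames** — with probability 0.3 per frame a
  class-independent hypoechoic texture (non-liver content in abdominal
  scans — vessels, kidney cortex, gallbladder — is predominantly darker
  than liver parenchyma, with a depth gradient). At least one liver
  frame per subject is guaranteed. Bags built purely from distractor
  frames classify at chance — they carry no label signal.

Not emulated: anatomy, attenuation/shadowing, device markers, operator
effects, the label noise of human grading, and realistic inter-grade
ambiguity (classes here differ by a clean monotone brightness shift).
Passing tests demonstrate that the machinery — graph construction,
invariant aggregation, balanced splitting, conformal calibration — is
correct under the stated assumptions; they say nothing about accuracy
on clinical data.

`gen_calibrated_scores` draws Dirichlet score vectors and then draws
the label *from* the scores, so P(y = k | σ) = σ_k exactly: samples are
i.i.d., hence exchangeable, and the conformal guarantee must hold —
this is the oracle harness for the coverage simulations.

## Benchmark conditions and problem sizes

The standard strong-separation benchmark used by the end-to-end tests:
400 two-class subjects, class_effect = 6 (Bayes ceiling ≈ 0.99),
distractor rate 0.3, 32×32 frames, groups of 2–8, `tinycnn` d = 16,
GAT-1 hidden dim 32, 50 epochs, base_lr 1e-2. Measured: held-out
accuracy 0.99; over 5 repeated balanced splits GAT-1 averages 0.984
(SE 0.006) vs 0.921 (SE 0.008) for the MAX baseline, reproducing the
graph-vs-no-graph ordering as a property. Coverage simulations use
n_cal = 500, n_test = 5000, 100 replicates (measured APS coverage
90.0% at α = 0.1). Unit tests use smaller sizes; all sizes are plain
function arguments.

## Known limitations

* The aggregate encoders are dense-numpy and subject-at-a-time; they
  are sized for groups of tens of frames and hidden dims in the
  hundreds, not for GPU-scale workloads.
* Pretrained backbones are interface-only here; plugging one in means
  supplying precomputed feature matrices (the estimators accept any
  list of S×d arrays).
* The four-class per-class split of the reference cohort cannot be
  reproduced by any single rounding rule consistent with the other two
  tasks; only its rule-independent test total (216) is asserted.
* Conformal guarantees are marginal, not class-conditional, and require
  exchangeability between calibration and test subjects.
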