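# Methods

## Problem and model

Non-small cell lung cancer (NSCLC) is staged I–IV; treatment strategy and
prognosis depend strongly on the stage. This package implements an
assisted-staging pipeline over medical-record *text*: a record's tumor-marker
panel, demographics and symptoms are rendered as a token sequence, embedded
with skip-gram word vectors, and classified by a bank of four binary
(one-vs-rest) convolutional text classifiers whose confidences are mapped to
a clinical decision value, a stage, and a treatment recommendation.

The pipeline, end to end:

1. **Tokenization** (`records.render_text`). Each marker value x with
   reference interval [0, hi] contributes one categorical token:
   `normal` (x ≤ hi), `high` (hi < x ≤ 10·hi), `very_high` (x > 10·hi).
   The ten-fold cut mirrors the clinical reading of a marker exceeding its
   critical value "more than ten times". Age band, gender, smoking
   history, family history and symptoms contribute further tokens. The
   vocabulary is finite and closed.
2. **Embedding** (`embeddings.SkipgramEmbedding`). Skip-gram maximizes
   ∑_{γ∈G(w_c)} log p(γ | w_c) over all (center, context) pairs within a
   window of d tokens each side, p a softmax over context vectors. For the
   small closed vocabularies here (≈40–60 tokens) the exact softmax
   gradient is used; vocabularies above a configurable size switch to
   negative sampling (unigram^0.75 noise, 5 negatives). A document becomes
   the matrix V₁:num = v₁ ⊕ … ⊕ v_num, zero-padded / prefix-truncated to
   `max_len` rows; out-of-vocabulary tokens map to the zero UNK vector.
3. **Classifier** (`cnn.TextCNNClassifier`). Kernels of window sizes
   {3, 4, 5} (one per size by default; a multiplicity knob exists) produce
   feature maps aᵢ = f(⟨K, V_{i:i+m−1}⟩ + b), f = ReLU (tanh selectable);
   1-max pooling gives a feature vector of length = kernel count; a fully
   connected layer with dropout and 2-way softmax yields the
   positive-class probability η. Training is minibatch SGD on
   cross-entropy with hand-written backpropagation (validated by a
   finite-difference gradient check in the test suite).
4. **One-vs-rest training** (`sampling`). Labels train in descending
   positive-count order. For every later label the transfer source is the
   label with the maximal co-occurrence count F(lᵢ, lⱼ) (ties: larger
   positive count, then IV > III > II > I; all-zero off-diagonal: largest
   positive count) and the source model's parameters initialize the target
   model. Each binary model then trains by **dynamic sampling**: inclusion
   probabilities start at M/(2·Npos) per positive and M/(2·Nneg) per
   negative; each iteration draws a block (sample j included iff a uniform
   draw ≤ P(j)), trains `inner_epochs` SGD epochs on it, scores all N
   samples in evaluation mode, multiplies positive probabilities by
   exp(1 − η) and negative ones by exp(η), renormalizes each class to sum
   M/2, and caps entries at 1.
5. **Decision logic** (`decision`). The decision-value axis partitions as
   healthy [0, 18), I [18, 58), II [58, 119), III [119, 180], IV (180, ∞).
   Model confidences map onto that axis by interpolating the winning
   stage's confidence (rescaled from [0.5, 1] to [0, 1)) across its
   interval; a best confidence below 0.5 lands in the healthy interval.
   Treatment is a rule-table lookup; efficacy of a treatment trajectory is
   judged by per-marker first/last comparison and the decision-value delta.

## Key parameters

| parameter | default | notes |
| --- | --- | --- |
| embedding dim n | 64 | 16 in tests/demos; any ≥ 1 |
| window d | 2 | context tokens each side |
| skip-gram epochs | 5 | SGD, constant lr 0.05 |
| max_len | 64 | document rows after pad/truncate |
| kernel sizes | 3, 4, 5 | one kernel per size by default |
| dropout | 0.5 | on the pooled feature vector, training only |
| CNN lr / batch | 0.05 / 32 | constant-rate SGD |
| CNN epochs | 256 | the published "epoch size 256" is ambiguous (epoch count vs batch size); read here as the epoch budget, both exposed |
| iterations E | 10 | outer dynamic-sampling rounds |
| block size M | 2·Npos | `None` → twice the label's positive count |
| inner epochs | 1 | SGD epochs per iteration (the per-round training budget is otherwise open) |
| nsclc threshold | 0.5 | best confidence below it reads as healthy |
| efficacy threshold | 40 | decision-value drop declaring treatment effective (one early-stage interval width); no published value exists |

## Numerical and design choices

* **Probability cap at 1.** The initialization yields values > 1 whenever
  Npos < M/2, and the multiplicative update can inflate further; an
  inclusion probability compared against a uniform [0,1) draw is
  operationally 1 beyond that. The cap applies after the per-class
  renormalization; its documented consequence is an expected class draw
  below M/2 while capped. Update order each iteration: multiplicative
  update → positive rescale → negative rescale → cap.
* **η for the update** is computed on all N samples of the binary task in
  evaluation mode (dropout off). An empty block draw is retried up to 10
  times, then errors.
* **Staging-interval conventions.** The published ranges leave a one-unit
  gap between I (18–57) and II (58–119) and share the endpoint 119 with
  III (119–180); the gap is closed upward and 119 is assigned to III so
  the lookup is total and monotone. The open stage-IV interval is capped
  at 400 for confidence interpolation only (configurable).
* **Confidence → decision-value interpolation is a package construction**:
  the published system prints decision values such as 233.52 without
  defining their computation from the classifier output. The
  interpolation guarantees the round trip (stage of the value = argmax
  stage, ties toward the later stage); every staging-map result depends
  only on the interval lookup and is unaffected by this choice.
* **Tie-breaks** throughout prefer the later stage (IV > III > II > I),
  matching the fact that later stages carry the larger samples.
* **RNG.** One master seed spawns independent named streams (cohort,
  embedding, per-label CNN init/dropout/shuffle, sampling), so every
  sub-component reproduces in isolation; all derived seeds stay below 2³¹.

## Synthetic cohorts: what they emulate and what they do not

Real staging cohorts are not distributable, so `records.generate_cohort`
draws seeded synthetic ones: stage priors default to a III/IV-majority
imbalance (I 5 %, II 10 %, III 35 %, IV 40 %, remainder healthy); marker
values are log-normal (non-negative, right-skewed, CV 0.35) around 40 % of
the reference upper limit when normal and around a stage-dependent
multiple of the limit (1.5/3/8/15× for stages I–IV) when elevated, with
the elevation probability of the three high-relevance markers (CYFRA21-1,
CEA, CA-125) rising from 0.60 at stage I to 0.97 at stage IV; adjacent
stages co-occur on one record with a configurable rate (ambiguous
transitions); symptom count grows with stage. FERRITIN, which appears in
the reference panels without a published range, uses a conventional
[0, 400] KU/L upper reference.

What passing tests on these cohorts do **not** show: real records carry
free narrative text, correlated marker panels, longitudinal structure and
label noise, none of which the generator models; and under the coarse
three-level tokenization the early stages (I–III severity multiples 1.5–8
all fall mostly in the `high` band) are largely indistinguishable
one-vs-rest, so per-stage discrimination on synthetic cohorts is strong
only for stage IV and for NSCLC-vs-healthy. The published per-stage
accuracy figures were measured on millions of real records and are not
reproduction targets here.

## Controlled experiments (`experiments`)

Both headline training devices are measured on planted-signature document
matrices (a fixed unit vector added to a few consecutive rows of noise),
the minimal analogue of an elevated-marker token run:

* **Imbalance recovery**: 20 positives vs 380 negatives, separable
  signature; dynamic sampling (E = 10, M = 2·Npos) vs plain training with
  the identical epoch budget, paired by seed; compared on minority recall
  (median over 10 seeds).
* **Transfer convergence**: a multi-label dataset whose stages share one
  signature direction with severity growing by stage (I weakest and rare,
  IV strongest), plus a few {I, IV} records so the co-occurrence rule
  selects IV as stage I's source. The source model trains plainly; the
  stage-I model starts either from the source parameters or from random
  initialization (same seed) and trains on the identical balanced stage-I
  set until its loss drops below 0.55 (cap 40 epochs, batch 8); compared
  on epochs-to-threshold across 10 paired seeds.

Problem sizes throughout (hundreds of records, embedding dim 8–16, ≤ a few
hundred epochs) are the package's own choice of a desk-scale regime in
which every effect is measurable in seconds.

## Known limitations

* The numeric-to-token discretization is a stand-in: the published system
  never states how continuous laboratory values become text.
* Stages are clinically mutually exclusive, yet the training algorithm
  assumes label co-occurrence; on strictly single-label data the
  co-occurrence matrix is diagonal and source selection falls back to the
  largest class — that fallback is this package's decision.
* The multiplicative update raises the inclusion probability of
  confidently-positive-scored *negatives* (hard negatives). The
  surrounding prose of the published algorithm conflates this case; the
  formula is implemented literally.
* No GPU path, no attention/batch-norm/alternative optimizers; the CNN is
  deliberately the minimal published architecture.
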