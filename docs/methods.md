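# Methods

## The prediction problem

For an individual wheat plant observed on day *t*, the question posed is
binary: will the plant reach anthesis within *n* days of *t*, for a
critical horizon *n* ∈ {8, 10, 12, 14, 16}? The package answers it by
metric comparison rather than regression: a shared-parameter (Siamese)
feature extractor embeds observations, and a trained comparative head
decides, for an ordered pair of embeddings, whether the first plant
flowers sooner than the second. Inference against a critical day *n*
compares a query embedding with an *anchor* — the mean embedding of a
small support set of plants known to be exactly *n* days from anthesis.

## Weather features

Each observation carries a weather window of `history_days` (default
90) days before imaging, the imaging day, and `forecast_days` (default
6) forecast days: a 97×6 matrix with columns (T_min, T_max, sunlight,
rainfall, PDD, CPDD). PDD = (T_max − T_min)/2 × sunlight (degree·hours)
couples the diurnal temperature range with photoperiod exposure; CPDD
is its running sum and is the quantity that paces wheat development in
the synthetic world (below).

Interpretation choices, each configurable:

* **Window span.** The imaging day sits inside the window at row index
  `history_days`, so T = 90 + 1 + 6 = 97 by default.
* **CPDD origin.** CPDD is accumulated *within the window* (row 0
  contributes its own PDD). An absolute sowing-date origin would need
  the sowing date attached to every observation; within-window
  accumulation keeps each IWC self-contained.
* **Forecast rows.** Every row after the imaging day is treated as a
  forecast: temperatures and rainfall are taken from the records as
  given, but sunlight is always estimated from the condition category
  (100/75/50/25/0 % of the monthly climatological mean for
  sunny/mostly-sunny/mostly-cloudy/cloudy/shower), because measured
  future sunlight never exists at deployment time.
* **Gaps.** Missing days inside the required range are an error, never
  silently interpolated — interpolation changes CPDD.

Windows are z-scored per column with statistics fitted on the training
split only; constant columns map to zero.

## Architecture

* **Image branch.** A backbone maps the crop to a 1000-d vector (the
  ImageNet-classifier-head convention), reduced by an affine map + ReLU
  to 512. The backbone is a plug-in: any callable image → 1000-d
  qualifies. The bundled `tiny_cnn` (three 3×3 conv blocks with 2×2
  max-pooling, global average pooling, 1000-d head; ≈90 k parameters)
  keeps training tractable on one CPU; pretrained Swin V2-B or
  ConvNeXt-B adapters can be plugged in where available, and are never
  required by the test suite.
* **Weather branch.** A single-layer GRU (hidden size 512) consumes the
  window rows oldest-first; the final hidden state is the weather
  feature.
* **Fusion.** concat(512+512) = 1024 → FC(512) → ReLU → FC(256).
* **FC head.** The two 256-d features are concatenated to 512 and
  passed through four fully connected layers with halving widths
  (512→256→128→64→classes), ReLU between; the fourth layer is the
  classifier.
* **TF head.** The two feature vectors form a 2-token sequence (model
  dim 256) through one transformer block — 4-head self-attention with
  64-d head subspaces, residual, feed-forward (inner width 4× the model
  dim), residual; no embedding layer and no positional encoding, since
  the inputs are already continuous vectors. The block output is
  flattened to 512 and reduced by 1-D max-pooling (kernel 2, stride 2)
  to 256 before the dense classifier. Pooling along the *feature* axis
  rather than across tokens is deliberate: self-attention is
  permutation-equivariant, so a token-axis pool would make the head
  exactly swap-invariant and unable to express "first flowers sooner
  than second" — the asymmetry the pair labels require. With the
  feature-axis pool the head is symmetric only when the two inputs
  coincide.
* Layer normalisation is omitted from the 2-token block; with such
  short sequences training is stable without it.

## Pair labelling and sampling

Binary: *negative* iff d₁ ≥ d₂ (ties are negative — the rule is
deliberately asymmetric at equality). Ternary: *positive* iff
d₁ − d₂ ≤ −2, *neutral* iff |d₁ − d₂| ≤ 1, *negative* iff d₁ − d₂ ≥ 2;
the +2 boundary mirrors the −2 side so the rule is swap-symmetric.

A default epoch holds 24,000 training and 6,000 validation pairs drawn
with two composition quotas: 80 % of pairs juxtapose distinct
days-to-anthesis values and 95 % use distinct plants. The quotas are
enforced *in expectation* with independent Bernoulli draws per pair
(matching the frequency phrasing of the protocol); an exact-count mode
exists. Within the chosen bucket, members are sampled uniformly by
rejection with an exhaustive fallback; the degenerate corner where a
plant-day has a single image falls back to pairing the observation with
itself. The draw is a pure function of (pool order, seed), and the same
train/validation sets (disjoint streams: seed, seed+1) are reused every
epoch.

## Training

Adam (optionally decoupled weight decay and/or AMSGrad — the two common
"adapted Adam" stabilisations; both off by default), cosine-annealed
learning rate over the full schedule, label smoothing (ε = 0.1 default)
and a parameter EMA evaluated for validation and early stopping.
Defaults: lr 1e-4 → 1e-6, batch 32, ≤50 epochs, patience 5, EMA decay
0.999. The EMA applies the standard decay warmup
min(decay, (1+t)/(10+t)): at desk-scale step counts a fixed 0.999 decay
would leave the average pinned near the random initialisation for the
whole run. Early stopping monitors validation F1 on the EMA parameters
(macro-F1 for the ternary scheme); the best epoch's raw and EMA
parameter sets are returned and the EMA set is loaded. Training is
bit-reproducible given (seed, pair sets).

## Few-shot protocol

An anchor is the element-wise mean feature of a support set whose
members are all exactly *n* days from anthesis (validated). The
comparative head receives (query, anchor) as (first, second); the
positive class means "within *n* days".

Boundary semantics: ground-truth positive is d ≤ n (`inclusive`,
default; `strict` uses d < n). Because ties compare negative, a query
*exactly at* the boundary is predicted "beyond" — an irreducible
consequence of the tie rule, surfaced as the `boundary` switch and
documented rather than hidden.

The evaluation protocol runs `cycles` = 10 repetitions per critical
day. Within a cycle the same support plants (5 in five-shot, 1 in
one-shot) are used across all critical days; each support plant
contributes up to 8 images per day (five-shot anchors thus pool ~40
photos, inside the 30–50 range). Support plants are excluded from the
query set; every remaining (plant, observation-day) group is one query,
decided by majority vote over its images (per-image mode available —
the aggregation rule is not pinned down externally, and majority voting
is the simple robust choice). Cycle *c* seeds its RNG with seed + *c*,
so cycles are independently reproducible. Anchors may come from a
different pool than the queries (`anchor_pool`), which is the anchor
transfer API: anchors built in one field are applied to another without
retraining.

## Synthetic world

The generator produces exactly the structure the method assumes, so
that signal recovery is a fair test:

* **Weather.** Southern-hemisphere seasonal sinusoids (temperature
  minimum in July, sunlight minimum at the June solstice) plus Gaussian
  noise; T_max = T_min + |N(9, 1.5²)| keeps T_max ≥ T_min by
  construction; rainfall is Bernoulli(0.3)–exponential(3 mm). Condition
  categories are derived by bucketing sunlight against the monthly
  climatology of the noise-free curve.
* **Phenology.** Plant *i* draws θ_i ~ N(θ₀ = 2600, σ_θ² = 120²)
  degree·hours (truncated positive) and flowers on the first day its
  CPDD since sowing reaches θ_i. σ_θ = 120 corresponds to roughly a
  ±4-day flowering spread within a sowing group — matching the 5–10-day
  within-field variability reported for wheat trials. θ₀ = 2600 puts
  sowing→anthesis at ≈104–129 days under the default season, inside the
  typical 4–5-month range for an Australian autumn sowing. Two sowing
  groups (27 Apr, 21 May) give the later group warmer, sunnier
  development and hence a shorter sowing-to-anthesis duration.
* **Imagery.** Each plant is observed daily while 3–18 days from
  anthesis, 6 images per day at 32×32. The renderer draws a textured
  background, a dark sheath and a golden head ellipse whose exposed
  fraction equals developmental progress
  clip((CPDD_t/θ_i − 0.8)/0.2, 0, 1), i.e. appearance reveals the
  *fraction* of the plant's own threshold reached — not the threshold
  itself. Nuisances per image: rotation ±15°, illumination gain
  0.8–1.2, Gaussian noise (σ = 0.04), 0–2 box-blur passes.
* **Why both modalities matter.** Days-to-anthesis ≈
  θ_i(1 − fraction)/rate: the image reveals the fraction, the weather
  window the accumulation rate and recent CPDD. With the default
  σ_θ the image alone is informative; the `weather_dominated` variant
  (σ_θ = 320) widens the latent-threshold spread so appearance alone
  under-determines timing, which is the configuration used for the
  weather-ablation comparison (ablation = GRU input zeroed, identical
  training otherwise).

What the generator does **not** emulate: photorealistic wheat,
occlusion and background clutter, detection errors, vernalisation and
photoperiod-gene effects, weather-station displacement, or label noise
in recorded anthesis dates. Passing the synthetic benchmark therefore
demonstrates that the pipeline recovers the signal structure it assumes
— not field-ready accuracy.

## Problem sizes

The shipped benchmark trains on 2,000 + 400 pairs for ≤10 epochs
(batch 128, lr 1e-3 → 1e-5) on the 120-plant world — enough for
held-out pair F1 to plateau around 0.94 — and evaluates ten-cycle
one-/five-shot inference over critical days {8, 10, 12, 14, 16}. The
weather-ablation comparison uses a 60-plant world with 1,500 + 300
pairs and 6 epochs. The acceptance script measures the sampler quotas
over five independent full epochs (5 × 24,000 pairs).

## Numerical choices and degenerate inputs

* All network arithmetic is float32 on a bundled numpy reverse-mode
  autodiff engine; runs are deterministic (no op consults global random
  state) and inference is bit-stable.
* Softmax/log-softmax use max-shifting; the shift is treated as a
  constant in differentiation.
* Max reductions route gradients to the first maximum on ties.
* z-scoring maps zero-variance columns to zero instead of dividing.
* F1 of an all-zero confusion table is defined as 0 with a warning.
* Per-second frame selection breaks sharpness ties toward the earliest
  frame; the Laplacian is the 4-neighbour kernel on Rec. 601 luminance,
  valid-region only.
* Crop filtering removes images *strictly smaller than* 20×50; equality
  survives.

## Known limitations

* The tiny backbone saturates well below what a pretrained Swin V2 /
  ConvNeXt could achieve on real imagery; the plug-in contract exists
  precisely so those can be swapped in.
* Ternary (±1-day) inference shares the binary anchors' machinery but
  is intrinsically harder; the protocol's F1 reporting targets the
  binary question.
* Exact-boundary queries (d = n) are structurally predicted "beyond"
  under the tie rule (see Boundary semantics).
* Winter wheat (vernalisation-driven) is outside the model of both the
  comparator and the generator.
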