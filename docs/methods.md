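# Methods

This note records what the package computes and why the defaults are what
they are. Everything here is implemented and tested in `attnkit`; file
references are to `src/attnkit/`.

## 1. The GCLI module family

All modules operate channels-last on maps `x ∈ R^(H×W×C)` (or batched
`N×H×W×C`) and preserve shape.

### Global context pathway

Per-position logits are a learned linear functional of the channel vector,

    z(i, j) = w_k · x(i, j, ·) + b,        w_k ∈ R^C, b ∈ R,

and the context weights are their spatial softmax (max-subtracted for
stability),

    α(i, j) = exp z(i, j) / Σ_{u,v} exp z(u, v),

so Σ α = 1 exactly up to rounding. The context-weighted map is
`m(i, j, ·) = α(i, j) · x(i, j, ·)`; its spatial **sum** is the familiar
attention-pooled context vector, and its spatial **max** (the default,
`pooling_gc="max"`) keeps the strongest weighted response per channel,
which preserves peak evidence rather than averaging it away. A plain
global average of `x` (`pooling_plain="avg"`) provides the complementary
uniform view. Both pooling choices are configurable, which is how the
ablation variant with average/average pooling is built
(`make_variant("GCLI-avg-avg", C)`).

### Feature selection and local interaction

The two descriptors are stacked into a 2×C array and a single 2×7 kernel
(zero padding 3, no bias) slides along the channel axis; SiLU follows.
This lets the module *select*, per channel neighborhood, how to combine
the context and plain views. A second 1-D convolution of width 3 (zero
padding 1, no bias) then models each channel's dependency on its nearest
neighbors without any dimensionality reduction. A sigmoid turns the
result into gates `g ∈ (0, 1)^C`, applied multiplicatively per channel.

Parameter count per module: `(C + 1) + 2·7 + 3 = C + 18`.

### Partial attention (GCLI-B)

With fraction `f`, the first `⌊f·C⌋` channels pass through a GCLI-A sized
to that width; the remaining channels are copied bit-identically
(verified by exact equality in the tests) and concatenated in original
order. Rationale: gating every channel costs parameters and can re-weight
redundantly; routing a fraction keeps the global-context pathway while
leaving most of the representation untouched. Supported fractions are any
value in (0, 1]; the named variants use 1/2 (default) and 1/4.

The reference comparison table (`table6_report`) prints the GCLI-B row at
fraction 1/4 (146 parameters at C = 512, i.e. interacted width 128); the
fraction-1/2 reading (274) is available through `count_params` with an
explicit fraction. `count_params` always cross-checks its closed form
against an enumeration of the instantiated module's trainable values and
raises if they disagree.

## 2. Baselines

Four standard channel-attention baselines are implemented for the
parameter accounting and the harness, with bias conventions chosen so
that the closed-form counts reproduce the reference table exactly:

- **ECA**: global average pool, width-k (default 3) bias-free 1-D
  convolution across channels, sigmoid. 3 parameters.
- **GC block**: softmax context pooling (as above, `C + 1` parameters),
  then a bottleneck transform `C → C/r → C` (r = 16 default) with
  LayerNorm (ε = 1e-5) and ReLU between, fused **additively** (`x + z`).
  With all transform weights zero it is exactly the identity. 33,889
  parameters at C = 512.
- **CBAM**: channel gate from a shared bias-free MLP (`C → C/r → C`) on
  average- and max-pooled descriptors, then a spatial gate from a
  bias-free 7×7 convolution on the stacked spatial mean/max maps.
  32,866 parameters at C = 512 (r = 16).
- **Coordinate attention (CA)**: directional average pooling along H and
  W, shared reduction to width `m = max(8, C/32)` with per-sample
  normalization and SiLU, two sigmoid expansion gates. 25,648 parameters
  at C = 512.
- **ECA+GC**: the softmax context pooling followed by ECA's width-3
  convolution — the single-branch ablation between GC and GCLI.

## 3. Integration and tracing

Hosts are modeled as ordered stages with declared channel widths. An
`InsertionPlan` instantiates one module per position, sized to the width
there; `attach_to_stages` and `attach_to_neck` build the two placements.
The reference host (`StagedCNN`) is a small staged CNN: per stage a
same-padded 3×3 convolution, ReLU, 2×2 average pooling; global average
pooling and a linear head. `forward_with_trace` records every module's
spatial context map α and channel-gate vector; `export_attention_maps`
writes them as min-max normalized grayscale PNGs (a constant map renders
mid-gray) plus a CSV of gate values.

## 4. Synthetic noisy-label benchmark

The generator (`attnkit.data`) emulates the operative property of
noisy-label medical collections: classes that look alike, with label
errors between the lookalikes. Classes are grouped in pairs. Each class
has an oriented-grating texture (random phase roll, amplitude 0.7–1.0,
pixel noise σ = 0.08 per sample); each pair shares a pattern (Gaussian
blob + diagonal grating) mixed in with weight `similarity ∈ [0, 1)`.
Labels are then flipped *within* each pair: exactly
`round(noise_rate · n_per_class)` flips per pair member, `noise_rate ∈
[0, 0.5)`. Images are quantized to uint8 before the final float
conversion, so a fixed seed yields byte-identical datasets.

Defaults (4 classes, 60 per class, 32×32) are sized so that a full
training run takes a few seconds on one CPU. Realism limits: the images
are textures, not tissue; the noise process is exactly pairwise-symmetric
rather than annotator-specific; no class imbalance. The generator is a
property harness — it creates the regime (lookalike pairs + asymmetric
flips) in which attention placement matters, nothing more.

## 5. Training harness and metrics

`smoke_train` trains the reference host — plain, or with a module attached
after every stage — on the noisy set and evaluates on a clean held-out set
drawn from the same class patterns (noise rate 0, disjoint seed stream).
Recipe, identical for every arm: Adam (β = 0.9/0.999, bias-corrected),
learning rate 0.02, batch size 16, 15 epochs, cross-entropy via
log-sum-exp, per-image standardization, He-scaled convolution weights with
zero biases. The He/standardization/Adam combination was chosen because
uniform fan-in initialization on low-contrast inputs stalls on a long
plateau at chance level; the fix is applied to both comparison arms. Runs
are fully determined by the seed (identical loss histories and metrics on
repeat).

Metrics are computed from one-vs-rest contingency counts: macro accuracy,
precision, recall and F1 (unweighted class means; a class with a zero
denominator scores 0), plus confusion matrices with rows = true classes.
The implementation is verified against hand-worked tables and against
scikit-learn on random vectors to 1e-10.

## 6. Numerical choices

- float64 throughout; no framework dependency. Forward/backward run on a
  minimal reverse-mode tape (`attnkit.autodiff`) whose gradients are
  tested against central differences for every operation, including the
  im2col 2-D convolution and tie-splitting max reductions.
- Softmax and log-sum-exp are max-subtracted.
- All randomness flows through `numpy.random.Generator` objects seeded
  explicitly; derived seeds stay below 2³¹.

## 7. Limitations

- Desk scale only: the smoke benchmark establishes determinism and
  non-degradation of partial attention versus the plain host over five
  seeds; per-seed spread is a few accuracy points in either direction, and
  no claim is made about full-scale datasets or detection tasks.
- The CPU tape is slow by framework standards (seconds per run at the
  default sizes); `time_inference` measures wall-clock cost per item but
  is not a performance benchmark.
- The hosts are abstractions (staged widths), not reproductions of any
  published backbone or detector.
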