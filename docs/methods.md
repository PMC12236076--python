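# Methods

This note records the model as implemented, the parameters that matter, the
numerical conventions, and the choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Architecture

The detector follows the RT-DETR pattern: a convolutional backbone emits a
stride-8/16/32 pyramid; a hybrid encoder refines the deepest level with one
transformer block (AIFI) and fuses scales with a CNN top-down/bottom-up path
(CCFF); a transformer decoder selects 300 queries from the flattened encoder
memory and refines class scores and boxes over 3 layers, with no NMS at any
stage.

**Baseline backbone.** ResNet18-scale with the deep three-conv stem
(32-32-64, stride 2 then max-pool) and vd-style downsampling shortcuts
(average-pool + 1×1), stages of two basic blocks at widths 64/128/256/512.
ReLU activations, batch norm after every convolution, conv biases disabled
under a norm (they are redundant and would distort the closed-form
parameter accounting).

**PGRBlock / PGRNet.** PGRBlock preserves shape: 3×3 over all `C` channels,
5×5 over the *first* `C/2` channels of that result, 7×7 over the *first*
`C/4` of the 5×5 result; the untouched remainders pass through unchanged
(the partial-convolution "first continuous channels" rule, fixed here to
the leading slice for determinism); concatenate to `C` and add the block
input. `C` must be divisible by 4. Each conv carries BatchNorm + SiLU
(configurable); with norms disabled and weights zeroed the block is exactly
the identity. PGRNet arranges five stride-2 3×3 convolutions and four
PGRBlocks as

    conv(3→w0,/2) conv(w0→w1,/2) PGR(w1) | conv(w1→w1,/2) PGR(w1) conv(w1→w2,/2) | PGR(w2) conv(w2→w3,/2) PGR(w3)

with the pyramid tapped at the stride-8/16/32 PGRBlock outputs. Since all
five convolutions are the only downsampling layers, 2⁵ = 32 is reached with
no extra pooling; the five-conv/four-block budget admits no other stride
placement.

**AIFI and HiLo.** AIFI = flatten p5 → add 2-D sine/cosine positions →
attention → FFN (GELU, hidden 1024), post-norm residuals. The baseline
attention is 8-head MHSA in which queries/keys carry the positional term and
values do not. The HiLo variant feeds `x + pos` into both branches. Defaults
`a = 0.5` (half the heads to each branch) and window `s = 2` (suits the
20×20 grid at 640 input); both exposed in config. Each branch projects only
its own head subset and has its own output projection; the concatenation of
the two branch outputs is the block output, which is what keeps the swap
parameter-neutral — a shared full-width output projection would break that
property. Grids not divisible by `s` are reflect-padded and cropped back.

**MaSA / RetBlock / RetC3.** The decay mask is `M[n,m] = γ^|n−m|` per head,
γ log-spaced over [0.6, 0.98] across heads (stronger decay on early heads).
Decomposition: attention down columns with the H×H mask, then along rows
with the W×W mask, the second pass consuming the first's output. The mask
multiplies the softmax scores and rows are renormalized — this keeps every
row a convex combination and is numerically stable; the alternative
published convention (additive pre-softmax decay) is not used. RetBlock =
depthwise-3×3 positional term + pre-norm MaSA + pre-norm SiLU FFN, all
residual, so a fully zeroed block is exactly the identity. RetC3 wires
`cv1 → 3 RetBlocks` and `cv2` in parallel from the block input,
concatenates, and projects with `cv3`; depth 3 mirrors the RepC3 stack it
replaces. RepC3 itself is the reference design: two 1×1 projections at
expansion 0.5, three RepConv(3×3 ∥ 1×1) units, 1×1 out; it is profiled on
the training graph (branches unfused).

**Decoder.** Memory = concatenated projected pyramid. A linear head scores
every position; the 300 highest-peak-score positions become queries
(uncertainty-minimal selection), with reference boxes predicted from grid
anchors (`0.05·2^level` base size, border anchors masked) and detached.
Each of 3 layers: masked self-attention, multi-scale deformable
cross-attention (8 heads × 3 levels × 4 points, offsets scaled by the
reference box, bilinear sampling, zero padding outside the map), FFN;
post-norm. Boxes refine in inverse-sigmoid space and are re-detached
between layers. One efficiency deviation from the reference decoder: the
three-layer auxiliary box MLP runs only on the selected top-K positions
rather than on all memory positions — selection needs class scores only, so
the outputs are unchanged and ~2 G FLOPs are saved at 640².

**Denoising groups (training only).** Each ground truth contributes one
noised copy per group (default 4 groups; center jitter and scale jitter of
±40%, label flipped to a random class with probability 0.3), with content
embeddings from a class table. The attention mask blocks matching queries
from seeing denoising queries and denoising groups from seeing each other;
their assignment to the source ground truth is fixed, which stabilizes and
accelerates small-scale convergence.

## Losses and matching

Matching is exact Hungarian assignment with the standard cost
`2·(−score) + 5·L1 + 2·(1−GIoU)`; the *training* loss swaps only the
IoU-family term, per variant, between GIoU and Focaler-WIoUv3 — matching
always uses GIoU. Classification is sigmoid focal loss (α = 0.25, γ = 2),
normalized by the ground-truth count; box terms keep the 5 (L1, on
normalized center form) and 2 (IoU-family) weights. Auxiliary losses apply
to every decoder layer and to the encoder's selected queries.

Focaler-WIoUv3 internals: `R_WIoU`'s enclosing-box denominator and the
outlier degree β use detached values; the running mean of `L_IoU` is a
per-update EMA with momentum 0.01, and β falls back to 1 before the first
update (v3 starts as v1). Defaults `d = 0, u = 0.95` (the Focaler
general-detection setting) and `α = 1.9, δ = 3` (the WIoU reference
setting); none of these are printed by the source experiment, all are
config-exposed. The composite is computed as
`L_WIoUv3 + (IoU − IoU_focaler)` so that at `(d, u) = (0, 1)` the correction
cancels bitwise.

Degenerate geometry: zero-area or zero-union pairs give IoU 0 by
convention, a zero enclosing box gives `R_WIoU = 1`, and every loss is
finite for arbitrary valid boxes (property-tested over random degenerate
sweeps).

## Complexity accounting

`Params` is the exact trainable-weight count (the per-layer closed form
`K_w·K_h·C_in·C_out/groups` plus linear/norm terms; tests check the symbolic
sum against the array count). `FLOPs` are gathered during a real forward
pass at the stated input size: every convolution, linear and attention
matmul contributes its multiply–accumulate count ×2; normalisation,
activations and softmax contribute nothing. This MAC×2, parameterized-ops
convention is the one under which the reference profiles of this model
family (and the YOLO-series figures they are compared against) are
reported. `Size = Params × B / 1024²` with `B = 2` bytes/weight
(half-precision serialization — the only value consistent with the
reference size column).

## Calibration of free widths

The source experiment fixes the four modifications but not every width.
Free knobs were calibrated **once** against the printed complexity table
and frozen as defaults; they are design constants of this package, not
fitting parameters:

* PGRNet widths `(w0, w1, w2, w3) = (32, 48, 120, 264)`;
* RetC3 RetBlock width per fusion site `(112, 64, 84, 96)` (fpn-p4, fpn-p3,
  pan-p4, pan-p5) — the stride-8 site gets the narrowest block because it
  dominates FLOPs, the low-resolution sites carry more width because their
  parameters are cheap; heads 4, FFN ratio 2;
* everything else is the standard r18-scale setting: hidden width 256,
  8 heads, FFN 1024, 3 decoder layers, 300 queries.

With these defaults the package's own profiler reports (640×640): baseline
57.7 G / 19.89 M, backbone-swap 29.9 G / 10.57 M, fusion-swap 51.1 G /
18.62 M, full model 23.0 G / 9.27 M — the numbers
`scripts/acceptance.py` recomputes.

The printed table's row for the PGRNet+HiLo combination (30.6 G / 10.74 M)
is inconsistent with its own single-swap rows (composing them gives
29.9 − 0.2 G and 10.58 − 0.03 M); this package's builds compose exactly, so
that variant profiles to the composed value and the final model still sits
between it and the baseline.

## Synthetic scenes

The generator emulates the statistical shape of near-ground weed
photography, not its appearance: a soil background (low-frequency blotches
+ grain), five plant classes rendered as rosettes of elliptical lobes with
class-specific lobe count, elongation and hue (chosen so a trivial
colour/shape classifier separates them — property-tested), three layout
presets (single, multi, occlusion with a guaranteed overlapping pair),
global illumination jitter, and tight boxes from the rendered masks. Output
is bit-deterministic per (spec, seed). What passing tests on these scenes
show is that the architecture, objective and training loop can jointly fit
a five-class detection task end to end; they say nothing about real-field
robustness (leaf texture, motion blur, soil clutter, growth stages are all
absent).

Augmentation (training split only, after the 7:1:2 split): random crop
(resized back, boxes dropped below 30% visible area), rotation (exact 90°
multiples or ±25° with axis-aligned-hull boxes), Gaussian blur. The 7:1:2
split takes `⌊0.7N⌋ / ⌊0.1N⌋ / remainder`; stratified mode is available
since the source dataset's per-class fractions suggest the ratio held only
in aggregate.

## Problem sizes used by the checks

Complexity checks run the real builds at the full 640×640 input. The
training smoke check runs the full final-variant topology at reduced width
(`ModelConfig.tiny()`: hidden 64, 30 queries, 2 decoder layers) on twenty
160×160 scenes for 100 epochs with Adam (lr 3·10⁻⁴, batch 4, gradient-norm
clip 10) — a deliberate choice of scale for a pure-numpy training loop; the
reference training schedule (300 epochs, batch 8, lr 10⁻⁴) is not a claim
this package tests.

## Known limitations

* Forward/backward run on numpy; throughput is CPU-bound and far from the
  framework implementations this architecture family normally uses. The
  package's claims are architectural and numerical, not speed claims.
* Accuracy metrics of the source experiment (P/R/mAP on real field data)
  are out of reach by construction — the dataset is not public — and are
  not asserted anywhere.
* The profiler refuses nothing: layers outside the counted set simply add
  zero FLOPs. All layers used by the provided models are covered.
* BatchNorm in the tiny training harness uses batch statistics with small
  batches (4); this is adequate for the overfit check but would need
  batch-size-aware tuning for real training.
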