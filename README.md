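# phrfdet

A lightweight real-time detection-transformer toolkit for weed detection in
upland rice, built entirely on numpy.

Weed pressure is a major yield constraint for upland (dryland) rice, and
intelligent weeding robots need detectors that are both accurate and small
enough for edge hardware. `phrfdet` implements **PHRF-RTDETR**, a lightweight
derivative of RT-DETR (ResNet18 scale) that keeps the NMS-free
encoder–decoder design while cutting FLOPs, parameters and serialized size
roughly in half through four independent modifications:

1. **PGRNet backbone** — replaces the ResNet18-style feature extractor with
   five stride-2 3×3 convolutions and four **PGRBlocks**: residual
   channel-split units in which a 3×3 convolution sees all `C` channels, a
   5×5 convolution refines only the first `C/2` channels of that result, and
   a 7×7 convolution refines the first `C/4` of the 5×5 result (the
   partial-convolution principle); untouched slices pass through and the
   concatenation is added back to the input.
2. **AIFI-HiLo** — swaps the multi-head attention of the intra-scale encoder
   block (AIFI, applied to the stride-32 level) for **HiLo** attention:
   `(1−a)·N_h` heads run non-overlapping `s×s` window attention
   (high-frequency detail), `⌊a·N_h⌋` heads attend full-resolution queries
   against `s×s` average-pooled keys/values (global low-frequency context).
   The swap never increases the parameter count.
3. **RetC3** — replaces each RepC3 fusion block of the cross-scale fusion
   path (CCFF) with a C3-style block carrying **RetBlocks**: decomposed
   row/column attention whose softmax scores are damped by the spatial-decay
   mask `M[n,m] = γ^|n−m|` and renormalized (MaSA), plus a depthwise
   positional term and an FFN. Score cost is linear rather than quadratic in
   the token count.
4. **Focaler-WIoUv3 loss** — replaces the GIoU term of the box objective
   with

   ```
   L = L_WIoUv3 + IoU − IoU_focaler
   L_WIoUv3  = r · R_WIoU · (1 − IoU),  r = β / (δ·α^(β−δ)),  β = L_IoU / mean(L_IoU)
   R_WIoU    = exp(((cx−cx')² + (cy−cy')²) / (W_g² + H_g²))
   IoU_focaler = clip((IoU − d) / (u − d), 0, 1)
   ```

   where `(W_g, H_g)` are the enclosing-box dimensions (gradient-detached),
   the running mean of `L_IoU` is an exponential moving average, and
   `(d, u)` select the IoU band to emphasize.

The package also provides exact complexity accounting (`Params`,
`FLOPs = 2 × MACs` at a stated input size, `Size = Params·B/1024²`),
detection metrics (P/R/AP/mAP/F1, confusion matrix), YOLO-txt ↔ VOC-XML
annotation round-tripping, the 7:1:2 split-before-augmentation protocol with
crop/rotate/blur augmentations, and a seeded procedural generator of
five-class weed scenes (single-target / multi-target / occlusion layouts) so
everything is testable without field data. All tensor work — including the
reverse-mode autodiff used by the training harness — runs on a
self-contained numpy core (`phrfdet.nn`).

## Worked example

Profile the full lightweight model at the canonical 640×640 input:

```bash
$ phrfdet profile --variant final
{
  "variant": "final",
  "params": 9268904,
  "params_M": 9.2689,
  "flops": 23007376000,
  "GFLOPs": 23.0074,
  "size_MB": 17.679,
  "input_hw": [640, 640],
  "bytes_per_param": 2
}
```

The full model runs at ≈23 GFLOPs with ≈9.27 M trainable weights (≈17.7 MB
at half precision) — roughly 60% / 53% below the unmodified baseline
(`--variant basic`: 57.7 G, 19.89 M). Variants `m1_pgrnet` … `m6` toggle the
four modifications individually and in combination.

The loss ladder on a concrete box pair (prediction `(0,0,2,2)` vs ground
truth `(1,1,3,3)`; areas 4 each, intersection 1):

```python
>>> from phrfdet import iou, giou_loss, focaler_wiou_v3_loss, WIoUState
>>> p, g = [0, 0, 2, 2], [1, 1, 3, 3]
>>> iou(p, g)            # intersection 1 / union 7
0.142857
>>> giou_loss(p, g)      # 1 - (1/7 - 2/9): enclosing box 3x3 penalty
1.079365
>>> focaler_wiou_v3_loss(p, g, WIoUState())   # warm-up: r = 1.9²/3
1.145122
```

Generate scenes, train a width-reduced model and evaluate it on its own
training set (an overfit sanity check, ~3 min on one CPU):

```bash
$ phrfdet train --variant final --n-scenes 20 --epochs 100
...
{ "final_loss": 4.02, "mAP50": 0.997, "precision": 0.983, "recall": 1.0, ... }
```

## Layout

| module | contents |
|---|---|
| `phrfdet.nn` | numpy tensor autodiff, layers, Adam |
| `phrfdet.backbone` | PGRBlock, PGRNet, ResNet18-scale baseline, grouped conv |
| `phrfdet.hilo` | HiLo attention, AIFI block, 2-D sin/cos positions |
| `phrfdet.retention` | decay mask, MaSA, RetBlock, RetC3, RepC3 |
| `phrfdet.encoder` / `.decoder` | hybrid encoder (AIFI+CCFF); deformable-attention decoder with query selection and denoising groups |
| `phrfdet.losses` | IoU / GIoU / WIoU v1·v3 / Focaler composite, box objective |
| `phrfdet.metrics` | P, R, AP (101-point or continuous), mAP, F1, confusion matrix |
| `phrfdet.model` / `.profiling` | variant factory, prediction, complexity reports |
| `phrfdet.data` | annotations, splits, augmentations, scene generator |
| `phrfdet.train` | Hungarian matching, detection objective, smoke training |
| `phrfdet.cli` | `phrfdet build/profile/synth/convert/split/train/eval` |

See `docs/methods.md` for the modelling choices, calibration procedure and
known limitations.
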