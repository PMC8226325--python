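# wheatear

Occlusion-aware data augmentation and counting evaluation for wheat-ear
detection.

Counting grain-bearing spikes ("ears") in field images is a standard proxy
for wheat yield, and the hardest part of the task is occlusion: ears hide
behind other ears, leaves and stems, and detectors trained on clean boxes
systematically under-count dense canopies. `wheatear` packages the
data-side machinery for building and evaluating occlusion-robust ear
counters:

* **Annotation I/O** for the three dialects in common use: Global-Wheat-style
  CSV (`image_id, width, height, bbox "[x, y, w, h]", source`), COCO
  detection JSON, and Pascal VOC XML; all normalized to 0-based, half-open
  pixel coordinates with clipping at image bounds.
* **Random-Cutout**, a density-guided occlusion simulation. For an image
  with `N_total` annotated ears it builds a per-pixel placement map

  `I_i = 0.001 + 0.003 * n_i`

  (`n_i` = number of ear boxes covering pixel `i`), samples
  `N = max(1, floor(N_total / 4))` rectangle centers from the normalized
  map, and erases rectangles with per-image adaptive sizes
  `H ~ U[H_min/4, H_max/4]`, `W ~ U[W_min/4, W_max/4]`. Ground-truth boxes
  pass through unchanged, so occluded ears keep supervising the model. The
  position-uniform fixed-size **Cutout** and noise-filled **Random Erasing**
  baselines are included for comparison.
* **CBAM**, a numeric reference of the convolutional block attention module:
  channel attention `M_c(F) = σ(MLP(AvgPool(F)) + MLP(MaxPool(F)))`, spatial
  attention `M_s(F) = σ(f7×7([AvgPool_c(F); MaxPool_c(F)]))`, and the
  two-stage refinement `F' = M_c(F) ⊗ F`, `F'' = M_s(F') ⊗ F'`. Pure-numpy
  forward pass on supplied weights — in a detector such as EfficientDet-D0
  these modules sit between the backbone's multi-scale outputs and the
  BiFPN fusion layer; training them is out of scope here.
* **Post-processing**: strict confidence filtering (keep score > 0.5 by
  default) followed by greedy non-maximum suppression with a configurable
  IoU threshold, so one ear yields one box.
* **Counting metrics**: accuracy `P = N_cor / N_real` and false-detection
  rate `O = N_err / N_num`, with greedy one-to-one IoU matching (≥ 0.5)
  defining `N_cor`, per-stratum missed-detection rates for occlusion-type
  breakdowns, and `FPS = 1/T` timing reports.
* **Synthetic scenes**: a seeded generator of wheat-field-like images —
  dense, mutually overlapping elliptical ear blobs with awn-like striping on
  cluttered backgrounds, exact ground-truth boxes and a controllable overlap
  fraction — so everything above is testable without downloading a dataset.

## Worked example

```python
from wheatear import (SceneSpec, generate_scene, generate_detections,
                      build_probability_map, apply_random_cutout, CutoutConfig,
                      nms, NMSConfig, count_report)

scene = generate_scene(SceneSpec(image_size=(128, 128), n_ears=40,
                                 overlap_fraction=0.5, seed=42))
pmap = build_probability_map(scene.shape, scene.boxes)
aug, rects = apply_random_cutout(scene, CutoutConfig(seed=7))

dets = generate_detections(scene, miss_rate=0.1, false_rate=0.05,
                           jitter=0.5, seed=3)
dets = nms(dets, NMSConfig(confidence_threshold=0.5, iou_threshold=0.5))
report = count_report(scene.boxes, dets)
```

which, printed, gives:

```
scene: 40 ears on a (128, 128) canvas
probability map: floor 0.001, max 0.010 (= 0.001 + 0.003 x 3 overlapping ears)
random-cutout: erased 10 rectangles (N = 40/4), sizes ['3.5x1.6', '2.3x2.0', '1.7x3.1'] ...
evaluation: N_real=40 N_num=36 N_cor=36 -> P=0.900, O=0.000
```

The probability map peaks at 0.010 where three ear boxes stack, ten
rectangles are erased for forty ears, and with a 10 % simulated miss rate
the pooled counting accuracy comes out at P = 0.90 — four of the forty ears
were dropped by the simulated detector and the five simulated false
positives fell below the 0.5 confidence threshold after NMS.

## Command line

```
wheatear synth    --out data --images 4 --ears 30 --seed 42 --emit-detections
wheatear augment  --images data/images --annotations data/annotations.csv \
                  --out augmented --seed 42
wheatear evaluate --truth augmented/annotations.csv --dets data/detections.json \
                  --iou 0.5 --out report.json
```

Each command accepts `--config config.yaml` (flags override file keys),
writes artifacts atomically and records a `manifest.json` with the effective
configuration, seed and version; rerunning with the same manifest reproduces
every artifact byte for byte.

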