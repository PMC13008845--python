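# yolobt

Adaptive bad-trial detection in rendered EEG waveform screens.

ERP studies discard artifact-contaminated trials ("bad trials"), and experts
adapt their tolerance to the overall signal quality of a recording: strict on
clean data, lenient on noisy data. `yolobt` re-implements a one-stage detector
that works on rendered multichannel waveform screens (10 trials per image,
channels stacked as rows) and augments a small CSP-style backbone with three
modules:

* **CLAB / CLAC3** — bottlenecks with channel + 7x7 spatial attention whose
  per-layer spatial maps are fused across layers (concat → SE → 1x1) and gate
  the bottleneck output;
* **HFGM** — top-down fusion where globally pooled high-level descriptors gate
  the low-level features and learned sub-pixel (depth-to-space) convolution
  replaces interpolation upsampling, followed by SE fusion;
* **GICM** — per-scale global-context gate before the prediction heads: an
  inception-style local branch (1/3/5/7/9 kernels) produces a gate on the
  Value of a single-head self-attention branch, letting detection thresholds
  depend on global signal quality.

Because the clinical dataset behind the original system is private, the
package bundles a calibrated synthetic generator (`yolobt.synthetic_eeg`):
1/f + alpha background with a P300-like deflection, four artifact classes
(broadband noise, eye movement, EMG, movement), severity calibration into the
peak-to-peak bands >3000 µV / 500–3000 µV / ≤500 µV, and context-adaptive
ground-truth labels (a trial is bad iff its Max PTP exceeds
`max(500 µV, 3 x median clean-trial Max PTP of its screen)`).

**No deep-learning framework is required**: the network stack (reverse-mode
autograd, im2col convolution, batch norm, SGD) lives in `yolobt.nn` and runs
on NumPy.

## CLI

```bash
yolobt simulate --n-screens 100 --out screens/ --seed 0
yolobt render   --screens screens/ --out dataset/ --seed 0
yolobt train    --data dataset/manifest.yaml --cfg src/yolobt/configs/model_tiny.yaml --seed 0 --out weights.npz
yolobt detect   --weights weights.npz --source dataset/images --out preds/
yolobt evaluate --weights weights.npz --data dataset/manifest.yaml --out report.json
yolobt profile  --cfg src/yolobt/configs/model_full.yaml
```

Packaged configs: `model_full.yaml` (published widths; profiles to
11.0 M params / 32.3 GFLOPs at 640x640 under the 80-class convention),
`model_baseline.yaml` (7.2 M / 16.5), `model_tiny.yaml` (reduced width for
CPU experiments), `hyp_default.yaml` (the full 600-epoch SGD recipe with
cosine annealing, mosaic and mixup).

## Layout

```
src/yolobt/
  nn/                NumPy autograd engine, layers, SGD
  synthetic_eeg.py   screen generator, artifact calibration, adaptive labels
  waveform_renderer.py  screen -> PNG + YOLO-format labels
  blocks.py          conv-BN-SiLU, C3, SPPF building blocks
  clab_backbone.py   cross-layer attention bottleneck stages
  hfgm_neck.py       hierarchical feature guidance fusion
  gicm.py            global-context self-attention gate
  detector_pipeline/ model assembly, loss, training, inference, profiling
  eval_metrics.py    P/R/AP/mAP/F1 + severity-stratified reports
  benchmarks.py      synthetic benchmark regimes used by the tests
```
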