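# watercore

Toolkit for grading apple watercore severity from Vis/NIR transmission
spectra, built around a **quadratic 1-D convolutional neural network**
implemented directly on NumPy (no deep-learning framework), together with
the supporting chemometrics and a volumetric ground-truth pipeline:

- `watercore.synth` — synthetic labelled transmission spectra (701-band
  grid, 350–1050 nm): class-monotone water-absorption bands at 760/970 nm,
  multiplicative/additive scatter, sensor noise; fully seeded.
- `watercore.preprocess` — SNV, MSC, min-max, column standardization
  (all with the sample *n−1* standard deviation) and linear resampling to
  the network's canonical input length (2048).
- `watercore.partition` — stratified 3:1 splitting and deterministic SPXY
  (Kennard–Stone accretion on the joint spectra/response distance).
- `watercore.nn` — the quadratic convolution
  `(x·w_r + b_r)(x·w_g + b_g) + (x∘x)·w_b + c`, the full classifier
  (quad stem k=64 s=8 → 16 ch → pool → conv k=3 → pool → conv k=3 → 8 ch →
  512-dim flatten → 100 → 4), an identical linear-stem baseline, RAdam
  training with best-epoch checkpointing, and confusion/accuracy/macro-F1
  metrics. Backward passes are hand-written and verified against
  finite differences and a triple-loop convolution oracle.
- `watercore.volume3d` — watercore quantification from ordered binary slice
  masks (4.5 mm slabs): signed-distance-field shape interpolation between
  slices, fused voxel reconstruction, watercore/fruit volume ratio, and the
  4-level grade mapping (<0.1 % → 1, <3 % → 2, 3–6 % → 3, >6 % → 4), with
  analytic ellipsoid phantoms for validation.
- `watercore.cli` — `simulate`, `preprocess`, `split`, `train`, `evaluate`,
  `predict`, `quantify`, `pipeline` subcommands; plain-text artifacts.

## CLI quick start

```sh
watercore simulate --n-per-class 200 --seed 1 --out data.csv
watercore split --method stratified --train-fraction 0.75 --in data.csv --out split.json
watercore train --train data.csv --test data.csv --quadratic --epochs 40 --out model.npz
watercore evaluate --model model.npz --in data.csv --report metrics.json
watercore quantify --manifest slices/manifest.json --n-intermediate 8
```

Or run everything from one YAML:

```sh
watercore pipeline --config run.yaml --out-dir out/
```

where `run.yaml` can set `seed`, `generator:`, `train_fraction`, `model:`
and `quadratic:`. The published training profile (RAdam, lr 0.5,
weight-decay 1e-4, batch 32, 500 epochs) is available as
`--paper-profile` / `ModelConfig.paper_profile()`; the toolkit default
is lr 1e-3.

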