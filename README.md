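# hsiderm

Hyperspectral skin-lesion analysis pipeline: Lambertian photometric-stereo
reconstruction of albedo and skin-surface models from multi-angle 33-band
captures (477–891 nm), windowed dual-branch 3D/2D CNN classification of
pigmented (MM / PN / healthy) and non-pigmented (BCC / SCC / ID / healthy)
classes, and per-lesion majority voting.

Because no acquired data are available, the package ships a first-class
synthetic capture emulator (`hsiderm.synthdata`) that generates raw capture
sets with known ground truth — chromophore-like class spectra, surface
relief, lesion masks, dark/white references and three known illumination
directions — so every downstream stage is exercised end-to-end.

## Modules

| module | role |
| --- | --- |
| `hsiderm.synthdata` | sensor/light configuration, class spectra, scene phantoms, Lambertian rendering, cohorts, TIFF/PNG persistence |
| `hsiderm.photometric` | reflectance calibration, VIS/VNIR merge, per-band photometric stereo, Frankot–Chellappa depth integration, smoothing, 66-channel cube assembly, RGB reconstruction |
| `hsiderm.mlprep` | annotation-derived sampling masks (erosion / margin / annulus), 34-channel feature selection (33 albedo + 575 nm surface frame), normalization, vertical train/test slicing, quota window sampling, random over-sampling, flip augmentation |
| `hsiderm.model` | dual-branch 3D/2D CNN (NumPy implementation: LeakyReLU, max pooling, Adam, categorical cross-entropy, early stopping) |
| `hsiderm.evaluate` | rolling-window classification/confidence maps, majority voting, one-vs-rest metrics, cohort orchestration, report output |

The CNN is implemented directly on NumPy (exact convolutions + backprop)
because no deep-learning framework is available in the target environment;
training is fully deterministic under a fixed seed.

## CLI

```bash
hsiderm simulate   --out cohort/ --classes pigmented --n-lesions 4 --frame 256 --seed 1
hsiderm preprocess --capture cohort/lesion000 --out cube.tif --sigma 2
hsiderm prep       --cube cube.tif --annotation cohort/lesion000/annotation.png \
                   --label MM --seed 1 --out windows/
hsiderm train      --data windows/train --classes pigmented --seed 1 --out model.npz
hsiderm evaluate   --model model.npz --data windows/test --out report/
hsiderm all        --classes pigmented --n-lesions 4 --seed 1 --out report/
```

Any pipeline default can be overridden with `--config config.yaml` (keys
mirror `hsiderm.evaluate.PipelineConfig`; a `model:` section feeds
`hsiderm.model.ModelConfig`).

## Notes on scale

Synthetic cohorts default to 256×256 frames; the printed 30 / 60 px mask
margins assume the full 1605×1640 sensor and are scaled accordingly at desk
scale (`PipelineConfig.desk_scaled()`). Window quotas (250 lesion + 100
healthy per half-image) are kept at their stated values.
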