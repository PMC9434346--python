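# retquant

Quantification of retinal SD-OCT imaging biomarkers and random-forest
prognosis of 1-year disease activity, exercised end-to-end on synthetic
layered B-scans with analytic ground truth.

The pipeline has three parts:

1. **Identification & segmentation** — a clip-based CNN (four blocks of
   conv / batch-norm / ReLU / max-pool followed by two fully connected
   layers) detects the presence of the EZ and ELM photoreceptor layers in
   vertical 16-px clips of each B-scan; a small U-shaped fully
   convolutional network segments four lesion types (IRF, SRF, SHRM, PED)
   pixelwise. Both run on a hand-written numpy layer engine (`retquant.nn`)
   — no deep-learning framework required, CPU-only.
2. **Biomarker quantification** — 12 features per eye and visit: EZ/ELM
   length rates (proportion of clips with the layer present), per-lesion
   area (mm²) and maximum horizontal diameter (mm), and mean normalized
   intensity of SHRM and PED.
3. **Prognosis** — a random forest (grid-searched 150–800 trees, majority
   voting, stratified 10-fold CV) predicts a three-class outcome
   (0 stable / 1 persistent disease activity / 2 cured) from longitudinal
   feature vectors (baseline, month 1, month 3 blocks plus signed deltas),
   in two-metric / four-metric / six-metric variants.

Because no public dataset ships with the package, `retquant.synthetic`
renders seeded B-scan scenes (layered retina, thin bright EZ/ELM lines with
gaps, rasterized lesions, multiplicative speckle) with exactly consistent
annotations and analytic ground-truth biomarkers, plus longitudinal cohorts
whose labels follow a configurable planted outcome rule.

## CLI

```sh
retquant synth          --config cfg.yaml --seed 0 --out-dir runs/demo
retquant train-detector --config cfg.yaml
retquant train-segmenter --config cfg.yaml
retquant quantify       --config cfg.yaml       # features.csv
retquant evaluate       --config cfg.yaml       # metrics.csv (report table)
retquant predict        --config cfg.yaml       # prediction_metrics.csv
retquant run-all        --config cfg.yaml       # full pipeline + manifest
retquant segment --in scan.png --out mask.png --model runs/demo/segmenter.npz
retquant detect  --in scan.png --model runs/demo/detector_ez.npz
```

Config is YAML with per-stage blocks (`synth`, `detector`, `segmenter`,
`predict`); unknown keys are rejected by name. Re-running a config with the
same seeds reproduces every CSV output bit-exactly (the run manifest records
config hash, seeds and stage outputs).

Example config:

```yaml
seed: 0
out_dir: runs/demo
synth: {n_eyes: 10, height: 128, width: 512, speckle_sigma: 0.0}
detector: {epochs: 8}
segmenter: {epochs: 30}
predict: {cv_folds: 5}
```

## Layout

- `retquant.synthetic` — seeded scenes, annotations, longitudinal cohorts
- `retquant.preprocess` — crop/resize to H×W (W divisible by 16), min-max
  normalization, seeded flip/crop/intensity-shift augmentation
- `retquant.nn` — minimal numpy conv-net engine with manual backprop
- `retquant.detection` — clip slicing, clip labels, clip-CNN training,
  clipping-predicting-merging detection
- `retquant.segmentation` — U-shaped FCN training and argmax segmentation
- `retquant.biomarkers` — the 12-feature vector
- `retquant.metrics` — dice, confusion metrics, percentile-bootstrap CIs,
  AVG aggregation, class proportions
- `retquant.prognosis` — feature-matrix variants/horizons, nested-CV
  random forest, importance ranking, variant comparison
- `retquant.pipeline` / `retquant.cli` — orchestration and `retquant` CLI
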