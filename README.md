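# nucleovit

Nuclear-information enhancement plus a compact vision transformer with
wavelet position embedding, for benign/malignant classification of
H&E-stained histopathology images — together with the full evaluation-metric
suite (Dice, Jaccard, Hausdorff, F1, Youden, Cohen's kappa, ROC/AUC) and
Grad-CAM / feature-map inspection tools.

Everything runs on CPU with no external datasets: a synthetic-histology
module generates deterministic H&E-like fixtures (pink stroma, darker
elliptical nuclei, exact ground-truth masks, two classes differing in
nucleus size/eccentricity/density) that every stage trains and evaluates on.

The networks are built on a small self-contained reverse-mode autodiff
engine over numpy (`nucleovit.autograd` / `nucleovit.nn`), so the package
has no deep-learning-framework dependency.

## Components

| module | contents |
| --- | --- |
| `nucleovit.synthetic` | seeded synthetic H&E-like images + masks + manifests |
| `nucleovit.segmentation` | residual U-Net, hybrid BCE–Dice loss, step-decay LR, rotation/flip/intensity augmentation |
| `nucleovit.enhancement` | resize to 32-divisible dims, Canny on the predicted mask (8-bit 100/200 hysteresis), multiplicative edge fusion, ImageNet normalization |
| `nucleovit.evt` | conv tokenizer (3 blocks), Haar wavelet position embedding, pre-norm transformer encoder, sequence pooling, linear head; warmup+cosine Adam training; deterministic batch-1 inference |
| `nucleovit.metrics` | Dice / Jaccard / directed Hausdorff / confusion matrix / F1 / Youden / kappa / ROC-AUC, with flagged (never silent) undefined values |
| `nucleovit.pipeline` | stratified 7:2:1 splitting, seeded end-to-end runs, four-arm ablation (base / +wpe / +nie / +wpe+nie) |
| `nucleovit.visualization` | tokenizer feature-map colormap panels and Grad-CAM on dotted-index layer paths such as `model.tokenizer.conv_layers[0][0]` |

## CLI

```bash
nucleovit generate-synthetic --n-per-class 16 --size 64 --seed 42 --out data
nucleovit split       --manifest data/manifest.csv --ratios 7,2,1 --seed 42 --out splits
nucleovit train-seg   --train splits/train.csv --val splits/val.csv --epochs 50 --seed 21 --out seg
nucleovit enhance     --manifest splits/train.csv --model seg/resunet.npz --out enhanced --edge-gain 0.0
nucleovit train-cls   --train enhanced/manifest.csv --val splits/val.csv --wpe --epochs 100 --seed 42 --out cls
nucleovit evaluate    --manifest splits/test.csv --model cls/evt.npz --out eval
nucleovit ablation    --seed 42 --out runs/ablation
nucleovit visualize   --kind gradcam --model cls/evt.npz --input img.png \
                      --layer "model.tokenizer.conv_layers[0][0]" --out cam.png
```

Manifests are CSV (`id,image,mask,label`), metric reports JSON, model
checkpoints `.npz` with the configuration embedded.

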