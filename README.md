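# wmhda

Triplanar U-Net ensemble segmentation of white-matter hyperintensities
(WMH) on FLAIR + T1 brain MRI, together with five domain-adaptation
strategies and a voxel/cluster-wise evaluation suite, exercisable
end-to-end on built-in synthetic two-domain cohorts.

The networks run on a small numpy reverse-mode autodiff engine
(`wmhda.nn`) — no GPU or deep-learning framework is required; everything
is CPU-only and deterministic under fixed seeds.

## What is in the box

| module | role |
| --- | --- |
| `wmhda.synthgen` | seeded generator of two-domain FLAIR/T1-like cohorts with lesions, bias fields, noise, slice anisotropy and optional unlabelled "artifact" confounders; NIfTI + manifest I/O |
| `wmhda.preproc` | Gaussian intensity normalisation, FOV cropping, per-plane slice extraction/resizing, reassembly of planar predictions into 3D volumes |
| `wmhda.model` | depth-trimmed planar 2D U-Nets (axial/sagittal/coronal), weighted cross-entropy + soft Dice loss, triplanar probability averaging, checkpointing |
| `wmhda.training` | Adam with stepped LR schedule, online augmentation (10x axial / 6x sagittal-coronal expansion), subject-level validation split, patience-based early stopping |
| `wmhda.adapt_tl` | layer-wise transfer learning: decoder-end block map, airtight freezing (including batch-norm statistics), reduced fine-tuning schedule, subjects x layers sweep |
| `wmhda.adapt_dann` | unsupervised / semi-supervised domain-adversarial training: gradient-reversal layer, bottleneck domain head (1024/512/32 FC, dropout 0.2), momentum-SGD domain optimiser |
| `wmhda.adapt_du` | iterative domain unlearning: three sequential per-batch updates with a beta-weighted confusion loss (default beta 50), decoder-end domain head (468/96/32 FC) |
| `wmhda.metrics` | Dice SI, voxel TPR/FPR, 26-connected cluster TPR/precision/F1, log-volume difference, paired sign-flip permutation tests with max-T correction, linear domain-accuracy probe |
| `wmhda.experiments` | orchestration of the six test strategies over a source/target pair, comparison tables, domain swapping, and the desk-scale reference benchmark |
| `wmhda.nn` | the autodiff engine: conv2d, max-pool, batch-norm, bilinear resize, dropout, softmax, gradient reversal; Adam and momentum SGD |

## CLI

The `wmhda` entry point covers the full workflow:

```bash
# 1. simulate a two-domain pair of cohorts
wmhda simulate --config source.yaml --n 20 --seed 0 --out data/source/
wmhda simulate --config target.yaml --n 20 --seed 1 --out data/target/

# 2. train the triplanar baseline on the source domain
wmhda train --cohort data/source/manifest.csv --config train.yaml --out ckpt/

# 3. adapt to the target domain
wmhda adapt tl   --ckpt ckpt/checkpoint.npz --target data/target/manifest.csv \
                 --layers 3 --out tl.npz
wmhda adapt dann --source data/source/manifest.csv --target data/target/manifest.csv \
                 --semi-fraction 0.25 --out dann.npz
wmhda adapt du   --source data/source/manifest.csv --target data/target/manifest.csv \
                 --beta 50 --out du.npz

# 4. segment and evaluate
wmhda segment  --ckpt dann.npz --cohort data/target/manifest.csv --out preds/
wmhda evaluate --pred preds/ --truth data/target/manifest.csv --out metrics.csv
wmhda compare  --metrics a.csv b.csv --permutations 10000 --seed 0

# extras
wmhda sweep --ckpt ckpt/checkpoint.npz --target-train ... --target-test ... --out sweep/
wmhda features --ckpt dann.npz --cohort data/target/manifest.csv --tap bottleneck --out feats.csv
wmhda tune-beta --grid 20,30,40,50,60 --accuracies 0.70,0.65,0.60,0.52,0.55
wmhda bench run --out results/
```

A domain-spec YAML holds `wmhda.synthgen.DomainSpec` fields, e.g.

```yaml
name: source
volume_shape: [40, 48, 40]
tissue_means: {background: 0.0, brain: 100.0, lesion: 170.0}
noise_sigma: 5.0
lesion_count_range: [3, 8]
```

and a training YAML may carry `model:`, `train:`, `augment:` and
`preproc:` sections mirroring the respective config dataclasses.

## Notes

- Volumes are `(x, y, z)`; axial slices are fixed-`z`, sagittal fixed-`x`,
  coronal fixed-`y`. Inputs are assumed brain-extracted, bias-corrected and
  co-registered (that preprocessing is out of scope).
- Default slice sizes are 128x192 (axial), 192x120 (sagittal) and
  128x80 (coronal); synthetic configurations use smaller sizes.
- The reference benchmark (`wmhda.experiments.reference_benchmark_config`)
  is deliberately small: 13 subjects per domain, 28x32x28 voxel volumes,
  axial-plane training for 14 epochs, sized for a single CPU.
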