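# patchid

Patch-based photo-identification of individually patterned animals with a
four-patch twin-network similarity model, gradient-boosted decision fusion,
image-based and shark-based verification, and a temporal pattern-stability
test — exercised end-to-end on a built-in synthetic spot-pattern generator
that emulates adult pattern stability and neonate/juvenile pattern drift.

## How it works

1. **synthetic_sharks** renders labelled populations: capsule-shaped dorsal
   silhouettes with unique spot patterns, an ocellus landmark, masks,
   rotated-box annotations (head / pec / FDF / FDB) and a CSV manifest.
   Same-day baseline replicates differ only in photographic nuisance;
   time-series images advance a seeded drift walk whose strength depends on
   life stage (adults 0, juveniles 0.02, neonates 0.08 per step).
2. **annotations_io** reads/writes roLabelImg-dialect XML, manifests, and
   cleans datasets (byte-duplicate, low-resolution and blur rejection).
3. **patch_pipeline** masks the background, extracts each rotated box into a
   standardized square patch (default 380 px; bilinear, exact at 90°
   multiples), and applies the augmentation chain (flips, 90° rotations,
   Gaussian noise/blur, gamma and linear contrast).
4. **pairs_and_splits** builds held-out-individual train/test splits,
   labelled same/different patch pairs, and shuffled batches (default 16).
5. **similarity_net** is the per-patch twin network: a frozen backbone
   applied to both patches, average pooling, concatenation, a 32-unit ReLU
   dense layer and a 1-unit sigmoid — the similarity index. Only the head
   trains. A seeded random-frozen 4-layer conv backbone (64 px, F=64) runs
   everything at desk scale; the reference EfficientNet-B4 configuration is
   described by its architecture contract (feature dim 1792, 17,673,823
   feature-extractor parameters) without needing pretrained weights.
6. **ensemble_fusion** concatenates the four patch indices into X and fits
   a gradient-boosted regression-tree ensemble (residual chain, shrinkage,
   early stopping); the clipped prediction is the final similarity index,
   decided at a strict 0.5 threshold.
7. **evaluation_temporal** computes accuracy / precision / MAE (on binary
   decisions, so accuracy + MAE = 1 exactly), tie-aware ROC/AUC,
   image-based and K1×K2-averaged shark-based evaluation, and the
   per-time-marker stability analysis against baseline images.
8. **experiment / cli** orchestrate the whole flow from one YAML config
   with a single master seed; reruns are byte-identical.

## CLI

```bash
# generate a synthetic dataset
patchid simulate --adults 8 --juveniles 4 --neonates 5 \
    --baseline-reps 6 --time-steps 4 --seed 7 --out data/

# clean a manifest, extract patches
patchid clean --manifest data/manifest.csv --min-side 128 --blur-threshold 0.1
patchid prepare --manifest data/manifest.csv --out patches/ --size 380

# full experiment (simulate -> clean -> train x4 -> fuse -> eval -> temporal)
patchid run --seed 7 --out runs/exp
patchid run --config exp.yaml

# validate a config; inspect a stored temporal curve
patchid validate-config --config exp.yaml
patchid temporal --shark HO_100 --run-dir runs/exp
```

`patchid run` writes `reports/evaluation.json` (image-based and shark-based
accuracy/precision/MAE/AUC per life stage for the four patch models and the
fused model), `reports/temporal.json` (per-shark marker curves and
stable/unstable verdicts), the trained model directories, and every
intermediate artifact (images, masks, annotations, manifest, split).

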