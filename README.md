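# nodulecad

Hybrid-feature classification of pulmonary nodule patterns in CT patches.

Computer-aided detection systems for lung cancer must decide whether a
small cropped CT patch contains a true pulmonary nodule or a visually
similar distractor (vessel crossings, scars). This package implements a
classification approach built on four complementary feature-extraction
methods, greedy mRMR feature selection, and a set of trainable
classifiers, together with the full evaluation metric suite and a seeded
synthetic patch generator so every stage is testable without clinical
data. It is aimed at researchers studying shape- and projection-based
false-positive reduction in thoracic CAD pipelines.

## The approach

Each labeled pattern is an intensity patch `A` with a binary mask.
Four feature sets are extracted:

1. **Bilateral 2D-PCA** — from the image covariance matrix
   `S = (1/M) Σᵢ (Aᵢ − Ā)ᵀ(Aᵢ − Ā)` of the training patches, the top
   d = 7 eigenvectors on the column side (and of the transposed images on
   the row side) compress each patch to `B = Xᵀ(A − Ā)Y`, a 7 × 7 matrix
   flattened to 49 features (`pca_00..pca_48`); mRMR keeps 20.
2. **Projection statistics** — min, max, mean, std, var and third
   central moment of the 49 projection values (`stat_*`); mRMR keeps 5.
3. **Geometric descriptors** — area, perimeter, equivalent diameter,
   solidity, eccentricity, aspect ratio M/L, compactness P²/(4πA),
   roundness 4A/(πL²), circularity 4πA/P², ellipticity πL²/(2A)
   (`geo_*`); mRMR keeps 5.
4. **Hybrid** — the union of the three selected sets, exactly 30
   features, no further selection.

mRMR ranks features greedily by max(D − R) (or max(D/R)), with relevance
`D = (1/|S|) Σ I(xᵢ; c)` and redundancy `R = (1/|S|²) Σᵢⱼ I(xᵢ; xⱼ)` on
mean ± σ discretized features. Classifiers: a momentum back-propagation
MLP written out explicitly, a random forest, and bagging / AdaBoost.M1
ensembles over either base (`ann`, `rf`, `bag-ann`, `bag-rf`, `ada-ann`,
`ada-rf`). Evaluation reports sensitivity, specificity, total
classification accuracy (TCA), AUROC, Cohen's kappa and RMSE, under a
~50/50 hold-out or stratified 5-fold cross-validation. Everything fitted
(projection bases, discretization, selection, standardization, models)
uses the training split only.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

```python
from nodulecad import (GeneratorConfig, MethodSpec, generate_dataset,
                       run_method)

ds = generate_dataset(GeneratorConfig(seed=1))      # 95 nodules, 75 non-nodules
train, test = ds.train_test()                       # 84 / 86 stratified split
spec = MethodSpec(method_id=4, classifier="ann", seed=1)
report = run_method(spec, train, test)

print(f"selected features : {len(report.feature_names)}")
print(f"TCA               : {report.tca:.3f}")
print(f"sensitivity       : {report.sensitivity:.3f}")
print(f"specificity       : {report.specificity:.3f}")
print(f"AUROC             : {report.auroc:.3f}")
print(f"kappa             : {report.kappa:.3f}")
print(f"RMSE              : {report.rmse:.3f}")
```

prints

```
selected features : 30
TCA               : 0.988
sensitivity       : 1.000
specificity       : 0.974
AUROC             : 1.000
kappa             : 0.976
RMSE              : 0.072
```

The synthetic classes here are fully shape-separable
(`class_separation=1`), so the hybrid 30-feature pipeline recovers them
almost perfectly: 85 of 86 held-out patches are classified correctly,
every nodule is found (sensitivity 1.0), and the score ranking is
perfect (AUROC 1.0). With `class_separation=0` the two classes are drawn
from the same shape distribution and the same pipeline falls to chance
accuracy (~0.5), confirming that the features — not a leak — carry the
signal.

The same pipeline is available from the shell:

```sh
nodulecad simulate --out data/ --seed 1
nodulecad run --manifest data/manifest.csv --method 4 --classifier ann \
    --seed 1 --out results/run/
nodulecad table --manifest data/manifest.csv --seed 1 --out results/grid.csv
```

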