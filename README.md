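# retmae

Self-supervised pre-training and cross-dataset evaluation for retinal
OCT B-scan classification — a two-phase masked-autoencoder framework with
ViT / Swin / SwinV2 encoder backbones, a synthetic multi-source B-scan
generator, and an exact paired statistics harness.

## The problem

Classifiers for age-related macular degeneration (AMD) trained on one
clinic's optical coherence tomography (OCT) images often fail on scans
from another device or protocol. One remedy is a two-phase regime:

1. **Self-supervised pre-training.** A masked autoencoder (MAE) hides a
   fraction *m*<sub>ratio</sub> (default 0.7) of the 16×16 image patches,
   replaces their embeddings with a learned mask token, and reconstructs
   the pixels. The loss is mean squared error restricted to masked
   pixels,

   L = (1 / m_ratio) · (1/N) · Σᵢ (x̂ᵢ − xᵢ)² · mᵢ ,

   computed on the *fusion* of several sources' training splits —
   shuffled together, with every test split held out untouched.
2. **Supervised transfer.** The decoder is replaced by a three-layer
   dense head ending in a 2-way softmax (NORMAL vs AMD); the pre-trained
   encoder is frozen and only the head trains, with early stopping on
   validation accuracy. Each classifier is then evaluated on *every*
   source's held-out test set, giving a (train source × test source)
   matrix of accuracy / AUROC / AUPR / F1, and paired model comparisons
   use the exact Wilcoxon signed-rank test (full enumeration of the
   signed-rank distribution, mid-ranks for ties, zeros dropped).

Because the original clinical datasets are large and access-controlled,
the package ships a synthetic B-scan generator: layered retinal bands,
drusen-like bumps (AMD), neovascular-like elevations and fluid pockets
(extra classes used only during pre-training), log-normal speckle,
Gaussian blur, and per-source gain/offset shifts that create a real,
measurable domain gap. Every pipeline stage is exercisable at desk scale
on one CPU.

## Worked example

Exact signed-rank comparison of the published cross-dataset AUROC scores
of the ResNet-50 baseline versus the SwinV2 masked-autoencoder
classifier (nine paired train/test cells):

```python
from retmae.benchmarks import RESNET50_AUROC, SWINV2_AUROC, paired_auroc
from retmae.evaluation import wilcoxon_signed_rank_exact

resnet, swinv2 = paired_auroc(RESNET50_AUROC, SWINV2_AUROC)
res = wilcoxon_signed_rank_exact(resnet, swinv2)
print(f"n pairs: {len(resnet)}  dropped zeros: {len(resnet) - res.n_effective}")
print(f"W = {res.W}   exact two-sided p = {res.p_two_sided:.4f}")
```

```
n pairs: 9  dropped zeros: 1
W = 1.5   exact two-sided p = 0.0234
```

One of the nine paired differences is zero and is dropped; of the eight
ranked differences only one (rank 1.5) favours the baseline, so the
positive-rank sum sits in the extreme tail of the 2⁸-point exact null
distribution and p ≈ 0.023 — the difference is significant at the 5%
level.

A full desk-scale experiment — simulate three synthetic sources,
pre-train a tiny SwinV2 MAE on their fused training splits, train one
frozen-encoder classifier per source, and cross-evaluate:

```python
from retmae.experiments import ExperimentConfig, run_experiment

cfg = ExperimentConfig(out_dir="demo_run", seed=3, experiment="full")
report = run_experiment(cfg)
for train_src, row in report.cells.items():
    for test_src, rec in row.items():
        print(f"train {train_src} -> test {test_src}: "
              f"AUROC {rec.auroc:.2f}  AUPR {rec.aupr:.2f}  "
              f"acc {rec.accuracy:.2f}  F1 {rec.f1:.2f}")
```

```
train srcA -> test srcA: AUROC 0.66  AUPR 0.62  acc 0.75  F1 0.40
train srcA -> test srcB: AUROC 0.66  AUPR 0.62  acc 0.67  F1 0.50
train srcA -> test srcC: AUROC 0.88  AUPR 0.77  acc 0.75  F1 0.40
train srcB -> test srcA: AUROC 0.56  AUPR 0.48  acc 0.67  F1 0.00
train srcB -> test srcB: AUROC 0.81  AUPR 0.80  acc 0.67  F1 0.00
train srcB -> test srcC: AUROC 0.53  AUPR 0.55  acc 0.67  F1 0.00
train srcC -> test srcA: AUROC 0.62  AUPR 0.68  acc 0.83  F1 0.67
train srcC -> test srcB: AUROC 0.59  AUPR 0.49  acc 0.50  F1 0.40
train srcC -> test srcC: AUROC 0.84  AUPR 0.65  acc 0.67  F1 0.00
```

(Each synthetic test set holds only twelve binary-labelled scans, so the
matrix cells are coarse; the run takes under a minute on one CPU core and
leaves checkpoints, manifests, per-epoch logs and `report.json` under
`demo_run/`.)

The same pipeline is available from a shell:

```bash
retmae simulate --out data --sources 3 --subjects-per-source 30 \
    --scans-per-subject 2 --seed 3
retmae prepare --manifest data/manifest_srcA.csv \
    --manifest data/manifest_srcB.csv --manifest data/manifest_srcC.csv \
    --out prepared --seed 3
retmae pretrain --data prepared/fused_train.csv prepared/fused_val.csv \
    --images-root data --out ckpt --epochs 3
```

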