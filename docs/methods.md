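# Methods

## Masked-autoencoder model

An input B-scan (grayscale, values in [0,1]) is divided into square
patches on a `PatchGrid` (paper scale 224×224 / patch 16 → 196 patches;
tiny scale 64×64 / patch 8 → 64 patches). `sample_mask` hides exactly
⌊m_ratio · P⌋ patches chosen uniformly without replacement (floor
rounding; a fresh mask per image per epoch, streamed from the run seed).
The default masking ratio is 0.7; 0.2/0.5/0.7/0.8 are the standard
ablation settings.

**Dense masking.** Windowed attention cannot drop tokens the way a plain
ViT-MAE does, so all three encoder families process the *full* token
grid with masked positions replaced by a shared learned mask token.  The
patch-embedding granularity of the Swin families is 4×4 px, finer than
the 16×16 mask patch: every embedding token lying inside a masked mask
patch receives the token.  The ViT family uses the same strategy for
uniformity (token dropping would be an optimization, not a semantic
change).

**Encoders.**

| preset | embed | depths | heads | window |
|---|---|---|---|---|
| `vit-paper` | 1024 | (6,) | (4,) | — |
| `swin-paper` | 96 | (2, 2, 18, 2) | (6, 12, 24, 48) | 7 |
| `swinv2-paper` | 96 | (2, 2, 6, 2) | (3, 6, 12, 24) | 7 |
| `*-tiny` | 32 (vit) / 16 (swin) | (2,) / (1,1,1,1) | (2,) / (1,2,4,8) | 4 |

Swin blocks alternate unshifted and half-window-shifted partitions, with
the standard additive attention mask blocking cross-region pairs in
shifted windows; the window is clipped to the grid when the grid is
smaller.  SwinV2 blocks differ in three ways: post-norm residuals,
scaled cosine attention with a learnable per-head logit scale (capped at
100), and a continuous relative-position bias from a 2-layer MLP over
log-spaced relative coordinates.  Between stages, patch merging halves
the grid and doubles the channels.

**Decoders.** The ViT decoder projects encoder tokens to the decoder
width (1024 at paper scale), runs 4 global-attention blocks, and maps
each token to its patch's pixels.  The Swin/SwinV2 decoder projects the
final encoder grid to the decoder width (768 at paper scale), then
mirrors the encoder with patch-expanding upsampling stages (each halves
the channels and doubles the grid) interleaved with Swin blocks whose
depths/heads mirror the encoder's in reverse; a final linear layer emits
4×4-px pixel patches.  The exact layer-by-layer decoder schedule is a
design choice of this package and is recorded in each preset.

**Loss.** `masked_mse_loss` implements
L = (1/m_ratio)(1/N) Σ (x̂ᵢ−xᵢ)² mᵢ on raw pixels (no per-patch target
normalization), with N the pixel count and mᵢ the pixel-level mask.
Unmasked pixels contribute exactly zero, and when m_ratio equals the
realized masked fraction the loss equals the plain MSE over masked
pixels — both identities are tested to 1e-12.

## Training

Both phases use Adam with decoupled weight decay (the "AdamW" update:
the decay multiplies the parameter, not the gradient), lr 1.5e-4, weight
decay 0.05, β = (0.9, 0.95), batch 32.  Pre-training runs 50 epochs at
paper scale and keeps the minimum-validation-loss checkpoint; validation
uses a fixed mask set so epoch losses are comparable.  The supervised
phase runs up to 100 epochs with early stopping at patience 10 on
validation accuracy (only a strictly greater accuracy resets the
counter) and keeps the maximum-accuracy checkpoint.  The constant
learning-rate schedule is the default.

The classifier head is three dense layers (hidden dims configurable,
(512, 256) by default at paper scale, (64, 32) in the desk-scale
recipes) with ReLU after the first two and a 2-way softmax.  The encoder
is frozen bit-exactly — norms included (evaluation-mode statistics) —
which the suite asserts tensor by tensor.  Encoder features (mean-pooled
final-stage tokens) are standardized per dimension with training-split
statistics before the head sees them.  This is the usual practice when
probing a frozen encoder, and it matters here: early in pre-training the
reconstruction objective passes through a "predict the dataset mean"
plateau in which the encoder's pooled output varies only weakly with the
input, and without standardization the head would have to undo that
scale collapse on its own.

Training augmentations (training images only, never validation or test):
rotation ≤ 15°, horizontal flip, brightness/contrast jitter ±0.2,
Gaussian blur σ ∈ [0.1, 1.0], and a mild elastic warp.  The supervised
loss is unweighted 2-class cross-entropy; the class imbalance is
reported through AUROC/AUPR/F1 rather than reweighted away.

Supervised-phase learning rate: the paper-scale default reuses 1.5e-4;
the desk-scale experiment recipes raise the head lr to 3e-3 because the
tiny head trains for only a few hundred optimizer steps on cached
features.  Both values live in the config and are overridable.

## Data handling

A dataset is a manifest CSV (`image_path,source_id,subject_id,
class_label,split`).  `map_labels_binary` relabels DRUSEN as AMD
(drusen are the early-AMD signature) and removes every other class;
pre-training fusion, by contrast, retains all classes — representation
learning is label-free and benefits from the wider morphology spectrum.

Splits: `split_random_stratified` assigns train/val/test per class with
largest-remainder rounding (remainder to train; every split is forced
non-empty, so classes need ≥ 3 units).  When records carry subject ids
the subject is the sampling unit, so a subject's scans never straddle
splits.  `split_by_subject` assigns whole subjects in lexicographic
order (first *k* to train, then val, then test), per class.  Subject
integrity — no subject with scans in both test and non-test — is a
construction invariant of every manifest, and fusion refuses duplicate
image ids and re-fusion of its own output.  An optional `dedup_exact`
filter drops byte-identical image files.

## The synthetic generator

Each source (`DomainParams`) renders layered retinal bands with gently
undulating boundaries, then applies Gaussian blur, multiplicative
log-normal speckle, and an affine gain/offset — the appearance axes
along which OCT devices differ.  Pathology (`LesionParams`): AMD adds
1–3 dome-shaped deformations of the outer band (drusen-like, amplitude
4–8 px at 64-px height); the CNV-like class adds larger elevations; the
DME-like class an intraretinal dark ellipse.  The NORMAL/AMD mix
defaults to 80:20 (clinical datasets are heavily NORMAL-dominated);
pre-training sources use 60:20:10:10 over the four classes.  All of a
subject's scans share one class.  Everything is deterministic per seed,
and the base anatomy stream is independent of the lesion stream so a
seed-matched NORMAL render differs from its AMD counterpart only in the
lesion.

What the generator does **not** emulate: physically accurate speckle
statistics or A-scan physics, 3-D volume context, vascular detail,
acquisition artifacts (motion, vignetting), or realistic anatomical
variation across patients.  Passing desk-scale tests therefore shows the
pipeline's mechanisms work end to end (signal exists, fusion helps,
isolation holds) — not that the tiny models would classify clinical
scans.

## Evaluation and statistics

AMD is the positive class.  Accuracy and F1 come from hard labels at
threshold 0.5 on the AMD probability; AUROC uses the Mann–Whitney
convention (ties half credit) and AUPR is average precision (step
interpolation; trapezoidal PR interpolation is biased).  Single-class
ground truth marks the ranking metrics as undefined rather than zero.
Cross-evaluation audits image ids against the training manifests and
refuses to score a leaked test set.

The Wilcoxon signed-rank test is exact at every n (capped at 25 nonzero
pairs): zero differences are dropped (the classical treatment; a Pratt
variant is available), tied |differences| get mid-ranks, and the null
distribution of the positive-rank sum is enumerated over all 2ⁿ sign
assignments of the realized rank values (implemented as a
dynamic-programming convolution over doubled ranks, arithmetic-identical
to full enumeration).  The two-sided p is 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)),
capped at 1.  On the published nine-cell AUROC tables this reproduces
p = 0.02 (baseline vs SwinV2 classifier) and p = 0.01 (with vs without
pre-training).

Baselines (ResNet-50, ViT-Base/16 with 2-way heads) are constructed as
named-parameter registries of the published architectures for exact size
accounting — 23,512,130 (23.5 M) and 85,800,194 (≈ 86 M) trainable
parameters; they are not trained here.

## Desk-scale study conditions

The directional study (SSL vs no SSL; fused vs single-source
pre-training) uses three synthetic sources of 45 subjects × 4 scans
(≈ 150 training scans per source), tiny SwinV2 at 64×64, 3 pre-training
epochs, heads trained ≤ 30 epochs on cached frozen features, 5 seeds.
The no-SSL arm keeps the same frozen-encoder protocol with a randomly
initialized encoder, so the comparison isolates the value of the
pre-trained weights.  Medians are compared; no effect size is claimed.

## Numerical conventions and limitations

* Float64 throughout; single-threaded CPU determinism is the tested
  contract (fixed seeds ⇒ bit-identical losses, masks, manifests).
* Mask-count rounding: floor.  Stratified-split rounding:
  largest-remainder, remainder to train.
* LayerNorm ε = 1e-6; attention logit cap (SwinV2) at ln 100; the
  shifted-window attention mask uses −100 additive logits.
* The NumPy core favours clarity over speed: paper-scale configurations
  construct and export correctly but are not practical to train here;
  tiny presets run a forward pass in well under a second.
* Checkpoints are named-tensor `.npz` archives with a JSON sidecar
  (config, seed, provenance); weight names are stable across runs.
* GPU execution, mixed precision, fine-tuning (unfreezing) schedules and
  FLOP accounting are out of scope.
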