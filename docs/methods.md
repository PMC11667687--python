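# Methods

This note documents the models, the synthetic data, the numerical choices
and the limits of what the tests demonstrate.

## Pipeline

The package classifies H&E whole-slide images (WSIs) into four
breast-cancer molecular subtypes (LumA, LumB, HER2-enriched, Basal-like)
in two steps.

**Tumor filtering.** Slides are processed as grids of square tiles
(`tiling`): stride = `tile_px − overlap_px`, partial edge tiles dropped
(fixed-size classifier input; padding would distort statistics), tiles kept
when their tissue fraction is ≥ `min_tissue_fraction` (default 0.5). The
tissue rule is deliberately simple and configurable: a pixel is tissue if
HSV saturation > 0.05 and mean RGB < 235 — this catches stained tissue,
marker ink and folds while excluding white background. Default geometry is
512 px at 0.5 µm/px ("20×"); 64-px overlap is the conventional way to
densify sampling for a minority class. Inputs are assumed to be already at
the target resolution; pyramid resampling of vendor formats is out of
scope. A binary tumor/non-tumor tile classifier then scores every tile;
tiles with tumor probability ≥ 0.5 (configurable — the admission cutoff is
a free parameter of the method) enter the subtype stage, capped per WSI
with class-specific caps (defaults LumA 441, LumB 1180, BL 1410, HER2
uncapped) so the four subtype tile pools are roughly balanced; WSIs with
fewer admitted tiles keep them all, and WSIs with none are flagged and
abstain from prediction.

**Subtyping.** Four one-vs-rest (OvR) binary tile classifiers are trained,
each on all target-class tiles plus one third of the target count drawn
from each other class (quotas sum exactly to the positive count, so the
binary task is balanced; short strata are not re-weighted). Per classifier
a decision threshold is selected on validation tiles by precision–recall
analysis: every distinct score is tried as a cutoff (positive iff score ≥
cutoff) and the F1-maximizing cutoff is chosen, ties broken toward higher
recall, then toward the lower threshold. F1 maximization is the canonical
reading of "balancing precision and recall"; the selected threshold can
never have lower validation F1 than the fixed 0.5 cutoff. AUPRC uses
step-wise (right-continuous) interpolation, avoiding the optimism of
linear PR interpolation. Each WSI is then summarized by eight counts —
#{tiles: s_c ≥ τ_c} and its complement per class; the complement is used
for the ¬c count because the two-score softmax makes independent
thresholding of the rest score redundant — and an XGBoost multi-class
model maps the counts to the slide label. Raw counts (not fractions) are
the canonical features; a config flag can append n_tiles-normalized
fractions since raw counts confound WSI size.

**Meta-model defaults.** 400 rounds, depth 3, learning rate 0.05, early
stopping on an inner validation fold (a rounded per-class 20% allocation
that always leaves at least one training slide per class, so cohorts with
a handful of slides per class remain trainable). Two defaults matter at
small slide counts: `min_child_weight = 0`, because with ~3 slides per
class the soft-prob hessian sum of a pure leaf is far below XGBoost's
default floor of 1 and no split would ever be accepted; and
`colsample_bytree = 0.25` with `subsample = 0.63`, because a tiny training
set often contains several perfectly separating features of very different
margin and a single greedy tree picks one arbitrarily — subsampling makes
the ensemble spread over redundant count features, which measurably
stabilizes held-out accuracy.

## Stain normalization

Macenko estimation with the original method's conventional constants
(exposed in config): background OD threshold β = 0.15, stain vectors at
the 1st/99th percentile angles (α = 1) of the OD cloud projected on its
top-2 singular plane, concentration scale at the 99th percentile. OD uses
a +1 offset before the log (−log((p+1)/256)) to avoid log(0). Columns are
sign-fixed to nonnegative OD and ordered so the hematoxylin-like vector
(larger blue-channel OD) is first. Per-pixel nonnegative least-squares
concentrations are solved in closed form (unconstrained solution when
feasible, else the better single-stain active set), vectorized over
pixels; this is exact for the 2-stain case and is verified against
`scipy.optimize.nnls` in the tests. An OD cloud whose second singular
value is below 2% of the first is rejected as single-stain: the nominal
1° extreme-angle criterion alone misses rank-1 clouds because pixel
quantization spreads the projected angles by a few degrees.

Normalization maps a tile's concentrations (against its own estimated
matrix) through the reference matrix after matching each stain's 99th
percentile to the reference scale. Near-white tiles (mean > 240 in every
channel) pass through unchanged with a logged skip. One reference profile
is estimated once from a mosaic (row-major, near-square grid — any layout
yields the same pixel population) of one random tumor tile from each of
256 randomly chosen WSIs and reused everywhere; per-batch re-estimation is
deliberately not done.

## Tile classifiers

`TileClassifier` follows the scikit-learn estimator API over a pluggable
backbone registry. The default "tiny" backbone is two 3×3 conv blocks
(8 and 16 filters, ReLU, max-pool), dropout 0.33 on the flattened
features, and a linear softmax head, implemented directly on numpy with
im2col convolutions and exact backprop (gradient-checked against finite
differences). Training: Adam, cross-entropy, random horizontal/vertical
flips and rotations (restricted to multiples of 90° to avoid interpolation
artifacts), per-epoch train/validation loss logging, and restoration of
the minimum-validation-loss checkpoint (epoch counts and stopping rules
are free parameters; max_epochs and the checkpoint rule are the package's
choice). Inference applies no dropout and no augmentation and is
deterministic. Default learning rate is 1e-3 (2e-3 in the pipeline
presets): appropriate for a small network trained from scratch. The
hyperparameter presets used with large pretrained backbones in the
literature (batch 64 / lr 1e-5; batch 128 / lr 5e-6, dropout 0.33) are
kept as `TUMOR_PRESET` / `OVR_PRESET` for users who register such a
backbone; deep GPU-scale architectures are intentionally out of scope.

## Synthetic cohorts

The generator (`synthdata`) emulates the *structure* of a multi-center
slide cohort, not histology itself: patients → WSIs → tiles, four subtype
labels, and a tumor/non-tumor tile mixture per WSI (default 70% tumor;
non-tumor mass split 55% stroma, 20% normal epithelium, 15% white, 5%
marker ink, 5% folds — stroma dominating, epithelium and folds rare, as on
real slides). Tiles are rendered through the Beer–Lambert law,
`pixels = round(255·exp(−S·C))` plus Gaussian read noise, with S the 3×2
H&E optical-density matrix (conventional hematoxylin/eosin vectors by
default) and C a hematoxylin field of Gaussian nuclear blobs plus a
smooth eosin background. The eosin field's modulation reaches zero in
patches so that nearly-pure pixels of each stain exist — the geometric
assumption behind extreme-angle stain estimation. Read noise defaults to
sd 1.0 intensity levels; larger values bias the percentile-angle extremes
at low OD.

The subtype signal is planted as monotone shifts of nuclear-blob density
and radius: class k (offsets −1, −1/3, +1/3, +1) has density
32·(1 + 0.75·s·offset) blobs per 64² px and radius 2.5·(1 + 0.25·s·offset)
px, with s = `signal_strength`. At the default s = 1 adjacent classes are
separable by a small CNN at ≈0.95+ tile accuracy (the signal survives
stain normalization because it is spatial, not colorimetric); at s = 0 the
four class-conditional distributions are identical, which the tests use as
a leakage guard. Tile size defaults to 64×64 for desk-scale training; the
tiling module still supports 512. One integer seed drives a splittable RNG
hierarchy (cohort → WSI → tile), so any subset is reproducible.

What passing tests do and do not show: they demonstrate that the pipeline
machinery — filtering, normalization, OvR decomposition, thresholding,
count aggregation, splitting, evaluation — is correct and recovers planted
signal end-to-end; they say nothing about the strength of real
morphology–subtype associations, scanner variation beyond stain-matrix
perturbation, intratumoral heterogeneity, or label noise in PAM50/IHC
assignments, none of which the generator models.

## Splits and hygiene

Patients are atomic: all WSIs of a patient land in one of CNN-train /
CNN-val / meta / test (fractions 0.70·0.80, 0.70·0.20, 0.15, 0.15),
allocated per class by largest remainder after a seeded shuffle, with a
guarantee of at least one patient per outer split and an error below 3
patients per class. Multi-WSI patients are assigned wholly, accepting a
small stratification error — patient exclusivity dominates exact
stratification. Leakage (patient or WSI in two splits) is re-checked on
every pipeline run. In the pipeline the patient split is computed first
and the tumor classifier is trained only on CNN-split patients (in the
original study design the tumor model comes from a separate annotated
cohort; with a single synthetic cohort, training it before splitting would
leak test patients into a learned component).

## Evaluation

Per-class metrics are one-vs-rest reductions of the K×K confusion matrix;
zero-denominator metrics return 0 with a flag. Macro averages are
unweighted means; with imbalanced cohorts "macro-average accuracy" is read
as macro recall (the mean of per-class accuracies, i.e. recalls).
Confidence intervals: nonparametric percentile bootstrap, B = 1000 by
default, resampling WSIs (the independent units); degenerate resamples
missing a class are redrawn up to 10·B total draws and then skipped with a
reported count; an error is raised if more than half are undefined.
Coverage of the 95% recall interval is verified by simulation to sit in
(0.90, 0.99). PR curves are preferred over ROC for the imbalanced slide
cohorts. Display rounding is 3 decimals; internals keep full precision.
WSIs with no admitted tumor tiles abstain and are excluded from the
confusion matrix, with the abstention count reported.

## Problem sizes and defaults used in tests

The end-to-end recovery experiment uses 4 classes × 20 patients × 1 WSI ×
60 tiles at 64×64 with strong signal (s = 1), tiny backbone, 5 tumor
epochs and 24 OvR epochs — chosen as the smallest cohort at which the
slide-level meta-classifier has three training slides per class and the
hold-out split has 12 WSIs. The null-signal control runs the same pipeline
at s = 0 with shorter training (3/4 epochs): chance-level performance does
not depend on convergence, and any above-chance result would indicate
leakage regardless of epoch count. The bootstrap coverage simulation uses
200 cohorts of 100 WSIs with true focal-class recall 0.7.

## Known limitations

- The tiny backbone is not a substitute for modern pretrained CNN features
  on real histology; the backbone registry is the extension point.
- Tissue detection is threshold-based; heavily hemorrhagic or faintly
  stained material would need tuned thresholds.
- Macenko estimation assumes two stains and some nearly-pure pixels of
  each; single-stain or heavily inked tiles are rejected (and passed
  through unnormalized by the pipeline rather than dropped).
- The generator plants a one-dimensional morphology axis (density/radius);
  real subtype signal is higher-dimensional and weaker.
- Raw-count slide features confound tumor area with class evidence;
  fraction features are available behind a flag but off by default to
  keep the canonical feature definition.
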