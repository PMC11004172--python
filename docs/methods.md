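# Methods

## Data model

A sample is an `EventMatrix`: n ≤ 250,000 events × 12 channels in instrument
units, with the fixed ALOT panel (8 fluorescence, 4 scatter). Cell-type
labels use a frozen 16-class vocabulary — 9 physiological classes (B-lym,
T-lym, Neu, Mono, Ery, Eos, NK, CD34posM, CD34posB), debris, and 6
pathological classes (AML-CD34pos/neg, B-ALL-CD34pos/neg, T-ALL, BCLPD) —
and patient diagnoses a frozen 5-class vocabulary (Normal, AML, B-ALL,
Complex, Other). Both orders are stable across compositions, classifier
outputs and reports.

### FCS subset

The codec emits FCS 3.1, `$DATATYPE=F`, `$MODE=L`, little-endian, and reads
FCS 3.0/3.1 float list mode (either byte order). Write→read round-trips are
value-preserving to float32 precision and order-preserving. Channels are
located by `$PnS` (stain name) first, `$PnN` second, through a
case-insensitive pattern table, because vendors name the same conjugate
differently; the claim order resolves substring collisions (CyCD79a before
CD7, cytoplasmic/surface CD3 before CD7). Header byte offsets, when nonzero,
must agree with the TEXT-segment offsets, and the DATA length must equal
`$TOT·$PAR·4`; NaN/Inf in the data segment is rejected. Compensation and
spillover are out of scope: values are read as stored. Per-event labels
travel as CSV sidecars (`event_index,label`); events without a sidecar row
default to `debris`.

### Transforms

Fluorescence is arcsinh-transformed with cofactor 150 (standard for
conventional cytometry: linear near zero, logarithmic above), scatter is
scaled linearly to [0, 1] by the instrument full scale 262,144. All models
and templates operate in this transformed space.

## Synthetic ALOT cohort simulator

Each cell class is a multivariate Gaussian in transformed space (default
diagonal; per-channel SD 0.25 fluorescence / 0.04 scatter; debris broader at
0.30 / 0.05), truncated at the instrument floor (and scatter ceiling) and
back-transformed to instrument units. Template locations encode canonical
marker logic — e.g. T-lym SmCD3+/CyCD3+/CD7+/CD45-high; Neu SSC-high/MPO+;
blasts CD34±/CD45-dim; T-ALL CyCD3+/CD7+/SmCD3−/CD45-negative (its key
diagnostic contrast with invariably CD45-positive normal T cells);
AML-CD34neg is identical to AML-CD34pos except the CD34 channel. Negative /
dim / positive / high levels are 0.5 / 2.3 / 4.5 / 5.1 arcsinh units,
roughly 50 / 740 / 6,700 / 12,000 instrument units — typical positions for
this kind of 8-color panel.

A patient draws its class composition from a diagnosis-specific Dirichlet
prior and event counts from a multinomial. The priors are shaped like
clinical samples: Normal is neutrophil-dominated with ~1% CD34+ precursors;
AML/B-ALL carry a large blast fraction split over CD34+ and CD34− subclones
with suppressed normal hematopoiesis; Complex is the possible-MDS group,
modeled as a Normal composition with an abnormal CD34+ myeloid-precursor
excess (the only cytometric definition available for that clinical label);
Other mixes T-ALL and BCLPD with normal background. Default n_events is
20,000 per patient (cap 250,000).

Two deliberate hard cases mirror practice: BCLPD overlaps mature B cells,
and the CD34-negative blasts sit near physiological confusers. A
`separation` scalar in (0, 1] interpolates the hard-case templates
(AML-CD34neg → Mono, B-ALL-CD34neg → BCLPD, BCLPD → B-lym, resolved against
the already-shrunk anchor so collapsing templates collapse together) toward
those confusers; at ~0.02 the CD34-negative blast classes are essentially
indistinguishable per event, which is the regime used for the robustness
check.

Reproducibility: one global seed spawns per-patient child seeds through
numpy's `SeedSequence`, so any patient is independently reproducible and
repeated runs are byte-identical.

What the simulator does **not** emulate: spectral spillover, doublets,
acquisition-time drift, per-patient staining variation, and the
within-patient relative-expression structure a human gater exploits. Passing
tests therefore demonstrate correctness of the pipeline and learnability
under the stated noise model, not clinical performance on real cohorts. A
quadratic-discriminant oracle must reach ≥95% held-out accuracy on the
physiological classes before any CNN result is interpreted — this guards
against blaming a model for an unlearnable simulation.

## EverFlow (per-event classifier)

Each event is a length-12, single-feature 1-D signal in fixed panel order.
The default stack is three Flow Blocks (Conv1d → BatchNorm1d → ReLU →
optional MaxPool1d) with widths 32/64/128, kernel 3, pooling after blocks 1
and 2 (12 → 6 → 3 positions), then adaptive average pooling and a dense
16-class softmax head — exactly 3 convolutional, 3 batch-norm and 2 max-pool
layers, asserted structurally. The signal-axis interpretation (convolution
over the channel axis) makes channel order part of the model contract; it is
frozen in the panel definition.

Training: Ranger — the published composition of RAdam (variance-rectified
warmup) and Lookahead (k = 6, α = 0.5) — at lr 5e-3, batch 256, at most 75
epochs, early stopping on a 10%-carve-out validation loss with patience 10
and best-weights restoration. The validation loss is unweighted (the
carve-out may miss rare classes); the training loss uses inverse-frequency
class weights by default because clinical class imbalance reaches ~100:1.
Argmax ties break to the lowest class index. An Adam fallback is available
behind the `optimizer` flag.

## Patient-level classifiers

**Phase I (raw event clouds).** A variable-length event list cannot enter a
CNN directly; each sample is rendered into P = 6 stacked 64×64 2-D
histograms over the canonical gating views (CD45×SSC-A, CD34×CD45,
CD19×CyCD79a, CyCD3×SmCD3, CyMPO×SSC-A, CD7×SmCD3) on fixed per-channel
ranges (arcsinh 0–8.2, scatter 0–1), so images are comparable across
patients and invariant to event order; events are clipped into range, making
each plane's raw count sum exactly n_events. Counts are log1p-compressed and
scaled to unit maximum per plane. The default classifier is a compact
residual CNN (stem conv + two basic residual blocks, ~10 learnable layers,
global average pooling); a 50-layer bottleneck stack (3/4/6/3 blocks,
ResNet-50-style) is available behind `variant="resnet50"` for fidelity at
much higher cost. Downsampling uses max pooling rather than strided
convolution (the convolutions in this framework are stride-1).

**Phase III (composition).** Features are the 16 class fractions, optionally
concatenated with the 16×12 per-class median transformed intensities (192
extra features, the "with channels" variant). Medians were chosen over means
for robustness in heavy-tailed fluorescence data; absent classes contribute
a zero row plus a presence mask rather than imputation, so the model can
learn absence. The classifier is a dense residual stack (width 64; 2 blocks
in the tiny variant, 16 in the deep variant). Composition-only input is by
construction invariant to the event count.

Both phases share the training protocol of Phase II (optimizer, weighting,
early stopping) with batch 16.

## Evaluation protocol

Stratified 80/20 train/test split (scikit-learn `StratifiedShuffleSplit`)
plus stratified 5-fold assignment of the training portion; every training
sample is validated exactly once across folds, fold sizes differ by ≤1
within each stratum, and a stratum smaller than k raises rather than
silently degrading. Any overlap between training and test sample ids is a
hard failure. Metrics are one-vs-rest per diagnosis from a single 5-class
softmax (not five separate binary models): accuracy, sensitivity,
specificity, F1. Ratios with zero denominators are reported as
not-applicable (`None`), never NaN. Displayed percentages are rounded
half-up to one decimal with raw fractions retained.

## Numerical framework

All networks run on a small numpy layer framework with hand-derived
backpropagation (stride-1 'same' convolutions in 1-D/2-D via sliding-window
einsum, batch normalization with running moments, non-overlapping max
pooling with argmax routing, residual wrappers, weighted softmax
cross-entropy). Every layer type is gradient-checked against central finite
differences (tolerance 1e-6 on a scale-aware relative error). Training is
deterministic given the seed (single-threaded numpy; the shuffle, init and
carve-out all derive from the configured seed).

## Problem sizes

Default test/demo scale was chosen to keep the full pipeline comfortable on
one CPU: 100-patient cohorts (20 per diagnosis) at 3,000 events/patient,
per-event training pools capped at 2,000 events/class, and the tiny model
variants. The end-to-end run takes ~3 minutes; the acceptance recomputation
(two full pipelines plus the metric worked examples) ~5 minutes. Larger
cohorts and the 50-layer variant scale the same code paths.

## Known limitations

* Clinical ALOT cohorts are not publicly available; all learning results in
  the test suite are statements about the simulator's noise model.
* Phase II pools events across patients, losing within-patient relative
  expression (a population is defined partly relative to its neighbors);
  the composition features likewise discard per-patient normalization.
* The "Complex" group has no precise cytometric definition; its simulated
  phenotype (CD34posM excess) is one plausible reading and the hardest class
  in every report, as expected for a possible-MDS screening category.
* Whether Phase I's raw-event input could alternatively be consumed as an
  events×channels matrix is undecidable from the available description; only
  the density-image path is implemented.
* The FCS codec intentionally covers the float list-mode subset only — no
  FCS 2.0, integer gain encodings, or compensation keywords.
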