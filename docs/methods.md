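# Methods

`nirsgait` re-implements, end to end, a pipeline for classifying walking-task
conditions in older adults from prefrontal fNIRS: synthesize (or ingest) raw
dual-wavelength intensity recordings, preprocess them into baseline-corrected
hemoglobin task epochs, encode each epoch as a 3 x 224 x 224 image, and
classify the three conditions — single-task walking (STW), dual-task walking
(DTW, walking while reciting alternate alphabet letters) and standing
recitation (STA) — with a cross-validated learning harness, traditional
baselines and an ablation suite.

## The measurement model

The simulated instrument is a continuous-wave forehead sensor: 16
source–detector channels ("voxels", 2.5 cm separation) sampled at 2 Hz at two
wavelengths (730 and 850 nm). Light attenuation follows the modified
Beer–Lambert law (MBLL),

    ΔOD(λ, t) = log10( I0(λ) / I(λ, t) )
              = [ ε_HbO2(λ) ΔHbO2(t) + ε_Hb(λ) ΔHb(t) ] · d · DPF(λ),

a 2 × 2 linear system per sample whose inversion recovers the oxy- and
deoxy-hemoglobin concentration changes (µM). Extinction coefficients come
from the standard compiled hemoglobin spectra (730 nm: 390 / 1102.2; 850 nm:
1058 / 691.32 cm⁻¹ M⁻¹) and the differential pathlength factor from the
general age- and wavelength-dependent equation (≈ 7.5 / 6.4 at 730 / 850 nm
for a 76-year-old). These enter only as a unit system: the forward model and
the inversion share one `OpticalParams` table, and the package property-tests
that the inversion is the exact algebraic inverse of the forward model
(≤ 1e-8 relative error) for *any* invertible extinction matrix.

## The synthetic cohort

The study population the pipeline targets is not publicly deposited, so the
generator reproduces its reported statistical structure rather than any
individual recording:

* **Protocol.** One session per subject: one block per condition in a
  counterbalanced order (Latin-square cycling over the six permutations by
  subject index), each preceded by a 10-s proximal baseline. STA lasts
  exactly 30 s; STW/DTW durations are lognormal (medians 45 s and 60 s,
  log-sd 0.25, truncated to [20, 180] s) scaled by a per-subject pace factor,
  so DTW takes longer than STW on average and both are right-skewed.
* **Response.** Condition-specific mean shifts in HbO2 (STW 0, STA 0.5,
  DTW 1.0 µM) and small negative Hb shifts, entering through a 10-s linear
  onset/offset ramp and scaled by lognormal per-subject and per-voxel gains.
  The shape is deliberately minimal — only the marginal distributions are
  constrained by the source data — and the HbO2 ordering STW < STA < DTW and
  the larger DTW spread (noise sd 0.3 vs 0.2 µM, AR(1) with ρ = 0.9) are the
  invariants the generator must satisfy.
* **Nuisance structure.** Slow drift (0.15 µM, ~400 s), Mayer waves
  (0.05 µM at 0.1 Hz), respiration (0.03 µM at 0.25 Hz), an aliased cardiac
  component, multiplicative detector shot noise (0.3%), Poisson motion
  spikes (0.25 × I0), saturation and dark-current episodes, and per-voxel
  hardware dropouts (p = 0.05, Binomial across the 16 voxels).
* **Demographics.** Age ~ N(76.16, 6.67²) clipped at 65, 49.4% female,
  cognitive index ~ N(91.77, 11.71²); these ride along as epoch metadata and
  can optionally be fused into the classifier.

Concentration amplitudes are arbitrary µM-scale units: the emulated
histograms publish no absolute scale, so none is claimed. A single master
seed drives everything; per-subject and per-stage streams are derived by
fixed offsets, which makes any sub-computation bit-reproducible in
isolation.

What the generator does **not** emulate: spatial correlation between voxels
(each has an independent gain and noise stream), realistic hemodynamic
response kinetics (no basis-function HRF, no undershoot), systemic
physiology shared across voxels, or gait-cycle structure. Passing tests
therefore certify the pipeline's mechanics and its behavior under the
reported marginal statistics — not classification performance on real
cohort data.

## Preprocessing

Stages run in the published order, each applied identically to both
chromophore streams; all are deterministic.

1. **Voxel screening** replaces the study's human visual inspection with a
   deterministic surrogate: a voxel is dropped when either wavelength sits
   at/above 98% of the detector ceiling or at/below a 2% dark floor for
   more than 1 s, or when its first-difference sd exceeds 10× the median
   voxel sd. If all 16 voxels fail, the recording is rejected.
2. **Wavelet artifact removal** (db5, level 5, symmetric extension) zeroes
   detail coefficients whose magnitude exceeds 3 robust standard deviations
   (MAD-based, per level) — in the three finest levels only (≥ 0.125 Hz at
   fs = 2 Hz). Spiky artifacts are broadband and are caught there; the
   hemodynamic band lives in the approximation and coarse-detail levels,
   which are left untouched. Screening all five levels measurably clips
   genuine response edges, which is why the coarse levels are exempt.
3. **MBLL inversion** as above. If no reference intensity is configured, the
   per-channel mean over the initial rest is used; the proximal-baseline
   correction later removes any residual offset, so the choice of reference
   only fixes the zero point.
4. **Spline filtering** (p = 0.99) has two parts. (a) *Artifact windows*:
   sample-to-sample jumps beyond 8 robust sd of the first differences —
   required to also tower ≥ 3× over neighboring differences, so smooth
   ramps never qualify even in the noiseless limit — are corrected by
   subtracting the within-window near-interpolating spline and re-leveling
   the subsequent data for continuity. This removes both transient spikes
   and persistent baseline jumps. (b) *Trend removal*: the cubic smoothing
   spline in the classic p-convention, evaluated on a time axis normalized
   to the record length (penalty scaled by n so the trade-off is
   sampling-density independent), is subtracted. At p = 0.99 this keeps only
   record-scale structure: linear drifts are removed exactly while 30–60-s
   task responses pass through ~85–90% intact. A globally near-interpolating
   spline is *not* usable here: block-shaped responses cost no curvature, so
   it would absorb the signal itself (~99% measured) — the reason the
   correction is windowed.
5. **FIR low-pass**: 100-tap Hamming-window sinc, 0.08 Hz cutoff at 2 Hz
   (unit DC gain; ≥ 50 dB attenuation at the 0.25 Hz respiration band).
   Zero-phase by default: the group delay of 49.5 samples is compensated by
   a 50-sample shift after reflection padding; the residual half-sample
   (0.25 s) misalignment is negligible below the cutoff, where a causal
   application would instead shift epochs by 25 s. A causal mode is
   provided.
6. **Epoch extraction** cuts one epoch per block over the half-open sample
   interval [round(fs·start), round(fs·end)), so a T-second task yields
   2T samples; epoch geometry depends only on the markers, never on the
   filters.
7. **Baseline correction** subtracts, per voxel and chromophore, the mean of
   the 10-s proximal baseline preceding each task.

End-to-end verification compares the pipeline against the generator's
ground-truth concentrations pushed through the identical
detrend/low-pass/baseline chain (agreement ≤ 2%), plus recovery of ≥ 75% of
the configured condition shifts with the ordering intact. Full shift
recovery is not a meaningful target: trend removal, FIR edge smear and
baseline contamination jointly attenuate block means by ~10–15% under *any*
faithful implementation of this chain.

## Image encoding

Epochs with more than 3 missing voxels are screened out; the remainder are
imputed to 16 rows by linear interpolation over voxel index (nearest valid
row at the edges), stacked as (HbO2, Hb, HbO2 − Hb) — the third channel is
the oxygen index; HbO2 + Hb is the ablation variant — and brought to
224 × 224. The time axis keeps the first 224 samples and zero-fills the rest
(the padding boundary intentionally encodes completion time and pace;
resampling to 224 is the ablation variant). The 16 voxel rows are expanded
by bilinear or bicubic interpolation (with or without corner alignment,
half-pixel convention otherwise) or by exact 14× interleave repetition —
five configurations in all. Hemisphere ablations (voxels 1–8 left, 9–16
right) zero rows *before* row resizing so interpolation cannot leak signal
across the boundary; channel ablations zero a channel of the final image.
Imputation runs per chromophore before the third channel is formed, so the
diff identity ch2 = ch0 − ch1 survives imputation exactly.

## Learning harness

The trainable model is a compact numpy CNN (`ToyCNN`): fixed 8× average-pool
stem (224 → 28), two 3 × 3 convolution blocks (8 and 16 maps, ReLU, 2×
average pooling), global average pooling and a linear 3-way head (~1.4k
parameters), trained with softmax cross-entropy and Adam at the protocol's
fixed learning rate 0.001. Optional covariate fusion concatenates the two
standardized subject covariates (gender, cognitive score) to the penultimate
features. Defaults: batch 16, up to 60 epochs, early stopping with patience
10 monitoring training accuracy (optionally an inner stratified validation
split via ``val_fraction``), best-epoch weights restored; per-channel
z-scoring uses training-split statistics only. The inference fold is never
used for model selection — monitoring it would inflate reported inference
accuracy through best-epoch selection, visibly so under label-permutation
controls. Batch/epoch settings were chosen for stable convergence in the
~240-training-sample regime; reported "train accuracy" is the best-epoch
value.

Evaluation uses stratified 5-fold cross-validation in which each fold serves
in turn as the 20% inference set (realizing the 8:2 split), with mean ± sd
of train and inference accuracy, the 3 × 3 confusion matrix and per-class
precision/recall/F1 (zero-denominator classes reported as 0 and flagged).
Traditional baselines — decision tree, random forest (25 trees), k-NN
(k = 5) — run under the identical fold protocol on images average-pooled to
3 × 16 × 28 and flattened (1,344 features; raw flattening available).
Binary classifiers for the three condition pairs reuse the same protocol
with a 2-way head.

The named backbone architectures (ResNet-18/26, VGG-13/16, MobileNetV2-050,
EfficientNet-B0, TinyNet-E, ViT-Base/Tiny) are implemented as exact
layer-by-layer parameter-accounting tables validated against the published
1000-class totals of their reference implementations. `adapt_head` swaps the
classifier for an n-class head and `count_params` reports the trainable
count and float32 storage (4 bytes/parameter, MiB). Pretrained weights are
not bundled; requesting them falls back to fresh initialization with a
warning. The ablation suite re-encodes the epochs per variant (channel
drops, hemisphere drops, third-channel kind, pretraining flag, time mode,
the five resize configurations) and cross-validates each under one shared
protocol, emitting a provenance-tagged table.

## Numerical and design notes

* Epoch timing uses 0-based sample indices and half-open intervals; markers
  in seconds are rounded to the nearest sample. Voxel names are 1-based.
* The jump detector's isolation rule (jump > 3× the median neighboring
  difference) is what separates instantaneous baseline steps from the
  generator's 10-s ramps; a clean step is leveled > 99%, a noisy one ≥ 90%.
* Smoothing-spline p maps to the solver's penalty as λ = n·(1 − p)/p on the
  unit-normalized time axis; p = 1 is the interpolant limit (detrend output
  is then the mean-centered input of the artifact-corrected series).
* Degenerate inputs: all-flagged recordings raise a rejection signal;
  screening-rejected epochs yield no image and are counted; evaluation of an
  empty set raises; a single-class training set raises.
* Simulation sizes: the end-to-end learning checks use 100 subjects
  (300 epochs), matching the scale at which the cohort-marginal invariants
  are specified; unit-level property tests run at much smaller n.

## Limitations

* Only `toy_cnn` is trainable; the backbone zoo supports cost accounting,
  head adaptation and provenance, not fine-tuning. Published cohort
  accuracies are not reproduction targets — the underlying data is
  proprietary.
* No short-separation-channel regression or systemic-physiology correction;
  no spatial encoding of sensor geometry beyond the fixed row order.
* The windowed spline correction handles isolated jumps; slowly growing
  motion artifacts within the hemodynamic band are not separable by any
  stage of this chain and survive preprocessing.
* Because the third image channel is the oxygen index HbO2 − Hb, the three
  channels are linearly dependent: zeroing any single channel removes no
  information, only redundancy. Single-channel ablation differences
  therefore reflect how a given model copes with the remaining channel
  geometry rather than information content; axis-aligned learners (the
  tree-based baselines) are the cleaner probe of where the signal lives.
* A single label-permutation control is biased above chance by the
  permutation draw's accidental class-label contingency whenever the model
  can recognize the latent condition; permutation controls here average
  over several independent draws.
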