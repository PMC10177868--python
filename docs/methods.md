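# Methods

## Problem

The package quantifies pesticide-residue content (µg/g) on fruit surfaces
from visible/near-infrared diffuse-reflectance spectra (380–1140 nm),
replacing gas-chromatography reference measurement with a rapid,
nondestructive optical calibration. The core model is a one-dimensional
convolutional neural network ("Deepspectra") in two variants — a
single-scale network with one convolution channel, and a multiscale network
with three parallel channels whose feature maps are fused by concatenation
along the length axis — compared against the two conventional chemometric
models, partial least squares regression (PLSR) and RBF-kernel support
vector regression (SVR).

## Pipeline

1. **Reflectance calibration.** Raw counts are converted to reflectance with
   white/dark reference scans, `R = (raw − dark) / (white − dark)`. The
   operation fails loudly, naming the wavelength, wherever `white ≤ dark`.
2. **Replicate averaging.** Four replicate spectra per sample (configurable)
   are averaged into one sample spectrum.
3. **Resampling.** Spectra are linearly interpolated onto a uniform
   1000-point grid spanning the instrument range. The native grid has 1101
   points (~0.69 nm); the network input is fixed at 1000, and interpolation
   (rather than truncation) is this package's choice. Resampling precedes
   the derivative so the uniform-spacing precondition of the filter holds.
4. **Savitzky–Golay first derivative,** window 5, polynomial order 2, in
   reflectance per nm (the filter output is divided by the grid spacing).
   The signal is mirror-padded so length is preserved; interior points are
   identical to the local least-squares fit and are the only points the
   oracle tests rely on.
5. **Dataset division.** Interval sampling by content rank: each block of 5
   consecutive ranks contributes 3 samples to calibration, 1 to validation,
   1 to prediction (60/20/20 on 100 samples). Ranks are ordered by
   (content, sample id), so the division is deterministic and invariant to
   row order. Placing rank 1 in calibration guarantees the calibration set
   contains the global minimum; by default the global maximum is swapped
   into calibration if the block rule put it elsewhere, so the calibration
   range covers the other sets entirely. SD uses the n−1 denominator.

## Networks

Each convolution channel is Conv → BN → ReLU → MaxPool, twice. Convolutions
use valid padding and stride 1 (length `l → l − k + 1`), pooling is 2:1
valid (length `l → ⌊l/2⌋`). The single-scale network uses 32 kernels per
convolution; the multiscale network uses 16 per convolution in each of the
three channels, with kernel pairs (7,5), (7,3), (5,3), and concatenates the
channel outputs along the length axis (depths equal, lengths add). The head
is Flatten → BN → FC(16, ReLU) → FC(1, linear). On a 1000-point input the
single-scale (5,3) network flattens to 32 × 248 = 7936 features and the
multiscale network to 16 × (246 + 247 + 248) = 11 856. The shape-trace
routine performs this arithmetic exactly and is cross-checked at runtime
against the built model's flatten activations.

Choices where the architecture description is ambiguous: BN sits between
convolution and ReLU (the dominant convention; `bn_placement` can flip it);
the hidden FC layer uses ReLU (only the output layer is explicitly linear);
the post-flatten BN sits immediately after Flatten, before FC(16). Weights
are initialized Kaiming-uniform on fan-in with a recorded seed; the engine
is float32 (float64 available for gradient checking) and fully
deterministic given the seed on one CPU.

The network engine (convolution, batch normalization, pooling, dense
layers, reverse-mode gradients, Adam) is implemented in NumPy within the
package; its gradients are verified against central-difference numerical
differentiation in the test suite.

## Training protocol

Adam (lr 0.005, β = (0.9, 0.999), ε = 1e−8, no weight decay) on MSE in
µg/g², batch size 16 with shuffled calibration batches, exactly 100 epochs,
no early stopping. Validation MSE is computed once per epoch in evaluation
mode over the full validation set, and the weights kept are those of the
epoch with minimum validation loss (earliest on ties). A trailing
single-sample batch is merged with the previous batch because BN needs at
least two samples.

Two numerical-stability measures are this package's own additions:

* **Input scaling** (default `'global'`): each wavelength is centered on
  its calibration-set mean and all wavelengths are divided by one pooled
  standard deviation, preserving relative band magnitudes. Derivative
  spectra are ~1e−3 in magnitude, which makes conv feature variances ~1e−6;
  Adam's per-step parameter drift (~lr) then exceeds the feature scale by
  orders of magnitude and the BN running statistics can never track
  training — evaluation-mode predictions collapse to a constant. Scaling
  the input to O(1) removes the pathology; a full per-wavelength z-score is
  also available but amplifies pure-noise wavelengths. Target values stay
  in µg/g: standardizing them was tried and rejected (it induced immediate
  overfitting with early, poor validation minima).
* **Batch-norm recalibration** (default on): after the best weights are
  restored, BN running statistics are re-estimated with one full pass over
  the calibration set ("precise BN"). The mini-batch EMA is a noisy
  estimate taken along a moving training trajectory; recalibration improved
  calibration-set R² consistently across seeds without systematic change to
  prediction R².

## Baselines

PLSR operates on mean-centered, unscaled data (NIPALS-style components via
scikit-learn); the number of latent variables (1..20 by default) minimizes
validation RMSE, earliest on ties. SVR uses an RBF kernel with ε = 0.1 and
a log₂-spaced grid 2⁻⁸…2⁸ for both the penalty `c` and kernel width `g`,
selected by validation RMSE with ties broken toward smaller `c`, then
smaller `g`. Both baselines consume exactly the same preprocessed spectra
and splits as the networks.

## Evaluation

R² = 1 − SSE/SST (SST about the mean of the reference values; may be
negative), RMSE in µg/g, and RPD = (1 − Rp²)^{−1/2} from the prediction-set
R². RPD bands (left-closed): < 1.5 no predictive value, 1.5–2.0 initiatory,
2.0–2.5 admissible, 2.5–3.0 suitable, ≥ 3.0 sufficient. Reports are rounded
to three decimals at reporting time only. A perfect prediction set (Rp² = 1)
is flagged with an infinite RPD rather than an error.

## Synthetic data

Real pesticide-residue spectra are not distributable, so the generator
emulates their statistical structure: a smooth low-order-polynomial
baseline rising toward the NIR, multiplicative Gaussian absorption bands at
420 and 675 nm (chlorophyll, depths 0.30/0.35), 835 nm (C–H third
overtone, 0.08) and 975 nm (water, 0.35), per-sample multiplicative
scatter (SD 1%), additive reflectance noise (SD 0.002 per replicate, a
realistic figure for a miniature fiber-optic spectrograph after scan
averaging), four replicates per sample, and contents drawn uniformly on
0.96–32.36 µg/g (a three-cluster mode mimicking dilution groups is
available). The analyte signal is a planted Gaussian band at 835 nm
(σ = 12 nm) whose fractional depression is 0.004 per µg/g — chosen so the
derivative-domain signal-to-noise ratio per wavelength is ≈ 8 at mid-range
content, i.e. recoverable but not trivial. Raw counts are produced by
inverting the white/dark calibration, so the calibration step recovers the
simulated reflectance exactly (to machine precision when noise is zero).

The planted band is a testing convention, not a claim about where real
pesticide signal lives; the generator also omits instrument drift,
wavelength-correlated noise, melon-to-melon rind variability beyond a
scalar scatter factor, and any nonlinear matrix effects. Passing tests
therefore demonstrate that the pipeline recovers a recoverable signal under
controlled conditions — not field performance on real produce.

Because the planted response is linear in content, the synthetic problem is
*easier* for linear chemometrics than the real one: PLSR reaches Rp² ≈ 0.99
while the CNNs reach ≈ 0.8 under the fixed 400-step training budget. The
published comparison (CNN > PLSR on real data) is a property of the real
spectra and is not expected, or asserted, on this generator; what is
asserted is the architecture ordering (multiscale ≥ single-scale median
prediction R²) and absolute recovery thresholds.

## Problem sizes and determinism

The end-to-end checks train on the default study: 100 samples, 60/20/20
split, 1000-point inputs, 100 epochs — about 20 s per multiscale run on one
CPU; the acceptance test suite trains ten such runs (five seeds × two
architectures) and asserts medians over the fixed seed ensemble, which is
deterministic and robust to individual seed luck. Unit tests use scaled-down
networks (inputs of 32–128 points) and the float64 engine for gradient
checks.

## Known limitations

* The BN evaluation-mode gap makes single-run validation-epoch selection
  noisy on 20-sample validation sets; medians over a seed ensemble are the
  stable summary.
* PLSR latent-variable selection and SVR grids are validation-set driven
  (no nested cross-validation), matching the networks' epoch selection for
  comparability.
* The CLI reproduces byte-identical CSV artifacts for identical config and
  seed on a fixed machine/thread configuration; trained-weight files are
  not serialized by the CLI (metrics and predictions are the artifacts).
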