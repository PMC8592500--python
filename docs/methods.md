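# Methods

This note documents the models the package implements, the choices that were
genuinely open, and what the synthetic testbed does and does not show.

## The signal model behind the simulator

`eeggan.synthetic` draws each channel of a segment as

    x(t) = b(t) + Σ_bands a · sin(2π f t + φ) + a_line · sin(2π f_line t + φ_line) + ε(t)

where `b(t)` is 1/f^α-shaped Gaussian noise (α = 1 by default, unit standard
deviation scaled by `background_amp`), each class band `(center, bandwidth,
amplitude)` contributes one sinusoid whose frequency is drawn uniformly in
`center ± bandwidth/2` with a per-channel random phase, the mains component
has a common random phase across channels, and `ε` is white Gaussian noise
(`noise_sd`, default 0.5).

The two classes differ *only* through their band sets. Defaults place the
interictal class in the alpha/low-beta range (9 ± 1.5 Hz, 14 ± 1.5 Hz) and
the pre-ictal class in the beta/low-gamma range (21 ± 2 Hz, 36 ± 3 Hz) with
amplitudes 1.5–2.5 against unit background. These values were chosen once so
that (a) per-band log-power features are linearly separable with accuracy
> 0.9 over a few dozen segments — the learnability contract the rest of the
pipeline assumes — and (b) all centers sit far from the notch bands and
below Nyquist for every preset. The band-shift mechanism is a stand-in for
whatever distinguishes real pre-ictal dynamics; it is not a claim about
biology.

Reproducibility: every segment is drawn from a `SeedSequence` substream
keyed by `(seed, segment_index, class)`, so segment *i* is bit-identical in
isolation and across platforms using the same numpy generator.

Timelines place `n` onsets in the tail of the recording, spaced by more than
1.25 × (SPH + SOP); pre-ictal segments are tiled backwards from
`onset − SPH` and interictal segments only from regions at least 4 h from
every onset. Packing that cannot satisfy these constraints raises rather
than silently degrading.

What the simulator does **not** model: seizure morphology, artifacts (EMG,
eye blinks, electrode pops), circadian structure, inter-patient variability,
non-stationarity within a segment. A pipeline that passes here has been
shown to be *mechanically correct and able to learn a band-power contrast*;
nothing more.

## Preprocessing

Per segment: (1) zero-phase 4th-order Butterworth band-stop filters at
`line ± 3 Hz` and `2·line ± 3 Hz` (harmonic bands that would reach Nyquist
are skipped with a log message; an infeasible fundamental is an error);
(2) per-channel magnitude STFT with non-overlapping Hann windows (60 s
windows at full scale, 1 s in the desk configuration), using only complete
windows so the column count is exactly `floor(duration/window)`;
(3) channel spectrograms stacked vertically in channel order;
(4) log(1 + m) compression; (5) bilinear resize to S×S; (6) per-image
min-max normalization to [−1, 1] (a constant image maps to −1); (7)
replication to 3 identical channels.

Open choices, decided here and config-exposed: Hann window with FFT length
equal to the window; log before resize, normalization last; bilinear
interpolation; 3-channel construction by replication of the log-magnitude
(a colormap rendering would be non-invertible and palette-dependent). The
[−1, 1] range matches the generator's tanh head.

## The GAN

Full-size generator: latent 100 → dense 4096 → reshape 4×4×256 → six
stride-2 5×5 transposed convolutions (filters 256, then 128) → stride-1 5×5
convolution to 3 channels → tanh. The architecture description gives the
deconvolution filter counts and the output shape but not how the last
128-filter map becomes 3 channels; the trailing stride-1 convolution is this
package's resolution. Batch normalization and ReLU follow every layer but
the output. Discriminator: four stride-2 5×5 convolutions (256/128/64/32),
LeakyReLU(0.2), no batch norm, dense sigmoid head. Weights are initialized
N(0, 0.02), the common DCGAN convention.

Losses. The discriminator's two-term value
`(1/n)Σ[log D(x) + log(1 − D(G(z)))]` is ascended; as a minimized training
loss this is the binary cross-entropy over the real and fake half-batches,
`d_bce = −value/2` (the equivalence is unit-tested). The generator uses the
non-saturating form `−(1/n)Σ log D(G(z))`. A printed generator loss that
depends only on real data appears in the source description; it has zero
gradient with respect to the generator and is treated as a typo. All
probabilities are clamped at 1e−7 before logs.

Training: one discriminator step then one generator step per batch (the
ratio is unstated in the source; 1:1 is the default convention), batch 32,
Adam with β₁ = 0.5. Early stopping monitors the per-batch pair
(d_bce, g): a batch with d > g increments a violation streak, any other
batch resets it, and the run stops at streak ≥ k = 15. The comparison is
made on the minimized forms because the raw two-term value is negative
while the generator loss is positive, which would make a literal comparison
vacuous. The full loss history is retained and the stopping rule is
replay-checked against a reference implementation in the tests.

Desk scale: 64×64 images, generator 4×4×64 with deconvolution filters
(32, 16, 16, 8), discriminator (16, 16, 8, 8). At this scale the networks
run in numpy on one CPU; 100 epochs on ~150 images take a few minutes.
Learning rate 1e−3 as at full scale.

## One-class SVM screening

The ν-one-class SVM with RBF kernel K(x, y) = exp(−γ‖x − y‖²) is fitted on
features of real spectrograms (sklearn's solver, tolerance 1e−6 so that
decisions are permutation-invariant and the training-outlier fraction tracks
ν; ν = 1 exactly is degenerate in libsvm and is clamped just below 1). The
input representation is unspecified in the source; here: channel mean,
bilinear downsample to 32×32, flattened (d = 1024), with ν = 0.1 and the
`scale` heuristic γ = 1/(d·Var) as defaults — all config-exposed, and none
of them to be read as the original experiments' values. Acceptance is the
sign of Σ βᵢK(xᵢ, x) − ρ; the stored (β, ρ, γ) reproduce the decision
function to 1e−6 against a brute-force kernel sum.

## The convolutional predictor

Three [3×3 stride-1 conv, ReLU, 2×2 max-pool] blocks with 126/64/64 filters
(the 126 is implemented as printed, not rounded to 128), then dense 32 and
dense 2, both sigmoid. The two outputs are independent sigmoids trained by
binary cross-entropy on one-hot targets; the pre-ictal unit is the ranking
score, optionally normalized by the two-unit sum for thresholding. Weights
use He-scaled initialization (√(2/fan-in)): with the DCGAN's 0.02
initialization the forward signal decays through three ReLU blocks and the
small desk model cannot learn in a reasonable epoch budget.

Cross-validation: stratified k-fold (k = 10 at full scale) for the reported
per-fold validation accuracy, early stopping on fold-validation loss with
patience 10, and the deployed model refit on the full training split — how
the final model is obtained after CV is unstated in the source; refitting
is this package's choice, with CV metrics kept for reporting. Adam at 1e−4
at full scale; the desk configuration (16/16/16 filters, 20 epochs) uses
1e−3 to compensate for the much smaller model and epoch budget.

## Evaluation protocol

Regime matrix: both the real and synthetic pools are split on `t_start`
(last 25 % by time as test) so test samples come from time sections disjoint
from training; regimes that test on the same source share the identical test
partition. One classifier is trained per regime.

Alarm scoring: an alarm fires when the score crosses the threshold (default
0.5) outside a refractory period (default = SOP). An alarm at t predicts an
onset o iff t + SPH ≤ o ≤ t + SPH + SOP (SPH 10 min, SOP 30 min by
default). Boundary conventions this package fixes: an alarm closer than SPH
to the onset is a false alarm (it did not give the required warning time);
each alarm is counted exactly once; FPR/h divides false alarms by the
interictal hours, i.e. the recording minus the union of
(onset − SPH − SOP, onset] windows.

Chance-level comparison: a random alarm process at rate FPR alarms within
one SOP with probability P = 1 − e^(−FPR·SOP) (SOP converted to hours so
the exponent is dimensionless); predicting n of N independent seizures at
random has tail probability Σ_{k≥n} C(N,k)Pᵏ(1−P)^{N−k} (evaluated via the
regularized binomial survival function; exact enumeration and a
100,000-draw Monte-Carlo oracle agree in the tests). Hanley–McNeil:
SE²(A) = [A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²)]/(n₊n₋) with
Q₁ = A/(2−A), Q₂ = 2A²/(1+A); the comparison is the independent-samples,
single-tailed z-test (the correlated-ROC variant needs a correlation
estimate that is not available here), with a Bonferroni α/m helper.

## Problem sizes for tests and the acceptance script

The full-scale protocol (256×256 images, thousands of epochs) is far beyond
a single-CPU run, so the shipped experiments use the desk sizes: 200
simulated segments per class, 64×64 images, the reduced filter counts
above, 100 GAN epochs, 150 generated samples, a 10 h timeline with 2
seizures. At these sizes the end-to-end run finishes in minutes while still
exercising every stage: TRTR reference, GAN synthesis, one-class-SVM
screening, TSTR transfer (synthesized pre-ictal + real interictal training
images — the augmentation-style reading of "train on synthesized", since
only the pre-ictal class is synthesized), alarm scoring and the
chance-level test.

## Known limitations

* The numpy engine is single-threaded and eager; it is sized for the desk
  experiments, not for 256×256 training.
* Score calibration of the two-sigmoid head is not addressed; thresholded
  metrics use the pair-normalized score, and the threshold itself (0.5) is
  a convention, sweepable via the ROC utilities.
* The simulator's stationary band contrast makes the desk problems easy;
  none of the desk-scale numbers transfer to real EEG.
* EDF interoperability is read-only (via mne, optional); EDF export is not
  provided.
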