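# Methods

This note documents the models, conventions and design choices behind
`rehabconn`, in the order the pipeline runs.

## Preprocessing

**Filtering.** All filters are Hamming-windowed sinc FIR kernels applied in
a single forward pass with the integer group delay (order/2 samples)
compensated, so the net phase shift is zero at every frequency — unlike
forward–backward filtering, the magnitude response is applied once.
Kernels are built from DC-normalized low-pass prototypes; a band-stop is
low-pass(low) plus the spectral inversion of low-pass(high), and a
band-pass is the spectral complement of that band-stop. Edges are handled
by symmetric reflection padding of order/2 samples, which avoids start-up
transients on short records. Defaults: line-noise band-stop of order 990
with −6 dB cutoffs at 48/52 Hz, and a 1–70 Hz band-pass of order 1650, at
500 Hz sampling.

A caveat worth stating precisely: the classical "Hamming window" figures
(−53 dB stop-band attenuation, 0.22% pass-band deviation) describe a
*single* transition of the windowed-sinc prototype. In a band-stop whose
two transitions sit only 4 Hz apart, the stop-band tails of the two edges
add coherently at the band center; the realized order-990 filter measures
about −51.3 dB over the 49–51 Hz stop-band interior (each edge alone is
below −54 dB) and about 0.27% peak pass-band deviation, concentrated in
the first ripple lobe adjacent to each transition. `scripts/acceptance.py`
reports these realized values, not the nominal window constants.

**Epoching.** Epochs span −100 ms to +1000 ms around each event marker
(550 samples at 500 Hz); the pre-stimulus 100 ms is the baseline. Events
whose window crosses a record edge are dropped with a warning.

**Bad channels.** The paper-style "normalized activity" rule is made
concrete as: per-channel standard deviation pooled over all epochs and
samples, z-scored against the leave-self-out mean/SD of the remaining
channels; |z| > 5 flags the channel. Leave-self-out prevents a single
extreme channel from masking itself; simultaneous multiple outliers can
still mask one another, which at 5 SD and ≥ 12 channels we accept.

**Order of operations** (fixed): notch → band-pass → epoch → bad-channel
detection → (optional epoch-transform hook, standing in for manual
ICA-based artifact removal, identity by default) → baseline subtraction →
±50 μV epoch rejection (on baseline-corrected values) → common-average
re-reference computed over good channels → spherical-spline interpolation
of the flagged channels. Baseline/re-reference are idempotent; rejection
never alters surviving epochs.

**Spherical interpolation.** Bad channels are re-estimated by a spherical
spline over the unit-sphere electrode positions: kernel
g(cos θ) = (1/4π) Σₙ (2n+1)/(n(n+1))⁴ Pₙ(cos θ) truncated at 50 Legendre
terms, fitted with a constant term and diagonal regularization λ = 1e−5.
On a 32-channel montage a smooth low-order harmonic field is recovered to
within a few percent at interior electrodes; extrapolation to rim
electrodes of a hemispheric montage is less accurate, as for any spline.

## Connectivity

Band-limited analytic signals come from a windowed-sinc band-pass of order
3·fs/low_hz (rounded to even), followed by the Hilbert transform. On
1.1 s epochs that order is capped at n_samples − 2 so the zero-phase
padding stays valid; for the delta band this cap (order 548 at 500 Hz)
widens the transition band considerably — delta-band estimates on short
epochs are correspondingly smooth, which we document rather than hide.
The first and last 10% of samples are flagged as Hilbert edge regions and
can be excluded from every estimator (`exclude_edges=True`); defaults use
all samples.

Estimator conventions: wPLI with an (up to rounding) purely real
cross-spectrum returns 0 — no lagged coupling. MI uses equal-width
histograms with ⌈√(N/5)⌉ bins per axis over each channel's envelope range
and plug-in entropies in bits; a constant envelope gives MI = 0. GC fits
AR models of order p = 5 (10 ms memory at 500 Hz) by ordinary least
squares on per-epoch de-meaned broadband signals, with no further
detrending; in-sample nesting guarantees GC ≥ 0. Matrix diagonals: PLV
and absCPCC 1, wPLI and iCPCC 0, CPCC 1+0i, MI the marginal envelope
entropy, GC 0. iCPCC is antisymmetric in the pair order (the normalized
cross-spectrum is Hermitian); only one half-matrix of it is ever used.

Vectorization offers three conventions: `upper_triangle` (C(C−1)/2
features, the mathematically clean default), `paper_half` (upper triangle
plus the first C/2 diagonal cells, i.e. exactly C²/2 — 7442 at 122
channels — and the full ordered C² matrix for directed GC, 14 884), and
`full_offdiag`. The complex CPCC contributes two features (Re, Im) per
cell. The orchestrator maps `upper_triangle` to `full_offdiag` when the
measure is directed.

## Feature selection

Per feature, a two-sided repeated-measures t-test between sessions. The
default pairing unit averages each feature over a subject's epochs within
a session and pairs across subjects (df = n_subjects − 1): epochs cannot
be paired one-to-one between sessions, and subject means respect the
within-subject design. A Welch epoch-level test is available
(`pairing_unit="epoch_unpaired"`) for exploration. The top 10% lowest
p-values are kept (ties broken by larger |t|, then lower index); selection
is a ranking, not an inference, so p-values are reported uncorrected.
By default the test and mask are recomputed inside each LOSO training fold
(leakage-free); `selection_scope="global"` computes one mask on all
subjects first, reproducing a selection-before-validation protocol.

## Classifier

A three-layer fully connected network (input → 10 → 5 → 2) with leaky-ReLU
(slope 0.01) activations and a softmax output, trained by mini-batch SGD
with momentum on cross-entropy: v ← μv − η∇, w ← w + v; 40 epochs,
batch size 10, re-shuffled each epoch. Hyperparameters the protocol leaves
open are fixed once: learning rate 0.01, momentum 0.9, fan-in-scaled
uniform initialization, zero biases, no weight decay, no early stopping.
Features are z-scored per column with training-fold statistics (raw
connectivity scales differ by orders of magnitude across measures);
constant columns map to zero. Analytic gradients are verified against
central finite differences. An exact 0.5 probability tie resolves to
"before" and is logged.

## Evaluation

One fold per subject; all of the held-out subject's epochs (both sessions)
form the test set. Per-fold seeds derive deterministically from the run
seed. Metrics take "after" as the positive class; degenerate denominators
are reported as NaN with a flag. ROC curves are averaged vertically (mean
TPR on a fixed 101-point FPR grid across folds; single-class folds are
excluded with a warning). Summary tables report mean, median and sample SD
(n−1) of per-subject accuracies in percent — over subjects, not epochs; a
single-subject group reports SD 0 with a flag.

## Synthetic cohort

Each virtual subject × session × task is synthesized as a continuous
recording and pushed through the real preprocessing path, so epoching,
rejection and referencing are exercised, not bypassed. Per channel, the
signal is

    sensors = M · (band-limited latent oscillators) · σ_osc
              + 1/f background · σ_bg + white sensor noise · σ_noise

with latent oscillators as FIR-band-passed Gaussian noise (nondegenerate
phase, EEG-like spectra, not sinusoids), M a row-normalized Gaussian
mixing kernel in great-circle angle over a Fibonacci-hemisphere montage
(instantaneous, zero-lag — exactly the spread wPLI/iCPCC reject), and an
FFT-shaped 1/f^α background added at the sensors.

The planted contrast changes the coupling strength s of known channel
pairs between sessions. Mechanisms: `phase_coupling` (target latent =
√(1−s²)·own + s·phase-lagged copy of the source, constant lag via Hilbert
rotation), `directed_var` (s-scaled copy of the source delayed ~4 ms —
raises source→target GC), `amplitude_dependence` (target keeps its carrier
phase but takes s of the source's envelope — raises envelope MI). Subject
variability is a log-normal multiplicative jitter (σ = 0.15) on s, drawn
once per subject; strengths are clipped to [0, 1], so at extreme jitter
the pre/post ratio can saturate.

Defaults emulate the study layout: 8 subjects × 2 sessions, 80 trials per
session (500/1200/800 ms stimulus/maintenance/rest, marker at maintenance
onset), 500 Hz, 16 channels (122 supported; 16 keeps a desk-scale
runtime), phase coupling on three low-gamma pairs with s = 0.1 → 0.9,
σ_osc = 4 μV, σ_bg = 6 μV (α = 1), σ_noise = 2 μV, mixing spread 0.35 rad.
These amplitudes put epoch peaks well inside the ±50 μV rejection bound
while leaving in-band SNR realistic for cortical oscillations.

What the generator does *not* emulate: ocular/muscle artifacts (the ICA
stage is out of scope, so its input is artifact-free by construction),
task-evoked transients, nonstationary coupling, realistic leadfields, or
inter-channel differences in noise level. Passing tests therefore
demonstrate that the pipeline recovers planted coupling changes under
volume conduction, 1/f noise and inter-subject variability — not that it
would attain any particular accuracy on clinical data.

## Calibration and scaled problem sizes

The test suite checks, among others: uniformity of the per-feature
p-values on an effect-free cohort (Kolmogorov–Smirnov at α = 0.01 over
552 features: 8 subjects, 24 channels, 12 trials, two bands);
chance-level LOSO accuracy on null cohorts; monotonicity of mean LOSO
accuracy in the planted effect size (three strengths × three seeds on a
4-subject, 8-channel cohort); and the full study-scale recovery run
(8 × 16 × 80, one seed). The reduced cohort sizes in the property tests
are a deliberate compute/coverage trade-off; the end-to-end run keeps the
full study geometry.

## Known limitations

- The high-gamma band (45–60 Hz) straddles the 48–52 Hz notch; estimates
  there exclude the line-noise region by construction (a warning is
  logged). Delta estimates on 1.1 s epochs are transition-band-limited
  (above) and effectively cover 1–4 Hz after the 1–70 Hz band-pass.
- Per-epoch wPLI has a positive finite-sample floor of roughly
  (bandwidth × epoch length)^(−1/2); "wPLI ≈ 0" for zero-lag mixtures
  means "at that floor", not numerically zero.
- GC is time-domain and per-epoch; no spectral decomposition, no
  multivariate (conditional) variant.
- Real-recording support covers EDF and BrainVision with an events
  sidecar; the minimal EDF writer targets round-tripping synthetic data
  (16-bit, 1 s records), not clinical archival.
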