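# Methods

## Problem and data model

The package targets 4-class rhythm classification (SB, AFIB, GSVT, SR) from
10-second 12-lead ECGs with 13 accompanying clinical measurements, in a
setting where records are distributed across hospitals ("clients") that must
not share raw data. Every component operates on `ECGRecord` objects: a
12 × d millivolt matrix (d = fs × duration), a label, and a 13-entry
`FeatureVector` (age, gender, ventricular rate, atrial rate, QRS duration,
QT, QTc, R axis, T axis, QRS count, Q onset/offset, T offset).

## Synthetic generator

Real multi-hospital ECG corpora cannot ship with a package, so a generator
produces labeled records whose class structure a learner can recover:

- Each beat is a sum of Gaussian bumps (P, Q, R, S, T). The per-lead signal
  is a fixed 12-entry projection of one underlying waveform, made zero-mean
  per lead (AC-coupled recording convention).
- The rhythm class fixes the ventricular-rate draw: SB [40, 60), SR
  [60, 100), AFIB [60, 160), GSVT [100, 200) bpm. RR-interval multipliers
  are Gaussian with CV 0.03 (sinus classes) or 0.20 (AFIB), floored at 0.3
  and normalized to sample mean 1 so the drawn rate is exact; AFIB
  additionally suppresses the P bump. A rate-threshold rule therefore
  separates SB/SR/GSVT perfectly on clean data, and AFIB is identifiable
  from RR irregularity, the missing P wave, and its fibrillatory atrial-rate
  feature (300–450 bpm).
- The 13 features are computed from the same beat train (ventricular rate =
  60 / mean RR, QRS count = number of beats, QT by Bazett scaling with
  subject-level QTc variability N(380, 15) ms).
- Contamination is additive and parameterized by `NoiseSpec`: a 50 Hz
  power-line sinusoid, a sub-0.5 Hz drift sinusoid, and white Gaussian
  noise, each in millivolts. The clean waveform is retained on the record so
  denoising can be scored against truth. Defaults are zero (clean records);
  `NoiseSpec.typical()` gives a mild realistic preset (0.2 / 0.5 / 0.05 mV).

What the generator does **not** emulate: genuine 12-lead vectorcardiographic
geometry, intra-class morphology pathology (e.g. bundle-branch blocks),
non-stationary noise such as electrode motion bursts, or inter-feature
correlations beyond those induced by rate. Passing the learning-recovery
tests therefore demonstrates that the pipeline's mechanics are correct — not
that the model would reach comparable accuracy on clinical data.

## Denoising pipeline

Stages run per channel, in fixed order.

1. **Butterworth 50 Hz low-pass**, order 4, zero phase. The two-pass
   amplitude response 1/(1 + (f/fc)^(2·order)) is applied exactly in the
   frequency domain on a reflect-padded copy. A bilinear time-domain design
   warps the response near Nyquist (at fs = 500 Hz its gain at 100 Hz is
   ~0.0016 instead of the analytic 0.0039); the spectral application
   realizes the analytic forward–backward response at every frequency and
   preserves QRS timing.
2. **LOESS detrending**: a degree-1 locally weighted regression of the
   signal on time (span 0.15 of the record) estimates the baseline; the
   estimate is then band-limited below 0.5 Hz (order-4 low-pass) before
   subtraction, because baseline wander is by definition sub-0.5 Hz — this
   stops the trend from tracking beat-frequency structure in slow rhythms
   and makes the stage approximately idempotent.
3. **1-D non-local means**: each sample becomes a similarity-weighted
   average over a 101-sample search window; the weight of offset j is
   exp(−d²/h²) with d² the mean squared difference between the 11-sample
   patches, normalized to sum 1. h defaults to 0.7 × the noise std estimated
   from the median absolute deviation of the first difference — on a clean
   signal that estimate is ~0, weights collapse onto identical patches and
   the stage is near-identity.

The 50 Hz cutoff equals the power-line frequency; the low-pass therefore
attenuates (gain 0.5 at exactly 50 Hz with the two-pass response) rather
than eliminates that interference, and no separate notch stage is provided.

## Classifier

A stacked GRU consumes the sequence one 12-entry lead vector per time step;
gates are exactly

    z_t = σ(W_z x_t + U_z h_{t−1} + b_z)
    r_t = σ(W_r x_t + U_r h_{t−1} + b_r)
    h̃_t = tanh(W_h x_t + U_h (r_t ⊙ h_{t−1}) + b_h)
    h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ h̃_t

Note the blend direction: as written, z_t → 1 selects the candidate state
(some textbook descriptions attach z_t to the previous state instead); the
equations above are what is implemented and tested. The last layer's final
hidden state, concatenated with the normalized features when fusion is on,
feeds a linear head and softmax. Forward, full backpropagation through time
and the Adam/SGD optimizers are implemented in numpy over a name → array
parameter dict, which keeps flattening for DP clipping and per-array
federated averaging trivial; a numerical-gradient check validated the BPTT
implementation to ~1e-10.

The loss is label-smoothed cross-entropy, target q_k = (1−s)·1[k=y] + s/4,
default s = 0.2, probabilities floored at 1e-12 inside the log. Adam uses
lr 0.001, weight decay 1e-5 (folded into the gradient, torch-style),
β = (0.9, 0.999). Weights initialize uniform ±1/√hidden, biases zero,
deterministically per seed.

Named presets mirror the four experiment scenarios: scenario 1 = hidden 64,
5 layers, no fusion; scenarios 2–4 = hidden 48, 5 layers, fusion on; all at
lr 0.001. Desk-scale tests use a reduced preset — hidden 16, 2 layers,
fusion, mean-pooling window 10 (so a 10 s record at 100 Hz becomes 100 GRU
steps), batch 16, lr 0.005 — chosen once as a configuration that a small
separable problem can be learned with in ≤30 epochs; pooling is an explicit
`GRUConfig.pool` field defaulting to 1 (raw samples).

## Differential privacy

Per batch the flattened loss gradient is clipped to g·min(1, C/‖g‖₂)
(direction preserved, ‖·‖ ≤ C always) and perturbed with independent
Gaussian noise. Two std conventions are supported: `multiplier` (std = σ·C,
the DP-SGD convention; default) and `literal` (std = σ). σ may be calibrated
from a privacy budget as σ = constant · sensitivity / ε, with the constant
and sensitivity both defaulting to the clipping norm (the L2 sensitivity of
a clipped contribution). Clipping granularity is the per-batch gradient;
per-sample clipping is deliberately not the default. A `linear_decay`
schedule interpolates σ down to 0.5·σ₀ across rounds (clip norm fixed).

Limitations, stated plainly: there is no (ε, δ) accountant — ε enters only
through the calibration formula, so no formal privacy guarantee across
rounds is computed. With σ = 0 and C = ∞ the mechanism is the exact identity
(and consumes no random numbers), so DP-federated runs reduce bit-exactly to
plain FedAvg under equal seeds.

With the per-batch mechanism, noise of std σ·C is added to every coordinate
of a ~3·10³-dimensional gradient whose clipped norm is ≤ C; at σ = 0.5 the
noise norm (~σ·C·√dim) exceeds the signal norm by an order of magnitude, so
a substantial accuracy cost at moderate σ is intrinsic to this mechanism.
The privacy-utility check is therefore monotonicity (accuracy at σ = 5.0
strictly below σ = 0.5), not closeness to the noise-free run.

## Federated core

All clients participate in every round (no sampling). A master seed derives
per-(round, client) generators — round 1 / client 0 being the centralized
stream — so runs replay bit-identically and a single client holding the full
training split with no DP reproduces centralized training to within 1e-9.
Aggregation is the size-weighted mean computed as W₀ + Σ w_i (W_i − W₀),
which preserves any array all clients agree on bit-exactly. Personalization
(plain, non-DP fine-tuning of the fresh global model on local data) runs
inside every round by default, with `final`-only and `none` modes; a
per-client 20 % holdout, split off before any training, scores personalized
vs global models on local data. Only weight arrays and dataset sizes cross
the client boundary.

The number of clients defaults to 4 and the non-IID partition draws each
class's allocation across clients from a symmetric Dirichlet(α), default
α = 0.5; both are benchmarking conventions, not constraints of the method.

## Metrics

All metrics derive from the 4×4 confusion matrix (rows = truth). Per class,
one-vs-rest precision, sensitivity, specificity and F1; overall accuracy;
Cohen's kappa; and the multiclass Matthews correlation in its covariance
(Gorodkin) form. Every 0/0 returns 0 with a logged warning; kappa and MCC
are clipped to [−1, 1] to absorb float round-off. Argmax ties break to the
lowest class index.

## Numerical and design notes

- Splits are stratified 75/10/15 by default, with integer sizes fixed by
  largest-remainder rounding before delegation to scikit-learn.
- Feature z-scoring uses train-split moments only; zero-std features map to
  0; the transform is invertible from the returned stats.
- Storage is plain CSV: a manifest (one row per record) plus one 12-column
  signal file per record, lossless for float64 round-trips.
- Divergent training (non-finite loss) aborts with a diagnostic rather than
  propagating NaNs.
- Desk-scale experiment sizes (400 records at 100 Hz, reduced model) are the
  package's chosen study conditions for its learning-recovery, privacy-
  utility and personalization experiments; the scenario presets carry the
  full-scale hyperparameters.

## Known limitations

Single-process simulation of clients (no transport, stragglers or dropout);
no formal privacy accounting; phenomenological rather than physiological
ECG synthesis; class boundaries in rate are adjacent (e.g. SB 59.9 bpm vs SR
60.1 bpm), so finite samples place learned thresholds imperfectly and
perfect accuracy on generated data is not expected even for ideal learners.
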