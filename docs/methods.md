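# Methods

## Optical strain transduction

The stretchable waveguide is modelled as a Beer–Lambert attenuator whose
loss coefficient grows linearly with tensile strain ε (a fraction;
reports use % strain):

    I(ε) = I₀ η₁ η₂ exp(−(α₀ + k_s ε) L)

- `I₀` — launched optical power (arbitrary units, > 0)
- `η₁, η₂` — input/output coupling efficiencies, held constant in (0, 1];
  their strain dependence is a known source of high-strain nonlinearity but
  is not parameterized — the operational window is restricted instead
- `α₀` — intrinsic attenuation (mm⁻¹, ≥ 0)
- `k_s` — strain-extinction coefficient (mm⁻¹ per unit strain, ≥ 0)
- `L` — effective sensing length (mm, > 0)

Log-linearization gives `ln I = C − k_s L ε` with
`C = ln(I₀η₁η₂) − α₀L`, so a degree-1 fit to the log of the output recovers
the product `k_s·L`; an optional second-order form
`ln I = C − a₁ε − a₂ε²` absorbs coupling and scattering nonlinearities.

Calibration fitting operates in two domains. The *voltage* domain fits
output mV against % strain on the replicate-mean loading branch and reports
the absolute slope as the sensitivity (mV/%) — the demodulator is affine in
intensity, which is what a practitioner calibrates against. The *log*
domain fits ln(mV) against fractional strain to recover `k_s·L`; this is
exact only when the demodulator offset is negligible, which holds for the
simulated rig (offset 0). R² on a zero-variance response is reported as 0
with a degeneracy flag rather than raising.

The hysteresis statistic averages replicates pointwise per branch, scans
the grid for the maximum |loading − unloading| gap, normalizes by the
full-scale span of the mean loading branch, and breaks ties toward the
lowest strain. A zero full-scale span raises an explicit division error.
Baseline drift (photo-aging) is the fluctuation/initial ratio reported to
two significant figures.

## Synthetic cohort generator

The generator stands in for a 60-subject clinical cohort; its default
composition is 15 healthy, 15 left-hemiplegia, 15 right-hemiplegia, and 15
PD split 5/5/5 over the tremor-dominant, akinetic-rigid, and PIGD subtypes.
Each subject yields a 4-channel, 10 Hz recording (plantar pressure;
gastrocnemius, vastus medialis, biceps femoris strain), 120 s by default.

Archetypes are phenomenological: step times are a truncated-Gaussian renewal
process at a class-specific cadence and interval CV; the plantar channel
carries one biphasic pulse per foot strike (difference of two 0.08 s
Gaussians, positive contact lobe then negative separation lobe, amplitude
shaped by a logarithmic force-to-amplitude curve anchored at 500 relative
units @ 1 N and 1150 @ 40 N); each strain channel carries one smooth bump
per gait cycle at a muscle-specific phase offset. Pathology enters as:

- hemiplegia — alternate-step amplitudes attenuated by an asymmetry ratio
  (0.55 by default), with the attenuated parity encoding the affected side;
- tremor-dominant PD — a sinusoidal overlay on the strain channels at
  3.5 Hz. The clinical tremor band (4–6 Hz) sits at or above the 5 Hz
  Nyquist limit of the 10 Hz sampling rate, so the default is a
  representability compromise, not a clinical claim;
- akinetic-rigid PD — globally reduced amplitudes and slower cadence;
- PIGD — freezing-of-gait episodes (Poisson-arriving, 4 s default) that
  delete steps, plus high interval CV.

All channels receive white Gaussian noise (σ = 0.05 by default) and
random-walk baseline drift (step σ = 0.01/sample). Per-subject seeds are
spawned deterministically from the master seed, so cohorts are reproducible
and subjects independent. The class-conditional statistics are free
parameters — the original study does not quantify them — so passing tests
demonstrate correct *mechanics* (recovery of generator truth, separability
under stated margins), not clinical realism of the archetypes.

The calibration-rig simulator drives the staircase protocol (0→100→0% in
10% steps, three replicates) through the transduction model, maps intensity
to mV affinely (default gain 2758 mV at zero strain), and applies a
first-order lag with time constant τ per hold period; τ = 0 and zero noise
collapse the branches exactly, and the hysteresis grows monotonically
with τ, which is how the simulator earns its role as a truth source.

## Preprocessing

- Strain channels: mean subtraction, then a fourth-order zero-phase
  (forward–backward) Butterworth high-pass. The cutoff defaults to
  0.15 Hz — below the slowest plausible cadence (~0.5 Hz), above drift —
  and is configurable; only the filter order and zero-phase application are
  fixed design features. The plantar channel is mean-subtracted only, since
  its biphasic pulses carry near-DC energy.
- Robust normalization: per recording, per channel, (x − median)/IQR with a
  1e−6 floor guard for constant channels (warned, not raised). This is the
  classifier-input transform: it harmonizes amplitude ranges across
  participants, and therefore deliberately destroys absolute-amplitude
  information. Gait feature statistics that compare amplitudes across
  subjects (RMS, peak-to-peak) are computed on baseline-corrected but
  un-normalized signals for exactly this reason.
- Windowing: 300-sample windows (30 s at 10 Hz) at 50% overlap;
  `count = floor((N − 300)/stride) + 1`. The window length is interpreted
  as samples; a 300-*step* window would span ~5 minutes and exceed any
  plausible recording here.
- Augmentation (training only): circular temporal shift uniform in ±5
  samples, Gaussian noise (σ = 0.02 robust units), amplitude scale uniform
  in [0.9, 1.1]. Augmented windows inherit the source subject ID, which is
  what keeps grouped cross-validation leak-free under augmentation.

## Gait features

Step detection picks plantar peaks with prominence ≥ 0.5 × a robust
amplitude scale, separated by ≥ 0.3 s. Two plumbing choices matter: a 2 s
rolling-median baseline is subtracted first (the plantar channel keeps its
low-frequency content by design, and drift bumps otherwise masquerade as
strikes), and the robust scale is the 98th percentile of the rectified
signal rather than the IQR — on sparse pulse trains the IQR tracks the
noise floor, not the pulse amplitude.

Cadence = 1/mean(interval); interval CV = 100·SD/mean (sample SD); the
symmetry index is min/max of the mean durations of alternate (odd/even)
cycles — with a single instrumented foot this is a left/right proxy, a
documented limitation. MPF uses a Welch spectrum (Hann, 128-sample
segments, 50% overlap, DC bin excluded) with linear interpolation to the
half-power frequency; the estimator details are package choices.
Peak-to-peak is the mean per-cycle (max − min) between consecutive strikes.
Features needing more steps than available are returned as missing, not
raised.

## Classifier

Default architecture (the study states the branch/layer structure but not
sizes): plantar branch conv(16, k5)→BN→pool2→conv(32, k5)→BN→pool2; strain
branch conv(16, k5)→pool2→conv(32, k5)→pool2→conv(64, k5) — the pooling on
the strain branch aligns both branches at 75 time steps so they concatenate
along the channel axis; LSTM hidden 64; dropout 0.3; weight decay 1e−4;
Adam at 1e−3 halved every 20 epochs; early-stop patience 10; max 100
epochs. A `compact()` preset (8/16 and 8/16/32 channels, LSTM 32, 25
epochs, patience 6) is the desk-scale default used by the pipeline and
tests; it trains a fold in seconds on one CPU. Label schemes: six groups
(the default), four (PD subtypes merged), three (healthy/stroke/PD).

The layers are implemented directly in numpy with analytic backward passes
(BPTT for the LSTM) and are gradient-checked against central finite
differences to < 1e−7 in the test suite. Training is seeded end to end;
repeated runs agree to within 0.5 percentage points of accuracy.

Cross-validation is subject-wise and stratified by class: subjects are
dealt round-robin into test folds (order-invariant under a fixed seed), and
each fold's early-stopping validation split takes one training subject per
class, leaving the test fold untouched. `evaluate` recomputes nothing from
training state: it hard-fails if any held-out subject intersects the set a
fold's model trained on, and it scores only unaugmented windows. The
modality ablation trains plantar-only, strain-only, and fused models on the
identical fold plan and seed.

The clinical accuracies reported for the original cohort (94.23/88.46/
40.38%) are not reproducible without the unreleased recordings and are not
claimed. The suite instead checks behaviourally: near-perfect held-out
accuracy on a strongly separated two-class cohort, chance-level accuracy
under subject-level label permutation, and fused ≥ unimodal on a cohort
whose class cues are modality-specific by construction (a plantar-only
polarity factor crossed with a strain-only tremor factor).

## Energy and telemetry budget

Pure arithmetic, exactly linear in durations, currents, and step counts:
phase energy V·I·t (mJ), per-step harvest P·t_contact·η (default 3.92 mW,
0.25 s, 72% → 0.7056 mJ/step), surplus = n·per-step − cycle consumption.
Wire framing defaults to 10 bits/byte (8N1 UART: start + 8 data + stop),
the framing consistent with the measured 6.7 kbps at 67 bytes × 10 Hz.
Reports format energies to 2 decimals; internal arithmetic is unrounded.

## Rehabilitation comparison

Per metric: paired differences (Post − Pre), two-tailed paired-samples
t-test, 95% t-interval. Metrics are reported without multiplicity
correction by default, matching the presentation style of single-metric
rehabilitation reports, with an optional Holm flag. Unmatched subjects are
excluded with a warning. Degenerate cases (constant differences) collapse
the CI to a point rather than raising.

## Problem sizes and numerical choices

Test and acceptance runs use scaled-down study conditions chosen as the
package's desk-scale defaults: 60 s recordings (three 300-sample windows
per subject) for classifier checks, a 60-subject two-class cohort for the
separability/permutation checks, a 24-subject 2×2-factor cohort with 3
folds and 3 seeds for the ablation, 400 replicates for the CI-coverage
simulation, and 1,000 random draws for the hysteresis-oracle and
fold-leakage scans. Numerical guards: IQR floor 1e−6, sigmoid argument
clipping at ±50, softmax max-subtraction, probability floor 1e−300 in the
cross-entropy, forget-gate bias initialized to 1.

## Known limitations

- Archetypes are signal-level, not biomechanical; asymmetry from a single
  instrumented side is a modelling proxy.
- The 10 Hz sampling rate cannot represent clinical tremor frequencies;
  tremor is emulated at 3.5 Hz.
- The log-domain calibration fit assumes a negligible demodulator offset.
- Per-recording normalization precludes cross-subject absolute-amplitude
  learning by design; classifiers must rely on shape, rhythm, and relative
  cues, which is also true of the feature path only when normalization is
  explicitly disabled.
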