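# dualgait

Computational pipeline for a self-powered, dual-mode wearable gait platform:
a footwear system that pairs a contact-separation triboelectric
nanogenerator (plantar-pressure sensing *and* energy harvesting) with three
polyurethane optical strain sensors on lower-limb muscles, streaming four
channels at 10 Hz. The package is aimed at researchers in wearable digital
health who want to prototype, stress-test, and reason about such a system
without access to clinical recordings: every stage of the analysis runs on a
seeded synthetic gait cohort that emulates healthy controls, left/right
hemiplegic stroke survivors, and Parkinson's disease motor subtypes
(tremor-dominant, akinetic-rigid, postural-instability/gait-difficulty).

## What it computes

**Optical strain transduction.** Transmitted intensity through the stretchable
waveguide follows a Beer–Lambert form with a strain-proportional loss term,

```
I(ε) = I₀ η₁ η₂ exp(−(α₀ + k_s ε) L),     ln I = C − k_s L ε,
```

with a second-order extension `ln I = C − a₁ε − a₂ε²` for large strains.
Calibration follows a staircase protocol (0–100% strain in 10% steps,
loading and unloading, three replicates): least-squares sensitivity (mV/%),
R², log-domain recovery of `k_s·L`, and the maximum hysteresis error

```
H% = max_ε |V_load(ε) − V_unload(ε)| / V_FS × 100.
```

**Gait statistics.** Plantar-pulse step detection, cadence, step-interval
coefficient of variation, alternate-cycle symmetry index, per-channel RMS,
Welch median power frequency, per-cycle peak-to-peak amplitude, and paired
pre/post rehabilitation comparisons (two-tailed paired t, 95% CI).

**Classification.** A dual-branch CNN-LSTM: two conv blocks (with batch norm
and pooling) on the plantar channel, a three-layer conv stack on the strain
channels, channel-wise concatenation, an LSTM, and a softmax head — trained
with Adam, learning-rate halving, dropout, weight decay, early stopping, and
augmentation (±5-sample shifts, Gaussian noise, amplitude scaling).
Evaluation is subject-wise grouped cross-validation (~80/20 subjects per
fold) with a programmatic zero-leakage guarantee, plus a three-way modality
ablation (plantar-only / strain-only / fused). The network layers are a
compact numpy implementation with analytic backprop, gradient-checked
against finite differences.

**Energy & telemetry budget.** Exact duty-cycle arithmetic: phase energies
V·I·t for acquire/upload/sleep, per-step triboelectric harvest
P·t_contact·η, net surplus over a walking bout, and serial-framed Bluetooth
throughput.

## Worked example

```
$ dualgait budget
cycle_consumption_mJ: 424.64
per_step_harvest_mJ: 0.7056
harvest_mJ: 705.6
net_surplus_mJ: 280.96
throughput_kbps: 6.7
sustainable: True
n_steps: 1000
```

A 10-minute acquire(480 s)/upload(20 s)/sleep(100 s) cycle at 3.2 V consumes
424.64 mJ; 1,000 steps harvesting 0.7056 mJ each yield 705.6 mJ, so the
bout ends 280.96 mJ in surplus — the device is energy-positive under typical
walking — while the 67-byte, 10 Hz telemetry frame needs only 6.7 kbps of
the 9.6 kbps serial budget.

```
$ dualgait calibrate --seed 0 --lag-tau 0.8 --noise 1.0 --out cal
sensitivity 15.09 mV/%  R2 0.989  hysteresis 2.34% at 10% strain
```

This simulates a staircase calibration on a sensor with a viscoelastic lag
of 0.8 s and 1 mV measurement noise, then fits it: the voltage-domain slope
magnitude is the sensitivity, and the lag opens a loading/unloading gap that
the hysteresis statistic localizes on the strain grid.

Other verbs: `simulate` (write a synthetic cohort), `features` (gait feature
table), `ablate` (modality ablation with grouped CV), `rehab` (paired
pre/post report), `run-all` (full pipeline into a run directory).

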