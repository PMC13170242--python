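"""Seeded synthetic gait cohort and calibration-rig simulators.

Stands in for a 60-subject clinical cohort (healthy controls, left/right
hemiplegic stroke survivors, and Parkinson's disease patients) recorded by a
footwear platform: one triboelectric plantar-pressure channel plus three
optical muscle-strain channels (gastrocnemius, vastus medialis, biceps
femoris), all sampled at 10 Hz.

The archetypes are phenomenological signal models, not biomechanical
simulations: each gait class is a parameterization of step rhythm, amplitude,
left/right asymmetry, freezing episodes and tremor overlay, on top of which
Gaussian noise and random-walk baseline drift are added.  Class-conditional
statistics are free parameters of the generator; no claim of clinical realism
is made beyond the qualitative structure of the pathologies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .transduction import CalibrationCurve, TransductionParams, forward_intensity

__all__ = [
    "ArchetypeParams",
    "GaitRecording",
    "CohortSpec",
    "CHANNEL_NAMES",
    "CLASS_LABELS",
    "archetype",
    "simulate_recording",
    "make_cohort",
    "simulate_calibration_run",
    "teng_amplitude_from_force",
]

CHANNEL_NAMES = ("plantar", "gastro", "vastus", "biceps")

CLASS_LABELS = ("healthy", "hemi_left", "hemi_right", "pd_td", "pd_ar", "pd_pigd")

#: Per-cycle phase offsets (fraction of the gait cycle) of the three muscle
#: bumps relative to heel strike.
_STRAIN_PHASES = (0.10, 0.30, 0.55)


@dataclass(frozen=True)
class ArchetypeParams:
    """Class-conditional generator parameters for one gait archetype."""

    class_label: str
    step_frequency_hz: float = 0.9       # mean cadence; must stay < Nyquist
    step_interval_cv: float = 5.0        # % variability of step intervals
    amplitude_scale: tuple = (1.0, 1.0, 1.0, 1.0)  # per channel
    asymmetry_ratio: float = 1.0         # alternate-step amplitude ratio, (0,1]
    asymmetric_side: str = "none"        # which alternate phase is attenuated
    freeze_rate_per_min: float = 0.0     # freezing-of-gait episodes per minute
    freeze_duration_s: float = 0.0
    tremor_hz: float = 0.0               # strain-channel tremor overlay
    tremor_amp: float = 0.0
    noise_sigma: float = 0.05            # additive white noise (robust units)
    drift_sigma: float = 0.01            # random-walk step size per sample
    step_force_N: float = 20.0           # nominal foot-strike force

    def __post_init__(self) -> None:
        if not (0 < self.asymmetry_ratio <= 1):
            raise ValueError("asymmetry_ratio must lie in (0, 1]")
        if self.freeze_rate_per_min < 0 or self.freeze_duration_s < 0:
            raise ValueError("freeze parameters must be >= 0")
        if self.tremor_amp < 0 or self.noise_sigma < 0 or self.drift_sigma < 0:
            raise ValueError("rates and scales must be >= 0")


# Defaults chosen so that classes differ along the axes their pathology
# suggests: hemiplegia -> alternate-step asymmetry, tremor-dominant PD ->
# tremor overlay, akinetic-rigid PD -> reduced amplitude, PIGD -> freezing
# gaps + high rhythm variability.  Tremor sits at 3.5 Hz because the 10 Hz
# sampling rate puts the clinical 4-6 Hz band at/above Nyquist.
_ARCHETYPES: Dict[str, ArchetypeParams] = {
    "healthy": ArchetypeParams(
        class_label="healthy", step_frequency_hz=1.0, step_interval_cv=4.0
    ),
    "hemi_left": ArchetypeParams(
        class_label="hemi_left",
        step_frequency_hz=0.75,
        step_interval_cv=10.0,
        asymmetry_ratio=0.55,
        asymmetric_side="left",
    ),
    "hemi_right": ArchetypeParams(
        class_label="hemi_right",
        step_frequency_hz=0.75,
        step_interval_cv=10.0,
        asymmetry_ratio=0.55,
        asymmetric_side="right",
    ),
    "pd_td": ArchetypeParams(
        class_label="pd_td",
        step_frequency_hz=0.85,
        step_interval_cv=8.0,
        tremor_hz=3.5,
        tremor_amp=0.35,
    ),
    "pd_ar": ArchetypeParams(
        class_label="pd_ar",
        step_frequency_hz=0.7,
        step_interval_cv=8.0,
        amplitude_scale=(0.6, 0.5, 0.5, 0.5),
    ),
    "pd_pigd": ArchetypeParams(
        class_label="pd_pigd",
        step_frequency_hz=0.8,
        step_interval_cv=15.0,
        freeze_rate_per_min=2.0,
        freeze_duration_s=4.0,
    ),
}


def archetype(class_label: str, **overrides) -> ArchetypeParams:
    """Default archetype for ``class_label``, with optional field overrides."""
    try:
        base = _ARCHETYPES[class_label]
    except KeyError as exc:
        raise ValueError(
            f"unknown class label {class_label!r}; choose from {CLASS_LABELS}"
        ) from exc
    return replace(base, **overrides) if overrides else base


@dataclass
class GaitRecording:
    """A 4-channel uniformly sampled gait recording with generator truth."""

    sample_rate: float
    channels: np.ndarray          # shape (4, n_samples), CHANNEL_NAMES order
    subject_id: str
    class_label: str
    true_step_times: np.ndarray   # seconds, strictly increasing

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.true_step_times = np.asarray(self.true_step_times, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != len(CHANNEL_NAMES):
            raise ValueError("channels must have shape (4, n_samples)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.true_step_times.size > 1 and np.any(
            np.diff(self.true_step_times) <= 0
        ):
            raise ValueError("step times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"t_s": self.times})
        for i, name in enumerate(CHANNEL_NAMES):
            df[name] = self.channels[i]
        df.to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "subject_id": self.subject_id,
                    "class_label": self.class_label,
                    "sample_rate_hz": self.sample_rate,
                    "true_step_times_s": self.true_step_times.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "GaitRecording":
        df = pd.read_csv(path)
        meta = json.loads(Path(path).with_suffix(".json").read_text())
        return cls(
            sample_rate=meta["sample_rate_hz"],
            channels=df[list(CHANNEL_NAMES)].to_numpy().T,
            subject_id=meta["subject_id"],
            class_label=meta["class_label"],
            true_step_times=np.asarray(meta["true_step_times_s"]),
        )


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a synthetic cohort.

    The default mirrors a 60-subject study: 15 healthy, 15 left and 15 right
    hemiplegia, and 15 PD split evenly over the three motor subtypes.
    """

    class_counts: Dict[str, int] = field(
        default_factory=lambda: {
            "healthy": 15,
            "hemi_left": 15,
            "hemi_right": 15,
            "pd_td": 5,
            "pd_ar": 5,
            "pd_pigd": 5,
        }
    )
    duration_s: float = 120.0
    master_seed: int = 0
    overrides: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, count in self.class_counts.items():
            if label not in CLASS_LABELS:
                raise ValueError(f"unknown class label {label!r}")
            if count < 0:
                raise ValueError("class counts must be >= 0")
        if self.duration_s < 10:
            raise ValueError("duration must be at least 10 s")


def teng_amplitude_from_force(force_N: float | np.ndarray) -> float | np.ndarray:
    """Relative triboelectric pulse amplitude as a function of foot-strike force.

    Monotone, concave (logarithmically saturating) curve anchored to measured
    open-circuit voltages: 500 at 1 N and 1150 at 40 N.  Used only to shape
    simulated plantar pulses; units are relative.
    """
    f = np.asarray(force_N, dtype=float)
    if np.any(f <= 0):
        raise ValueError("force must be positive")
    out = 500.0 + (1150.0 - 500.0) * np.log(f) / np.log(40.0)
    return out if np.ndim(force_N) else float(out)


def _draw_step_times(
    rng: np.random.Generator, arch: ArchetypeParams, duration_s: float
) -> np.ndarray:
    mean_int = 1.0 / arch.step_frequency_hz
    sd = mean_int * arch.step_interval_cv / 100.0
    times: List[float] = []
    t = mean_int  # first strike one nominal interval in
    while t < duration_s - 0.5:
        times.append(t)
        interval = rng.normal(mean_int, sd)
        t += max(interval, 0.25 * mean_int)  # floor keeps times increasing
    return np.asarray(times)


def _freeze_mask(
    rng: np.random.Generator,
    arch: ArchetypeParams,
    step_times: np.ndarray,
    duration_s: float,
) -> np.ndarray:
    """Boolean mask of steps to keep (True) after freezing-of-gait deletion."""
    keep = np.ones(step_times.size, dtype=bool)
    if arch.freeze_rate_per_min <= 0 or arch.freeze_duration_s <= 0:
        return keep
    n_episodes = rng.poisson(arch.freeze_rate_per_min * duration_s / 60.0)
    for _ in range(n_episodes):
        start = rng.uniform(0, max(duration_s - arch.freeze_duration_s, 0))
        keep &= ~(
            (step_times >= start) & (step_times < start + arch.freeze_duration_s)
        )
    return keep


def _biphasic_pulse(t: np.ndarray, t0: float, width_s: float = 0.08) -> np.ndarray:
    """Contact-separation pulse: positive lobe followed by a negative lobe.

    Difference of two Gaussians; polarity reflects contact electrification
    followed by separation of the triboelectric layers.
    """
    return np.exp(-0.5 * ((t - t0) / width_s) ** 2) - np.exp(
        -0.5 * ((t - t0 - 2.0 * width_s) / width_s) ** 2
    )


def simulate_recording(
    arch: ArchetypeParams,
    duration_s: float,
    subject_id: str,
    seed: int | np.random.SeedSequence,
    sample_rate: float = 10.0,
) -> GaitRecording:
    """Simulate one 4-channel recording from a gait archetype.

    The plantar channel carries a biphasic triboelectric pulse at each foot
    strike; the three strain channels carry one smooth activation bump per
    gait cycle at channel-specific phase offsets.  Hemiplegic asymmetry
    attenuates alternate steps, tremor adds a sinusoid to the strain
    channels, and freezing episodes delete steps.  Identical
    ``(arch, seed)`` pairs produce bit-identical recordings.
    """
    if duration_s < 10:
        raise ValueError("duration must be at least 10 s")
    nyquist = sample_rate / 2.0
    if arch.tremor_hz >= nyquist and arch.tremor_amp > 0:
        raise ValueError(f"tremor_hz must be below the Nyquist rate ({nyquist} Hz)")
    if arch.step_frequency_hz >= nyquist:
        raise ValueError("step frequency must be below the Nyquist rate")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate

    raw_steps = _draw_step_times(rng, arch, duration_s)
    keep = _freeze_mask(rng, arch, raw_steps, duration_s)
    step_times = raw_steps[keep]
    # parity of the ORIGINAL step index encodes left/right alternation
    parities = np.nonzero(keep)[0] % 2

    channels = np.zeros((4, n))

    # plantar pulses, amplitude shaped by the force-to-amplitude curve
    rel_amp = teng_amplitude_from_force(arch.step_force_N) / teng_amplitude_from_force(
        40.0
    )
    for t0, parity in zip(step_times, parities):
        amp = arch.amplitude_scale[0] * rel_amp
        if arch.asymmetric_side == "left" and parity == 0:
            amp *= arch.asymmetry_ratio
        elif arch.asymmetric_side == "right" and parity == 1:
            amp *= arch.asymmetry_ratio
        channels[0] += amp * _biphasic_pulse(t, t0)

    # strain-channel bumps: one per gait cycle, phase-offset per muscle
    intervals = np.diff(np.concatenate([step_times, [duration_s]]))
    for ch in range(1, 4):
        phase = _STRAIN_PHASES[ch - 1]
        for t0, dt_cycle, parity in zip(step_times, intervals, parities):
            amp = arch.amplitude_scale[ch]
            if arch.asymmetric_side == "left" and parity == 0:
                amp *= arch.asymmetry_ratio
            elif arch.asymmetric_side == "right" and parity == 1:
                amp *= arch.asymmetry_ratio
            center = t0 + phase * dt_cycle
            width = max(0.15 * dt_cycle, 0.1)
            channels[ch] += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        if arch.tremor_amp > 0:
            channels[ch] += arch.tremor_amp * np.sin(2 * np.pi * arch.tremor_hz * t)

    if arch.noise_sigma > 0:
        channels += rng.normal(0.0, arch.noise_sigma, size=channels.shape)
    if arch.drift_sigma > 0:
        channels += np.cumsum(
            rng.normal(0.0, arch.drift_sigma, size=channels.shape), axis=1
        )

    return GaitRecording(
        sample_rate=sample_rate,
        channels=channels,
        subject_id=subject_id,
        class_label=arch.class_label,
        true_step_times=step_times,
    )


def make_cohort(spec: CohortSpec) -> List[GaitRecording]:
    """Generate one recording per subject according to the cohort spec.

    Subject seeds are spawned deterministically from the master seed, so the
    same spec reproduces the same cohort and subjects are independent.
    """
    recordings: List[GaitRecording] = []
    subject_idx = 0
    for label in CLASS_LABELS:  # fixed order for determinism
        count = spec.class_counts.get(label, 0)
        arch = archetype(label, **spec.overrides.get(label, {}))
        for k in range(count):
            seed = np.random.SeedSequence([spec.master_seed, subject_idx])
            rec = simulate_recording(
                arch,
                spec.duration_s,
                subject_id=f"S{subject_idx:03d}",
                seed=seed,
            )
            recordings.append(rec)
            subject_idx += 1
    return recordings


def cohort_manifest(recordings: Sequence[GaitRecording]) -> pd.DataFrame:
    """Subject-level manifest (one row per recording)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in recordings],
            "class_label": [r.class_label for r in recordings],
            "duration_s": [r.duration_s for r in recordings],
            "n_steps": [r.true_step_times.size for r in recordings],
        }
    )


def simulate_calibration_run(
    params: TransductionParams,
    noise_sigma_mV: float = 0.0,
    lag_tau_s: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    replicates: int = 3,
    hold_time_s: float = 2.0,
    gain_mV: float = 2758.0,
    offset_mV: float = 0.0,
    grid_pct: Optional[np.ndarray] = None,
) -> CalibrationCurve:
    """Simulate the staircase calibration protocol on a stepper rig.

    The strain staircase goes 0..100% in 10% steps and back; the demodulated
    output is an affine map of the transmitted intensity.  A first-order
    viscoelastic lag with time constant ``lag_tau_s`` makes the sensor output
    approach each plateau exponentially, which opens a loading/unloading gap;
    with zero lag and zero noise the two branches coincide exactly.
    """
    if noise_sigma_mV < 0 or lag_tau_s < 0:
        raise ValueError("noise sigma and lag tau must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    if grid_pct is None:
        grid_pct = np.arange(0.0, 101.0, 10.0)
    grid_pct = np.asarray(grid_pct, dtype=float)

    # steady-state output at each grid strain
    target = offset_mV + gain_mV * np.asarray(
        forward_intensity(params, grid_pct / 100.0)
    )

    n_grid = grid_pct.size
    loading = np.empty((replicates, n_grid))
    unloading = np.empty((replicates, n_grid))
    # relaxation factor over one hold period
    relax = 1.0 if lag_tau_s == 0 else 1.0 - np.exp(-hold_time_s / lag_tau_s)

    for rep in range(replicates):
        y = target[0]
        for i in range(n_grid):  # loading sweep: 0 -> 100%
            y = y + relax * (target[i] - y)
            loading[rep, i] = y
        for i in range(n_grid - 1, -1, -1):  # unloading sweep: 100% -> 0
            y = y + relax * (target[i] - y)
            unloading[rep, i] = y
        if noise_sigma_mV > 0:
            loading[rep] += rng.normal(0, noise_sigma_mV, n_grid)
            unloading[rep] += rng.normal(0, noise_sigma_mV, n_grid)

    return CalibrationCurve(grid_pct, loading, unloading)
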