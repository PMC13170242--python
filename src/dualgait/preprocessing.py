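"""Signal conditioning for multichannel gait recordings.

The chain applied before feature extraction or classification:

1. baseline correction — mean subtraction on every channel, plus a
   fourth-order zero-phase Butterworth high-pass on the muscle-strain
   channels to suppress drift and low-frequency motion artifacts (the
   plantar pulse train keeps its shape and only loses its DC offset);
2. robust normalization — per-channel median/IQR scaling, resistant to the
   gross outliers triboelectric spikes can produce;
3. fixed-length overlapping windowing (default 300 samples = 30 s at 10 Hz);
4. training-time augmentation — small circular temporal shifts, low-variance
   Gaussian noise and mild amplitude scaling, with augmented windows
   inheriting the source subject ID so grouped cross-validation splits stay
   leak-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import signal

from .synthetic import CHANNEL_NAMES, GaitRecording

__all__ = [
    "Window",
    "WindowSet",
    "remove_baseline",
    "robust_normalize",
    "preprocess_recording",
    "make_windows",
    "augment_window",
    "augment_windowset",
]

IQR_FLOOR = 1e-6

#: Channel indices treated as muscle-strain (high-pass filtered) channels.
STRAIN_CHANNELS = (1, 2, 3)
PLANTAR_CHANNEL = 0


def remove_baseline(
    series: np.ndarray,
    sample_rate: float,
    cutoff_hz: float = 0.15,
    filter_order: int = 4,
) -> np.ndarray:
    """Mean-subtract then zero-phase high-pass filter a 1-D series.

    Forward-backward (``sosfiltfilt``) application of a Butterworth high-pass
    doubles the effective order and cancels phase distortion; output length
    equals input length.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.size <= 3 * filter_order:
        raise ValueError("series too short for the requested filter order")
    nyq = sample_rate / 2.0
    if not (0 < cutoff_hz < nyq):
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    x = x - x.mean()
    sos = signal.butter(filter_order, cutoff_hz, btype="highpass", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def _robust_scale_channel(x: np.ndarray) -> tuple[np.ndarray, bool]:
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    degenerate = iqr <= IQR_FLOOR
    return (x - med) / max(iqr, IQR_FLOOR), degenerate


def robust_normalize(recording: GaitRecording) -> GaitRecording:
    """Median/IQR scale each channel of a recording.

    After scaling, every non-constant channel has median 0 and IQR 1.
    Constant channels hit the IQR floor guard and come out (numerically)
    all-zero; a warning is emitted rather than an error.
    """
    out = np.empty_like(recording.channels)
    for i in range(recording.channels.shape[0]):
        out[i], degenerate = _robust_scale_channel(recording.channels[i])
        if degenerate:
            warnings.warn(
                f"channel {CHANNEL_NAMES[i]} of {recording.subject_id} has "
                "(near-)zero IQR; floor guard applied",
                stacklevel=2,
            )
    return GaitRecording(
        sample_rate=recording.sample_rate,
        channels=out,
        subject_id=recording.subject_id,
        class_label=recording.class_label,
        true_step_times=recording.true_step_times,
    )


def preprocess_recording(
    recording: GaitRecording,
    cutoff_hz: float = 0.15,
    filter_order: int = 4,
    normalize: bool = True,
) -> GaitRecording:
    """Full conditioning chain on one recording.

    The plantar channel is mean-subtracted only (its biphasic pulses carry
    near-DC energy worth keeping); the strain channels additionally pass
    through the zero-phase high-pass.  With ``normalize=True`` all four
    channels are then median/IQR scaled — the right input for the
    classifier, which should not key on absolute amplitude ranges.  Feature
    statistics that compare amplitudes across subjects (e.g. RMS) should use
    ``normalize=False``, since per-recording scaling deliberately removes
    exactly that information.
    """
    ch = recording.channels.copy()
    ch[PLANTAR_CHANNEL] = ch[PLANTAR_CHANNEL] - ch[PLANTAR_CHANNEL].mean()
    for i in STRAIN_CHANNELS:
        ch[i] = remove_baseline(ch[i], recording.sample_rate, cutoff_hz, filter_order)
    out = GaitRecording(
        sample_rate=recording.sample_rate,
        channels=ch,
        subject_id=recording.subject_id,
        class_label=recording.class_label,
        true_step_times=recording.true_step_times,
    )
    return robust_normalize(out) if normalize else out


@dataclass
class Window:
    """One fixed-length multichannel window with provenance."""

    data: np.ndarray          # (n_channels, window_len)
    subject_id: str
    label: str
    source: str               # source recording / lineage tag
    augmented: bool = False


@dataclass
class WindowSet:
    """A collection of windows with aligned provenance arrays."""

    data: np.ndarray                  # (n_windows, n_channels, window_len)
    subject_ids: np.ndarray           # (n_windows,) str
    labels: np.ndarray                # (n_windows,) str
    sources: np.ndarray               # (n_windows,) str lineage tags
    augmented: np.ndarray             # (n_windows,) bool

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        for arr_name in ("subject_ids", "labels", "sources", "augmented"):
            arr = np.asarray(getattr(self, arr_name))
            if arr.shape[0] != n:
                raise ValueError(f"{arr_name} length does not match data")
            setattr(self, arr_name, arr)

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def window_len(self) -> int:
        return self.data.shape[2]

    def subset(self, mask: np.ndarray) -> "WindowSet":
        return WindowSet(
            self.data[mask],
            self.subject_ids[mask],
            self.labels[mask],
            self.sources[mask],
            self.augmented[mask],
        )

    def select_channels(self, channel_idx: Sequence[int]) -> "WindowSet":
        return WindowSet(
            self.data[:, list(channel_idx), :],
            self.subject_ids,
            self.labels,
            self.sources,
            self.augmented,
        )

    @classmethod
    def concatenate(cls, sets: Sequence["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            raise ValueError("nothing to concatenate")
        return cls(
            np.concatenate([s.data for s in sets]),
            np.concatenate([s.subject_ids for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.sources for s in sets]),
            np.concatenate([s.augmented for s in sets]),
        )


def make_windows(
    recording: GaitRecording,
    window_len: int = 300,
    overlap_fraction: float = 0.5,
) -> WindowSet:
    """Segment a recording into fixed-length overlapping windows.

    stride = round(window_len * (1 - overlap)); a recording of N samples
    yields floor((N - window_len)/stride) + 1 windows (0 if N < window_len).
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    stride = max(int(round(window_len * (1.0 - overlap_fraction))), 1)
    n = recording.n_samples
    if n < window_len:
        warnings.warn(
            f"recording {recording.subject_id} shorter than one window; "
            "empty window set",
            stacklevel=2,
        )
        count = 0
    else:
        count = (n - window_len) // stride + 1
    data = np.empty((count, recording.channels.shape[0], window_len))
    for k in range(count):
        data[k] = recording.channels[:, k * stride : k * stride + window_len]
    return WindowSet(
        data=data,
        subject_ids=np.full(count, recording.subject_id, dtype=object),
        labels=np.full(count, recording.class_label, dtype=object),
        sources=np.array(
            [f"{recording.subject_id}:w{k}" for k in range(count)], dtype=object
        ),
        augmented=np.zeros(count, dtype=bool),
    )


def windows_from_cohort(
    recordings: Sequence[GaitRecording],
    window_len: int = 300,
    overlap_fraction: float = 0.5,
    preprocess: bool = True,
    cutoff_hz: float = 0.15,
) -> WindowSet:
    """Preprocess and window every recording of a cohort."""
    sets: List[WindowSet] = []
    for rec in recordings:
        if preprocess:
            rec = preprocess_recording(rec, cutoff_hz=cutoff_hz)
        ws = make_windows(rec, window_len, overlap_fraction)
        if len(ws):
            sets.append(ws)
    return WindowSet.concatenate(sets)


def augment_window(
    window: Window,
    seed: int | np.random.Generator,
    shift_max: int = 5,
    noise_sigma: float = 0.02,
    scale_range: tuple[float, float] = (0.9, 1.1),
) -> Window:
    """One augmented copy of a window: circular shift, noise, amplitude scale.

    The shift is an integer drawn uniformly from [-shift_max, +shift_max];
    noise is zero-mean Gaussian in robust units; the multiplicative scale is
    uniform in ``scale_range``.  Subject ID and label are inherited so that
    subject-wise splits remain valid.
    """
    if shift_max < 0 or noise_sigma < 0:
        raise ValueError("shift_max and noise_sigma must be >= 0")
    if not (0 < scale_range[0] <= scale_range[1]):
        raise ValueError("scale_range must be positive and ordered")
    if window.data.shape[1] <= 2 * shift_max:
        raise ValueError("window too short for the requested shift range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shift = int(rng.integers(-shift_max, shift_max + 1))
    scale = float(rng.uniform(*scale_range))
    data = np.roll(window.data, shift, axis=1) * scale
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    return Window(
        data=data,
        subject_id=window.subject_id,
        label=window.label,
        source=window.source + "+aug",
        augmented=True,
    )


def augment_windowset(
    windows: WindowSet,
    n_copies: int,
    seed: int,
    shift_max: int = 5,
    noise_sigma: float = 0.02,
    scale_range: tuple[float, float] = (0.9, 1.1),
) -> WindowSet:
    """Append ``n_copies`` augmented variants of every window in the set."""
    if n_copies < 1:
        return windows
    rng = np.random.default_rng(seed)
    pieces = [windows]
    for _ in range(n_copies):
        aug_data = np.empty_like(windows.data)
        for i in range(len(windows)):
            w = Window(
                windows.data[i],
                windows.subject_ids[i],
                windows.labels[i],
                windows.sources[i],
            )
            aug_data[i] = augment_window(
                w, rng, shift_max, noise_sigma, scale_range
            ).data
        pieces.append(
            WindowSet(
                aug_data,
                windows.subject_ids.copy(),
                windows.labels.copy(),
                np.array([s + "+aug" for s in windows.sources], dtype=object),
                np.ones(len(windows), dtype=bool),
            )
        )
    return WindowSet.concatenate(pieces)
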