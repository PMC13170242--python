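"""Step detection and gait statistics.

The feature set quantifies gait quality per channel and per recording:
signal RMS, median power frequency (MPF) of the muscle-strain channels,
step frequency, step-interval coefficient of variation, a left/right
symmetry index, and mean per-cycle peak-to-peak amplitude.  Step times are
detected from the plantar-pressure channel by prominence-gated peak picking.

With a single instrumented foot, symmetry is proxied by comparing the mean
durations of alternate (odd vs even) step cycles; a value of 1 means the two
interleaved step series have equal mean duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocessing import STRAIN_CHANNELS, PLANTAR_CHANNEL
from .synthetic import GaitRecording

__all__ = [
    "GaitFeatures",
    "IntervalStats",
    "detect_steps",
    "interval_stats",
    "rms",
    "median_power_frequency",
    "peak_to_peak",
    "compute_features",
    "feature_table",
    "step_count_relative_error",
]


class IntervalStats(NamedTuple):
    step_frequency_hz: Optional[float]
    step_interval_cv_pct: Optional[float]
    symmetry_index: Optional[float]


@dataclass
class GaitFeatures:
    """Per-recording (or per-window) gait feature vector."""

    subject_id: str
    class_label: str
    rms_plantar: float
    rms_gastro: float
    rms_vastus: float
    rms_biceps: float
    mpf_gastro: Optional[float]
    mpf_vastus: Optional[float]
    mpf_biceps: Optional[float]
    step_frequency_hz: Optional[float]
    step_interval_cv_pct: Optional[float]
    symmetry_index: Optional[float]
    p2p_amplitude: Optional[float]
    step_count: int


def detect_steps(
    plantar_series: np.ndarray,
    sample_rate: float,
    prominence_factor: float = 0.5,
    min_separation_s: float = 0.3,
) -> np.ndarray:
    """Detect foot-strike times (s) from a mean-subtracted plantar series.

    Peaks must exceed ``prominence_factor`` times the series' robust
    amplitude scale and be separated by at least ``min_separation_s``.
    Because the pulse train is sparse (foot strikes occupy a small fraction
    of samples), the scale is the 98th percentile of the rectified signal —
    an outlier-resistant stand-in for the pulse amplitude — rather than the
    IQR, which tracks the noise floor on spike-like signals.  A
    rolling-median baseline (2 s window) is subtracted first so that
    residual low-frequency drift in the plantar channel (which is only
    mean-subtracted upstream) cannot masquerade as foot strikes.  A flat or
    empty series yields an empty result.
    """
    x = np.asarray(plantar_series, dtype=float)
    if x.size == 0:
        return np.empty(0)
    med_win = int(round(2.0 * sample_rate)) | 1  # odd window
    if x.size > med_win:
        from scipy.ndimage import median_filter

        x = x - median_filter(x, size=med_win, mode="nearest")
    scale = float(np.percentile(np.abs(x), 98))
    if scale <= 0:
        scale = float(np.max(np.abs(x)))
    if scale == 0:
        return np.empty(0)
    distance = max(int(round(min_separation_s * sample_rate)), 1)
    peaks, _ = sps.find_peaks(
        x, prominence=prominence_factor * scale, distance=distance
    )
    return peaks / sample_rate


def interval_stats(step_times: Sequence[float]) -> IntervalStats:
    """Cadence, rhythm variability and alternate-cycle symmetry.

    frequency = 1/mean(step intervals); CV = 100*SD/mean (sample SD);
    symmetry = min(mA, mB)/max(mA, mB) with mA, mB the mean durations of the
    even- and odd-indexed cycles.  Fields that need more steps than provided
    are returned as None.
    """
    t = np.asarray(step_times, dtype=float)
    if t.size < 2:
        return IntervalStats(None, None, None)
    intervals = np.diff(t)
    mean_int = intervals.mean()
    freq = 1.0 / mean_int
    cv = None
    if t.size >= 3:
        sd = intervals.std(ddof=1)
        cv = 100.0 * sd / mean_int
    symmetry = None
    if t.size >= 4:
        m_a = intervals[0::2].mean()
        m_b = intervals[1::2].mean()
        symmetry = min(m_a, m_b) / max(m_a, m_b)
    return IntervalStats(freq, cv, symmetry)


def rms(series: np.ndarray) -> float:
    """Root mean square, sqrt(mean(x**2))."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("rms of an empty series is undefined")
    return float(np.sqrt(np.mean(x**2)))


def median_power_frequency(
    series: np.ndarray,
    sample_rate: float,
    segment_len: int = 128,
) -> float:
    """Median power frequency via a Welch spectrum.

    Hann window, ``segment_len``-sample segments at 50% overlap, DC bin
    excluded; the MPF is the frequency at which cumulative power reaches half
    of the total, linearly interpolated between bins.
    """
    x = np.asarray(series, dtype=float)
    if x.size < segment_len:
        raise ValueError(
            f"series ({x.size}) shorter than the PSD segment ({segment_len})"
        )
    freqs, psd = sps.welch(
        x, fs=sample_rate, window="hann", nperseg=segment_len, noverlap=segment_len // 2
    )
    freqs, psd = freqs[1:], psd[1:]  # drop the DC bin
    cum = np.cumsum(psd)
    total = cum[-1]
    if total <= 0:
        return 0.0
    half = total / 2.0
    idx = int(np.searchsorted(cum, half))
    if idx == 0:
        prev_cum, prev_f = 0.0, freqs[0] - (freqs[1] - freqs[0])
    else:
        prev_cum, prev_f = cum[idx - 1], freqs[idx - 1]
    frac = (half - prev_cum) / (cum[idx] - prev_cum)
    return float(prev_f + frac * (freqs[idx] - prev_f))


def peak_to_peak(series: np.ndarray, step_times: Sequence[float], sample_rate: float) -> Optional[float]:
    """Mean per-gait-cycle (max - min) amplitude.

    Cycles are the spans between consecutive step times; needs >= 2 steps.
    """
    t = np.asarray(step_times, dtype=float)
    if t.size < 2:
        return None
    x = np.asarray(series, dtype=float)
    ranges = []
    for t0, t1 in zip(t[:-1], t[1:]):
        i0, i1 = int(round(t0 * sample_rate)), int(round(t1 * sample_rate))
        seg = x[i0 : max(i1, i0 + 1)]
        if seg.size:
            ranges.append(seg.max() - seg.min())
    return float(np.mean(ranges)) if ranges else None


def step_count_relative_error(detected: int, reference: int) -> float:
    """Relative step-count error (%) against a reference count."""
    if reference <= 0:
        raise ValueError("reference count must be positive")
    return 100.0 * abs(detected - reference) / reference


def compute_features(
    recording: GaitRecording,
    prominence_factor: float = 0.5,
    min_separation_s: float = 0.3,
    mpf_segment_len: int = 128,
) -> GaitFeatures:
    """Full feature vector for one (preprocessed) recording."""
    plantar = recording.channels[PLANTAR_CHANNEL]
    steps = detect_steps(
        plantar, recording.sample_rate, prominence_factor, min_separation_s
    )
    stats = interval_stats(steps)
    rms_vals = [rms(recording.channels[i]) for i in range(4)]
    mpfs = []
    for i in STRAIN_CHANNELS:
        try:
            mpfs.append(
                median_power_frequency(
                    recording.channels[i], recording.sample_rate, mpf_segment_len
                )
            )
        except ValueError:
            mpfs.append(None)
    return GaitFeatures(
        subject_id=recording.subject_id,
        class_label=recording.class_label,
        rms_plantar=rms_vals[0],
        rms_gastro=rms_vals[1],
        rms_vastus=rms_vals[2],
        rms_biceps=rms_vals[3],
        mpf_gastro=mpfs[0],
        mpf_vastus=mpfs[1],
        mpf_biceps=mpfs[2],
        step_frequency_hz=stats.step_frequency_hz,
        step_interval_cv_pct=stats.step_interval_cv_pct,
        symmetry_index=stats.symmetry_index,
        p2p_amplitude=peak_to_peak(plantar, steps, recording.sample_rate),
        step_count=int(steps.size),
    )


def feature_table(
    recordings: Sequence[GaitRecording], **kwargs
) -> pd.DataFrame:
    """Feature DataFrame, one row per recording."""
    rows = [vars(compute_features(rec, **kwargs)) for rec in recordings]
    return pd.DataFrame(rows)
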