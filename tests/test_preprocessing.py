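"""Baseline removal, robust normalization, windowing, augmentation."""

import numpy as np
import pytest

from dualgait.preprocessing import (
    Window,
    augment_window,
    augment_windowset,
    make_windows,
    preprocess_recording,
    remove_baseline,
    robust_normalize,
)
from dualgait.synthetic import GaitRecording, archetype, simulate_recording


def _recording_from_channels(ch, fs=10.0):
    return GaitRecording(
        sample_rate=fs,
        channels=ch,
        subject_id="S0",
        class_label="healthy",
        true_step_times=np.empty(0),
    )


class TestRemoveBaseline:
    def test_constant_series_zeroed(self):
        out = remove_baseline(np.full(200, 3.7), 10.0)
        assert np.abs(out).max() < 1e-9

    def test_stop_band_attenuation(self):
        t = np.arange(3000) / 10.0
        drift = np.sin(2 * np.pi * 0.01 * t)
        out = remove_baseline(drift, 10.0, cutoff_hz=0.15)
        assert np.sqrt(np.mean(out**2)) < 0.05 * np.sqrt(np.mean(drift**2))

    def test_pass_band_preserved_zero_phase(self):
        t = np.arange(3000) / 10.0
        sig = np.sin(2 * np.pi * 1.0 * t)
        out = remove_baseline(sig, 10.0, cutoff_hz=0.15)
        assert np.sqrt(np.mean(out**2)) == pytest.approx(
            np.sqrt(np.mean(sig**2)), rel=0.02
        )
        # zero phase: cross-correlation peak at zero lag
        lags = np.arange(-5, 6)
        xc = [np.dot(np.roll(out, k), sig) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            remove_baseline(np.zeros(100), 10.0, cutoff_hz=5.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            remove_baseline(np.zeros(10), 10.0)


class TestRobustNormalize:
    def test_median_zero_iqr_one(self):
        rng = np.random.default_rng(0)
        rec = _recording_from_channels(rng.normal(2.0, 3.0, size=(4, 500)))
        out = robust_normalize(rec)
        for ch in out.channels:
            assert np.median(ch) == pytest.approx(0.0, abs=1e-9)
            q75, q25 = np.percentile(ch, [75, 25])
            assert q75 - q25 == pytest.approx(1.0, abs=1e-9)

    def test_constant_channel_floor_guard(self):
        ch = np.vstack([np.full(100, 5.0), np.random.default_rng(1).normal(size=(3, 100))])
        with pytest.warns(UserWarning, match="IQR"):
            out = robust_normalize(_recording_from_channels(ch))
        assert np.abs(out.channels[0]).max() == pytest.approx(0.0, abs=1e-9)

    def test_outlier_robustness_vs_moment_scaling(self):
        rng = np.random.default_rng(2)
        clean = rng.normal(size=1000)
        dirty = clean.copy()
        idx = rng.choice(1000, size=50, replace=False)
        dirty[idx] = 100.0 * np.sign(rng.normal(size=50))

        def robust(x):
            q75, q25 = np.percentile(x, [75, 25])
            return (x - np.median(x)) / (q75 - q25)

        inliers = np.setdiff1d(np.arange(1000), idx)
        spread_clean = robust(clean)[inliers].std()
        spread_dirty = robust(dirty)[inliers].std()
        assert abs(spread_dirty - spread_clean) / spread_clean < 0.10
        # moment-based scaling fails the same check
        z_dirty = (dirty - dirty.mean()) / dirty.std()
        assert abs(z_dirty[inliers].std() - spread_clean) / spread_clean > 0.10

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        rec = _recording_from_channels(rng.normal(size=(4, 400)))
        once = robust_normalize(rec)
        twice = robust_normalize(once)
        assert np.allclose(once.channels, twice.channels, atol=1e-9)

    def test_drift_removed_by_preprocessing(self):
        """High-pass removes injected random-walk drift from strain channels.

        Same-seed recordings with and without drift are preprocessed; the
        median residual between them (the surviving drift) must stay below
        5% of the pulse amplitude, though the raw drift is far larger.
        """
        clean_arch = archetype("healthy", noise_sigma=0.0, drift_sigma=0.0)
        drift_arch = archetype("healthy", noise_sigma=0.0, drift_sigma=0.01)
        clean = simulate_recording(clean_arch, 60.0, "S0", seed=4)
        drifty = simulate_recording(drift_arch, 60.0, "S0", seed=4)
        p_clean = preprocess_recording(clean, normalize=False)
        p_drift = preprocess_recording(drifty, normalize=False)
        for ch in (1, 2, 3):
            pulse_amp = np.percentile(np.abs(p_clean.channels[ch]), 99)
            raw_resid = np.median(np.abs(drifty.channels[ch] - clean.channels[ch]))
            filt_resid = np.median(
                np.abs(p_drift.channels[ch] - p_clean.channels[ch])
            )
            assert filt_resid < 0.05 * pulse_amp
            assert filt_resid < raw_resid


class TestMakeWindows:
    @pytest.mark.parametrize(
        "n,expected", [(900, 5), (300, 1), (299, 0), (600, 3), (750, 4)]
    )
    def test_count_formula(self, n, expected):
        rec = _recording_from_channels(np.zeros((4, n)))
        if expected == 0:
            with pytest.warns(UserWarning):
                ws = make_windows(rec, 300, 0.5)
        else:
            ws = make_windows(rec, 300, 0.5)
        assert len(ws) == expected

    def test_window_shape_and_provenance(self):
        rec = simulate_recording(archetype("healthy"), 90.0, "S9", seed=0)
        ws = make_windows(rec, 300, 0.5)
        assert ws.data.shape[1:] == (4, 300)
        assert set(ws.subject_ids) == {"S9"}
        assert set(ws.labels) == {"healthy"}
        assert not ws.augmented.any()

    def test_invalid_overlap_rejected(self):
        rec = _recording_from_channels(np.zeros((4, 600)))
        with pytest.raises(ValueError):
            make_windows(rec, 300, 1.0)


class TestAugmentWindow:
    def _window(self, n=300):
        rng = np.random.default_rng(0)
        return Window(rng.normal(size=(4, n)), "S1", "healthy", "S1:w0")

    def test_null_augmentation_is_identity(self):
        w = self._window()
        out = augment_window(w, seed=0, shift_max=0, noise_sigma=0.0, scale_range=(1.0, 1.0))
        assert np.allclose(out.data, w.data)

    def test_subject_inheritance(self):
        w = self._window()
        rng = np.random.default_rng(1)
        for _ in range(200):
            out = augment_window(w, rng)
            assert out.subject_id == "S1"
            assert out.label == "healthy"
            assert out.augmented

    def test_shift_distribution_uniform(self):
        """Empirical shifts cover all 11 integers, near-uniformly."""
        base = np.zeros((1, 300))
        base[0, 150] = 1.0
        w = Window(base, "S1", "healthy", "src")
        rng = np.random.default_rng(2)
        counts = np.zeros(11, dtype=int)
        n_draws = 10000
        for _ in range(n_draws):
            out = augment_window(w, rng, noise_sigma=0.0, scale_range=(1.0, 1.0))
            shift = int(np.argmax(out.data[0])) - 150
            counts[shift + 5] += 1
        assert np.all(counts > 0)
        expected = n_draws / 11
        sigma = np.sqrt(n_draws * (1 / 11) * (10 / 11))
        assert np.all(np.abs(counts - expected) < 3 * sigma + 1)

    def test_too_short_window_rejected(self):
        w = Window(np.zeros((1, 8)), "S1", "healthy", "src")
        with pytest.raises(ValueError):
            augment_window(w, seed=0, shift_max=5)

    def test_windowset_augmentation_lineage(self):
        rec = simulate_recording(archetype("healthy"), 90.0, "S2", seed=1)
        ws = make_windows(rec)
        aug = augment_windowset(ws, n_copies=2, seed=0)
        assert len(aug) == 3 * len(ws)
        assert aug.augmented.sum() == 2 * len(ws)
        assert set(aug.subject_ids) == {"S2"}
        assert all(s.endswith("+aug") for s in aug.sources[aug.augmented])
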