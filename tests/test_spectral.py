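"""Preprocessing, time-frequency power, robust averaging, baselines, ICC."""

import numpy as np
import pandas as pd
import pytest

from laminarmeg.data import EpochedData
from laminarmeg.spectral import (
    band_power,
    baseline_correct,
    icc_2k,
    load_signal_definitions,
    morlet_tf,
    multitaper_tf,
    preprocess,
    robust_average,
    sensor_tf_summary,
    windowed_band_variance,
)


def _epochs(data, sfreq=250.0, t0=-1.0):
    times = t0 + np.arange(data.shape[-1]) / sfreq
    return EpochedData(data=data, sfreq=sfreq, times=times)


class TestPreprocess:
    def test_notch_removes_line_frequency(self):
        sfreq = 1000.0
        t = np.arange(2000) / sfreq
        x = np.sin(2 * np.pi * 50 * t)[None, None, :] * np.ones((3, 2, 1))
        out = preprocess(_epochs(x, sfreq), band=(2, 100), notch=50, fs_out=250)
        mid = out.data[..., 200:-200]  # trim notch ringing transients
        assert np.abs(mid).max() < 0.05

    def test_equal_variance_trials_kept(self):
        # identical variance by construction: phase-shifted sinusoids
        t = np.arange(1000) / 1000.0
        x = np.stack(
            [np.sin(2 * np.pi * 11 * t + ph) * np.ones((3, 1))
             for ph in np.linspace(0, 3, 20)]
        )
        out = preprocess(_epochs(x, 1000.0), fs_out=250)
        assert not out.trials["rejected"].any()

    def test_high_variance_trial_flagged(self, rng):
        x = rng.standard_normal((100, 3, 1000))
        x[42] *= np.sqrt(10.0)
        out = preprocess(_epochs(x, 1000.0), fs_out=250)
        flagged = np.where(out.trials["rejected"])[0]
        np.testing.assert_array_equal(flagged, [42])

    def test_band_above_nyquist_rejected(self, rng):
        x = rng.standard_normal((2, 2, 1000))
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess(_epochs(x, 1000.0), band=(2, 150), fs_out=250)


class TestMorlet:
    def test_peak_at_stimulus_frequency(self):
        sfreq = 250.0
        t = np.arange(1250) / sfreq
        x = np.sin(2 * np.pi * 10 * t)[None, None, :]
        tf = morlet_tf(_epochs(x, sfreq))
        prof = tf.power[0, 0][:, 400:800].mean(axis=1)  # interior samples
        assert tf.freqs[np.argmax(prof)] == pytest.approx(10.0, abs=1.0)

    def test_power_quadratic_in_amplitude(self):
        sfreq = 250.0
        t = np.arange(1000) / sfreq
        x = np.sin(2 * np.pi * 15 * t)[None, None, :]
        tf1 = morlet_tf(_epochs(x, sfreq), freqs=np.array([15.0]))
        tf2 = morlet_tf(_epochs(2 * x, sfreq), freqs=np.array([15.0]))
        mid = slice(300, 700)
        np.testing.assert_allclose(
            tf2.power[0, 0, 0, mid], 4 * tf1.power[0, 0, 0, mid], rtol=1e-10
        )

    def test_impulse_matches_direct_convolution(self):
        """Power of the Morlet response to a unit impulse equals a direct
        (naive loop) convolution oracle."""
        from laminarmeg.spectral import _morlet_wavelet

        sfreq, n = 250.0, 600
        x = np.zeros((1, 1, n))
        x[0, 0, 300] = 1.0
        f = 12.0
        tf = morlet_tf(_epochs(x, sfreq), freqs=np.array([f]))
        w = _morlet_wavelet(f, sfreq, 7.0)
        half = (len(w) - 1) // 2
        direct = np.zeros(n, dtype=complex)
        for i in range(n):
            k = 300 - i + half  # x is an impulse: conv picks one tap
            if 0 <= k < len(w):
                direct[i] = w[k]
        np.testing.assert_allclose(
            tf.power[0, 0, 0], np.abs(direct) ** 2, atol=1e-8
        )

    def test_matches_mne_reference(self):
        """Cross-check against the mne implementation on a chirp-like
        signal (interior samples, same wavelet convention)."""
        mne = pytest.importorskip("mne")
        sfreq = 250.0
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 3, 1000))
        freqs = np.array([8.0, 12.0, 20.0])
        tf = morlet_tf(_epochs(x, sfreq), freqs=freqs)
        ref = mne.time_frequency.tfr_array_morlet(
            x, sfreq=sfreq, freqs=freqs, n_cycles=7.0, output="power",
            zero_mean=False,
        )
        mid = slice(200, 800)
        ratio = tf.power[..., mid] / ref[..., mid]
        assert np.abs(ratio - 1).max() < 0.02

    def test_epoch_too_short_raises(self):
        x = np.zeros((1, 1, 100))
        with pytest.raises(ValueError, match="cycles"):
            morlet_tf(_epochs(x, 250.0), freqs=np.array([2.0]))


class TestMultitaper:
    def test_peak_at_stimulus_frequency(self):
        sfreq = 250.0
        t = np.arange(1000) / sfreq
        x = np.sin(2 * np.pi * 80 * t)[None, None, :]
        tf = multitaper_tf(_epochs(x, sfreq))
        prof = tf.power[0, 0].mean(axis=1)
        assert tf.freqs[np.argmax(prof)] == pytest.approx(80.0, abs=5.0)

    def test_stationary_signal_constant_over_time(self):
        sfreq = 250.0
        t = np.arange(2000) / sfreq
        x = np.sin(2 * np.pi * 75 * t)[None, None, :]
        tf = multitaper_tf(_epochs(x, sfreq), freqs=np.array([75.0]))
        p = tf.power[0, 0, 0]
        assert p.max() / p.min() < 1.05

    def test_white_noise_spectrum_flat(self, rng):
        """Across 55–115 Hz, mean white-noise power per bin is flat within
        10% (large trial average)."""
        x = rng.standard_normal((2000, 1, 250))
        tf = multitaper_tf(_epochs(x, 250.0), t_window=0.2, t_step=0.05)
        mean_per_freq = tf.power.mean(axis=(0, 1, 3))
        assert mean_per_freq.max() / mean_per_freq.min() < 1.10

    def test_window_exceeding_epoch_raises(self):
        with pytest.raises(ValueError, match="window"):
            multitaper_tf(_epochs(np.zeros((1, 1, 40)), 250.0), t_window=0.2)


class TestRobustAverage:
    def test_clean_gaussian_matches_mean(self, rng):
        x = rng.standard_normal(400)
        mu, w = robust_average(x)
        assert abs(mu - x.mean()) < 0.1 * x.std() / np.sqrt(len(x))

    def test_outlier_downweighted(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 100.0])
        mu, w = robust_average(x)
        assert 1.0 <= mu <= 2.0
        assert w[-1] < 0.1

    def test_permutation_invariant(self, rng):
        x = rng.standard_normal(50)
        mu1, _ = robust_average(x)
        mu2, _ = robust_average(x[::-1].copy())
        assert mu1 == pytest.approx(mu2, rel=1e-12)

    def test_bounded_by_extremes(self, rng):
        for _ in range(20):
            x = rng.standard_normal(15) * rng.uniform(0.1, 5)
            mu, _ = robust_average(x)
            assert x.min() <= mu <= x.max()

    def test_all_equal_returns_value(self):
        mu, w = robust_average(np.full(6, 3.25))
        assert mu == 3.25
        np.testing.assert_array_equal(w, 1.0)


class TestBaselineCorrection:
    def _tf(self, power, t0=-1.0):
        from laminarmeg.spectral import TFRepresentation

        n_f, n_t = power.shape[-2:]
        return TFRepresentation(
            power=power, freqs=np.arange(n_f) + 5.0,
            times=t0 + np.arange(n_t) / 100.0, method="morlet",
        )

    def test_equal_power_maps_to_zero(self):
        tf = self._tf(np.full((3, 2, 200), 4.0))
        out = baseline_correct(tf, (-1.0, -0.5))
        np.testing.assert_allclose(out.power, 0.0, atol=1e-12)

    def test_doubled_power_maps_to_one(self):
        p = np.full((1, 2, 200), 2.0)
        p[..., :50] = 1.0  # baseline half
        tf = self._tf(p)
        out = baseline_correct(tf, (-1.0, -0.51))
        np.testing.assert_allclose(out.power[..., 60:], 1.0, atol=1e-9)
        pct = baseline_correct(tf, (-1.0, -0.51), mode="percent")
        np.testing.assert_allclose(pct.power[..., 60:], 100.0, atol=1e-7)

    def test_two_frequency_hand_toy(self):
        p = np.ones((1, 2, 100))
        p[0, 0] *= 2.0  # baseline b = 2 for f0, 1 for f1
        p[0, :, 50:] = 6.0
        tf = self._tf(p)
        out = baseline_correct(tf, (-1.0, -0.51))
        np.testing.assert_allclose(out.power[0, 0, 50:], (6 - 2) / 2, atol=1e-9)
        np.testing.assert_allclose(out.power[0, 1, 50:], (6 - 1) / 1, atol=1e-9)

    def test_uncorrection_recovers_power(self, rng):
        p = rng.uniform(1.0, 3.0, (2, 3, 120))
        tf = self._tf(p)
        out = baseline_correct(tf, (-1.0, -0.4))
        mask = (tf.times >= -1.0) & (tf.times <= -0.4)
        flat = np.moveaxis(p[..., mask], -2, 0).reshape(3, -1)
        b, _ = robust_average(flat, axis=1)
        recovered = out.power * b[None, :, None] + b[None, :, None]
        np.testing.assert_allclose(recovered, p, rtol=1e-9)

    def test_nonpositive_baseline_rejected(self):
        p = np.zeros((1, 1, 100))
        tf = self._tf(p)
        with pytest.raises(ValueError, match="baseline"):
            baseline_correct(tf, (-1.0, -0.5))


class TestBandPower:
    def test_burst_inside_window_dominates(self, rng):
        sfreq = 250.0
        n = 750
        times = -1.0 + np.arange(n) / sfreq
        x = 0.05 * rng.standard_normal((100, n))
        burst = (times >= 0.2) & (times <= 0.6)
        carrier = np.sin(2 * np.pi * 20 * times)
        x[:, burst] += carrier[burst]
        p_in = band_power(x, sfreq, times, (15, 30), (0.2, 0.6))
        p_out = band_power(x, sfreq, times, (15, 30), (-0.9, -0.5))
        assert np.all(p_in > p_out)

    def test_quadratic_amplitude_scaling(self):
        sfreq = 250.0
        times = np.arange(500) / sfreq
        x = np.sin(2 * np.pi * 10 * times)[None, :]
        p1 = band_power(x, sfreq, times, (7, 13), (0.5, 1.5))
        p2 = band_power(2 * x, sfreq, times, (7, 13), (0.5, 1.5))
        assert p2[0] == pytest.approx(4 * p1[0], rel=1e-10)

    def test_equals_tf_submatrix_mean(self, rng):
        sfreq = 250.0
        times = -0.5 + np.arange(400) / sfreq
        x = rng.standard_normal((5, 400))
        p = band_power(x, sfreq, times, (8, 12), (0.0, 0.5))
        tf = morlet_tf(x[:, None, :], freqs=np.arange(8.0, 13.0), sfreq=sfreq,
                       times=times)
        mask = (times >= 0.0) & (times <= 0.5)
        expected = tf.power[..., mask].mean(axis=(-2, -1)).mean(axis=-1)
        np.testing.assert_allclose(p, expected, rtol=1e-10)

    def test_filter_variance_equivalent_for_band_limited_signal(self, rng):
        """The fast variance-of-filtered-signal band power tracks the TF
        band power for band-limited content (Parseval)."""
        sfreq = 250.0
        times = -1.0 + np.arange(750) / sfreq
        from scipy import signal as sps

        sos = sps.butter(4, (15, 30), btype="bandpass", fs=sfreq, output="sos")
        x = sps.sosfiltfilt(sos, rng.standard_normal((30, 750)), axis=-1)
        v = windowed_band_variance(x[:, None, :], sfreq, times, (15, 30),
                                   (-0.5, 0.5))[:, 0]
        p = band_power(x, sfreq, times, (15, 30), (-0.5, 0.5))
        r = np.corrcoef(v, p)[0, 1]
        assert r > 0.95


class TestSensorSummary:
    def _corrected_tf(self, power):
        from laminarmeg.spectral import TFRepresentation

        n_f, n_t = power.shape[-2:]
        return TFRepresentation(
            power=power, freqs=np.arange(n_f, dtype=float) * 1.0 + 2,
            times=np.arange(n_t) / 100.0, method="morlet",
            baseline_corrected=True,
        )

    def test_single_sensor_no_smoothing_identity(self, rng):
        p = rng.standard_normal((4, 3, 10, 50))
        tfs = [self._corrected_tf(p)]
        out = sensor_tf_summary(tfs, [1], smooth_fwhm=(0.0, 0.0))
        np.testing.assert_allclose(out["mean"], p[:, 1].mean(axis=0))

    def test_smoothing_preserves_total_power(self, rng):
        p = rng.uniform(0.5, 1.5, (2, 1, 30, 200))
        tfs = [self._corrected_tf(p)]
        out = sensor_tf_summary(tfs, [0], smooth_fwhm=(4.0, 0.2))
        raw = p[:, 0].mean(axis=0)
        # away from edges, kernel mass is conserved
        inner = (slice(8, -8), slice(40, -40))
        assert abs(out["mean"][inner].sum() / raw[inner].sum() - 1) < 0.01

    def test_null_data_mask_empty(self, rng):
        """Bonferroni mask stays empty for null data in ≥95/100 simulations."""
        empty = 0
        for rep in range(100):
            r = np.random.default_rng(rep)
            tfs = [
                self._corrected_tf(r.standard_normal((6, 1, 8, 30)))
                for _ in range(8)
            ]
            out = sensor_tf_summary(tfs, [0], smooth_fwhm=(0.0, 0.0))
            empty += not out["significant"].any()
        assert empty >= 95

    def test_empty_cluster_rejected(self, rng):
        tfs = [self._corrected_tf(rng.standard_normal((2, 2, 4, 10)))]
        with pytest.raises(ValueError, match="cluster"):
            sensor_tf_summary(tfs, [])


class TestICC:
    def test_identical_runs_unity(self, rng):
        row = rng.standard_normal(30)
        X = np.tile(row, (4, 1))
        assert icc_2k(X) == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_near_zero(self, rng):
        X = rng.standard_normal((3, 1000))
        assert abs(icc_2k(X)) < 0.1

    def test_worked_table_matches_mean_squares(self):
        """6 items × 4 raters table against an explicit mean-squares hand
        computation and the pingouin reference."""
        X = np.array(
            [
                [9.0, 2, 5, 8],
                [6, 1, 3, 2],
                [8, 4, 6, 8],
                [7, 1, 2, 6],
                [10, 5, 6, 9],
                [6, 2, 4, 7],
            ]
        ).T  # raters × items
        val = icc_2k(X)
        pg = pytest.importorskip("pingouin")
        k, n = X.shape
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "scores": X.T.ravel(),
            }
        )
        ref = pg.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="scores"
        )
        # two-way random, average measures = ICC(A,k) in pingouin's labels
        icc2k = float(
            ref.loc[ref["Type"].isin(["ICC2k", "ICC(A,k)"]), "ICC"].iloc[0]
        )
        assert val == pytest.approx(icc2k, abs=1e-9)

    def test_degenerate_items_flagged(self):
        with pytest.raises(ValueError):
            icc_2k(np.ones((3, 10)))


class TestParsevalSanity:
    def test_total_power_linear_in_variance(self, rng):
        sfreq = 250.0
        totals, variances = [], [1.0, 2.0, 4.0, 8.0, 16.0]
        for v in variances:
            x = np.sqrt(v) * rng.standard_normal((20, 1, 500))
            tf = morlet_tf(x, freqs=np.arange(5.0, 40.0, 5.0), sfreq=sfreq,
                           times=np.arange(500) / sfreq)
            totals.append(tf.power.mean())
        r = np.corrcoef(variances, totals)[0, 1]
        assert r**2 > 0.99


def test_packaged_signal_definitions():
    sigs = load_signal_definitions()
    assert len(sigs) == 6
    by_name = {s.name: s for s in sigs}
    alpha = by_name["visual_alpha_rdk"]
    assert alpha.band == (7, 13) and alpha.woi == (0.0, 2.0)
    assert alpha.baseline_woi == (-1.0, -0.5) and alpha.hypothesis == "deep"
    assert {s.event for s in sigs} == {"rdk", "cue", "response"}
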