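"""Preprocessing and time-frequency power.

Low frequencies (≤ 45 Hz) use seven-cycle complex Morlet wavelets on a 1 Hz
grid; high frequencies (55–115 Hz) use a sliding-window sine-taper
(multitaper) estimate on a 5 Hz grid with 200 ms windows stepped by 10 ms.
Baseline correction is frequency-specific and robust: the per-frequency
baseline is an iteratively reweighted (bisquare) average over baseline
samples, and power is expressed as a fractional (or percent) change from it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sps
from scipy.ndimage import gaussian_filter
from scipy.stats import t as t_dist

from .data import EpochedData

__all__ = [
    "TFRepresentation",
    "SignalDefinition",
    "load_signal_definitions",
    "preprocess",
    "morlet_tf",
    "multitaper_tf",
    "robust_average",
    "baseline_correct",
    "band_power",
    "windowed_band_variance",
    "sensor_tf_summary",
    "icc_2k",
]


@dataclass
class TFRepresentation:
    """Time-frequency power with its axes.

    ``power`` has shape (..., n_freqs, n_times) — leading axes are typically
    (trials, channels).  ``edge_mask`` flags time-frequency cells whose
    estimate overlaps the epoch edges (True = contaminated).
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    method: str
    baseline_corrected: bool = False
    baseline_woi: tuple | None = None
    edge_mask: np.ndarray | None = None  # (n_freqs, n_times)

    def __post_init__(self) -> None:
        if self.power.shape[-2] != len(self.freqs):
            raise ValueError("frequency axis inconsistent with power array")
        if self.power.shape[-1] != len(self.times):
            raise ValueError("time axis inconsistent with power array")
        if not self.baseline_corrected and np.any(self.power < -1e-12):
            raise ValueError("raw power must be non-negative")


@dataclass
class SignalDefinition:
    """A frequency band × epoch window contrast with a laminar hypothesis."""

    name: str
    band: tuple[float, float]
    event: str  # 'rdk' | 'cue' | 'response'
    woi: tuple[float, float]
    baseline_woi: tuple[float, float]
    hypothesis: str  # 'deep' | 'superficial'


def load_signal_definitions(path: str | Path | None = None) -> list[SignalDefinition]:
    """The six standard band/window contrasts, or a custom YAML file."""
    if path is None:
        text = (
            resources.files("laminarmeg") / "configs" / "signals.yaml"
        ).read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return [
        SignalDefinition(
            name=d["name"],
            band=tuple(d["band"]),
            event=d["event"],
            woi=tuple(d["woi"]),
            baseline_woi=tuple(d["baseline_woi"]),
            hypothesis=d["hypothesis"],
        )
        for d in raw["signals"]
    ]


# ---------------------------------------------------------------------------
# Preprocessing

def preprocess(
    raw: EpochedData,
    band: tuple[float, float] = (2.0, 100.0),
    notch: float | None = 50.0,
    fs_out: float = 250.0,
    reject_sd: float = 2.5,
) -> EpochedData:
    """Band-pass (5th-order Butterworth, zero-phase), notch, downsample and
    flag high-variance trials.

    Trials whose broadband variance exceeds ``reject_sd`` standard deviations
    of the across-trial mean variance are marked ``rejected`` in the trial
    table (they are kept in the array; downstream analyses drop them).
    """
    if fs_out > raw.sfreq:
        raise ValueError("fs_out must not exceed the input sampling rate")
    if band[1] >= fs_out / 2:
        raise ValueError(
            f"band edge {band[1]} Hz at or above Nyquist ({fs_out / 2} Hz) "
            "after resampling"
        )
    x = raw.data
    sos = sps.butter(5, band, btype="bandpass", fs=raw.sfreq, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=-1)
    if notch is not None and notch < raw.sfreq / 2:
        b, a = sps.iirnotch(notch, Q=30.0, fs=raw.sfreq)
        x = sps.filtfilt(b, a, x, axis=-1)
    up, down = (np.round([fs_out, raw.sfreq]) / np.gcd(
        int(round(fs_out)), int(round(raw.sfreq))
    )).astype(int)
    if (up, down) != (1, 1):
        x = sps.resample_poly(x, up, down, axis=-1)
    n_samp = x.shape[-1]
    times = raw.times[0] + np.arange(n_samp) / fs_out

    var = x.var(axis=(1, 2))
    z_sd = var.std(ddof=0)
    rejected = (
        np.abs(var - var.mean()) > reject_sd * z_sd if z_sd > 0 else np.zeros(
            len(var), bool
        )
    )
    trials = raw.trials.copy()
    trials["rejected"] = rejected
    return EpochedData(data=x, sfreq=fs_out, times=times, event=raw.event, trials=trials)


# ---------------------------------------------------------------------------
# Morlet wavelets

def _morlet_wavelet(f: float, sfreq: float, n_cycles: float) -> np.ndarray:
    sigma_t = n_cycles / (2.0 * np.pi * f)
    half = int(np.ceil(5.0 * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    w = np.exp(-(t**2) / (2 * sigma_t**2)) * np.exp(2j * np.pi * f * t)
    # L2 normalization
    w /= np.sqrt(0.5) * np.linalg.norm(w)
    return w


def morlet_tf(
    epochs: EpochedData | np.ndarray,
    freqs: np.ndarray | None = None,
    n_cycles: float = 7.0,
    sfreq: float | None = None,
    times: np.ndarray | None = None,
) -> TFRepresentation:
    """Per-trial power from complex Morlet convolution.

    ``freqs`` defaults to 2–45 Hz in 1 Hz steps.  Samples within one wavelet
    half-length of the epoch edges are flagged in ``edge_mask``.
    """
    if isinstance(epochs, EpochedData):
        x, sfreq, times = epochs.data, epochs.sfreq, epochs.times
    else:
        x = np.asarray(epochs, float)
        if sfreq is None or times is None:
            raise ValueError("sfreq and times required for array input")
    if freqs is None:
        freqs = np.arange(2.0, 46.0, 1.0)
    freqs = np.asarray(freqs, float)
    n_samp = x.shape[-1]
    fmin = freqs.min()
    if n_samp / sfreq < n_cycles / fmin:
        raise ValueError(
            f"epoch too short for {n_cycles} cycles at {fmin} Hz "
            f"(needs {n_cycles / fmin:.2f} s)"
        )
    power = np.empty(x.shape[:-1] + (len(freqs), n_samp))
    edge = np.zeros((len(freqs), n_samp), dtype=bool)
    flat = x.reshape(-1, n_samp)
    for fi, f in enumerate(freqs):
        w = _morlet_wavelet(f, sfreq, n_cycles)
        conv = sps.fftconvolve(flat, w[None, :], mode="same", axes=-1)
        power[..., fi, :] = (np.abs(conv) ** 2).reshape(x.shape[:-1] + (n_samp,))
        half = (len(w) - 1) // 2
        if half > 0:
            edge[fi, : min(half, n_samp)] = True
            edge[fi, -min(half, n_samp):] = True
    return TFRepresentation(
        power=power, freqs=freqs, times=np.asarray(times), method="morlet",
        edge_mask=edge,
    )


# ---------------------------------------------------------------------------
# Sine-taper (multitaper) sliding-window power

def _sine_tapers(n: int, k: int) -> np.ndarray:
    j = np.arange(1, n + 1)
    return np.stack(
        [np.sqrt(2.0 / (n + 1)) * np.sin(np.pi * m * j / (n + 1)) for m in
         range(1, k + 1)]
    )


def multitaper_tf(
    epochs: EpochedData | np.ndarray,
    freqs: np.ndarray | None = None,
    t_window: float = 0.2,
    t_step: float = 0.01,
    n_tapers: int = 3,
    sfreq: float | None = None,
    times: np.ndarray | None = None,
) -> TFRepresentation:
    """Sliding-window sine-taper spectral power on a coarse frequency grid
    (default 55–115 Hz in 5 Hz steps)."""
    if isinstance(epochs, EpochedData):
        x, sfreq, times = epochs.data, epochs.sfreq, epochs.times
    else:
        x = np.asarray(epochs, float)
        if sfreq is None or times is None:
            raise ValueError("sfreq and times required for array input")
    if freqs is None:
        freqs = np.arange(55.0, 116.0, 5.0)
    freqs = np.asarray(freqs, float)
    n_samp = x.shape[-1]
    win = int(round(t_window * sfreq))
    step = max(1, int(round(t_step * sfreq)))
    if win > n_samp:
        raise ValueError("analysis window exceeds epoch length")
    starts = np.arange(0, n_samp - win + 1, step)
    centers = np.asarray(times)[starts + win // 2]
    tapers = _sine_tapers(win, n_tapers)  # (k, win)
    tt = np.arange(win) / sfreq
    # DFT kernels at the requested frequencies, per taper
    kern = tapers[:, None, :] * np.exp(-2j * np.pi * freqs[None, :, None] * tt)
    flat = x.reshape(-1, n_samp)
    out = np.empty((flat.shape[0], len(freqs), len(starts)))
    for si, s in enumerate(starts):
        seg = flat[:, s : s + win]
        spec = np.einsum("nt,kft->nkf", seg, kern)
        out[:, :, si] = (np.abs(spec) ** 2).mean(axis=1) / win
    return TFRepresentation(
        power=out.reshape(x.shape[:-1] + (len(freqs), len(starts))),
        freqs=freqs,
        times=centers,
        method="multitaper",
    )


# ---------------------------------------------------------------------------
# Robust averaging & baseline correction

def robust_average(
    samples: np.ndarray,
    axis: int = 0,
    c: float = 4.685,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively reweighted mean with Tukey bisquare weights.

    The scale is the median absolute deviation (consistency-scaled); samples
    beyond ``c`` scaled deviations get zero weight.  Returns the weighted
    mean and the final weights in [0, 1].
    """
    x = np.moveaxis(np.asarray(samples, float), axis, 0)
    if x.shape[0] < 2:
        raise ValueError("robust_average needs at least 2 samples")
    mu = x.mean(axis=0)
    w = np.ones_like(x)
    for _ in range(max_iter):
        resid = x - mu
        med = np.median(resid, axis=0)
        mad = np.median(np.abs(resid - med), axis=0)
        scale = np.where(mad > 0, mad / 0.6745, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(scale > 0, resid / (c * scale), 0.0)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        # MAD = 0: a majority of samples sit exactly at the median — keep
        # those, reject the rest (the bisquare limit for scale → 0)
        w = np.where(scale > 0, w, (np.abs(resid - med) == 0).astype(float))
        wsum = w.sum(axis=0)
        new_mu = np.where(wsum > 0, (w * x).sum(axis=0) / np.where(wsum > 0, wsum, 1),
                          mu)
        if np.max(np.abs(new_mu - mu)) < tol * (1 + np.max(np.abs(mu))):
            mu = new_mu
            break
        mu = new_mu
    return mu, np.moveaxis(w, 0, axis)


def baseline_correct(
    tf: TFRepresentation,
    baseline_woi: tuple[float, float],
    mode: str = "fractional",
) -> TFRepresentation:
    """Frequency-specific robust-average baseline correction.

    The baseline b is the robust average of power over baseline time points,
    pooled across trials (the leading axis when present) but kept separate
    per channel and per frequency; output is (P − b)/b, times 100 for
    ``mode='percent'``.
    """
    if mode not in ("fractional", "percent"):
        raise ValueError("mode must be 'fractional' or 'percent'")
    mask = (tf.times >= baseline_woi[0]) & (tf.times <= baseline_woi[1])
    if not mask.any():
        raise ValueError("baseline window outside epoch")
    base = tf.power[..., mask]  # (..., f, tb)
    if base.ndim > 2:
        # pool trials (axis 0) with baseline times into one sample axis
        samples = np.moveaxis(base, 0, -1).reshape(base.shape[1:-1] + (-1,))
    else:
        samples = base
    b, _ = robust_average(samples, axis=-1)  # per channel × frequency
    if np.any(b <= 0):
        raise ValueError("non-positive baseline power; cannot normalize")
    b_full = b.reshape((1,) * (tf.power.ndim - 1 - b.ndim) + b.shape + (1,))
    out = (tf.power - b_full) / b_full
    if mode == "percent":
        out = out * 100.0
    return replace(
        tf, power=out, baseline_corrected=True, baseline_woi=tuple(baseline_woi)
    )


# ---------------------------------------------------------------------------
# Band power

def band_power(
    ts: np.ndarray,
    sfreq: float,
    times: np.ndarray,
    band: tuple[float, float],
    woi: tuple[float, float],
    method: str | None = None,
) -> np.ndarray:
    """Mean time-frequency power over band × window, one value per trial.

    Morlet is used for bands at or below 45 Hz, multitaper above — the same
    split as the sensor-level analysis.  ``ts`` is (trials, samples) or
    (trials, series, samples); series are averaged.
    """
    ts = np.asarray(ts, float)
    if ts.ndim == 2:
        ts = ts[:, None, :]
    if method is None:
        method = "morlet" if band[1] <= 45 else "multitaper"
    if method == "morlet":
        freqs = np.arange(np.floor(band[0]), np.ceil(band[1]) + 1.0, 1.0)
        tf = morlet_tf(ts, freqs=freqs, sfreq=sfreq, times=times)
    else:
        freqs = np.arange(band[0], band[1] + 1e-9, 5.0)
        tf = multitaper_tf(ts, freqs=freqs, sfreq=sfreq, times=times)
    tmask = (tf.times >= woi[0]) & (tf.times <= woi[1])
    if not tmask.any():
        raise ValueError("window of interest outside epoch")
    return tf.power[..., tmask].mean(axis=(-2, -1)).mean(axis=-1)


def windowed_band_variance(
    ts: np.ndarray,
    sfreq: float,
    times: np.ndarray,
    band: tuple[float, float],
    woi: tuple[float, float],
    sos: np.ndarray | None = None,
) -> np.ndarray:
    """Band power as the variance of the band-pass-filtered signal in a
    window — the fast Parseval-equivalent of averaging TF power over the
    band, used for per-vertex source power.

    ``ts`` is (trials, series, samples); returns (trials, series).
    """
    ts = np.asarray(ts, float)
    if sos is None:
        sos = sps.butter(4, band, btype="bandpass", fs=sfreq, output="sos")
    filt = sps.sosfiltfilt(sos, ts, axis=-1)
    mask = (times >= woi[0]) & (times <= woi[1])
    if not mask.any():
        raise ValueError("window of interest outside epoch")
    return filt[..., mask].var(axis=-1)


# ---------------------------------------------------------------------------
# Sensor-level summary across participants

def sensor_tf_summary(
    tfs: list[TFRepresentation],
    sensor_cluster: np.ndarray | list[int],
    smooth_fwhm: tuple[float, float] = (8.0, 0.08),
    alpha: float = 0.05,
) -> dict:
    """Cluster-averaged, smoothed spectrograms with a significance mask.

    Each participant's power (trials × channels × freqs × times, baseline-
    corrected) is averaged over trials and the sensor cluster, smoothed with
    a Gaussian kernel (FWHM in Hz and seconds), then tested against zero
    per pixel with a one-sample t across participants, Bonferroni-corrected
    over pixels.
    """
    cluster = np.asarray(sensor_cluster, int)
    if cluster.size == 0:
        raise ValueError("empty sensor cluster")
    maps = []
    ref = tfs[0]
    df_f = np.diff(ref.freqs).mean() if len(ref.freqs) > 1 else 1.0
    dt = np.diff(ref.times).mean() if len(ref.times) > 1 else 1.0
    sig_f = smooth_fwhm[0] / (2.3548 * df_f)
    sig_t = smooth_fwhm[1] / (2.3548 * dt)
    for tf in tfs:
        m = tf.power[:, cluster].mean(axis=(0, 1))  # (f, t)
        if sig_f > 0 or sig_t > 0:
            m = gaussian_filter(m, sigma=(sig_f, sig_t), mode="nearest")
        maps.append(m)
    stack = np.stack(maps)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    if n > 1:
        se = stack.std(axis=0, ddof=1) / np.sqrt(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, mean / se, 0.0)
        p = 2.0 * t_dist.sf(np.abs(tval), df=n - 1)
        mask = p < alpha / mean.size
    else:
        tval = np.zeros_like(mean)
        mask = np.zeros_like(mean, dtype=bool)
    return {
        "mean": mean,
        "per_participant": stack,
        "t": tval,
        "significant": mask,
        "freqs": ref.freqs,
        "times": ref.times,
    }


# ---------------------------------------------------------------------------
# Reproducibility

def icc_2k(measurements: np.ndarray) -> float:
    """ICC(2,k): two-way random effects, average-measures consistency of
    ``measurements`` shaped (raters/runs, items).

    From the two-way mean squares (items = targets, runs = raters):
    ICC(2,k) = (MS_items − MS_error) / (MS_items + (MS_runs − MS_error)/n).
    """
    X = np.asarray(measurements, float)
    k, n = X.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 runs and 2 items")
    grand = X.mean()
    item_means = X.mean(axis=0)
    run_means = X.mean(axis=1)
    ss_items = k * np.sum((item_means - grand) ** 2)
    ss_runs = n * np.sum((run_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_items - ss_runs
    ms_items = ss_items / (n - 1)
    ms_runs = ss_runs / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_items + (ms_runs - ms_err) / n
    if ms_items <= 0 or denom == 0:
        raise ValueError("zero between-item variance; ICC undefined")
    return float((ms_items - ms_err) / denom)
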