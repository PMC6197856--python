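"""Perturbation controls for a fitted laminar pipeline.

Four control experiments probe what the laminar statistic does when the
forward model or the data are degraded: lead-field shuffling (destroys the
anatomy↔sensor correspondence), simulated co-registration error (random
rigid transform of the sensor array), trial subsampling (effective SNR via
trial count), and white-noise injection (effective SNR via sensor noise).
Every control is a pure function of (session, spec): outputs are
bit-identical on re-run with the same seeds, and the veridical session is
never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import build_lead_field, perturb_coregistration, shuffle_lead_fields
from .pipeline import FittedSession, fit_session, laminar_analysis
from .spectral import SignalDefinition

__all__ = [
    "ControlSpec",
    "run_shuffle_control",
    "run_coreg_control",
    "run_subsample_control",
    "run_noise_control",
]


@dataclass
class ControlSpec:
    """Parameters of one control experiment."""

    kind: str  # 'shuffle' | 'coreg' | 'subsample' | 'noise'
    repetitions: int = 10
    seeds: list[int] = field(default_factory=list)
    trial_counts: tuple = ()  # subsample ladder; () = {10,20,40,80,160,all}
    noise_sds: tuple = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)  # × per-channel data SD
    mean_rot_deg: float = 10.0
    sd_rot_deg: float = 2.5
    mean_trans_mm: float = 10.0
    sd_trans_mm: float = 2.5

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not self.seeds:
            self.seeds = list(range(self.repetitions))
        if len(self.seeds) != self.repetitions:
            raise ValueError("seed list length must equal repetitions")


def run_shuffle_control(
    fitted: FittedSession,
    signals: list[SignalDefinition],
    spec: ControlSpec | None = None,
    metric: str = "global",
) -> dict:
    """Re-run the laminar analysis with permuted lead-field columns.

    Returns per-repetition results and, per signal, the mean shuffled
    pial−white ROI difference — the shifted null for the follow-up group
    Wilcoxon test.  The default ROI metric is global: after shuffling there
    is no meaningful functional peak, and the whole-brain ROI exposes the
    absolute superficial bias of a geometry-free model.
    """
    spec = spec or ControlSpec(kind="shuffle")
    session = fitted.session
    rows, results = [], {s.name: [] for s in signals}
    for rep, seed in enumerate(spec.seeds):
        lf_shuf = shuffle_lead_fields(fitted.leadfield, seed=seed)
        refit = fit_session(
            session, patch_fwhm=0.0, leadfield=lf_shuf,
            n_spatial=fitted.reduced.n_spatial,
            n_temporal=fitted.reduced.n_temporal,
            lambdas=(fitted.inversion.lam,),
        )
        for s in signals:
            r = laminar_analysis(refit, s, metric=metric)
            results[s.name].append(r)
            rows.append({"control": "shuffle", "repetition": rep,
                         "parameter": seed, "signal": s.name, "t": r.t,
                         "classification": r.classification,
                         "difference": r.difference})
    null_values = {
        name: float(np.mean([r.difference for r in res]))
        for name, res in results.items()
    }
    return {"results": results, "null_values": null_values,
            "table": pd.DataFrame(rows)}


def run_coreg_control(
    fitted: FittedSession,
    signals: list[SignalDefinition],
    spec: ControlSpec | None = None,
    metric: str = "functional",
) -> dict:
    """Re-run the laminar analysis with a randomly mis-registered sensor
    array (lead field rebuilt per repetition)."""
    spec = spec or ControlSpec(kind="coreg")
    session = fitted.session
    rows, results = [], {s.name: [] for s in signals}
    for rep, seed in enumerate(spec.seeds):
        sens = perturb_coregistration(
            session.sensors,
            mean_rot_deg=spec.mean_rot_deg, sd_rot_deg=spec.sd_rot_deg,
            mean_trans_mm=spec.mean_trans_mm, sd_trans_mm=spec.sd_trans_mm,
            seed=seed,
        )
        lf = build_lead_field(session.model, sens)
        refit = fit_session(
            session, patch_fwhm=fitted.patch_fwhm, leadfield=lf,
            n_spatial=fitted.reduced.n_spatial,
            n_temporal=fitted.reduced.n_temporal,
            lambdas=(fitted.inversion.lam,),
        )
        for s in signals:
            r = laminar_analysis(refit, s, metric=metric)
            results[s.name].append(r)
            rows.append({"control": "coreg", "repetition": rep,
                         "parameter": seed, "signal": s.name, "t": r.t,
                         "classification": r.classification,
                         "difference": r.difference})
    return {"results": results, "table": pd.DataFrame(rows)}


def run_subsample_control(
    fitted: FittedSession,
    signals: list[SignalDefinition],
    trial_counts: tuple = (),
    repetitions: int = 10,
    metric: str = "functional",
    base_seed: int = 0,
) -> dict:
    """Mean laminar t as a function of the number of trials used.

    For each count, ``repetitions`` random trial subsets are drawn, the
    inversion refitted on the subset, and the resulting t-statistics
    averaged.  Counts below 2 are skipped.
    """
    session = fitted.session
    n_avail = session.epochs.n_trials
    if not trial_counts:
        trial_counts = tuple(
            c for c in (10, 20, 40, 80, 160) if c < n_avail
        ) + (n_avail,)
    if max(trial_counts) > n_avail:
        raise ValueError("trial count exceeds available trials")
    rows = []
    for count in trial_counts:
        if count < 2:
            continue
        for rep in range(repetitions):
            rng = np.random.default_rng(base_seed + 1000 * rep + count)
            subset = (
                np.arange(n_avail) if count == n_avail
                else np.sort(rng.choice(n_avail, size=count, replace=False))
            )
            sub_epochs = session.epochs
            X = sub_epochs.data[subset]
            from dataclasses import replace as _replace

            from .data import EpochedData

            sub_session = _replace(
                session,
                epochs=EpochedData(
                    data=X, sfreq=sub_epochs.sfreq, times=sub_epochs.times,
                    event=sub_epochs.event,
                    trials=sub_epochs.trials.iloc[subset].reset_index(drop=True),
                ),
            )
            refit = fit_session(
                sub_session, patch_fwhm=fitted.patch_fwhm,
                n_spatial=fitted.reduced.n_spatial,
                n_temporal=fitted.reduced.n_temporal,
                lambdas=(fitted.inversion.lam,),
            )
            for s in signals:
                r = laminar_analysis(refit, s, metric=metric)
                rows.append({"control": "subsample", "repetition": rep,
                             "parameter": count, "signal": s.name, "t": r.t,
                             "classification": r.classification,
                             "difference": r.difference})
    df = pd.DataFrame(rows)
    mean_t = df.groupby(["signal", "parameter"])["t"].mean().reset_index()
    return {"table": df, "mean_t": mean_t}


def run_noise_control(
    fitted: FittedSession,
    signals: list[SignalDefinition],
    noise_sds: tuple = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0),
    metric: str = "functional",
    base_seed: int = 0,
) -> dict:
    """Laminar t as a function of added white sensor noise.

    ``noise_sds`` are multiples of the per-channel data SD; noise is added
    to the epoched sensor data before inversion and band power extraction.
    """
    if list(noise_sds) != sorted(noise_sds):
        raise ValueError("noise_sds must be ascending")
    session = fitted.session
    data_sd = float(session.epochs.data.std())
    rows = []
    from dataclasses import replace as _replace

    from .data import EpochedData

    for li, mult in enumerate(noise_sds):
        rng = np.random.default_rng(base_seed + 7919 * li)
        if mult == 0:
            sub_session = session
        else:
            X = session.epochs.data + mult * data_sd * rng.standard_normal(
                session.epochs.data.shape
            )
            sub_session = _replace(
                session,
                epochs=EpochedData(
                    data=X, sfreq=session.epochs.sfreq,
                    times=session.epochs.times, event=session.epochs.event,
                    trials=session.epochs.trials.copy(),
                ),
            )
        refit = fit_session(
            sub_session, patch_fwhm=fitted.patch_fwhm,
            n_spatial=fitted.reduced.n_spatial,
            n_temporal=fitted.reduced.n_temporal,
            lambdas=(fitted.inversion.lam,),
        )
        for s in signals:
            r = laminar_analysis(refit, s, metric=metric)
            rows.append({"control": "noise", "repetition": 0,
                         "parameter": mult, "signal": s.name, "t": r.t,
                         "classification": r.classification,
                         "difference": r.difference})
    return {"table": pd.DataFrame(rows)}
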