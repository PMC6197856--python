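"""End-to-end orchestration: simulate → invert → laminar statistics → group.

A fitted session holds the inversion operator (sensors → combined source
space); per-signal laminar analyses band-pass the sensor data, project to
source space, and contrast window-of-interest power against baseline power
per vertex and trial.  Group analysis runs several synthetic participants
and applies the exact Wilcoxon test to their pial−white differences.

Seeding: a single global seed fans out deterministically — participant p
uses seed ``base + p``, control repetition r of kind k uses
``base + 1000·(k+1) + r`` — so every stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .forward import LeadField, coherence_smooth
from .inversion import (
    InversionResult,
    NoiseModel,
    ReducedData,
    ebb_prior,
    invert,
    multi_reg_invert,
    reml_mix,
    svd_reduce,
)
from .laminar import (
    GroupResult,
    LaminarResult,
    define_roi,
    fractional_change,
    group_wilcoxon,
    laminar_ttest,
    vertexwise_t,
)
from .spectral import SignalDefinition
from .synthetic import SessionConfig, SimulatedSession, SourceSpec, simulate_session

__all__ = [
    "FittedSession",
    "fit_session",
    "laminar_analysis",
    "source_window_power",
    "run_participant",
    "run_group",
    "default_session_config",
    "RunManifest",
]


@dataclass
class FittedSession:
    """A simulated session with its fitted inversion."""

    session: SimulatedSession
    leadfield: LeadField  # coherence-smoothed, used for inversion
    reduced: ReducedData
    inversion: InversionResult
    operator: np.ndarray  # (n_sources, n_channels), full-rank sensor space
    patch_fwhm: float


def fit_session(
    session: SimulatedSession,
    patch_fwhm: float = 0.010,
    n_spatial: int = 180,
    n_temporal: int = 16,
    lambdas: tuple = (0,),
    noise: NoiseModel | None = None,
    leadfield: LeadField | None = None,
) -> FittedSession:
    """Reduce the data, build the beamformer prior on the patch-smoothed
    lead field, optimize hyperparameters by ReML and form the inversion
    operator.

    ``leadfield`` overrides the session's veridical (unsmoothed) lead field
    — used by the perturbation controls.
    """
    lf_raw = leadfield if leadfield is not None else session.leadfield
    lf = coherence_smooth(lf_raw, session.model, patch_fwhm)
    epochs = session.epochs
    keep = ~epochs.trials.get("rejected", pd.Series(False, index=epochs.trials.index))
    X = epochs.data[np.asarray(keep, bool)]
    n_spatial = min(n_spatial, X.shape[1])
    n_temporal = min(n_temporal, X.shape[2])
    reduced = svd_reduce(X, n_spatial=n_spatial, n_temporal=n_temporal)
    result, operator = _fit_reduced(reduced, lf, lambdas, noise)
    return FittedSession(
        session=session, leadfield=lf, reduced=reduced, inversion=result,
        operator=operator, patch_fwhm=patch_fwhm,
    )


def _fit_reduced(
    reduced: ReducedData,
    lf: LeadField,
    lambdas: tuple,
    noise: NoiseModel | None,
) -> tuple[InversionResult, np.ndarray]:
    """ReML-fit the beamformer in the reduced spatial basis and return the
    full-channel inversion operator (sources × channels).

    The lead field is projected into the spatial-mode basis so data and
    gains live in the same coordinates.
    """
    L_red = LeadField(
        L=reduced.spatial_projector @ lf.L, model=lf.model,
        patch_fwhm=lf.patch_fwhm,
    )
    if len(lambdas) == 1:
        prior = ebb_prior(reduced, L_red, lam=lambdas[0])
        result = reml_mix(reduced, L_red, prior, noise)
        est = invert(reduced, L_red, result)
    else:
        result, est = multi_reg_invert(reduced, L_red, lambdas=lambdas, noise=noise)
    return result, est.operator @ reduced.spatial_projector


def source_window_power(
    operator: np.ndarray, data: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Per-trial, per-source power (variance) within a time window.

    Computed covariance-side — diag(M C_t Mᵀ) per trial — which avoids
    materializing full source time courses.  ``data`` is
    (trials, channels, samples); returns (trials, sources).
    """
    n_trials = data.shape[0]
    nm = int(mask.sum())
    out = np.empty((n_trials, operator.shape[0]))
    for t in range(n_trials):
        seg = data[t][:, mask]
        mu = seg.mean(axis=1)
        C = (seg @ seg.T) / nm
        MC = operator @ C
        second = np.einsum("sc,sc->s", MC, operator)
        first = operator @ mu
        out[t] = np.maximum(second - first**2, 0.0)
    return out


def laminar_analysis(
    fitted: FittedSession,
    signal: SignalDefinition,
    metric: str = "global",
    mask: np.ndarray | None = None,
    percentile: float = 80.0,
    variance_floor: float | None = None,
    use_floor: bool = True,
    extra_noise_sd: float = 0.0,
    trial_subset: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    rms_exclude_frac: float = 0.1,
) -> LaminarResult:
    """The laminar discrimination statistic for one signal.

    Band-passes the sensor data to the signal band and builds unit-gain
    beamformer weights from the band-limited sensor covariance (regularized
    at the inversion's λ, as a percent of the mean eigenvalue).  Per-trial,
    per-vertex power is computed in the WOI and baseline windows; the ROI
    comes from the trial-pooled unsigned fractional-change maps (top 20% on
    either surface plus partners); per-trial ROI values are unsigned
    fractional changes against the trial-pooled frequency-specific baseline
    (the robust-average-over-trials convention), compared between surfaces
    with the variance-floored paired t-test.

    Sources whose lead-field column RMS falls below ``rms_exclude_frac`` of
    the median are excluded (their fractional change is set to zero): on a
    spherical conductor, near-radial sources are externally silent and
    carry no laminar information.
    """
    session = fitted.session
    epochs = session.epochs
    model = session.model
    keep = np.asarray(
        ~epochs.trials.get("rejected", pd.Series(False, index=epochs.trials.index)),
        bool,
    )
    X = epochs.data[keep]
    if trial_subset is not None:
        X = X[trial_subset]
    if extra_noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        X = X + extra_noise_sd * rng.standard_normal(X.shape)
    sos = sps.butter(4, signal.band, btype="bandpass", fs=epochs.sfreq, output="sos")
    Xf = sps.sosfiltfilt(sos, X, axis=-1)
    woi_mask = epochs.time_mask(*signal.woi)
    base_mask = epochs.time_mask(*signal.baseline_woi)
    if not woi_mask.any() or not base_mask.any():
        raise ValueError("signal windows fall outside the epoch")

    operator, good = band_beamformer(
        fitted.leadfield, Xf, lam=fitted.inversion.lam,
        rms_exclude_frac=rms_exclude_frac,
    )
    p_woi = source_window_power(operator, Xf, woi_mask)
    p_base = np.maximum(
        source_window_power(operator, Xf, base_mask), np.finfo(float).tiny
    )
    # trial-pooled maps define the ROI (orthogonal to the laminar contrast)
    pooled = np.where(
        good, fractional_change(p_woi.mean(axis=0), p_base.mean(axis=0)), 0.0
    )
    roi = define_roi(
        pooled[model.pial_slice], pooled[model.white_slice],
        percentile=percentile, metric=metric, mask=mask, model=model,
    )
    # per-trial unsigned change against the trial-pooled baseline
    base_pooled = p_base.mean(axis=0)
    frac = np.where(good[None, :], fractional_change(p_woi, base_pooled[None, :]),
                    0.0)
    white_frac = frac[:, model.white_slice]
    pial_frac = frac[:, model.pial_slice]
    pial_trials = pial_frac[:, roi].mean(axis=1)
    white_trials = white_frac[:, roi].mean(axis=1)
    t, p, cls = laminar_ttest(
        pial_trials, white_trials, variance_floor=variance_floor,
        use_floor=use_floor,
    )
    vw = vertexwise_t(pial_frac, white_frac, roi=roi)
    return LaminarResult(
        signal=signal, roi=roi, pial_trials=pial_trials,
        white_trials=white_trials, t=t, p=p, classification=cls,
        roi_metric=metric, vertexwise=vw,
    )


def band_beamformer(
    leadfield: LeadField,
    Xf: np.ndarray,
    lam: float = 0.0,
    rms_exclude_frac: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-gain beamformer weights from the band-limited sensor covariance.

    Row i is  wᵢ = C⁻¹Lᵢ / (LᵢᵀC⁻¹Lᵢ)  with C the trial-pooled sample
    covariance of ``Xf`` regularized by ``lam`` percent of its mean
    eigenvalue (plus a minimal numerical jitter at λ=0) — the empirical-
    covariance form of the MAP operator, with the per-source variance
    normalization absorbed by the unit-gain constraint.  Returns the
    operator (sources × channels) and the boolean mask of usable sources
    (column RMS ≥ ``rms_exclude_frac`` × median).
    """
    L = leadfield.L
    n_trials, n_ch, n_samp = Xf.shape
    C = np.einsum("tcs,tds->cd", Xf, Xf) / (n_trials * n_samp)
    mean_eig = np.trace(C) / n_ch
    C = C + (max(lam, 0.0) / 100.0 + 1e-8) * mean_eig * np.eye(n_ch)
    W = np.linalg.solve(C, L)  # (ch, src)
    denom = np.einsum("cs,cs->s", L, W)
    rms = np.sqrt((L**2).mean(axis=0))
    good = rms >= rms_exclude_frac * np.median(rms)
    denom = np.where(np.abs(denom) > 0, denom, 1.0)
    return (W / denom).T, good


# ---------------------------------------------------------------------------
# Standard study conditions

def default_session_config(
    seed: int = 0,
    snr_db: float = 0.0,
    subdivisions: int = 3,
    n_sensors: int = 130,
    trials_per_block: int = 120,
    n_blocks: int = 1,
    alpha_vertex: int | None = None,
    gamma_vertex: int | None = None,
) -> SessionConfig:
    """The canonical synthetic study condition: a deep (white-surface) alpha
    decrease and a superficial (pial-surface) gamma burst in an RDK-aligned
    epoch."""
    cfg = SessionConfig(
        sources=[],
        subdivisions=subdivisions,
        n_sensors=n_sensors,
        trials_per_block=trials_per_block,
        n_blocks=n_blocks,
        snr_db=snr_db,
        epoch_event="rdk",
        # 250 ms margin beyond the analysis windows keeps band-pass filter
        # transients out of the baseline and WOI
        epoch_tmin=-1.25,
        epoch_tmax=2.25,
        seed=seed,
    )
    # deterministic, seed-dependent source placement in the upper hemisphere
    rng = np.random.default_rng(seed + 77)
    n_vert = {1: 42, 2: 162, 3: 642, 4: 2562}.get(subdivisions)
    if alpha_vertex is None or gamma_vertex is None:
        from .synthetic import make_two_layer_model

        model = make_two_layer_model(subdivisions=subdivisions,
                                     wrinkle_amplitude=cfg.wrinkle_amplitude)
        n_vert = model.n_pairs
        upper = np.where(model.pial.vertices[:, 2] > 0.02)[0]
        if alpha_vertex is None:
            alpha_vertex = int(rng.choice(upper))
        if gamma_vertex is None:
            far = upper[
                np.linalg.norm(
                    model.pial.vertices[upper]
                    - model.pial.vertices[alpha_vertex],
                    axis=1,
                )
                > 0.05
            ]
            gamma_vertex = int(rng.choice(far if far.size else upper))
    cfg.sources = [
        SourceSpec(
            surface="white", vertex=alpha_vertex, band=(7, 13),
            woi=(0.0, 2.0), modulation=-0.4, patch_fwhm=0.010, amplitude=1.0,
        ),
        SourceSpec(
            surface="pial", vertex=gamma_vertex, band=(60, 90),
            woi=(0.25, 0.5), modulation=0.6, patch_fwhm=0.010, amplitude=0.6,
        ),
    ]
    return cfg


ALPHA_SIGNAL = SignalDefinition(
    name="visual_alpha_rdk", band=(7, 13), event="rdk", woi=(0.0, 2.0),
    baseline_woi=(-1.0, -0.5), hypothesis="deep",
)
GAMMA_SIGNAL = SignalDefinition(
    name="visual_gamma_rdk", band=(60, 90), event="rdk", woi=(0.25, 0.5),
    baseline_woi=(-0.5, -0.25), hypothesis="superficial",
)


def run_participant(
    config: SessionConfig,
    signals: list[SignalDefinition] | None = None,
    metric: str = "functional",
    patch_fwhm: float = 0.010,
    lambdas: tuple = (0,),
) -> dict:
    """Simulate one participant and run the laminar analysis per signal."""
    session = simulate_session(config)
    fitted = fit_session(session, patch_fwhm=patch_fwhm, lambdas=lambdas)
    signals = signals or [ALPHA_SIGNAL, GAMMA_SIGNAL]
    results = {s.name: laminar_analysis(fitted, s, metric=metric) for s in signals}
    return {"session": session, "fitted": fitted, "results": results}


def run_group(
    n_participants: int = 8,
    base_seed: int = 0,
    snr_db: float = 0.0,
    signals: list[SignalDefinition] | None = None,
    metric: str = "functional",
    config_factory=None,
    **config_kwargs,
) -> dict:
    """Simulate a group of participants and run group-level laminar tests.

    Returns per-participant results, per-signal :class:`GroupResult`s, and a
    tidy summary table.
    """
    signals = signals or [ALPHA_SIGNAL, GAMMA_SIGNAL]
    factory = config_factory or (
        lambda seed: default_session_config(seed=seed, snr_db=snr_db,
                                            **config_kwargs)
    )
    participants = []
    for p in range(n_participants):
        cfg = factory(base_seed + p)
        participants.append(run_participant(cfg, signals=signals, metric=metric))
    groups: dict[str, GroupResult] = {}
    rows = []
    for s in signals:
        res = [pt["results"][s.name] for pt in participants]
        groups[s.name] = group_wilcoxon(res)
        for i, r in enumerate(res):
            rows.append(
                {"participant": i, "signal": s.name, "metric": r.roi_metric,
                 "t": r.t, "p": r.p, "classification": r.classification,
                 "difference": r.difference}
            )
    return {
        "participants": participants,
        "group": groups,
        "table": pd.DataFrame(rows),
    }


# ---------------------------------------------------------------------------
# Run manifest

@dataclass
class RunManifest:
    """Provenance for a pipeline run: config hash, seeds, stage outputs."""

    config: dict
    seed: int
    stages: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def record(self, stage: str, outputs: list[str]) -> None:
        self.stages[stage] = {"outputs": sorted(outputs), "status": "ok"}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"config_hash": self.config_hash, "seed": self.seed,
                 "config": self.config, "stages": self.stages},
                indent=2, sort_keys=True, default=str,
            )
        )
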