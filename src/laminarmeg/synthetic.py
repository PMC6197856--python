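"""Synthetic laminar MEG sessions with known ground truth.

Generates the full study material: a two-layer cortical model, a synthetic
axial-gradiometer helmet, a factorial task schedule, and epoched sensor
data containing band-limited induced responses placed on either the pial or
the white surface as Gaussian spatial patches, plus white sensor noise at a
controlled SNR.

Geometry note: on a perfectly spherical cortex with surface-normal source
orientations every source is radial and hence externally silent in a
spherical conductor.  Real cortex is folded, which is what makes it visible
to MEG.  The generator therefore supports a smooth radial "wrinkle" of the
pial sphere (the white surface follows at a fixed thickness along the local
normal); sessions default to a wrinkled pair so normals acquire tangential
components, while amplitude 0 reproduces plain concentric spheres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
import yaml
from scipy import signal as sps

from .data import EpochedData
from .forward import (
    LeadField,
    SensorArray,
    build_lead_field,
    geodesic_distances,
)
from .mesh import LaminarModel, SurfaceMesh

__all__ = [
    "SourceSpec",
    "SessionConfig",
    "SimulatedSession",
    "make_two_layer_model",
    "make_sensor_array",
    "make_task_schedule",
    "simulate_session",
]


def _wrinkle(u: np.ndarray, omega: float = 6.0) -> np.ndarray:
    """Smooth bounded radial modulation field on the unit sphere."""
    x, y, z = u[:, 0], u[:, 1], u[:, 2]
    f = (
        np.sin(omega * x) * np.sin(omega * y)
        + np.sin(omega * y) * np.sin(omega * z)
        + np.sin(omega * z) * np.sin(omega * x)
    )
    return f / 1.5


def make_two_layer_model(
    radius: float = 0.07,
    thickness: float = 0.003,
    subdivisions: int = 3,
    wrinkle_amplitude: float = 0.0,
    scalp_offset: float = 0.01,
) -> LaminarModel:
    """Concentric two-layer source model (white inner, pial outer).

    The pial surface is an icosphere of the given radius, optionally
    modulated radially by a smooth wrinkle field of the given amplitude
    (meters); the white surface lies at ``thickness`` along the inward pial
    normal, so index correspondence holds by construction.  The scalp hull
    sits ``scalp_offset`` outside the pial hull.
    """
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    if thickness >= radius:
        raise ValueError("thickness must be smaller than the radius")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = np.asarray(ico.vertices, float)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    faces = np.asarray(ico.faces, np.int64)
    r = radius + wrinkle_amplitude * _wrinkle(u) if wrinkle_amplitude else radius
    pial = SurfaceMesh(u * np.atleast_1d(r)[:, None] if np.ndim(r) else u * r, faces)
    white = SurfaceMesh(pial.vertices - thickness * pial.normals, faces.copy())
    return LaminarModel(pial=pial, white=white, scalp_offset=scalp_offset)


def make_sensor_array(
    n: int = 130,
    helmet_radius: float = 0.105,
    cap_half_angle_deg: float = 120.0,
    sensor_type: str = "axial_gradiometer",
    baseline: float = 0.05,
) -> SensorArray:
    """Quasi-uniform (Fibonacci lattice) spherical-cap helmet with radial
    coil orientations."""
    if n < 10:
        raise ValueError("need at least 10 sensors")
    cosmax = np.cos(np.deg2rad(cap_half_angle_deg))
    i = np.arange(n) + 0.5
    # uniform in cos(theta) over the cap, golden-angle in azimuth
    costheta = 1.0 - (1.0 - cosmax) * i / n
    theta = np.arccos(costheta)
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    pos = helmet_radius * np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
        axis=1,
    )
    ori = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    return SensorArray(
        names=[f"CH{k:03d}" for k in range(n)],
        positions=pos,
        orientations=ori,
        types=[sensor_type] * n,
        baseline=baseline,
    )


def make_task_schedule(
    n_blocks: int = 1,
    trials_per_block: int = 180,
    congruent_frac: float = 0.7,
    coherence_levels: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomized factorial trial table with exact per-block counts.

    Per block: trials are balanced over coherence levels, motion direction
    within each level, and the congruent fraction within each
    level × direction cell, so counts are exact by design (a 180-trial block
    at 70% congruency contains 126 congruent and 54 incongruent trials, and
    60 per coherence level with 30 leftward each).  Raises when the design
    does not divide into integer cell counts.
    """
    per_level = trials_per_block / coherence_levels
    per_dir = per_level / 2.0
    n_cong = per_dir * congruent_frac
    for val, name in [(per_level, "coherence"), (per_dir, "direction"),
                      (n_cong, "congruence")]:
        if abs(val - round(val)) > 1e-9:
            raise ValueError(f"non-integer {name} cell count ({val}) for "
                             f"{trials_per_block} trials per block")
    per_dir, n_cong = int(round(per_dir)), int(round(n_cong))
    levels = ["low", "medium", "high"][:coherence_levels] + [
        f"level{i}" for i in range(3, coherence_levels)
    ]
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_blocks):
        for lev in levels:
            for direction in ("left", "right"):
                for i in range(per_dir):
                    congruent = i < n_cong
                    cue = direction if congruent else (
                        "right" if direction == "left" else "left"
                    )
                    rows.append(
                        {"block": b, "coherence": lev, "direction": direction,
                         "congruent": congruent, "cue_dir": cue}
                    )
    df = pd.DataFrame(rows)
    order = np.concatenate(
        [b * trials_per_block + rng.permutation(trials_per_block)
         for b in range(n_blocks)]
    )
    df = df.iloc[order].reset_index(drop=True)
    df["trial"] = np.arange(len(df))
    df["correct"] = True
    return df


@dataclass
class SourceSpec:
    """One laminar source: a Gaussian patch with band-limited induced
    activity whose power is modulated inside a window of interest.

    ``modulation`` is the signed fractional power change in the WOI relative
    to the ongoing (baseline) level: −0.3 is a 30% decrease (e.g. alpha),
    +0.5 a 50% burst (e.g. gamma).  ``condition_effects`` maps a trial-table
    column to per-value additive modulation offsets, e.g.
    ``{"congruent": {False: 0.2}}`` for an extra gamma increase on
    incongruent trials.
    """

    surface: str  # 'pial' | 'white'
    vertex: int
    band: tuple[float, float]
    woi: tuple[float, float]
    modulation: float
    patch_fwhm: float = 0.010  # m
    amplitude: float = 1.0  # baseline source strength (arbitrary units)
    condition_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.surface not in ("pial", "white"):
            raise ValueError("surface must be 'pial' or 'white'")
        if self.patch_fwhm <= 0:
            raise ValueError("patch FWHM must be > 0")


@dataclass
class SessionConfig:
    """Everything needed to generate one synthetic session."""

    sources: list[SourceSpec]
    radius: float = 0.07
    thickness: float = 0.003
    subdivisions: int = 3
    wrinkle_amplitude: float = 0.007
    n_sensors: int = 130
    helmet_radius: float = 0.105
    n_blocks: int = 1
    trials_per_block: int = 180
    congruent_frac: float = 0.7
    coherence_levels: int = 3
    snr_db: float = 0.0
    sfreq: float = 250.0
    epoch_event: str = "rdk"
    epoch_tmin: float = -1.0
    epoch_tmax: float = 2.0
    error_rate: float = 0.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        raw = yaml.safe_load(open(path))
        raw["sources"] = [SourceSpec(**s) for s in raw.get("sources", [])]
        return cls(**raw)


@dataclass
class SimulatedSession:
    config: SessionConfig
    model: LaminarModel
    sensors: SensorArray
    leadfield: LeadField  # unsmoothed, veridical
    epochs: EpochedData
    truth: pd.DataFrame


def _band_noise(
    rng: np.random.Generator, band, sfreq: float, n: int, shape: tuple
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (independent per trial →
    random phase, i.e. induced rather than evoked activity)."""
    sos = sps.butter(4, band, btype="bandpass", fs=sfreq, output="sos")
    pad = int(sfreq)  # 1 s padding absorbs filter transients
    x = rng.standard_normal(shape + (n + 2 * pad,))
    x = sps.sosfiltfilt(sos, x, axis=-1)[..., pad:-pad]
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _window_envelope(
    times: np.ndarray, woi, gain: float, ramp: float = 0.05
) -> np.ndarray:
    """Amplitude envelope: 1 outside the WOI, ``gain`` inside, raised-cosine
    ramps of ``ramp`` seconds at the edges."""
    env = np.ones_like(times)
    t0, t1 = woi
    inside = (times >= t0) & (times <= t1)
    env[inside] = gain
    for edge, sign in ((t0, 1), (t1, -1)):
        m = (times >= edge - ramp / 2) & (times <= edge + ramp / 2)
        x = (times[m] - edge) * sign / ramp + 0.5
        env[m] = 1.0 + (gain - 1.0) * (0.5 - 0.5 * np.cos(np.pi * np.clip(x, 0, 1)))
    return env


def simulate_session(config: SessionConfig) -> SimulatedSession:
    """Generate one complete synthetic session.

    Sensor SNR is 10·log10(P_signal/P_noise) where P_signal is the mean
    squared signal over channels and the union of source WOIs, and P_noise
    the white-noise variance.  Ground truth (surface, vertex, band,
    modulation, condition effects) is exported in ``truth``.
    """
    rng = np.random.default_rng(config.seed)
    model = make_two_layer_model(
        radius=config.radius,
        thickness=config.thickness,
        subdivisions=config.subdivisions,
        wrinkle_amplitude=config.wrinkle_amplitude,
    )
    sensors = make_sensor_array(n=config.n_sensors,
                                helmet_radius=config.helmet_radius)
    lf = build_lead_field(model, sensors)

    schedule = make_task_schedule(
        n_blocks=config.n_blocks,
        trials_per_block=config.trials_per_block,
        congruent_frac=config.congruent_frac,
        coherence_levels=config.coherence_levels,
        seed=config.seed,
    )
    if config.error_rate > 0:
        schedule["correct"] = rng.random(len(schedule)) >= config.error_rate
    n_trials = len(schedule)
    n_samp = int(round((config.epoch_tmax - config.epoch_tmin) * config.sfreq)) + 1
    times = config.epoch_tmin + np.arange(n_samp) / config.sfreq

    X = np.zeros((n_trials, sensors.n_channels, n_samp))
    woi_mask = np.zeros(n_samp, dtype=bool)
    truth_rows = []
    for spec in config.sources:
        mesh = model.pial if spec.surface == "pial" else model.white
        offset = model.n_pairs if spec.surface == "pial" else 0
        sigma = spec.patch_fwhm / 2.3548
        d = geodesic_distances(mesh, np.array([spec.vertex]), cutoff=4 * sigma)[0]
        w = np.exp(-0.5 * (d / sigma) ** 2)
        w[~np.isfinite(d)] = 0.0
        patch_idx = np.where(w > 1e-3)[0]
        gain = lf.L[:, offset + patch_idx] @ w[patch_idx]  # (channels,)

        mods = np.full(n_trials, spec.modulation)
        for col, effects in spec.condition_effects.items():
            vals = schedule[col]
            for key, extra in effects.items():
                mods = mods + np.where(vals == key, extra, 0.0)
        carriers = _band_noise(
            rng, spec.band, config.sfreq, n_samp, (n_trials,)
        )
        amp_gain = np.sqrt(np.maximum(1.0 + mods, 0.0))
        for t in range(n_trials):
            env = _window_envelope(times, spec.woi, amp_gain[t])
            X[t] += gain[:, None] * (spec.amplitude * carriers[t] * env)[None, :]
        woi_mask |= (times >= spec.woi[0]) & (times <= spec.woi[1])
        truth_rows.append(
            {"surface": spec.surface, "vertex": spec.vertex,
             "band_lo": spec.band[0], "band_hi": spec.band[1],
             "woi_lo": spec.woi[0], "woi_hi": spec.woi[1],
             "modulation": spec.modulation, "patch_fwhm": spec.patch_fwhm,
             "condition_effects": repr(spec.condition_effects)}
        )

    p_sig = float(np.mean(X[:, :, woi_mask] ** 2)) if woi_mask.any() else float(
        np.mean(X**2)
    )
    if p_sig <= 0:
        raise ValueError("zero signal power; target SNR unreachable")
    noise_sd = np.sqrt(p_sig / 10.0 ** (config.snr_db / 10.0))
    X = X + noise_sd * rng.standard_normal(X.shape)

    epochs = EpochedData(
        data=X, sfreq=config.sfreq, times=times, event=config.epoch_event,
        trials=schedule,
    )
    return SimulatedSession(
        config=config, model=model, sensors=sensors, leadfield=lf,
        epochs=epochs, truth=pd.DataFrame(truth_rows),
    )
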