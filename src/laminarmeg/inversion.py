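"""Empirical Bayesian beamformer (EBB) source inversion.

The generative model is Gaussian at both levels: sensor data Y with noise
covariance h_ε·Qε and source activity with prior covariance h_Q·Q, where Q
is diagonal with one variance per source of the combined two-surface space.
The beamformer prior estimates each diagonal element directly from the
sensor covariance,

    Q(i) = (1 / LiᵀLi) · (Liᵀ (YYᵀ)⁻¹ Li + λ̃)⁻¹ ,

with Li the lead-field column of source i and λ the regularization level
expressed as a percent of the mean eigenvalue of YYᵀ.  The hyperparameters
(h_ε, h_Q) are then optimized by restricted maximum likelihood (Fisher
scoring on log-scales), and the MAP current estimate is

    Ĵ = Q L ᵀ (Qε + L Q Lᵀ)⁻¹ Y

evaluated with the ReML-scaled covariances.  The ReML objective value F
("free energy") is retained for model comparison within a candidate set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data import EpochedData
from .forward import LeadField, coherence_smooth
from .mesh import LaminarModel

__all__ = [
    "ReducedData",
    "SourcePrior",
    "NoiseModel",
    "InversionResult",
    "SourceEstimate",
    "svd_reduce",
    "ebb_prior",
    "reml_mix",
    "invert",
    "multi_reg_invert",
    "patch_size_sweep",
]


@dataclass
class ReducedData:
    """SVD-reduced sensor data: spatial modes × temporal modes per trial."""

    Y: np.ndarray  # (trials, n_spatial, n_temporal)
    spatial_projector: np.ndarray  # (n_spatial, channels), orthonormal rows
    temporal_projector: np.ndarray  # (n_temporal, samples), orthonormal rows
    variance_captured: float = 1.0

    @property
    def n_spatial(self) -> int:
        return self.spatial_projector.shape[0]

    @property
    def n_temporal(self) -> int:
        return self.temporal_projector.shape[0]

    @property
    def n_trials(self) -> int:
        return self.Y.shape[0]

    def concatenated(self) -> np.ndarray:
        """Spatial modes × (trials · temporal modes)."""
        return np.concatenate(list(self.Y), axis=1)


@dataclass
class SourcePrior:
    """Diagonal source covariance with its regularization level."""

    q: np.ndarray  # (n_sources,), diagonal of Q
    lam: float = 0.0  # percent of mean eigenvalue of YYᵀ
    candidate_set: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, float)
        if np.any(self.q < 0):
            raise ValueError("source prior variances must be >= 0")


@dataclass
class NoiseModel:
    """Sensor-level noise covariance; identity unless an empty-room matrix
    is supplied."""

    Q_eps: np.ndarray | None = None
    source: str = "identity"

    def matrix(self, n: int) -> np.ndarray:
        if self.Q_eps is None:
            return np.eye(n)
        Q = np.asarray(self.Q_eps, float)
        if Q.shape != (n, n):
            raise ValueError("noise covariance shape mismatch")
        if not np.allclose(Q, Q.T, atol=1e-10):
            raise ValueError("noise covariance must be symmetric")
        return Q


@dataclass
class SourceEstimate:
    """MAP current estimate tied to the combined [white, pial] source space.

    ``operator`` is the linear map sensors→sources; ``J`` its application to
    the (reduced) data.
    """

    J: np.ndarray  # (n_sources, n_time) or per-trial via operator
    operator: np.ndarray  # (n_sources, n_channels)


@dataclass
class InversionResult:
    h_eps: float
    h_q: float
    free_energy: float
    lam: float
    prior: SourcePrior
    noise: NoiseModel
    n_iter: int
    converged: bool
    all_free_energies: dict = field(default_factory=dict)

    @property
    def hyperparameters(self) -> tuple[float, float]:
        return (self.h_eps, self.h_q)

    def save(self, path, estimate: "SourceEstimate | None" = None) -> None:
        """Serialize to HDF5: hyperparameters, free energy, λ, the prior
        diagonal, and optionally the current estimate Ĵ."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["h_eps"] = self.h_eps
            f.attrs["h_q"] = self.h_q
            f.attrs["free_energy"] = self.free_energy
            f.attrs["lambda"] = self.lam
            f.attrs["n_iter"] = self.n_iter
            f.attrs["converged"] = self.converged
            f.attrs["noise_source"] = self.noise.source
            f.create_dataset("prior_q", data=self.prior.q)
            if self.all_free_energies:
                g = f.create_group("candidate_free_energies")
                for lam, F in self.all_free_energies.items():
                    g.attrs[str(lam)] = F
            if estimate is not None:
                f.create_dataset("J", data=estimate.J)
                f.create_dataset("operator", data=estimate.operator)

    @classmethod
    def load(cls, path) -> tuple["InversionResult", "SourceEstimate | None"]:
        import h5py

        with h5py.File(path, "r") as f:
            res = cls(
                h_eps=float(f.attrs["h_eps"]),
                h_q=float(f.attrs["h_q"]),
                free_energy=float(f.attrs["free_energy"]),
                lam=float(f.attrs["lambda"]),
                prior=SourcePrior(q=f["prior_q"][()]),
                noise=NoiseModel(source=str(f.attrs["noise_source"])),
                n_iter=int(f.attrs["n_iter"]),
                converged=bool(f.attrs["converged"]),
                all_free_energies={
                    float(k): float(v)
                    for k, v in (f["candidate_free_energies"].attrs.items()
                                 if "candidate_free_energies" in f else [])
                },
            )
            est = None
            if "J" in f:
                est = SourceEstimate(J=f["J"][()], operator=f["operator"][()])
        return res, est


# ---------------------------------------------------------------------------
# Data reduction

def _as_array(epochs) -> np.ndarray:
    if isinstance(epochs, EpochedData):
        return epochs.data
    x = np.asarray(epochs, float)
    if x.ndim == 2:
        x = x[None]
    return x


def svd_reduce(epochs, n_spatial: int = 180, n_temporal: int = 16) -> ReducedData:
    """Reduce epoched data to dominant spatial and temporal modes.

    Spatial modes are the top left-singular vectors of the channel-wise
    concatenated data; temporal modes the top right-singular vectors of the
    spatially reduced, trial-stacked window.  Requested mode counts beyond
    the numerical rank are truncated with a warning.
    """
    X = _as_array(epochs)  # (trials, ch, samp)
    n_trials, n_ch, n_samp = X.shape
    if n_spatial > n_ch or n_temporal > n_samp:
        raise ValueError("requested modes exceed data dimensions")
    Xc = X.transpose(1, 0, 2).reshape(n_ch, n_trials * n_samp)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = min(n_spatial, rank)
    if k < n_spatial:
        warnings.warn(
            f"spatial modes truncated to rank {k} (< requested {n_spatial})",
            stacklevel=2,
        )
    A = U[:, :k].T  # (k, ch)
    total_var = float(np.sum(s**2))
    spat_var = float(np.sum(s[:k] ** 2))

    Xs = np.einsum("kc,tcs->tks", A, X)  # (trials, k, samp)
    M = Xs.reshape(n_trials * k, n_samp)
    _, st, Vt = np.linalg.svd(M, full_matrices=False)
    rank_t = int(np.sum(st > st[0] * 1e-12)) if st.size else 0
    m = min(n_temporal, rank_t)
    if m < n_temporal:
        warnings.warn(
            f"temporal modes truncated to rank {rank_t} (< requested {n_temporal})",
            stacklevel=2,
        )
    T = Vt[:m]  # (m, samp)
    temp_var = float(np.sum(st[:m] ** 2)) / float(np.sum(st**2))
    Y = np.einsum("tks,ms->tkm", Xs, T)
    return ReducedData(
        Y=Y,
        spatial_projector=A,
        temporal_projector=T,
        variance_captured=(spat_var / total_var) * temp_var if total_var else 1.0,
    )


def _data_matrix(Y) -> np.ndarray:
    if isinstance(Y, ReducedData):
        return Y.concatenated()
    Yc = np.asarray(Y, float)
    if Yc.ndim == 3:
        Yc = np.concatenate(list(Yc), axis=1)
    return Yc


# ---------------------------------------------------------------------------
# Beamformer prior

def ebb_prior(Y, L: LeadField | np.ndarray, lam: float = 0.0) -> SourcePrior:
    """Beamformer estimate of the diagonal source prior covariance.

    ``lam`` regularizes the sensor covariance: YYᵀ + (lam/100)·mean-eig·I is
    inverted in place of YYᵀ.  ``lam = 0`` is the default, highest-resolution
    estimate.
    """
    Yc = _data_matrix(Y)
    Lm = L.L if isinstance(L, LeadField) else np.asarray(L, float)
    if Lm.shape[0] != Yc.shape[0]:
        raise ValueError("lead field channel count does not match data")
    C = Yc @ Yc.T
    if lam > 0:
        C = C + (lam / 100.0) * (np.trace(C) / C.shape[0]) * np.eye(C.shape[0])
    try:
        cf = cho_factor(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "sensor covariance YYT is singular; use lam > 0 to regularize"
        ) from exc
    # also guard near-singular positive-definite failures
    if np.linalg.cond(C) > 1e12:
        raise np.linalg.LinAlgError(
            "sensor covariance YYT is numerically singular; use lam > 0"
        )
    M = cho_solve(cf, Lm)  # (ch, src) = C⁻¹ L
    power = np.einsum("cs,cs->s", Lm, M)  # Liᵀ C⁻¹ Li
    norm2 = np.einsum("cs,cs->s", Lm, Lm)  # LiᵀLi
    q = np.zeros(Lm.shape[1])
    ok = (norm2 > 0) & (power > 0)
    q[ok] = 1.0 / (norm2[ok] * power[ok])
    return SourcePrior(q=q, lam=lam)


# ---------------------------------------------------------------------------
# ReML hyperparameter optimization

def reml_mix(
    Y,
    L: LeadField | np.ndarray,
    prior: SourcePrior,
    noise: NoiseModel | None = None,
    max_iter: int = 128,
    tol: float = 1e-4,
) -> InversionResult:
    """Optimally mix noise and source covariances by restricted maximum
    likelihood.

    Maximizes F(h) = −N/2·(log det C + tr(C⁻¹ S)) over h = (h_ε, h_Q) with
    C = h_ε·Qε + h_Q·L Q Lᵀ and S the sample covariance of the N reduced
    data columns.  Hyperparameters are log-parameterized (hence positive);
    updates are Fisher-scoring steps with step-halving whenever F decreases
    or C loses positive definiteness.
    """
    Yc = _data_matrix(Y)
    Lm = L.L if isinstance(L, LeadField) else np.asarray(L, float)
    noise = noise or NoiseModel()
    n_ch, N = Yc.shape
    S = (Yc @ Yc.T) / N
    Q_eps = noise.matrix(n_ch)
    LQLt = (Lm * prior.q) @ Lm.T
    comps = [Q_eps, LQLt]

    tr_S = max(np.trace(S), 1e-300)
    h = np.array(
        [tr_S / (2.0 * np.trace(Q_eps)), tr_S / (2.0 * max(np.trace(LQLt), 1e-300))]
    )
    theta = np.log(np.maximum(h, 1e-300))
    theta_floor = np.log(h) - 40.0  # keep scales within exp(±40) of start

    def objective(th: np.ndarray):
        hh = np.exp(th)
        C = hh[0] * comps[0] + hh[1] * comps[1]
        try:
            cf = cho_factor(C, lower=True)
        except np.linalg.LinAlgError:
            return None
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Cinv = cho_solve(cf, np.eye(n_ch))
        F = -0.5 * N * (logdet + np.sum(Cinv * S))
        return F, Cinv, hh

    res = objective(theta)
    if res is None:
        raise np.linalg.LinAlgError("initial model covariance not positive definite")
    F, Cinv, h = res
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        CinvS = Cinv @ S
        g = np.empty(2)
        P = [Cinv @ c for c in comps]
        for k in range(2):
            g[k] = -0.5 * N * (np.trace(P[k]) - np.sum(CinvS * P[k].T)) * h[k]
        FIM = np.empty((2, 2))
        for k in range(2):
            for l in range(k, 2):
                FIM[k, l] = FIM[l, k] = (
                    0.5 * N * np.sum(P[k] * P[l].T) * h[k] * h[l]
                )
        try:
            step = np.linalg.solve(FIM + 1e-10 * np.eye(2) * np.trace(FIM), g)
        except np.linalg.LinAlgError:
            step = g / max(np.trace(FIM), 1e-300)
        step = np.clip(step, -8.0, 8.0)

        improved = False
        for _ in range(16):  # step-halving
            cand = np.maximum(theta + step, theta_floor)
            res = objective(cand)
            if res is not None and res[0] >= F - 1e-12:
                dF = res[0] - F
                theta, (F, Cinv, h) = cand, res
                improved = True
                break
            step = step / 2.0
        if not improved:
            converged = True
            break
        if abs(dF) < tol:
            converged = True
            break
    if not converged and n_iter == max_iter:
        warnings.warn("ReML did not converge within max_iter", stacklevel=2)
    return InversionResult(
        h_eps=float(h[0]),
        h_q=float(h[1]),
        free_energy=float(F),
        lam=prior.lam,
        prior=prior,
        noise=noise,
        n_iter=n_iter,
        converged=converged,
    )


def invert(Y, L: LeadField | np.ndarray, result: InversionResult) -> SourceEstimate:
    """MAP current estimate Ĵ = Q̂Lᵀ(Q̂ε + LQ̂Lᵀ)⁻¹Y with the ReML-scaled
    covariances Q̂ = h_Q·Q and Q̂ε = h_ε·Qε."""
    Yc = _data_matrix(Y)
    Lm = L.L if isinstance(L, LeadField) else np.asarray(L, float)
    if Lm.shape[0] != Yc.shape[0]:
        raise ValueError("lead field channel count does not match data")
    q_scaled = result.h_q * result.prior.q
    C = result.h_eps * result.noise.matrix(Lm.shape[0]) + (Lm * q_scaled) @ Lm.T
    cf = cho_factor(C)
    # M = Q̂ Lᵀ C⁻¹  (sources × channels)
    M = (q_scaled[:, None] * Lm.T) @ cho_solve(cf, np.eye(Lm.shape[0]))
    return SourceEstimate(J=M @ Yc, operator=M)


def multi_reg_invert(
    Y,
    L: LeadField | np.ndarray,
    lambdas: tuple = (0, 5, 10, 50, 100, 1000),
    noise: NoiseModel | None = None,
) -> tuple[InversionResult, SourceEstimate]:
    """Augmented EBB: score one beamformer prior per regularization level by
    ReML free energy and invert with the winner."""
    if len(lambdas) == 0:
        raise ValueError("at least one lambda required")
    results = {}
    errors = {}
    for lam in lambdas:
        try:
            prior = ebb_prior(Y, L, lam=lam)
            results[lam] = reml_mix(Y, L, prior, noise)
        except np.linalg.LinAlgError as exc:
            errors[lam] = exc
    if not results:
        raise RuntimeError(f"all regularization candidates failed: {errors}")
    best_lam = max(results, key=lambda k: results[k].free_energy)
    best = results[best_lam]
    best.all_free_energies = {k: v.free_energy for k, v in results.items()}
    return best, invert(Y, L, best)


def patch_size_sweep(
    Y,
    leadfield: LeadField,
    model: LaminarModel,
    fwhms: tuple = (0.0025, 0.005, 0.010, 0.020),
    noise: NoiseModel | None = None,
    lam: float = 0.0,
):
    """Fit one inversion per patch FWHM and report free energy relative to
    the mean over patch sizes (relative values sum to zero)."""
    import pandas as pd

    rows = []
    for fwhm in fwhms:
        lf = coherence_smooth(leadfield, model, fwhm)
        prior = ebb_prior(Y, lf, lam=lam)
        res = reml_mix(Y, lf, prior, noise)
        rows.append({"fwhm": fwhm, "free_energy": res.free_energy})
    df = pd.DataFrame(rows)
    df["relative_free_energy"] = df["free_energy"] - df["free_energy"].mean()
    return df
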