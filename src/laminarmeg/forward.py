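"""MEG forward model: dipole-in-sphere fields, lead fields, patch priors.

The volume conductor is the analytic homogeneous conducting sphere: the
external magnetic field of a current dipole has the Sarvas closed form and
is independent of the (spherically symmetric) conductivity profile.  Sources
sit at mesh vertices with fixed orientation along the vertex normal, so each
source contributes one lead-field column (Tesla per A·m).  Axial
gradiometer channels measure the field component along the coil orientation
at the pickup coil minus the same component at a second coil displaced by
the gradiometer baseline along that orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .mesh import LaminarModel, SurfaceMesh

__all__ = [
    "SensorArray",
    "LeadField",
    "dipole_field_sphere",
    "fit_sphere",
    "build_lead_field",
    "coherence_smooth",
    "shuffle_lead_fields",
    "perturb_coregistration",
    "read_sensor_csv",
    "write_sensor_csv",
]

MU0_OVER_4PI = 1e-7  # μ0 / 4π, T·m/A


@dataclass
class SensorArray:
    """MEG sensor geometry: coil positions, orientations, channel types."""

    names: list[str]
    positions: np.ndarray  # (n, 3) m
    orientations: np.ndarray  # (n, 3) unit
    types: list[str]  # 'magnetometer' | 'axial_gradiometer'
    baseline: float = 0.05  # m, axial gradiometer coil separation

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, float)
        self.orientations = np.ascontiguousarray(self.orientations, float)
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("sensor orientations must be unit vectors")
        if any(t == "axial_gradiometer" for t in self.types) and self.baseline <= 0:
            raise ValueError("gradiometer baseline must be > 0")

    @property
    def n_channels(self) -> int:
        return len(self.names)


@dataclass
class LeadField:
    """Gain matrix ``L`` (channels × sources) with provenance."""

    L: np.ndarray
    model: str = "sphere"
    sphere_center: np.ndarray | None = None
    sphere_radius: float | None = None
    patch_fwhm: float = 0.0  # m; 0 = unsmoothed point sources

    @property
    def n_channels(self) -> int:
        return self.L.shape[0]

    @property
    def n_sources(self) -> int:
        return self.L.shape[1]

    def column(self, i: int) -> np.ndarray:
        return self.L[:, i]

    def column_rms(self) -> np.ndarray:
        """Lead-field strength per source: root-mean-square of each column."""
        return np.sqrt(np.mean(self.L**2, axis=0))

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("L", data=self.L)
            f.attrs["model"] = self.model
            f.attrs["patch_fwhm"] = self.patch_fwhm
            if self.sphere_center is not None:
                f.attrs["sphere_center"] = self.sphere_center
                f.attrs["sphere_radius"] = self.sphere_radius

    @classmethod
    def load(cls, path: str | Path) -> "LeadField":
        with h5py.File(path, "r") as f:
            return cls(
                L=f["L"][()],
                model=str(f.attrs["model"]),
                patch_fwhm=float(f.attrs["patch_fwhm"]),
                sphere_center=f.attrs.get("sphere_center"),
                sphere_radius=(
                    float(f.attrs["sphere_radius"])
                    if "sphere_radius" in f.attrs
                    else None
                ),
            )


# ---------------------------------------------------------------------------
# Sarvas closed form

def dipole_field_sphere(
    dipole_position: np.ndarray,
    dipole_moment: np.ndarray,
    sensor_point: np.ndarray,
    sphere_center: np.ndarray | None = None,
) -> np.ndarray:
    """Magnetic field (T) of a current dipole in a conducting sphere.

    Closed form for the field outside a spherically symmetric conductor
    (Sarvas 1987):

        B(r) = μ0/(4π F²) · (F q×r0 − (q×r0 · r) ∇F)

    with r0 the dipole position and r the field point, both relative to the
    sphere center, a = r − r0, F = a(ra + r² − r0·r) and

        ∇F = (a²/r + a·r/a + 2a + 2r) r − (a + 2r + a·r/a) r0.

    A purely radial dipole moment produces zero external field.
    """
    c = np.zeros(3) if sphere_center is None else np.asarray(sphere_center, float)
    r0 = np.asarray(dipole_position, float) - c
    r = np.asarray(sensor_point, float) - c
    q = np.asarray(dipole_moment, float)

    return _sarvas(r0[None, :], q[None, :], r)[0]


def _sarvas(r0: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Vectorized Sarvas field: dipoles (d,3)+(d,3), one field point (3,).

    Returns (d, 3) fields at ``r`` for each dipole.
    """
    a_vec = r[None, :] - r0  # (d, 3)
    a = np.linalg.norm(a_vec, axis=1)  # (d,)
    rn = np.linalg.norm(r)
    if np.any(a < 1e-12):
        raise ValueError("sensor point coincides with a dipole")
    adotr = a_vec @ r  # (d,)
    F = a * (rn * a + rn**2 - (r0 @ r))
    if np.any(np.abs(F) < 1e-30):
        raise ValueError("field point on the dipole-center axis singularity")
    gF_r = a**2 / rn + adotr / a + 2.0 * a + 2.0 * rn  # coefficient of r
    gF_r0 = a + 2.0 * rn + adotr / a  # coefficient of r0
    gradF = gF_r[:, None] * r[None, :] - gF_r0[:, None] * r0  # (d, 3)
    qxr0 = np.cross(q, r0)  # (d, 3)
    B = (
        MU0_OVER_4PI
        / (F**2)[:, None]
        * (F[:, None] * qxr0 - (qxr0 * r[None, :]).sum(axis=1)[:, None] * gradF)
    )
    return B


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit (algebraic) to a point cloud.

    Solves ``|p|² = 2 c·p + (R² − |c|²)`` linearly for center c and radius R.
    """
    p = np.asarray(points, float)
    A = np.hstack([2.0 * p, np.ones((len(p), 1))])
    b = (p**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def build_lead_field(
    model: LaminarModel,
    sensors: SensorArray,
    patch_fwhm: float = 0.0,
) -> LeadField:
    """Lead field of the combined [white, pial] source space.

    One source per vertex, unit moment (1 A·m) along the vertex normal.  The
    conductor sphere is fitted to the scalp-hull vertices.  Isolated vertices
    (zero normal) get zero columns.  If ``patch_fwhm`` > 0 the columns are
    subsequently smoothed with :func:`coherence_smooth`.
    """
    center, radius = fit_sphere(model.scalp.vertices)
    pos = model.combined_vertices()
    mom = model.combined_normals()
    rad = np.linalg.norm(pos - center, axis=1)
    bad = np.where(rad >= radius)[0]
    if bad.size:
        raise ValueError(
            f"{bad.size} source vertices lie outside the fitted sphere "
            f"(radius {radius:.4f} m): indices {bad[:10].tolist()}..."
        )

    n_ch = sensors.n_channels
    L = np.zeros((n_ch, len(pos)))
    r0 = pos - center
    for ch in range(n_ch):
        ori = sensors.orientations[ch]
        p_out = sensors.positions[ch] - center
        B = _sarvas(r0, mom, p_out) @ ori
        if sensors.types[ch] == "axial_gradiometer":
            p_ref = p_out + sensors.baseline * ori
            B = B - _sarvas(r0, mom, p_ref) @ ori
        L[:, :][ch] = B
    lf = LeadField(L=L, model="sphere", sphere_center=center, sphere_radius=radius)
    if patch_fwhm > 0:
        lf = coherence_smooth(lf, model, patch_fwhm)
    return lf


# ---------------------------------------------------------------------------
# Spatial coherence (patch) prior

def _surface_graph(mesh: SurfaceMesh) -> csr_matrix:
    e = mesh.edges()
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    g = csr_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
    return g + g.T


def geodesic_distances(
    mesh: SurfaceMesh, sources: np.ndarray, cutoff: float = np.inf
) -> np.ndarray:
    """Graph-shortest-path distances along mesh edges from source vertices."""
    g = _surface_graph(mesh)
    return dijkstra(g, indices=sources, limit=cutoff)


def coherence_smooth(
    leadfield: LeadField, model: LaminarModel, fwhm: float
) -> LeadField:
    """Replace each column by a Gaussian-weighted sum of same-surface columns.

    Weights are a normalized Gaussian of geodesic (graph shortest-path)
    distance with the given FWHM in meters; smoothing never crosses between
    the white and pial surfaces.  ``fwhm = 0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return replace(leadfield, patch_fwhm=0.0)
    import warnings

    n = model.n_pairs
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    cache = model.__dict__.setdefault("_coherence_weights", {})
    out = np.empty_like(leadfield.L)
    for surf, sl in (("white", model.white_slice), ("pial", model.pial_slice)):
        mesh = model.white if surf == "white" else model.pial
        key = (surf, float(fwhm))
        if key in cache:
            W = cache[key]
        else:
            mean_edge = float(
                np.mean(
                    np.linalg.norm(
                        mesh.vertices[mesh.edges()[:, 0]]
                        - mesh.vertices[mesh.edges()[:, 1]],
                        axis=1,
                    )
                )
            )
            if fwhm < mean_edge / 2:
                warnings.warn(
                    f"patch FWHM {fwhm:.4f} m under-resolved on {surf} mesh "
                    f"(mean edge {mean_edge:.4f} m)",
                    stacklevel=2,
                )
            D = geodesic_distances(mesh, np.arange(n), cutoff=4.0 * sigma)
            W = np.exp(-0.5 * (D / sigma) ** 2)
            W[~np.isfinite(D)] = 0.0
            W /= W.sum(axis=1, keepdims=True)
            cache[key] = W
        block = leadfield.L[:, sl]
        out[:, sl] = block @ W.T
    return replace(leadfield, L=out, patch_fwhm=float(fwhm))


# ---------------------------------------------------------------------------
# Perturbations

def shuffle_lead_fields(leadfield: LeadField, seed: int) -> LeadField:
    """Permute lead-field columns with a uniform random permutation."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(leadfield.n_sources)
    return replace(leadfield, L=leadfield.L[:, perm])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    k = np.asarray(axis, float)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def perturb_coregistration(
    sensors: SensorArray,
    mean_rot_deg: float = 10.0,
    sd_rot_deg: float = 2.5,
    mean_trans_mm: float = 10.0,
    sd_trans_mm: float = 2.5,
    seed: int = 0,
) -> SensorArray:
    """Simulate between-session co-registration error.

    A rigid transform with rotation angle ~ N(mean_rot_deg, sd_rot_deg) about
    a uniformly random axis through the head origin, and a translation of
    magnitude ~ N(mean_trans_mm, sd_trans_mm) along a uniformly random
    direction, is applied to the whole sensor array (equivalent to
    mis-registering the anatomy against the sensors).
    """
    rng = np.random.default_rng(seed)
    angle = np.deg2rad(rng.normal(mean_rot_deg, sd_rot_deg)) if (
        mean_rot_deg or sd_rot_deg
    ) else 0.0
    trans_mag = (
        rng.normal(mean_trans_mm, sd_trans_mm) / 1000.0
        if (mean_trans_mm or sd_trans_mm)
        else 0.0
    )
    axis = _random_unit(rng)
    direction = _random_unit(rng)
    R = _rotation_matrix(axis, angle)
    t = trans_mag * direction
    return SensorArray(
        names=list(sensors.names),
        positions=sensors.positions @ R.T + t,
        orientations=sensors.orientations @ R.T,
        types=list(sensors.types),
        baseline=sensors.baseline,
    )


# ---------------------------------------------------------------------------
# Sensor layout I/O

def read_sensor_csv(path: str | Path) -> SensorArray:
    df = pd.read_csv(path)
    return SensorArray(
        names=df["name"].astype(str).tolist(),
        positions=df[["x", "y", "z"]].to_numpy(float),
        orientations=df[["ox", "oy", "oz"]].to_numpy(float),
        types=df["type"].tolist(),
        baseline=float(df["baseline"].iloc[0]),
    )


def write_sensor_csv(sensors: SensorArray, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "name": sensors.names,
            "x": sensors.positions[:, 0],
            "y": sensors.positions[:, 1],
            "z": sensors.positions[:, 2],
            "ox": sensors.orientations[:, 0],
            "oy": sensors.orientations[:, 1],
            "oz": sensors.orientations[:, 2],
            "type": sensors.types,
            "baseline": sensors.baseline,
        }
    )
    df.to_csv(path, index=False)
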