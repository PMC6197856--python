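"""Paired cortical surface meshes and derived geometry.

The laminar source space is built from two triangulated surfaces with a
one-to-one vertex correspondence: the white-matter/grey boundary (deep) and
the pial surface (superficial).  All coordinates are in meters in a
right-handed head frame with the origin at the conductor-sphere center.
The combined source space concatenates the two surfaces in the fixed order
``[white block, pial block]``; downstream sign conventions (positive
laminar t = pial/superficial) depend on this ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
from scipy.spatial import ConvexHull, cKDTree

__all__ = [
    "SurfaceMesh",
    "LaminarModel",
    "read_surface",
    "write_surface",
    "vertex_normals",
    "pair_laminar_vertices",
    "scalp_distance",
    "downsample_mesh",
    "downsample_pair",
]


class MeshValidationError(ValueError):
    """Raised when a mesh fails structural validation."""


@dataclass
class SurfaceMesh:
    """A triangle surface mesh.

    Parameters
    ----------
    vertices : (n, 3) float array, meters.
    faces : (m, 3) int array of vertex index triples.
    normals : (n, 3) float array of per-vertex unit normals; computed
        (area-weighted) on construction when not supplied.  Vertices with no
        incident face get a zero normal and are flagged in ``isolated``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None
    isolated: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be (n, 3)")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise MeshValidationError("faces must be (m, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise MeshValidationError(
                f"face index {self.faces.max()} out of range for "
                f"{len(self.vertices)} vertices"
            )
        if self.faces.size and self.faces.min() < 0:
            raise MeshValidationError("negative face index")
        counts = np.zeros(len(self.vertices), dtype=int)
        if self.faces.size:
            np.add.at(counts, self.faces.ravel(), 1)
        self.isolated = counts == 0
        if self.normals is None:
            self.normals = vertex_normals(self)
        else:
            self.normals = np.ascontiguousarray(self.normals, dtype=float)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) sorted-index array."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)


def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex unit normals, area-weighted over incident faces.

    Face normals weighted by face area (the cross-product magnitude) are
    accumulated at each corner vertex and normalized.  Degenerate faces have
    zero cross product and contribute nothing.  Isolated vertices keep a zero
    normal; callers exclude them from the source space.
    """
    if mesh.n_faces < 1:
        raise MeshValidationError("mesh has no faces")
    v = mesh.vertices
    f = mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    acc = np.zeros_like(v)
    for k in range(3):
        np.add.at(acc, f[:, k], fn)
    norm = np.linalg.norm(acc, axis=1)
    out = np.zeros_like(acc)
    ok = norm > 0
    out[ok] = acc[ok] / norm[ok, None]
    return out


# ---------------------------------------------------------------------------
# File I/O

def _read_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            if len(parts) < 4:
                raise MeshValidationError(f"malformed OBJ vertex line: {line!r}")
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            if len(parts) < 4:
                raise MeshValidationError(f"malformed OBJ face line: {line!r}")
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:4]]
            faces.append(idx)
    if not verts:
        raise MeshValidationError(f"no vertices found in {path}")
    return np.asarray(verts, float), np.asarray(faces, np.int64).reshape(-1, 3)


def read_surface(path: str | Path, format: str | None = None) -> SurfaceMesh:
    """Read a surface mesh from GIFTI (.gii) or Wavefront OBJ (.obj).

    A JSON sidecar ``<path>.json`` with ``{"units": "mm"}`` triggers
    conversion to meters; GIFTI xform units are honored the same way.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("gii", "gifti"):
        img = nib.load(str(path))
        verts = img.darrays[0].data.astype(float)
        faces = img.darrays[1].data.astype(np.int64)
    elif fmt == "obj":
        verts, faces = _read_obj(path)
    else:
        raise ValueError(f"unsupported surface format: {fmt}")
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("units", "m") in ("mm", "millimeters"):
            verts = verts / 1000.0
    return SurfaceMesh(verts, faces)


def write_surface(mesh: SurfaceMesh, path: str | Path, role: str | None = None) -> None:
    """Write a mesh as OBJ or GIFTI, with a JSON metadata sidecar."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "obj":
        lines = [f"v {x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.vertices]
        lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
    elif fmt in ("gii", "gifti"):
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))
    else:
        raise ValueError(f"unsupported surface format: {fmt}")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"units": "m", "role": role or "unknown"}))


# ---------------------------------------------------------------------------
# Laminar pairing

@dataclass
class LaminarModel:
    """Paired pial/white surfaces forming a two-layer source space.

    Vertex correspondence is strictly index-based: vertex ``i`` on the white
    surface pairs with vertex ``i`` on the pial surface, as produced by the
    surface generator.  The combined source space is ordered
    ``[white (0..n-1), pial (n..2n-1)]``.
    """

    pial: SurfaceMesh
    white: SurfaceMesh
    scalp_offset: float = 0.0  # m, radial inflation of the pial hull
    scalp: SurfaceMesh = field(init=False)
    pair_separation: np.ndarray = field(init=False)
    scalp_distance_pial: np.ndarray = field(init=False)
    scalp_distance_white: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.pial.n_vertices != self.white.n_vertices:
            raise MeshValidationError(
                f"pial/white vertex counts differ: "
                f"{self.pial.n_vertices} vs {self.white.n_vertices}"
            )
        self.pair_separation = np.linalg.norm(
            self.pial.vertices - self.white.vertices, axis=1
        )
        self.scalp = _convex_hull_mesh(self.pial.vertices)
        if self.scalp_offset > 0:
            centroid = self.scalp.vertices.mean(axis=0)
            rel = self.scalp.vertices - centroid
            rad = np.linalg.norm(rel, axis=1, keepdims=True)
            self.scalp = SurfaceMesh(
                centroid + rel * (1.0 + self.scalp_offset / rad),
                self.scalp.faces.copy(),
            )
        tree = cKDTree(self.scalp.vertices)
        self.scalp_distance_pial = tree.query(self.pial.vertices)[0]
        self.scalp_distance_white = tree.query(self.white.vertices)[0]

    @property
    def n_pairs(self) -> int:
        return self.pial.n_vertices

    @property
    def n_sources(self) -> int:
        """Size of the combined [white, pial] source space."""
        return 2 * self.n_pairs

    @property
    def white_slice(self) -> slice:
        return slice(0, self.n_pairs)

    @property
    def pial_slice(self) -> slice:
        return slice(self.n_pairs, 2 * self.n_pairs)

    def combined_vertices(self) -> np.ndarray:
        return np.vstack([self.white.vertices, self.pial.vertices])

    def combined_normals(self) -> np.ndarray:
        return np.vstack([self.white.normals, self.pial.normals])

    def combined_scalp_distance(self) -> np.ndarray:
        return np.concatenate([self.scalp_distance_white, self.scalp_distance_pial])


def _convex_hull_mesh(points: np.ndarray) -> SurfaceMesh:
    try:
        hull = ConvexHull(points)
    except Exception as exc:  # qhull raises its own error class
        raise MeshValidationError(f"convex hull construction failed: {exc}") from exc
    # reindex to hull vertices only
    idx = hull.vertices
    remap = -np.ones(len(points), dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    faces = remap[hull.simplices]
    return SurfaceMesh(points[idx], faces)


def pair_laminar_vertices(pial: SurfaceMesh, white: SurfaceMesh) -> LaminarModel:
    """Pair pial and white surfaces index-wise into a :class:`LaminarModel`.

    Raises on unequal vertex counts — there is deliberately no geometric
    nearest-neighbor fallback, because a silent mismatch would corrupt every
    downstream laminar comparison.
    """
    return LaminarModel(pial=pial, white=white)


def scalp_distance(model: LaminarModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex Euclidean distance to the nearest scalp-hull vertex.

    The scalp is the convex hull of the pial vertices; distances are from
    each (white, pial) vertex to the nearest hull vertex.
    """
    return model.scalp_distance_white.copy(), model.scalp_distance_pial.copy()


# ---------------------------------------------------------------------------
# Decimation

def downsample_mesh(
    mesh: SurfaceMesh, factor: float
) -> tuple[SurfaceMesh, np.ndarray]:
    """Decimate a mesh by iterative shortest-edge collapse.

    Returns the decimated mesh and the index array of surviving original
    vertices, so a partner surface can be decimated identically (see
    :func:`downsample_pair`).  The target vertex count is
    ``round(n / factor)``; topology is preserved by refusing collapses that
    would create non-manifold configurations.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = mesh.n_vertices
    target = int(round(n / factor))
    if target < 4:
        raise ValueError(f"factor {factor} would leave {target} < 4 vertices")
    if factor == 1 or target >= n:
        return SurfaceMesh(mesh.vertices.copy(), mesh.faces.copy()), np.arange(n)

    keep, faces = _edge_collapse(mesh.vertices, mesh.faces, target)
    return SurfaceMesh(mesh.vertices[keep], faces), keep


def _edge_collapse(
    vertices: np.ndarray, faces: np.ndarray, target: int
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy shortest-edge collapse onto surviving endpoints."""
    import heapq

    parent = np.arange(len(vertices))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # adjacency for manifold test: neighbors per vertex
    neighbors: list[set] = [set() for _ in range(len(vertices))]
    for a, b, c in faces:
        neighbors[a].update((b, c))
        neighbors[b].update((a, c))
        neighbors[c].update((a, b))

    heap: list[tuple[float, int, int]] = []
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    for a, b in np.unique(e, axis=0):
        heapq.heappush(heap, (float(np.linalg.norm(vertices[a] - vertices[b])), a, b))

    alive = len(vertices)
    while alive > target and heap:
        _, a, b = heapq.heappop(heap)
        ra, rb = find(a), find(b)
        if ra == rb or rb not in neighbors[ra]:
            continue
        # link condition: shared neighbors of the edge must be exactly 2
        shared = neighbors[ra] & neighbors[rb]
        if len(shared) != 2:
            continue
        # collapse rb into ra (ra survives at its original position)
        parent[rb] = ra
        neighbors[ra].discard(rb)
        for x in neighbors[rb]:
            if x != ra:
                neighbors[x].discard(rb)
                neighbors[x].add(ra)
                neighbors[ra].add(x)
                heapq.heappush(
                    heap, (float(np.linalg.norm(vertices[ra] - vertices[x])), ra, x)
                )
        neighbors[rb] = set()
        alive -= 1

    roots = np.array([find(i) for i in range(len(vertices))])
    keep = np.unique(roots)
    remap = -np.ones(len(vertices), dtype=np.int64)
    remap[keep] = np.arange(len(keep))
    new_faces = remap[roots[faces]]
    # drop degenerate faces (two corners collapsed together)
    good = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    new_faces = new_faces[good]
    # deduplicate faces that became identical
    key = np.sort(new_faces, axis=1)
    _, uniq = np.unique(key, axis=0, return_index=True)
    return keep, new_faces[np.sort(uniq)]


def downsample_pair(model: LaminarModel, factor: float) -> LaminarModel:
    """Decimate a laminar pair jointly so the vertex bijection survives.

    The collapse sequence is computed on the pial surface and the surviving
    vertex set carried over to the white surface, preserving index
    correspondence.
    """
    pial_ds, keep = downsample_mesh(model.pial, factor)
    white_ds = SurfaceMesh(model.white.vertices[keep], pial_ds.faces.copy())
    return LaminarModel(pial=pial_ds, white=white_ds)
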