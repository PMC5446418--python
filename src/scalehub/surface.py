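"""Template cortical surface geometry and surface-map smoothing.

The whole framework operates on a single template mesh with a companion
unit-sphere coordinate per vertex (the spherical parameterization on which
parcellation runs).  Vertex indices are 0-based and index-preserving across
the mesh, the sphere model and every scalar vertex map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import trimesh

__all__ = [
    "SurfaceMesh",
    "SphereModel",
    "VertexMap",
    "make_icosphere",
    "vertex_adjacency",
    "adjacency_matrix",
    "smooth_vertex_map",
    "load_mesh_obj",
    "save_mesh_obj",
    "load_sphere_tsv",
    "save_sphere_tsv",
    "load_vertex_map_tsv",
    "save_vertex_map_tsv",
]


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangle mesh in template mm space.

    ``hemisphere`` tags each vertex "L" or "R" so whole-cortex maps stay
    single arrays; the synthetic template assigns hemispheres by the sign
    of the x coordinate.
    """

    vertices: np.ndarray  # (V, 3) float, mm
    faces: np.ndarray     # (F, 3) int, 0-based
    hemisphere: np.ndarray = field(default=None)  # (V,) of "L"/"R"

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of vertex range")
        if self.hemisphere is None:
            hemi = np.where(v[:, 0] < 0, "L", "R")
            object.__setattr__(self, "hemisphere", hemi)
        else:
            hemi = np.asarray(self.hemisphere)
            if len(hemi) != len(v):
                raise ValueError("hemisphere tag length mismatch")
            object.__setattr__(self, "hemisphere", hemi)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class SphereModel:
    """Unit-sphere coordinate per mesh vertex (spherical parameterization)."""

    coords: np.ndarray  # (V, 3), unit norm rows

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        norms = np.linalg.norm(c, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sphere coordinates must have unit norm")
        object.__setattr__(self, "coords", c)

    @property
    def n_vertices(self) -> int:
        return len(self.coords)


@dataclass
class VertexMap:
    """A scalar field over mesh vertices with light provenance metadata.

    ``kind`` is one of {"bc", "nbc", "group_X", "his_st", "his_sc",
    "efficiency"}; ``scale``/``repeat`` apply where meaningful.
    """

    values: np.ndarray
    kind: str = "bc"
    scale: int | None = None
    repeat: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("vertex map contains non-finite values")
        self.values = v


def _values(m) -> np.ndarray:
    return np.asarray(m.values if isinstance(m, VertexMap) else m, dtype=float)


def make_icosphere(subdivisions: int, radius_mm: float = 80.0):
    """Deterministic icosphere template with its unit-sphere model.

    Returns ``(SurfaceMesh, SphereModel)`` with 10*4**subdivisions + 2
    vertices; the sphere model is the mesh scaled to unit norm, so the
    vertex correspondence is the identity.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
    verts = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=np.int64)
    unit = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return SurfaceMesh(verts, faces), SphereModel(unit)


def adjacency_matrix(mesh: SurfaceMesh) -> sp.csr_matrix:
    """Symmetric 0/1 vertex adjacency from the face list."""
    f = mesh.faces
    i = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    j = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    n = mesh.n_vertices
    a = sp.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    a = ((a + a.T) > 0).astype(float)
    a.setdiag(0)
    a.eliminate_zeros()
    return a.tocsr()


def vertex_adjacency(mesh: SurfaceMesh) -> list[np.ndarray]:
    """Neighbor index lists per vertex (sorted, self excluded)."""
    a = adjacency_matrix(mesh)
    return [a.indices[a.indptr[v]:a.indptr[v + 1]] for v in range(mesh.n_vertices)]


def _mean_edge_length(mesh: SurfaceMesh, adj: sp.csr_matrix) -> float:
    i, j = adj.nonzero()
    keep = i < j
    d = np.linalg.norm(mesh.vertices[i[keep]] - mesh.vertices[j[keep]], axis=1)
    return float(d.mean()) if d.size else 1.0


def smooth_vertex_map(vmap, mesh: SurfaceMesh, fwhm_mm: float, *, step: float = 0.5):
    """Surface-based diffusion smoothing of a vertex map.

    Realizes a heat kernel of full width at half maximum ``fwhm_mm`` by
    iterating the explicit graph-Laplacian step

        x <- x - (step / d_max) * L x

    which is symmetric, hence exactly mean-preserving, and with
    ``step <= 0.5`` has spectrum in [0, 1] so the variance never increases.
    The iteration count m is calibrated from the heat-equation diffusion
    time t = fwhm^2 / (16 ln 2) via m * step * h^2 ~= 2 t, with h the mean
    edge length.  Isolated vertices are left unchanged.
    """
    x = _values(vmap)
    if len(x) != mesh.n_vertices:
        raise ValueError("map length does not match mesh vertex count")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        out = x.copy()
    else:
        adj = adjacency_matrix(mesh)
        deg = np.asarray(adj.sum(axis=1)).ravel()
        d_max = deg.max() if deg.size else 1.0
        if d_max == 0:
            out = x.copy()
        else:
            h = _mean_edge_length(mesh, adj)
            t = fwhm_mm ** 2 / (16.0 * math.log(2.0))
            m = max(1, int(round(2.0 * t / (step * h * h))))
            lap = sp.diags(deg) - adj
            out = x.copy()
            c = step / d_max
            for _ in range(m):
                out = out - c * (lap @ out)
    if isinstance(vmap, VertexMap):
        return VertexMap(out, kind=vmap.kind, scale=vmap.scale, repeat=vmap.repeat)
    return out


# ---------------------------------------------------------------------------
# I/O: Wavefront OBJ for meshes, TSV for sphere coordinates and vertex maps.

def save_mesh_obj(mesh: SurfaceMesh, path) -> None:
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    tm.export(str(path), file_type="obj")


def load_mesh_obj(path) -> SurfaceMesh:
    tm = trimesh.load(str(path), file_type="obj", process=False)
    return SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))


def save_sphere_tsv(sphere: SphereModel, path) -> None:
    df = pd.DataFrame(sphere.coords, columns=["x", "y", "z"])
    df.insert(0, "vertex_id", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False)


def load_sphere_tsv(path) -> SphereModel:
    df = pd.read_csv(path, sep="\t").sort_values("vertex_id")
    return SphereModel(df[["x", "y", "z"]].to_numpy(float))


def save_vertex_map_tsv(vmap, path) -> None:
    vals = _values(vmap)
    df = pd.DataFrame({"vertex_id": np.arange(len(vals)), "value": vals})
    df.to_csv(path, sep="\t", index=False)


def load_vertex_map_tsv(path, kind: str = "bc") -> VertexMap:
    df = pd.read_csv(path, sep="\t").sort_values("vertex_id")
    return VertexMap(df["value"].to_numpy(float), kind=kind)
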