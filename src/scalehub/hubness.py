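"""Betweenness-centrality hub maps: nodal BC, z-normalization, projection.

Betweenness centrality of node i is the sum over unordered node pairs
(j, k), j != i != k, of the fraction of shortest paths between j and k
passing through i.  Shortest paths are computed on inverse-weight edge
lengths (the standard convention for fiber-count networks: stronger
connections are shorter), scaled by the maximum weight so that uniform
rescaling of all fiber counts leaves every edge length — and hence every
geodesic tie — bit-identical.  Disconnected pairs contribute zero, and no
(n-1)(n-2) normalization constant is applied; downstream z-scoring
absorbs constants either way.

Per repeat, the nodal BC values are z-normalized, projected to the template
surface (piecewise constant per parcel), averaged across the repeats, and
smoothed; the group map at each scale is the mean of the subjects'
z-normalized vertex maps.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np

from .parcellate import Parcellation
from .surface import SurfaceMesh, smooth_vertex_map

__all__ = [
    "betweenness_centrality",
    "znormalize_map",
    "project_to_vertices",
    "subject_hub_map",
    "group_average_map",
]


def _as_graph(matrix: np.ndarray, transform="inverse") -> nx.Graph:
    w = np.asarray(matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if (w < 0).any():
        raise ValueError("negative edge weights")
    if not np.allclose(w, w.T):
        raise ValueError("connectivity matrix must be symmetric")
    g = nx.Graph()
    g.add_nodes_from(range(len(w)))
    i, j = np.nonzero(np.triu(w, k=1))
    if i.size == 0:
        return g
    if transform == "inverse":
        # normalizing by the max weight leaves the metric unchanged up to a
        # constant but makes edge lengths (hence geodesic tie detection)
        # bit-identical under uniform scaling of all fiber counts
        dist = w[i, j].max() / w[i, j]
    elif transform == "neglog":
        dist = -np.log(w[i, j] / (w[i, j].max() + 1.0))
    else:
        raise ValueError(f"unknown weight transform {transform!r}")
    g.add_weighted_edges_from(zip(i.tolist(), j.tolist(), dist.tolist()), weight="dist")
    return g


def betweenness_centrality(matrix: np.ndarray, *, weight_transform="inverse",
                           ordered_pairs: bool = False) -> np.ndarray:
    """Exact weighted betweenness centrality per node (unordered pairs).

    ``ordered_pairs=True`` doubles every value (the directed-sum
    convention); the z-normalized map is identical either way.
    """
    g = _as_graph(matrix, weight_transform)
    bc = nx.betweenness_centrality(g, normalized=False, weight="dist")
    out = np.array([bc[i] for i in range(len(matrix))], dtype=float)
    return 2.0 * out if ordered_pairs else out


def znormalize_map(values: np.ndarray, *, ddof: int = 0) -> np.ndarray:
    """Center and scale to unit SD (population SD by default)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("degenerate map: all values identical (SD = 0), "
                         "cannot z-normalize")
    return (x - x.mean()) / sd


def project_to_vertices(values: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Piecewise-constant projection of nodal values onto mesh vertices.

    Excluded vertices (label 0) receive 0.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) != parcellation.K:
        raise ValueError(f"expected {parcellation.K} nodal values, got {len(vals)}")
    lut = np.concatenate([[0.0], vals])
    return lut[parcellation.labels]


def subject_hub_map(
    matrices_by_repeat: list,
    parcellations_by_repeat: list,
    mesh: SurfaceMesh,
    fwhm_mm: float = 20.0,
    *,
    normalize_per_repeat: bool = True,
    ordered_pairs: bool = False,
    ddof: int = 0,
) -> np.ndarray:
    """One subject's surface hub map at one nodal scale.

    For each parcellation repeat: BC -> z-normalize -> project to vertices;
    the repeat maps are averaged and the average smoothed with a
    ``fwhm_mm`` surface diffusion kernel.  Repeats whose BC map is constant
    (no information) are skipped with a warning.
    """
    if len(matrices_by_repeat) != len(parcellations_by_repeat):
        raise ValueError("matrices and parcellations must pair up per repeat")
    maps = []
    for w, parc in zip(matrices_by_repeat, parcellations_by_repeat):
        bc = betweenness_centrality(w, ordered_pairs=ordered_pairs)
        if bc.std() == 0:
            warnings.warn("constant BC map in one repeat; skipping it")
            continue
        vals = znormalize_map(bc, ddof=ddof) if normalize_per_repeat else bc
        maps.append(project_to_vertices(vals, parc))
    if not maps:
        raise ValueError("all repeats produced constant BC maps")
    mean_map = np.mean(maps, axis=0)
    if not normalize_per_repeat:
        mean_map = znormalize_map(mean_map, ddof=ddof)
    return smooth_vertex_map(mean_map, mesh, fwhm_mm)


def group_average_map(subject_maps: list, *, ddof: int = 0) -> np.ndarray:
    """Group hub map X: mean of the subjects' z-normalized vertex maps."""
    if len(subject_maps) < 2:
        raise ValueError("need at least 2 subject maps")
    n = len(subject_maps[0])
    if any(len(m) != n for m in subject_maps):
        raise ValueError("subject maps live on different meshes")
    return np.mean([znormalize_map(m, ddof=ddof) for m in subject_maps], axis=0)
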