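"""Per-subject weighted structural networks from streamline endpoints.

Two parcels are structurally connected when at least ``min_fibers``
(default 3) streamlines terminate with one endpoint in each; the edge
weight is the raw fiber count.  Intra-parcel streamlines never form edges.
The module also computes the short-association-fiber ratio: the share of
possible connections occupied by U-fibers / short fibers at a given nodal
scale, which shrinks as parcels get smaller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .parcellate import Parcellation
from .simulate import TractSet, SHORT_FIBER_MAX_MM
from .surface import SurfaceMesh

__all__ = [
    "EndpointAssignment",
    "snap_endpoints",
    "map_endpoints",
    "build_connectivity",
    "short_association_ratio",
    "save_matrix_mtx",
    "load_matrix_mtx",
]

DEFAULT_MIN_FIBERS = 3
DEFAULT_SNAP_TOLERANCE_MM = 2.0


@dataclass(frozen=True)
class EndpointAssignment:
    """Per-tract parcel pair (order-normalized, 0 = unassigned) and length."""

    parcel_a: np.ndarray   # (n,) int, <= parcel_b
    parcel_b: np.ndarray   # (n,) int
    lengths_mm: np.ndarray
    K: int

    def __post_init__(self):
        a = np.asarray(self.parcel_a, np.int64)
        b = np.asarray(self.parcel_b, np.int64)
        if np.any(a > b):
            raise ValueError("pairs must be order-normalized (parcel_a <= parcel_b)")
        if a.min(initial=0) < 0 or b.max(initial=0) > self.K:
            raise ValueError("parcel labels out of 0..K")
        object.__setattr__(self, "parcel_a", a)
        object.__setattr__(self, "parcel_b", b)
        object.__setattr__(self, "lengths_mm", np.asarray(self.lengths_mm, float))


def snap_endpoints(tracts: TractSet, mesh: SurfaceMesh):
    """Nearest mesh vertex (and distance) per endpoint; ties -> lowest index.

    Returns ``(va, vb, da, db)``.  Precompute once per subject and reuse
    across parcellations via ``map_endpoints(..., snapped=...)``.
    """
    tree = cKDTree(mesh.vertices)
    out = []
    for pts in (tracts.endpoints_a, tracts.endpoints_b):
        d, v = tree.query(pts, k=2)
        tie = np.isclose(d[:, 0], d[:, 1], rtol=0, atol=1e-12)
        idx = np.where(tie, np.minimum(v[:, 0], v[:, 1]), v[:, 0])
        out.append((idx.astype(np.int64), d[:, 0]))
    (va, da), (vb, db) = out
    return va, vb, da, db


def map_endpoints(
    tracts: TractSet,
    mesh: SurfaceMesh,
    parcellation: Parcellation,
    snap_tolerance_mm: float = DEFAULT_SNAP_TOLERANCE_MM,
    *,
    snapped=None,
) -> EndpointAssignment:
    """Assign each streamline endpoint to the parcel of its nearest vertex.

    Endpoints farther than ``snap_tolerance_mm`` from every vertex get
    label 0 and are excluded downstream.
    """
    if parcellation.n_vertices != mesh.n_vertices:
        raise ValueError("parcellation defined on a different mesh")
    va, vb, da, db = snapped if snapped is not None else snap_endpoints(tracts, mesh)
    lab = parcellation.labels
    pa = np.where(da <= snap_tolerance_mm, lab[va], 0)
    pb = np.where(db <= snap_tolerance_mm, lab[vb], 0)
    lo, hi = np.minimum(pa, pb), np.maximum(pa, pb)
    return EndpointAssignment(parcel_a=lo, parcel_b=hi,
                              lengths_mm=tracts.lengths_mm, K=parcellation.K)


def _pair_counts(assignment: EndpointAssignment, K: int):
    """Raw fiber counts per unordered parcel pair, including intra-parcel."""
    a, b = assignment.parcel_a, assignment.parcel_b
    ok = (a > 0) & (b > 0)
    flat = a[ok] * (K + 1) + b[ok]
    counts = np.bincount(flat, minlength=(K + 1) ** 2).reshape(K + 1, K + 1)
    return counts, ok


def build_connectivity(
    assignment: EndpointAssignment,
    K: int | None = None,
    min_fibers: int = DEFAULT_MIN_FIBERS,
) -> np.ndarray:
    """Symmetric K x K fiber-count matrix, thresholded at ``min_fibers``.

    Edges below the fiber threshold are dropped entirely (weight 0); kept
    edges carry the raw count.  The diagonal is zero: intra-parcel
    streamlines (U-fibers within one node) never form edges.
    """
    K = assignment.K if K is None else K
    if min_fibers < 1:
        raise ValueError("min_fibers must be >= 1")
    counts, _ = _pair_counts(assignment, K)
    inter = counts[1:, 1:].copy()
    np.fill_diagonal(inter, 0)
    inter[inter < min_fibers] = 0
    return inter + inter.T  # pairs were order-normalized into upper triangle


def short_association_ratio(
    assignment: EndpointAssignment,
    K: int | None = None,
    min_fibers: int = DEFAULT_MIN_FIBERS,
    short_length_mm: float = SHORT_FIBER_MAX_MM,
) -> float:
    """Share of possible connections occupied by short association fibers.

    Short association connections are (a) parcels whose *intra-parcel*
    streamline count reaches the fiber threshold (U-fibers living inside a
    single node) and (b) supra-threshold inter-parcel connections whose
    median streamline length is below ``short_length_mm``.  The denominator
    is the number of possible connections K(K-1)/2.
    """
    K = assignment.K if K is None else K
    if K < 2:
        raise ValueError("K must be >= 2")
    counts, ok = _pair_counts(assignment, K)
    intra = int(np.sum(np.diag(counts)[1:] >= min_fibers))
    a, b = assignment.parcel_a[ok], assignment.parcel_b[ok]
    ln = assignment.lengths_mm[ok]
    inter_mask = a != b
    short_edges = 0
    if inter_mask.any():
        df = pd.DataFrame({"a": a[inter_mask], "b": b[inter_mask], "l": ln[inter_mask]})
        g = df.groupby(["a", "b"])["l"].agg(["count", "median"])
        short_edges = int(((g["count"] >= min_fibers) & (g["median"] < short_length_mm)).sum())
    return (intra + short_edges) / (K * (K - 1) / 2)


def save_matrix_mtx(matrix: np.ndarray, path) -> None:
    scipy.io.mmwrite(str(path), sp.coo_matrix(matrix))


def load_matrix_mtx(path) -> np.ndarray:
    m = scipy.io.mmread(str(path))
    return np.asarray(m.todense() if sp.issparse(m) else m)
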