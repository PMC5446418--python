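"""Synthetic tractography cohort with planted, scale-stable connector hubs.

Real streamline data for this framework comes from deterministic whole-brain
tractography; none is bundled, so this module generates endpoint tables whose
*statistical* structure matches what the hub framework assumes:

* a modular wiring architecture (Voronoi modules on the template sphere);
* designated *connector* caps on module boundaries that mediate a large
  share of inter-module fibers, so connector cortex acquires elevated
  betweenness centrality at every nodal scale — the planted ground truth;
* a mixture of short association fibers (U-fibers: both endpoints within a
  small neighborhood, length < 30 mm) and long fibers (30-200 mm, mirroring
  tracking length bounds);
* independent per-subject sampling noise around the shared architecture.

Endpoints are snapped to mesh vertices and jittered by < 0.5 mm, which keeps
the endpoint-to-parcel mapping exact and testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from ._rng import derive_seed
from .surface import (
    SurfaceMesh,
    SphereModel,
    make_icosphere,
    adjacency_matrix,
    save_mesh_obj,
    save_sphere_tsv,
)

__all__ = [
    "ZoneLabels",
    "TractSet",
    "CohortData",
    "SimulationConfig",
    "plant_architecture",
    "simulate_subject_tracts",
    "simulate_cohort",
    "save_cohort",
    "load_cohort",
    "load_tracts_tsv",
]

SHORT_FIBER_MAX_MM = 30.0


@dataclass(frozen=True)
class ZoneLabels:
    """Planted architecture: module id per vertex plus a connector flag."""

    zone: np.ndarray       # (V,) int, 1..n_modules
    connector: np.ndarray  # (V,) bool

    def __post_init__(self):
        object.__setattr__(self, "zone", np.asarray(self.zone, dtype=np.int64))
        object.__setattr__(self, "connector", np.asarray(self.connector, dtype=bool))
        if len(self.zone) != len(self.connector):
            raise ValueError("zone/connector length mismatch")

    @property
    def n_modules(self) -> int:
        return int(self.zone.max())


@dataclass(frozen=True)
class TractSet:
    """Per-subject streamline endpoints (mm) and lengths."""

    subject_id: str
    endpoints_a: np.ndarray  # (n, 3)
    endpoints_b: np.ndarray  # (n, 3)
    lengths_mm: np.ndarray   # (n,)

    def __post_init__(self):
        a = np.asarray(self.endpoints_a, float)
        b = np.asarray(self.endpoints_b, float)
        ln = np.asarray(self.lengths_mm, float)
        if not (len(a) == len(b) == len(ln)):
            raise ValueError("endpoint/length arrays must have equal length")
        if np.any(ln <= 0):
            raise ValueError("streamline lengths must be positive")
        object.__setattr__(self, "endpoints_a", a)
        object.__setattr__(self, "endpoints_b", b)
        object.__setattr__(self, "lengths_mm", ln)

    @property
    def n_tracts(self) -> int:
        return len(self.lengths_mm)


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the bundled study conditions.

    A small two-hemisphere-like sphere (icosphere(4), 2562 vertices, 80 mm
    radius) stands in for the cortical template; 10 subjects with 20,000
    streamlines each stand in for a clinical cohort at desk scale.
    """

    subdivisions: int = 4
    radius_mm: float = 80.0
    n_modules: int = 4
    connector_fraction: float = 0.12
    n_subjects: int = 10
    n_tracts: int = 20000
    p_connector_route: float = 0.75
    short_fiber_rate: float = 0.30
    intra_module_rate: float = 0.5   # share of long fibers staying within a module
    short_radius_mm: float = 12.0    # endpoint separation cap for U-fibers


@dataclass
class CohortData:
    """A simulated cohort: shared template + architecture, per-subject tracts."""

    mesh: SurfaceMesh
    sphere: SphereModel
    zones: ZoneLabels
    tracts: list
    config: SimulationConfig
    master_seed: int


def _farthest_point_sample(coords: np.ndarray, k: int, rng: np.random.Generator):
    """Deterministic farthest-point vertex sample (first point from rng)."""
    n = len(coords)
    first = int(rng.integers(n))
    chosen = [first]
    mind = np.linalg.norm(coords - coords[first], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(mind))  # first occurrence -> lowest index on ties
        chosen.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(coords - coords[nxt], axis=1))
    return np.array(chosen, dtype=np.int64)


def plant_architecture(
    mesh: SurfaceMesh,
    sphere: SphereModel,
    n_modules: int = 4,
    connector_fraction: float = 0.12,
    seed: int = 0,
) -> ZoneLabels:
    """Plant Voronoi modules on the sphere with connector caps on boundaries.

    Modules are Voronoi cells of farthest-point-sampled seed vertices; one
    connector cap is placed per adjacent module pair, centered on that pair's
    boundary, and cap radii grow jointly until ``connector_fraction`` of
    vertices (to rounding) are flagged — so caps are spatially contiguous.
    """
    n = mesh.n_vertices
    if n_modules < 2:
        raise ValueError("n_modules must be >= 2")
    if n_modules > n:
        raise ValueError("n_modules exceeds vertex count")
    if not (0 < connector_fraction < 0.5):
        raise ValueError("connector_fraction must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    coords = sphere.coords
    seeds = _farthest_point_sample(coords, n_modules, rng)
    d = np.linalg.norm(coords[:, None, :] - coords[seeds][None, :, :], axis=2)
    zone = np.argmin(d, axis=1).astype(np.int64) + 1

    adj = adjacency_matrix(mesh)
    # boundary vertices: at least one neighbor in another module
    i, j = adj.nonzero()
    boundary_pairs = {}
    for u, v in zip(i, j):
        zu, zv = zone[u], zone[v]
        if zu != zv:
            key = (min(zu, zv), max(zu, zv))
            boundary_pairs.setdefault(key, []).append(u)
    centers = []
    for key in sorted(boundary_pairs):
        verts = np.unique(boundary_pairs[key])
        centroid = coords[verts].mean(axis=0)
        centers.append(verts[np.argmin(np.linalg.norm(coords[verts] - centroid, axis=1))])
    centers = np.array(sorted(set(centers)), dtype=np.int64)

    dc = np.linalg.norm(coords[:, None, :] - coords[centers][None, :, :], axis=2).min(axis=1)
    k = int(round(connector_fraction * n))
    order = np.argsort(dc, kind="stable")
    connector = np.zeros(n, dtype=bool)
    connector[order[:k]] = True
    return ZoneLabels(zone=zone, connector=connector)


def _short_neighbor_csr(mesh: SurfaceMesh, radius_mm: float):
    """CSR-style (offsets, indices) of vertices within radius, self excluded."""
    tree = cKDTree(mesh.vertices)
    lists = tree.query_ball_point(mesh.vertices, r=radius_mm)
    offsets = np.zeros(len(lists) + 1, dtype=np.int64)
    flat = []
    for v, lst in enumerate(lists):
        lst = [u for u in lst if u != v]
        offsets[v + 1] = offsets[v] + len(lst)
        flat.extend(lst)
    return offsets, np.array(flat, dtype=np.int64)


def simulate_subject_tracts(
    zones: ZoneLabels,
    mesh: SurfaceMesh,
    n_tracts: int,
    p_connector_route: float = 0.75,
    short_fiber_rate: float = 0.30,
    seed: int = 0,
    *,
    intra_module_rate: float = 0.5,
    short_radius_mm: float = 12.0,
    subject_id: str = "sub-00",
    _short_csr=None,
) -> TractSet:
    """Sample one subject's streamline endpoint set.

    Streamlines are drawn from three pools: U-fibers (rate
    ``short_fiber_rate``; endpoints within ``short_radius_mm``, length
    uniform on [20, 30) mm), intra-module long fibers, and inter-module long
    fibers.  An inter-module fiber terminates in a connector cap with
    probability ``p_connector_route`` (otherwise both endpoints are uniform
    over the two modules), which concentrates inter-module traffic on the
    connector cortex.  Long-fiber lengths are lognormal clipped to
    [30, 200] mm.  Endpoints are vertex positions jittered by < 0.5 mm.
    """
    if n_tracts <= 0:
        raise ValueError("n_tracts must be positive")
    if len(zones.zone) != mesh.n_vertices:
        raise ValueError("zones defined on a different mesh")
    rng = np.random.default_rng(seed)
    n = mesh.n_vertices
    zone = zones.zone
    modules = np.arange(1, zones.n_modules + 1)
    mod_verts = {m: np.flatnonzero(zone == m) for m in modules}
    mod_nonconn = {m: np.flatnonzero((zone == m) & ~zones.connector) for m in modules}
    conn_by_mod = {m: np.flatnonzero((zone == m) & zones.connector) for m in modules}

    u = rng.random(n_tracts)
    is_short = u < short_fiber_rate
    is_intra = (~is_short) & (u < short_fiber_rate + (1 - short_fiber_rate) * intra_module_rate)
    is_inter = ~is_short & ~is_intra

    va = np.empty(n_tracts, dtype=np.int64)
    vb = np.empty(n_tracts, dtype=np.int64)
    lengths = np.empty(n_tracts, dtype=float)

    # --- U-fibers
    idx = np.flatnonzero(is_short)
    if idx.size:
        if _short_csr is None:
            _short_csr = _short_neighbor_csr(mesh, short_radius_mm)
        offsets, flat = _short_csr
        a = rng.integers(n, size=idx.size)
        counts = offsets[a + 1] - offsets[a]
        # vertices with no in-radius neighbor fall back to themselves' nearest
        pick = (rng.random(idx.size) * np.maximum(counts, 1)).astype(np.int64)
        if flat.size:
            flat_idx = np.minimum(offsets[a] + np.minimum(pick, np.maximum(counts - 1, 0)),
                                  len(flat) - 1)
            b = np.where(counts > 0, flat[flat_idx], (a + 1) % n)
        else:
            # coarse template: no vertex pair within the U-fiber radius;
            # fall back to an adjacent vertex index
            b = (a + 1) % n
        va[idx], vb[idx] = a, b
        lengths[idx] = rng.uniform(20.0, SHORT_FIBER_MAX_MM - 1e-6, size=idx.size)

    # --- intra-module long fibers
    idx = np.flatnonzero(is_intra)
    if idx.size:
        m = rng.choice(modules, size=idx.size, p=[len(mod_verts[m]) / n for m in modules])
        a = np.empty(idx.size, dtype=np.int64)
        b = np.empty(idx.size, dtype=np.int64)
        for mm in modules:
            sel = m == mm
            if sel.any():
                a[sel] = rng.choice(mod_verts[mm], size=sel.sum())
                b[sel] = rng.choice(mod_verts[mm], size=sel.sum())
        va[idx], vb[idx] = a, b
        lengths[idx] = np.clip(rng.lognormal(np.log(70.0), 0.45, size=idx.size), 30.0, 200.0)

    # --- inter-module long fibers
    idx = np.flatnonzero(is_inter)
    if idx.size:
        pairs = [(m1, m2) for m1 in modules for m2 in modules if m1 < m2]
        pi = rng.integers(len(pairs), size=idx.size)
        routed = rng.random(idx.size) < p_connector_route
        a = np.empty(idx.size, dtype=np.int64)
        b = np.empty(idx.size, dtype=np.int64)
        side = rng.random(idx.size) < 0.5
        for k, (m1, m2) in enumerate(pairs):
            sel = pi == k
            if not sel.any():
                continue
            for flip in (False, True):
                s = sel & (side == flip)
                if not s.any():
                    continue
                src, dst = (m1, m2) if not flip else (m2, m1)
                conn = conn_by_mod[src]
                r = (s & routed) if conn.size else np.zeros_like(s)
                if r.any():
                    a[r] = rng.choice(conn, size=r.sum())
                    pool = mod_nonconn[dst] if mod_nonconn[dst].size else mod_verts[dst]
                    b[r] = rng.choice(pool, size=r.sum())
                d = s & ~r
                if d.any():
                    a[d] = rng.choice(mod_verts[src], size=d.sum())
                    b[d] = rng.choice(mod_verts[dst], size=d.sum())
        va[idx], vb[idx] = a, b
        lengths[idx] = np.clip(rng.lognormal(np.log(90.0), 0.40, size=idx.size), 30.0, 200.0)

    jitter_a = rng.uniform(-0.25, 0.25, size=(n_tracts, 3))
    jitter_b = rng.uniform(-0.25, 0.25, size=(n_tracts, 3))
    return TractSet(
        subject_id=subject_id,
        endpoints_a=mesh.vertices[va] + jitter_a,
        endpoints_b=mesh.vertices[vb] + jitter_b,
        lengths_mm=lengths,
    )


def simulate_cohort(
    config: SimulationConfig | None = None,
    n_subjects: int | None = None,
    master_seed: int = 0,
) -> CohortData:
    """Generate a full cohort: template, planted architecture, subject tracts.

    Per-subject seeds are derived from ``master_seed`` through a
    counter-based mixing function, so subjects are reproducible and
    mutually uncorrelated; all subjects share one template and architecture.
    """
    config = config or SimulationConfig()
    n_subjects = config.n_subjects if n_subjects is None else n_subjects
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    mesh, sphere = make_icosphere(config.subdivisions, config.radius_mm)
    zones = plant_architecture(
        mesh, sphere,
        n_modules=config.n_modules,
        connector_fraction=config.connector_fraction,
        seed=derive_seed(master_seed, 0),
    )
    short_csr = _short_neighbor_csr(mesh, config.short_radius_mm)
    tracts = []
    for s in range(n_subjects):
        tracts.append(simulate_subject_tracts(
            zones, mesh, config.n_tracts,
            p_connector_route=config.p_connector_route,
            short_fiber_rate=config.short_fiber_rate,
            seed=derive_seed(master_seed, 1, s),
            intra_module_rate=config.intra_module_rate,
            short_radius_mm=config.short_radius_mm,
            subject_id=f"sub-{s:02d}",
            _short_csr=short_csr,
        ))
    return CohortData(mesh=mesh, sphere=sphere, zones=zones, tracts=tracts,
                      config=config, master_seed=master_seed)


# ---------------------------------------------------------------------------
# Cohort I/O (plain-text formats)

def save_cohort(cohort: CohortData, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_mesh_obj(cohort.mesh, out / "template.obj")
    save_sphere_tsv(cohort.sphere, out / "sphere.tsv")
    pd.DataFrame({
        "vertex_id": np.arange(cohort.mesh.n_vertices),
        "zone": cohort.zones.zone,
        "connector": cohort.zones.connector.astype(int),
    }).to_csv(out / "zones.tsv", sep="\t", index=False)
    for ts in cohort.tracts:
        df = pd.DataFrame({
            "tract_id": np.arange(ts.n_tracts),
            "ax": ts.endpoints_a[:, 0], "ay": ts.endpoints_a[:, 1], "az": ts.endpoints_a[:, 2],
            "bx": ts.endpoints_b[:, 0], "by": ts.endpoints_b[:, 1], "bz": ts.endpoints_b[:, 2],
            "length_mm": ts.lengths_mm,
        })
        df.to_csv(out / f"{ts.subject_id}_endpoints.tsv", sep="\t", index=False,
                  float_format="%.4f")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({"master_seed": cohort.master_seed,
                        "simulation": asdict(cohort.config)}, fh)


def load_tracts_tsv(path, subject_id: str | None = None) -> TractSet:
    df = pd.read_csv(path, sep="\t")
    sid = subject_id or Path(path).stem.replace("_endpoints", "")
    return TractSet(
        subject_id=sid,
        endpoints_a=df[["ax", "ay", "az"]].to_numpy(float),
        endpoints_b=df[["bx", "by", "bz"]].to_numpy(float),
        lengths_mm=df["length_mm"].to_numpy(float),
    )


def load_cohort(indir) -> CohortData:
    from .surface import load_mesh_obj, load_sphere_tsv
    ind = Path(indir)
    mesh = load_mesh_obj(ind / "template.obj")
    sphere = load_sphere_tsv(ind / "sphere.tsv")
    zdf = pd.read_csv(ind / "zones.tsv", sep="\t").sort_values("vertex_id")
    zones = ZoneLabels(zone=zdf["zone"].to_numpy(), connector=zdf["connector"].to_numpy(bool))
    with open(ind / "config.yaml") as fh:
        meta = yaml.safe_load(fh)
    config = SimulationConfig(**meta["simulation"])
    tracts = [load_tracts_tsv(p) for p in sorted(ind.glob("sub-*_endpoints.tsv"))]
    return CohortData(mesh=mesh, sphere=sphere, zones=zones, tracts=tracts,
                      config=config, master_seed=meta["master_seed"])
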