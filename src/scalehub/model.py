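"""Scale-integrated hub analysis as a model/results pair.

``ScaleIntegratedHubModel`` bundles the full estimation pipeline — random
multi-scale parcellation, fiber-count network construction, betweenness
hub mapping, scale integration, hub detection and the local-efficiency
validation contrast — behind a statsmodels-like interface: build the model
from a cohort, call :meth:`fit`, inspect the returned
:class:`ScaleIntegratedHubResults` (``summary()``, ``save()``).

Everything is a deterministic function of the cohort and the model's
``seed``; re-running ``fit`` reproduces every output bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .simulate import CohortData, SimulationConfig, simulate_cohort
from .parcellate import (
    parcellation_ensemble,
    DEFAULT_SCALES,
    DEFAULT_REPEATS,
)
from .connectome import (
    snap_endpoints,
    map_endpoints,
    build_connectivity,
    short_association_ratio,
    save_matrix_mtx,
    DEFAULT_MIN_FIBERS,
    DEFAULT_SNAP_TOLERANCE_MM,
)
from .hubness import subject_hub_map, group_average_map, project_to_vertices
from .validate import nodal_local_efficiency, efficiency_contrast
from .integrate import his_strength, his_score, detect_hubs, per_scale_hubs
from .surface import save_vertex_map_tsv

__all__ = ["RunConfig", "ScaleIntegratedHubModel", "ScaleIntegratedHubResults"]


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; defaults follow the reference
    protocol (scales 100..600, 20 repeats, 3-fiber edge threshold, 20 mm
    FWHM smoothing, hubs at mean + 1 SD)."""

    scales: tuple = DEFAULT_SCALES
    n_repeats: int = DEFAULT_REPEATS
    min_fibers: int = DEFAULT_MIN_FIBERS
    fwhm_mm: float = 20.0
    threshold_sd: float = 1.0
    snap_tolerance_mm: float = DEFAULT_SNAP_TOLERANCE_MM
    master_seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        cfg = cls(**{k: v for k, v in d.items() if k != "simulation"})
        cfg.scales = tuple(cfg.scales)
        if sim is not None:
            cfg.simulation = sim if isinstance(sim, SimulationConfig) else SimulationConfig(**sim)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class ScaleIntegratedHubModel:
    """Multi-scale betweenness hub model of a tractography cohort.

    Parameters
    ----------
    cohort
        A :class:`~scalehub.simulate.CohortData` (template mesh + sphere,
        per-subject streamline endpoints).
    scales, n_repeats
        Nodal scales (parcel counts) and random parcellation repeats per
        scale over which hubness is integrated.
    min_fibers
        Minimum streamline count for an edge to exist.
    fwhm_mm
        Surface smoothing kernel applied to each subject's hub map.
    threshold_sd
        Hub threshold in SD units above the map mean.
    seed
        Seed for the parcellation ensemble (defaults to the cohort's
        master seed).
    """

    def __init__(self, cohort: CohortData, *, scales=DEFAULT_SCALES,
                 n_repeats: int = DEFAULT_REPEATS,
                 min_fibers: int = DEFAULT_MIN_FIBERS,
                 fwhm_mm: float = 20.0, threshold_sd: float = 1.0,
                 snap_tolerance_mm: float = DEFAULT_SNAP_TOLERANCE_MM,
                 seed: int | None = None,
                 normalize_per_repeat: bool = True):
        self.cohort = cohort
        self.scales = tuple(int(s) for s in scales)
        self.n_repeats = int(n_repeats)
        self.min_fibers = int(min_fibers)
        self.fwhm_mm = float(fwhm_mm)
        self.threshold_sd = float(threshold_sd)
        self.snap_tolerance_mm = float(snap_tolerance_mm)
        self.seed = int(cohort.master_seed if seed is None else seed)
        self.normalize_per_repeat = normalize_per_repeat

    @classmethod
    def from_config(cls, config: RunConfig, cohort: CohortData | None = None):
        """Build from a :class:`RunConfig`, simulating the cohort if absent."""
        if cohort is None:
            cohort = simulate_cohort(config.simulation, master_seed=config.master_seed)
        return cls(cohort,
                   scales=config.scales, n_repeats=config.n_repeats,
                   min_fibers=config.min_fibers, fwhm_mm=config.fwhm_mm,
                   threshold_sd=config.threshold_sd,
                   snap_tolerance_mm=config.snap_tolerance_mm,
                   seed=config.master_seed)

    # -- pipeline stages ---------------------------------------------------

    def build_ensemble(self):
        return parcellation_ensemble(self.cohort.sphere, self.scales,
                                     self.n_repeats, master_seed=self.seed)

    def fit(self, *, compute_validation: bool = True,
            compute_short_ratio: bool = True) -> "ScaleIntegratedHubResults":
        """Run the full pipeline and return the results object."""
        cohort = self.cohort
        mesh = cohort.mesh
        ensemble = self.build_ensemble()
        snapped = [snap_endpoints(ts, mesh) for ts in cohort.tracts]

        X_by_scale: dict = {}
        eff_by_scale: dict = {}
        ratio_rows = []
        matrices: dict = {}
        for s in self.scales:
            parcs = [ensemble[(s, r)] for r in range(self.n_repeats)]
            subj_maps = []
            subj_eff_maps = []
            for si, ts in enumerate(cohort.tracts):
                mats = []
                effs = []
                for r, parc in enumerate(parcs):
                    asg = map_endpoints(ts, mesh, parc, self.snap_tolerance_mm,
                                        snapped=snapped[si])
                    w = build_connectivity(asg, min_fibers=self.min_fibers)
                    mats.append(w)
                    matrices[(ts.subject_id, s, r)] = w
                    if compute_short_ratio:
                        ratio_rows.append({
                            "subject": ts.subject_id, "scale": s, "repeat": r,
                            "ratio": short_association_ratio(
                                asg, min_fibers=self.min_fibers)})
                    if compute_validation:
                        effs.append(project_to_vertices(
                            nodal_local_efficiency(w), parc))
                subj_maps.append(subject_hub_map(
                    mats, parcs, mesh, self.fwhm_mm,
                    normalize_per_repeat=self.normalize_per_repeat))
                if compute_validation:
                    subj_eff_maps.append(np.mean(effs, axis=0))
            X_by_scale[s] = group_average_map(subj_maps)
            if compute_validation:
                eff_by_scale[s] = np.mean(subj_eff_maps, axis=0)

        his_st = his_strength(X_by_scale)
        his_sc = his_score(his_st)
        his_hubs = detect_hubs(his_sc, self.threshold_sd, source="his")
        scale_hubs = per_scale_hubs(X_by_scale, self.threshold_sd)

        contrasts = {}
        if compute_validation:
            for s in self.scales:
                contrasts[s] = efficiency_contrast(
                    his_hubs, scale_hubs[s], eff_by_scale[s], scale=s)

        ratios = pd.DataFrame(ratio_rows) if ratio_rows else pd.DataFrame(
            columns=["subject", "scale", "repeat", "ratio"])
        return ScaleIntegratedHubResults(
            model=self, X_by_scale=X_by_scale, his_st=his_st, his_sc=his_sc,
            his_hubs=his_hubs, scale_hubs=scale_hubs,
            efficiency_by_scale=eff_by_scale, contrasts=contrasts,
            short_ratios=ratios, matrices=matrices)


@dataclass
class ScaleIntegratedHubResults:
    """Fitted hub maps, hub sets, ratios and validation contrasts."""

    model: ScaleIntegratedHubModel
    X_by_scale: dict
    his_st: np.ndarray
    his_sc: np.ndarray
    his_hubs: object
    scale_hubs: dict
    efficiency_by_scale: dict
    contrasts: dict
    short_ratios: pd.DataFrame
    matrices: dict

    # -- derived views -----------------------------------------------------

    def short_ratio_by_scale(self) -> pd.Series:
        """Cohort-mean short-association ratio per nodal scale."""
        if self.short_ratios.empty:
            return pd.Series(dtype=float)
        return self.short_ratios.groupby("scale")["ratio"].mean()

    def hub_fraction(self) -> float:
        return len(self.his_hubs) / len(self.his_sc)

    def connector_contrast(self) -> dict:
        """Mean integrated hub score over planted connector vs other cortex.

        Only meaningful for simulated cohorts carrying zone labels.
        """
        zones = self.model.cohort.zones
        conn = zones.connector
        return {
            "mean_connector": float(self.his_sc[conn].mean()),
            "mean_other": float(self.his_sc[~conn].mean()),
            "jaccard": self.his_hubs.jaccard(np.flatnonzero(conn)),
        }

    def summary(self) -> str:
        m = self.model
        lines = [
            "Scale-integrated hub analysis",
            "=" * 64,
            f"subjects: {len(m.cohort.tracts)}   vertices: {m.cohort.mesh.n_vertices}",
            f"scales: {list(m.scales)}   repeats/scale: {m.n_repeats}",
            f"edge threshold: >= {m.min_fibers} fibers   smoothing FWHM: {m.fwhm_mm} mm",
            f"hub threshold: mean + {m.threshold_sd} SD   seed: {m.seed}",
            "-" * 64,
            f"integrated hub score: mean {self.his_sc.mean():+.2e}, "
            f"SD {self.his_sc.std():.6f}",
            f"integrated hubs: {len(self.his_hubs)} vertices "
            f"({100 * self.hub_fraction():.1f}% of cortex)",
        ]
        ratios = self.short_ratio_by_scale()
        if not ratios.empty:
            lines.append("-" * 64)
            lines.append("short-association ratio by scale (cohort mean, %):")
            for s, v in ratios.items():
                lines.append(f"  K={s:>4d}: {100 * v:.4f}")
        if self.contrasts:
            lines.append("-" * 64)
            lines.append("local-efficiency contrast (integrated vs other hubs):")
            for s, c in sorted(self.contrasts.items()):
                if c.testable:
                    lines.append(
                        f"  K={s:>4d}: t={c.t:+.3f} p={c.p:.3g} {c.significance} "
                        f"(n={c.n_his}/{c.n_non}, mean {c.mean_his:.4f} vs {c.mean_non:.4f})")
                else:
                    lines.append(f"  K={s:>4d}: {c.note}")
        if self.model.cohort.zones is not None:
            cc = self.connector_contrast()
            lines.append("-" * 64)
            lines.append(
                "planted-connector recovery: score "
                f"{cc['mean_connector']:+.3f} (connector) vs {cc['mean_other']:+.3f} "
                f"(other), Jaccard(hubs, connectors) = {cc['jaccard']:.3f}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, outdir, *, write_matrices: bool = False) -> None:
        """Write hub maps, hub lists, ratio and validation tables + provenance."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        save_vertex_map_tsv(self.his_st, out / "his_st.tsv")
        save_vertex_map_tsv(self.his_sc, out / "his_sc.tsv")
        for s, x in self.X_by_scale.items():
            save_vertex_map_tsv(x, out / f"group_X_scale-{s}.tsv")
        pd.DataFrame({"vertex_id": self.his_hubs.as_array()}).to_csv(
            out / "hubs.tsv", sep="\t", index=False)
        for s, hs in self.scale_hubs.items():
            pd.DataFrame({"vertex_id": hs.as_array()}).to_csv(
                out / f"hubs_scale-{s}.tsv", sep="\t", index=False)
        if not self.short_ratios.empty:
            self.short_ratios.to_csv(out / "short_ratios.tsv", sep="\t", index=False)
        if self.contrasts:
            rows = []
            for s, c in sorted(self.contrasts.items()):
                rows.append({"scale": s, "n_his": c.n_his, "n_non": c.n_non,
                             "mean_his": c.mean_his, "mean_non": c.mean_non,
                             "sd_his": c.sd_his, "sd_non": c.sd_non,
                             "t": c.t, "p": c.p, "significance": c.significance})
            pd.DataFrame(rows).to_csv(out / "validation.tsv", sep="\t", index=False)
        if write_matrices:
            mdir = out / "matrices"
            mdir.mkdir(exist_ok=True)
            for (sid, s, r), w in self.matrices.items():
                save_matrix_mtx(w, mdir / f"{sid}_scale-{s}_rep-{r}.mtx")
        m = self.model
        prov = {
            "version": _version,
            "seed": m.seed,
            "scales": list(m.scales),
            "n_repeats": m.n_repeats,
            "min_fibers": m.min_fibers,
            "fwhm_mm": m.fwhm_mm,
            "threshold_sd": m.threshold_sd,
            "snap_tolerance_mm": m.snap_tolerance_mm,
            "n_subjects": len(m.cohort.tracts),
            "config_hash": hashlib.sha256(json.dumps(
                [m.seed, list(m.scales), m.n_repeats, m.min_fibers,
                 m.fwhm_mm, m.threshold_sd], sort_keys=True).encode()
            ).hexdigest()[:16],
        }
        with open(out / "run.json", "w") as fh:
            json.dump(prov, fh, indent=2, sort_keys=True)
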