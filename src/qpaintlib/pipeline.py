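"""End-to-end qPAINT pipeline: simulate -> filter -> cluster -> count -> map.

Stages run in a fixed order — uncertainty filter, ROI selection, DBSCAN,
mean-frame filter, dark-time fitting, calibration, counting, k-means
partitioning, grouping, summaries — with per-stage record counts collected
in a run manifest.  Configuration lives in one YAML-serialisable
:class:`RunConfig`; a fixed master seed makes every run byte-for-byte
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .cluster import (
    DEFAULT_TAIL_EPSILON,
    ClusteringParams,
    LocCluster,
    dbscan,
    expected_localizations_per_site,
    mean_frame_filter,
    min_points_from_poisson,
)
from .counting import (
    Calibration,
    calibrate,
    count_proteins,
    extract_dark_times,
    fit_dark_time,
    qpaint_index,
)
from .io import LocalizationTable, RoiSpec, filter_uncertainty, read_localizations, sample_rois, select_roi
from .maps import ProteinMap, RoiSummary, classify_cluster, group_proteins, kmeans_partition, summarize_roi
from .nena import nena_precision
from .params import AcquisitionParams, KineticsModel, UncertaintyModel
from .simulate import GeneratorConfig, simulate_dataset

logger = logging.getLogger("qpaintlib")


class ConfigError(ValueError):
    """A run configuration failed validation."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-stage parameters of a run."""

    max_uncertainty_nm: float = 13.0
    eps_nm: Optional[float] = None  # None -> NeNA precision, rounded to nm
    min_pts: Optional[int] = None  # None -> Poisson derivation from kinetics
    tail_epsilon: float = DEFAULT_TAIL_EPSILON
    calibration_max_extent_nm: float = 100.0
    calibration_n_peaks: int = 4
    calibration_min_clusters: int = 50
    linking_radius_nm: Optional[float] = None
    roi_size_nm: float = 3500.0
    n_rois: int = 0  # 0 -> analyse the whole table as a single ROI
    min_roi_localizations: int = 500

    def __post_init__(self) -> None:
        if self.max_uncertainty_nm < 0:
            raise ConfigError("analysis: max_uncertainty_nm must be >= 0")
        if self.eps_nm is not None and self.eps_nm <= 0:
            raise ConfigError("analysis: eps_nm must be > 0")
        if self.min_pts is not None and self.min_pts < 1:
            raise ConfigError("analysis: min_pts must be >= 1")
        if self.roi_size_nm <= 0:
            raise ConfigError("analysis: roi_size_nm must be > 0")


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of a simulate and/or analyze run."""

    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    kinetics: KineticsModel = field(default_factory=KineticsModel)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    # ------------------------------------------------------------- YAML I/O
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _listify(d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        blocks = {
            "acquisition": AcquisitionParams,
            "kinetics": KineticsModel,
            "generator": GeneratorConfig,
            "analysis": AnalysisConfig,
        }
        kwargs = {}
        for name, typ in blocks.items():
            if name not in d:
                raise ConfigError(f"missing configuration block: '{name}'")
            try:
                kwargs[name] = _build_dataclass(typ, d[name])
            except TypeError as exc:
                raise ConfigError(f"invalid '{name}' block: {exc}") from exc
        kwargs["seed"] = int(d.get("seed", 0))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def _build_dataclass(typ, d: dict):
    fields = {f.name: f for f in dataclasses.fields(typ)}
    kwargs = {}
    for key, value in d.items():
        if key not in fields:
            raise TypeError(f"unknown field '{key}'")
        ftype = fields[key].type
        if key == "uncertainty_noise" and isinstance(value, dict):
            value = UncertaintyModel(**value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return typ(**kwargs)


# ------------------------------------------------------------------ results
@dataclass
class ClusterResult:
    """All per-cluster quantities of one kept localization cluster."""

    roi_index: int
    cluster: LocCluster
    tau_d: float
    q_i: float
    n_proteins: int
    raw_ratio: float
    protein_positions: np.ndarray


@dataclass
class RoiResult:
    roi_index: int
    roi: Optional[RoiSpec]
    clusters: list[ClusterResult]
    protein_map: ProteinMap
    summary: RoiSummary
    n_clusters_detected: int
    n_clusters_rejected_mean_frame: int


@dataclass
class AnalysisResult:
    rois: list[RoiResult]
    calibration: Optional[Calibration]
    eps_nm: float
    min_pts: int
    stage_counts: dict

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rois:
            d = {"roi": r.roi_index}
            d.update(r.summary.to_dict())
            rows.append(d)
        return pd.DataFrame(rows)

    def clusters_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rois:
            for c in r.clusters:
                rows.append(
                    {
                        "roi": r.roi_index,
                        "cluster_id": c.cluster.cluster_id,
                        "n_locs": c.cluster.n_locs,
                        "max_extent_nm": c.cluster.max_extent,
                        "mean_frame": c.cluster.mean_frame,
                        "tau_d_s": c.tau_d,
                        "q_i_hz": c.q_i,
                        "n_proteins": c.n_proteins,
                    }
                )
        return pd.DataFrame(rows)

    def proteins_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rois:
            pm = r.protein_map
            sizes = pm.cluster_sizes()
            for i in range(pm.n_proteins):
                g = int(pm.group_labels[i])
                size = sizes[g]
                rows.append(
                    {
                        "roi": r.roi_index,
                        "protein_id": i,
                        "x_nm": pm.positions[i, 0],
                        "y_nm": pm.positions[i, 1],
                        "parent_cluster_id": int(pm.parent_cluster_ids[i]),
                        "protein_cluster": g if size >= 3 else -1,
                        "size_class": classify_cluster(size) if size >= 3 else "unclustered",
                    }
                )
        return pd.DataFrame(rows)


# ----------------------------------------------------------------- analysis
def analyze_tables(
    tables: Sequence[LocalizationTable],
    areas_um2: Sequence[float],
    acq: AcquisitionParams,
    kin: KineticsModel,
    cfg: AnalysisConfig,
    seed: int = 0,
    calibration: Optional[Calibration] = None,
    rois: Optional[Sequence[Optional[RoiSpec]]] = None,
) -> AnalysisResult:
    """Run the analysis stages on pre-cut ROI tables (one table per ROI).

    The uncertainty filter is assumed already applied (``run_analyze`` does
    so); calibration is pooled across all ROIs unless supplied externally.
    """
    if len(tables) != len(areas_um2):
        raise ValueError("one area per table is required")
    counts: dict = {"rois": len(tables)}

    if cfg.eps_nm is not None:
        eps = float(cfg.eps_nm)
    else:
        sigma = nena_precision(_largest(tables)).sigma
        eps = max(1.0, round(sigma))
        counts["nena_sigma_nm"] = sigma
    if cfg.min_pts is not None:
        min_pts = int(cfg.min_pts)
    else:
        mean_locs = expected_localizations_per_site(acq, kin, floor=True)
        min_pts = min_points_from_poisson(mean_locs, cfg.tail_epsilon)
    params = ClusteringParams(eps=eps, min_pts=min_pts)
    logger.info("clustering with eps=%.1f nm, min_pts=%d", eps, min_pts)

    # Pass 1: detect clusters, temporal filter, dark-time fits per ROI.
    per_roi: list[dict] = []
    q_pool: list[float] = []
    ext_pool: list[float] = []
    for i, table in enumerate(tables):
        labels, clusters = dbscan(table, params)
        mf = mean_frame_filter(clusters, acq.n_frames)
        fitted = []
        for c in mf.kept:
            dark = extract_dark_times(c.frames, acq.frame_time)
            if len(dark) == 0:
                continue  # a cluster bright in every frame carries no kinetics
            est = fit_dark_time(dark)
            q = qpaint_index(est.tau_d)
            fitted.append((c, est.tau_d, q))
            q_pool.append(q)
            ext_pool.append(c.max_extent)
        per_roi.append(
            {
                "table": table,
                "fitted": fitted,
                "n_detected": len(clusters),
                "n_rejected": mf.n_rejected,
            }
        )
        counts.setdefault("clusters_detected", 0)
        counts["clusters_detected"] += len(clusters)
        counts.setdefault("clusters_rejected_mean_frame", 0)
        counts["clusters_rejected_mean_frame"] += mf.n_rejected

    if calibration is None:
        calibration = calibrate(
            np.asarray(q_pool),
            np.asarray(ext_pool),
            max_extent=cfg.calibration_max_extent_nm,
            n_peaks=cfg.calibration_n_peaks,
            min_clusters=cfg.calibration_min_clusters,
        )
        counts["calibration"] = "fitted"
    else:
        logger.info("using externally supplied calibration; calibrate stage skipped")
        counts["calibration"] = "external"

    # Pass 2: counting, k-means partitioning, grouping, summaries.
    rng_master = np.random.SeedSequence(seed)
    roi_results: list[RoiResult] = []
    for i, info in enumerate(per_roi):
        table = info["table"]
        child = int(rng_master.spawn(1)[0].generate_state(1)[0] % (2**31))
        cluster_results: list[ClusterResult] = []
        positions_l, parents_l = [], []
        parent_locs = {}
        for j, (c, tau_d, q) in enumerate(info["fitted"]):
            pc = count_proteins(q, calibration)
            locs_xy = table.xy[c.indices]
            pos = kmeans_partition(locs_xy, pc.n_proteins, seed=(child + j) % (2**31))
            cluster_results.append(
                ClusterResult(
                    roi_index=i,
                    cluster=c,
                    tau_d=tau_d,
                    q_i=q,
                    n_proteins=pc.n_proteins,
                    raw_ratio=pc.raw_ratio,
                    protein_positions=pos,
                )
            )
            positions_l.append(pos)
            parents_l.append(np.full(len(pos), c.cluster_id))
            parent_locs[c.cluster_id] = locs_xy
        positions = np.concatenate(positions_l) if positions_l else np.empty((0, 2))
        parents = np.concatenate(parents_l) if parents_l else np.empty(0, dtype=int)
        groups = group_proteins(positions, parents, cfg.linking_radius_nm)
        pmap = ProteinMap(
            positions=positions,
            parent_cluster_ids=parents,
            group_labels=groups,
            area_um2=areas_um2[i],
            parent_locs=parent_locs,
        )
        roi_results.append(
            RoiResult(
                roi_index=i,
                roi=rois[i] if rois is not None else None,
                clusters=cluster_results,
                protein_map=pmap,
                summary=summarize_roi(pmap),
                n_clusters_detected=info["n_detected"],
                n_clusters_rejected_mean_frame=info["n_rejected"],
            )
        )
    counts["proteins_total"] = int(sum(r.summary.n_proteins for r in roi_results))
    return AnalysisResult(
        rois=roi_results,
        calibration=calibration,
        eps_nm=eps,
        min_pts=min_pts,
        stage_counts=counts,
    )


def _largest(tables):
    return max(tables, key=len)


# ------------------------------------------------------------------- runs
def run_simulate(config: RunConfig, outdir) -> dict:
    """Simulate a dataset and write localizations, ground truth and manifest."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise RuntimeError(f"cannot create output directory {outdir}: {exc}") from exc
    ds = simulate_dataset(config.generator, config.acquisition, config.kinetics, config.seed)
    ds.table.to_csv(outdir / "localizations.csv")
    ds.truth.to_csv(outdir / "ground_truth.csv")
    config.to_yaml(outdir / "config.yaml")
    manifest = {
        "stage": "simulate",
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": _pkg_version,
        "n_localizations": len(ds.table),
        "n_proteins": ds.truth.n_proteins,
        "n_nonspecific_sites": int(len(ds.nonspecific_positions)),
        "density_per_um2": config.generator.density_per_um2,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_analyze(
    source: Union[str, Path, LocalizationTable],
    config: RunConfig,
    outdir=None,
    calibration_path=None,
) -> AnalysisResult:
    """Analyse a localization table through the full qPAINT pipeline.

    ``source`` is a CSV path or an in-memory table.  With
    ``analysis.n_rois > 0`` random ROIs are cut from the field of view;
    otherwise the whole table is treated as a single ROI whose area is taken
    from the generator block (simulated data covers exactly that area).
    """
    cfg = config.analysis
    if isinstance(source, (str, Path)):
        table = read_localizations(source, n_frames=config.acquisition.n_frames)
    else:
        table = source
    counts = {"input": len(table)}
    table = filter_uncertainty(table, cfg.max_uncertainty_nm)
    counts["after_uncertainty_filter"] = len(table)
    if len(table) == 0:
        import warnings

        warnings.warn(
            "no localizations left after the uncertainty filter; emitting empty outputs",
            stacklevel=2,
        )
        empty = AnalysisResult(rois=[], calibration=None, eps_nm=float("nan"), min_pts=0, stage_counts=counts)
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            empty.clusters_frame().to_csv(outdir / "clusters.csv", index=False)
            empty.proteins_frame().to_csv(outdir / "proteins.csv", index=False)
            empty.summary_frame().to_csv(outdir / "roi_summary.csv", index=False)
            (outdir / "manifest.json").write_text(
                json.dumps({"stage": "analyze", "counts": counts}, indent=2, sort_keys=True)
            )
        return empty

    if cfg.n_rois > 0:
        roi_specs = sample_rois(
            table,
            cfg.n_rois,
            roi_size=cfg.roi_size_nm,
            seed=config.seed,
            min_localizations=cfg.min_roi_localizations,
        )
        tables = [select_roi(table, r) for r in roi_specs]
        areas = [r.area_um2 for r in roi_specs]
    else:
        roi_specs = [None]
        tables = [table]
        areas = [config.generator.area_um2]

    external = None
    if calibration_path is not None:
        external = Calibration.from_dict(json.loads(Path(calibration_path).read_text()))

    result = analyze_tables(
        tables,
        areas,
        config.acquisition,
        config.kinetics,
        cfg,
        seed=config.seed,
        calibration=external,
        rois=roi_specs,
    )
    result.stage_counts = {**counts, **result.stage_counts}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.clusters_frame().to_csv(outdir / "clusters.csv", index=False)
        result.proteins_frame().to_csv(outdir / "proteins.csv", index=False)
        result.summary_frame().to_csv(outdir / "roi_summary.csv", index=False)
        (outdir / "calibration.json").write_text(
            json.dumps(result.calibration.to_dict(), indent=2, sort_keys=True)
        )
        manifest = {
            "stage": "analyze",
            "stage_order": [
                "uncertainty_filter",
                "roi_selection",
                "dbscan",
                "mean_frame_filter",
                "dark_times",
                "calibration",
                "counting",
                "kmeans",
                "grouping",
                "summary",
            ],
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": _pkg_version,
            "eps_nm": result.eps_nm,
            "min_pts": result.min_pts,
            "counts": result.stage_counts,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result
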