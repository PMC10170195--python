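"""Parameter-recovery harnesses over the synthetic generator.

Each function simulates data at known ground truth and pushes it through the
analysis chain, returning the recovered quantity next to the planted one —
the package's primary self-validation instruments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .counting import calibrate, extract_dark_times, fit_dark_time, qpaint_index
from .io import filter_uncertainty
from .nena import nena_precision
from .params import AcquisitionParams, KineticsModel
from .pipeline import AnalysisConfig, AnalysisResult, analyze_tables
from .simulate import (
    GeneratorConfig,
    frames_from_events,
    simulate_binding_timeseries,
    simulate_dataset,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class SteadyStateRecovery:
    """Full-pipeline recovery on independently simulated ROIs."""

    mean_density: float  # proteins / um^2, mean over ROIs
    mean_pct_clustered: float  # %
    truth_density: float  # realized ground-truth mean
    truth_pct_clustered: float
    configured_density: float
    configured_pct_clustered: float
    n_rois: int
    result: AnalysisResult


def steady_state_recovery(
    n_rois: int = 20,
    seed: int = 0,
    generator: Optional[GeneratorConfig] = None,
    acq: Optional[AcquisitionParams] = None,
    kin: Optional[KineticsModel] = None,
    analysis: Optional[AnalysisConfig] = None,
) -> SteadyStateRecovery:
    """Simulate ``n_rois`` ROIs at the configured conditions and run the full
    pipeline (uncertainty filter, DBSCAN, mean-frame filter, dark times,
    pooled calibration, counting, k-means, grouping, summaries)."""
    generator = generator or GeneratorConfig()
    acq = acq or AcquisitionParams()
    kin = kin or KineticsModel()
    analysis = analysis or AnalysisConfig()
    seeds = _child_seeds(seed, n_rois + 1)
    tables, truths = [], []
    for s in seeds[:n_rois]:
        ds = simulate_dataset(generator, acq, kin, seed=s)
        tables.append(filter_uncertainty(ds.table, analysis.max_uncertainty_nm))
        truths.append(ds.truth)
    result = analyze_tables(
        tables,
        [generator.area_um2] * n_rois,
        acq,
        kin,
        analysis,
        seed=seeds[n_rois],
    )
    dens = [r.summary.protein_density for r in result.rois]
    pcts = [r.summary.pct_clustered for r in result.rois if r.summary.pct_clustered is not None]
    return SteadyStateRecovery(
        mean_density=float(np.mean(dens)),
        mean_pct_clustered=float(np.mean(pcts)),
        truth_density=float(np.mean([t.realized_density for t in truths])),
        truth_pct_clustered=float(np.mean([100.0 * t.fraction_clustered for t in truths])),
        configured_density=generator.density_per_um2,
        configured_pct_clustered=100.0 * generator.fraction_clustered,
        n_rois=n_rois,
        result=result,
    )


def calibration_mixture_recovery(
    n_clusters: int = 300,
    seed: int = 0,
    site_rate_hz: float = 0.012,
    weights: tuple[float, float, float] = (0.5, 0.3, 0.2),
    acq: Optional[AcquisitionParams] = None,
):
    """Recover the single-protein qPAINT index from a 1/2/3-site mixture.

    Each cluster holds 1-3 independent binding sites whose per-site mean
    dark time is ``1 / site_rate_hz``; event times are discretized with the
    lossless overlap camera model so the planted dark-time distribution is
    what the fit sees.  Returns the fitted calibration and the planted rate.
    """
    acq = acq or AcquisitionParams()
    kin = KineticsModel(k_on=1e7, imager_conc=site_rate_hz / 1e7, tau_bright=0.27)
    rng = np.random.default_rng(seed)
    ks = rng.choice([1, 2, 3], p=np.asarray(weights) / np.sum(weights), size=n_clusters)
    seeds = _child_seeds(seed + 1, n_clusters)
    qs = []
    for k, s in zip(ks, seeds):
        ev = simulate_binding_timeseries(int(k), acq, kin, seed=s)
        frames = np.unique(
            np.concatenate(
                [frames_from_events(e, acq, "overlap") for e in ev.site_events]
            )
        )
        dark = extract_dark_times(frames, acq.frame_time)
        if len(dark) == 0:
            continue
        qs.append(qpaint_index(fit_dark_time(dark).tau_d))
    qs = np.asarray(qs)
    cal = calibrate(qs, np.zeros(len(qs)))
    return cal, site_rate_hz, len(qs)


def bright_time_recovery(
    min_events: int = 10_000, seed: int = 0, acq=None, kin=None
) -> tuple[float, int]:
    """Mean sampled bright duration over at least ``min_events`` events."""
    acq = acq or AcquisitionParams()
    kin = kin or KineticsModel()
    expected_per_site = max(1.0, kin.binding_rate * acq.duration)
    n_sites = int(np.ceil(1.3 * min_events / expected_per_site))
    ev = simulate_binding_timeseries(n_sites, acq, kin, seed=seed)
    d = ev.all_durations()
    return float(d.mean()), int(len(d))


def nena_recovery(sigma_nm: float = 9.0, seed: int = 0):
    """NeNA precision on fixed emitters localized with known per-axis error."""
    acq = dataclasses.replace(AcquisitionParams(), loc_precision_sigma=sigma_nm)
    cfg = GeneratorConfig(
        density_per_um2=25.0,
        area_um=(5.0, 5.0),
        fraction_clustered=0.0,
        background_rate_per_um2_per_frame=0.001,
        nonspecific_site_density_per_um2=1e-9,
    )
    ds = simulate_dataset(cfg, acq, KineticsModel(), seed=seed)
    table = filter_uncertainty(ds.table, 13.0)
    return nena_precision(table), sigma_nm


def persistent_site_mean_frame(
    n_sites: int = 500, seed: int = 0, acq=None, kin=None
) -> tuple[float, int]:
    """Mean frame of localizations of persistent docking sites.

    A site visited by imagers throughout the acquisition has an expected
    mean frame of half the frame count; with ~15 binding events per site a
    single realization scatters by ~15%, so the estimate averages the
    per-site mean frames of ``n_sites`` independent sites.
    """
    acq = acq or AcquisitionParams()
    kin = kin or KineticsModel()
    ev = simulate_binding_timeseries(n_sites, acq, kin, seed=seed)
    means = []
    for e in ev.site_events:
        fr = frames_from_events(e, acq, "threshold")
        if len(fr):
            means.append(fr.mean())
    return float(np.mean(means)), len(means)
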