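"""qPAINT molecular counting: dark times, qPAINT indices, calibration.

The number of proteins under a cluster of localizations follows from its
binding kinetics: with N docking strands in the cluster, binding events
arrive N times faster, so the mean dark time shrinks to tau_off1 / N where
tau_off1 = 1 / (k_on * [imager]) is the single-site dark time,

    N = 1 / (k_on * [imager] * tau_off) = tau_off1 / tau_off.

The inverse fitted dark time of a cluster is its qPAINT index q_i; the
single-protein index q_i1 is calibrated from the multi-peak histogram of
small (sub-100 nm) clusters, and copy numbers are the rounded ratio
q_i / q_i1.  Because calibration and counting share every acquisition bias
(undetected short events, frame discretization), the ratio is unbiased even
when the absolute dark times are not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .cluster import LocCluster


@dataclass
class DarkTimeEstimate:
    """Dark-time sample of one cluster and its fitted mean."""

    dark_times: np.ndarray  # seconds
    tau_d: float  # fitted mean dark time, seconds
    n_gaps: int
    method: str  # "cdf_fit" | "sample_mean" | "degenerate"
    residual: float = float("nan")


def extract_dark_times(
    event_frames: Sequence[int], frame_time: float, min_dark_frames: int = 2
) -> np.ndarray:
    """Dark times of a cluster from its sorted set of event frames.

    Consecutive event frames f_a < f_b with g = f_b - f_a - 1 empty frames
    in between contribute one dark time g * frame_time (nothing for g = 0,
    i.e. an uninterrupted bright run).  The censored intervals before the
    first and after the last event are excluded: they are right/left
    truncated draws that would bias the mean upward.

    Gaps shorter than ``min_dark_frames`` (default 2) are also discarded:
    a single empty frame inside a bright run is indistinguishable from a
    localization lost to quality filtering or cluster-membership noise, and
    such dropout holes otherwise contaminate the gap sample with spurious
    sub-frame "dark times".  Set ``min_dark_frames=1`` to keep every gap.
    """
    frames = np.unique(np.asarray(event_frames, dtype=np.int64))
    if len(frames) < 2:
        if len(frames) == 0:
            warnings.warn("no event frames; empty dark-time list", stacklevel=2)
        return np.empty(0)
    gaps = np.diff(frames) - 1
    return gaps[gaps >= max(1, min_dark_frames)] * frame_time


def fit_dark_time(dark_times: np.ndarray, min_gaps_for_fit: int = 5) -> DarkTimeEstimate:
    """Estimate the mean dark time tau_d of a cluster.

    The empirical cumulative distribution of the observed gaps is fitted by
    least squares with 1 - exp(-t / tau_d), every gap serving as its own
    abscissa (no histogram binning).  With fewer than ``min_gaps_for_fit``
    gaps the sample mean (the exponential maximum-likelihood estimate) is
    returned instead, flagged in ``method``.
    """
    t = np.sort(np.asarray(dark_times, dtype=float))
    if len(t) == 0:
        raise ValueError("cannot fit a dark time from an empty gap list")
    if (t <= 0).any():
        raise ValueError("dark times must be > 0")
    if np.ptp(t) == 0.0:
        return DarkTimeEstimate(t, float(t[0]), len(t), "degenerate")
    if len(t) < min_gaps_for_fit:
        return DarkTimeEstimate(t, float(t.mean()), len(t), "sample_mean")
    ecdf = (np.arange(1, len(t) + 1) - 0.5) / len(t)

    def model(x, tau):
        return 1.0 - np.exp(-x / tau)

    try:
        popt, _ = curve_fit(
            model, t, ecdf, p0=[t.mean()], bounds=(1e-12, np.inf), maxfev=2000
        )
        tau = float(popt[0])
        resid = float(np.sqrt(np.mean((model(t, tau) - ecdf) ** 2)))
        return DarkTimeEstimate(t, tau, len(t), "cdf_fit", resid)
    except RuntimeError:
        return DarkTimeEstimate(t, float(t.mean()), len(t), "sample_mean")


def qpaint_index(tau_d: float) -> float:
    """qPAINT index q_i = 1 / tau_d (Hz)."""
    if not tau_d > 0:
        raise ValueError("tau_d must be > 0")
    return 1.0 / tau_d


@dataclass
class Calibration:
    """Single-protein qPAINT index and the counting precision it implies."""

    q_i1: float  # Hz
    peak_sigma: float  # Hz, SD of the first (monomer) peak
    counting_precision: float  # proteins, = peak_sigma / q_i1
    n_calibration_clusters: int
    method: str = "multi_gauss"  # or "histogram_mode" fallback

    def to_dict(self) -> dict:
        return {
            "q_i1_hz": self.q_i1,
            "peak_sigma_hz": self.peak_sigma,
            "counting_precision_proteins": self.counting_precision,
            "n_calibration_clusters": self.n_calibration_clusters,
            "method": self.method,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        return cls(
            q_i1=d["q_i1_hz"],
            peak_sigma=d["peak_sigma_hz"],
            counting_precision=d["counting_precision_proteins"],
            n_calibration_clusters=d["n_calibration_clusters"],
            method=d.get("method", "multi_gauss"),
        )


def _multi_gauss(q, q1, *amps_sigmas):
    k = len(amps_sigmas) // 2
    amps = amps_sigmas[:k]
    sigmas = amps_sigmas[k:]
    out = np.zeros_like(q, dtype=float)
    for i in range(k):
        out += amps[i] * np.exp(-((q - (i + 1) * q1) ** 2) / (2.0 * sigmas[i] ** 2))
    return out


def calibrate(
    q_indices: np.ndarray,
    max_extents: np.ndarray,
    max_extent: float = 100.0,
    n_peaks: int = 4,
    min_clusters: int = 50,
    n_bins: Optional[int] = None,
) -> Calibration:
    """Calibrate the single-protein qPAINT index q_i1.

    Clusters with a maximum pairwise extent below ``max_extent`` (default
    100 nm — compact enough to hold only a few proteins) enter a histogram
    of qPAINT indices, which is fitted with a sum of ``n_peaks`` Gaussians
    whose centres are constrained to integer multiples of a shared
    fundamental.  That fundamental is q_i1; the first peak's width divided
    by q_i1 is the counting precision in protein units.
    """
    q = np.asarray(q_indices, dtype=float)
    ext = np.asarray(max_extents, dtype=float)
    eligible = q[(ext < max_extent) & np.isfinite(q) & (q > 0)]
    if len(eligible) < min_clusters:
        raise ValueError(
            f"calibration needs >= {min_clusters} eligible clusters, got {len(eligible)}"
        )
    hi = np.quantile(eligible, 0.995)
    if n_bins is None:
        n_bins = max(40, min(120, int(np.sqrt(len(eligible)) * 3)))
    counts, edges = np.histogram(eligible, bins=n_bins, range=(0.0, hi))
    centres = 0.5 * (edges[:-1] + edges[1:])
    mode = centres[np.argmax(counts)]

    p0 = [mode] + [counts.max() / (i + 1.0) for i in range(n_peaks)] + [
        0.25 * mode
    ] * n_peaks
    lower = [0.2 * mode] + [0.0] * n_peaks + [edges[1] - edges[0]] * n_peaks
    upper = [2.0 * mode] + [2.0 * counts.max()] * n_peaks + [hi] * n_peaks
    p0 = list(np.clip(p0, np.asarray(lower) * 1.001, np.asarray(upper) * 0.999))
    try:
        popt, _ = curve_fit(
            _multi_gauss, centres, counts, p0=p0, bounds=(lower, upper), maxfev=20000
        )
        q1 = float(popt[0])
        sigma1 = float(popt[1 + n_peaks])
        return Calibration(
            q_i1=q1,
            peak_sigma=sigma1,
            counting_precision=sigma1 / q1,
            n_calibration_clusters=len(eligible),
            method="multi_gauss",
        )
    except RuntimeError:
        warnings.warn(
            "multi-peak calibration fit failed; falling back to the histogram mode "
            "(degraded counting precision)",
            stacklevel=2,
        )
        sigma1 = float(np.std(eligible[eligible < 1.5 * mode], ddof=1))
        return Calibration(
            q_i1=float(mode),
            peak_sigma=sigma1,
            counting_precision=sigma1 / mode,
            n_calibration_clusters=len(eligible),
            method="histogram_mode",
        )


def calibrate_clusters(
    clusters: Sequence[LocCluster],
    q_indices: Sequence[float],
    **kwargs,
) -> Calibration:
    """Convenience wrapper: calibrate from clusters and their indices."""
    ext = np.array([c.max_extent for c in clusters])
    return calibrate(np.asarray(q_indices, dtype=float), ext, **kwargs)


@dataclass(frozen=True)
class ProteinCount:
    """Copy-number estimate for one cluster."""

    n_proteins: int
    raw_ratio: float


def count_proteins(q_i: float, calibration: Calibration) -> ProteinCount:
    """Copy number N = q_i / q_i1, rounded half away from zero, minimum 1."""
    if not calibration.q_i1 > 0:
        raise ValueError("invalid calibration (q_i1 <= 0)")
    ratio = q_i / calibration.q_i1
    return ProteinCount(n_proteins=max(1, int(np.floor(ratio + 0.5))), raw_ratio=ratio)
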