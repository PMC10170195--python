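"""Acquisition and binding-kinetics parameter containers.

All spatial quantities are in nanometres, all times in seconds and all
concentrations in molar throughout the package.  Camera frames are 0-based
integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class UncertaintyModel:
    """Log-normal model for the per-localization uncertainty a fitter reports.

    Real localization software attaches a fitted precision estimate to every
    event; its distribution is unimodal with a heavy right tail.  A log-normal
    with median ``median_nm`` and log-scale ``sigma_log`` reproduces that shape
    and guarantees positivity.
    """

    median_nm: float = 9.0
    sigma_log: float = 0.25

    def __post_init__(self) -> None:
        if self.median_nm < 0:
            raise ValueError("uncertainty median must be >= 0")
        if self.sigma_log < 0:
            raise ValueError("uncertainty log-sigma must be >= 0")


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera acquisition settings.

    Defaults correspond to a typical total-internal-reflection DNA-PAINT
    acquisition: 15 000 frames at 100 ms integration with a 130 nm effective
    pixel size and ~9 nm per-axis localization precision.
    """

    n_frames: int = 15_000
    frame_time: float = 0.1
    pixel_size: float = 130.0
    loc_precision_sigma: float = 9.0
    uncertainty_noise: UncertaintyModel = field(default_factory=UncertaintyModel)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.loc_precision_sigma < 0:
            raise ValueError("loc_precision_sigma must be >= 0")

    @property
    def duration(self) -> float:
        """Total acquisition time in seconds."""
        return self.n_frames * self.frame_time


@dataclass(frozen=True)
class KineticsModel:
    """Two-state imager/docking-strand binding kinetics.

    The free docking strand binds an imager at rate ``k_on * imager_conc``
    (units s^-1) and a bound imager stays for an exponentially distributed
    bright time with mean ``tau_bright``.  Defaults are typical for a
    speed-optimised repetitive docking motif imaged at 1 nM.
    """

    k_on: float = 1.0e7
    imager_conc: float = 1.0e-9
    tau_bright: float = 0.27

    def __post_init__(self) -> None:
        if self.k_on <= 0:
            raise ValueError("k_on must be > 0")
        if self.imager_conc < 0:
            raise ValueError("imager_conc must be >= 0")
        if self.tau_bright <= 0:
            raise ValueError("tau_bright must be > 0")

    @property
    def binding_rate(self) -> float:
        """Binding rate per free docking site, s^-1."""
        return self.k_on * self.imager_conc

    @property
    def mean_dark_time(self) -> float:
        """Expected dark time of a single site, seconds (1 / binding rate)."""
        rate = self.binding_rate
        if rate == 0:
            return float("inf")
        return 1.0 / rate
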