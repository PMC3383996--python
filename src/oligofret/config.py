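"""Instrument and run configuration.

The instrument parameters describe a confocal two-channel (donor/acceptor)
single-molecule fluorescence setup with 1 ms binning and a moving stage:
channel thresholds used for burst detection, the gamma detection-correction
factor, the single-donor brightness used for apparent-size calibration, and
the probe-volume / scan-speed geometry used to convert burst rates into
concentrations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Any

__all__ = ["InstrumentConfig", "RunConfig"]

#: 40bp dual-labeled dsDNA reference: molar burst rate in bursts/s per pM.
DSDNA_MOLAR_BURST_RATE = 0.76

#: Representative oligomer size per size class (monomers), the median of
#: each class range: 4-mer for 2-5, 10-mer for 5-15, 30-mer for 15-150.
REPRESENTATIVE_SIZES = {"small": 4, "medium": 10, "large": 30}


@dataclass(frozen=True)
class InstrumentConfig:
    """Detection parameters of the two-channel confocal instrument.

    Parameters
    ----------
    bin_width_ms : float
        Photon binning time in milliseconds (fixed at 1 ms acquisition).
    donor_threshold, acceptor_threshold : float
        Burst-detection thresholds in photons per bin. A bin belongs to a
        burst when its count is at or above the channel threshold.
    gamma : float
        Correction factor for the different quantum yields and detection
        efficiencies of the donor and acceptor channels.
    monomer_donor_brightness : float
        Mean photons per bin emitted by a single donor-labeled monomer at
        the center of the confocal volume; calibrates apparent size.
    background_rate_donor, background_rate_acceptor : float
        Mean background photons per bin in each channel.
    coincidence_detection_efficiency : float
        Fraction of genuinely dual-labeled species that yield a detected
        coincident burst (calibrated with dual-labeled dsDNA).
    probe_volume_fl : float
        Confocal probe volume in femtoliters (assumed spherical).
    scan_speed_um_s : float
        Stage scanning speed in micrometers per second.
    """

    bin_width_ms: float = 1.0
    donor_threshold: float = 20.0
    acceptor_threshold: float = 10.0
    gamma: float = 0.26
    monomer_donor_brightness: float = 30.0
    background_rate_donor: float = 2.0
    background_rate_acceptor: float = 1.0
    coincidence_detection_efficiency: float = 0.25
    probe_volume_fl: float = 4.0
    scan_speed_um_s: float = 200.0

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if not 0 < self.coincidence_detection_efficiency <= 1:
            raise ValueError("coincidence_detection_efficiency must be in (0, 1]")
        if self.donor_threshold <= self.background_rate_donor:
            raise ValueError("donor_threshold must exceed donor background rate")
        if self.acceptor_threshold <= self.background_rate_acceptor:
            raise ValueError("acceptor_threshold must exceed acceptor background rate")
        for name in ("bin_width_ms", "monomer_donor_brightness", "probe_volume_fl",
                     "scan_speed_um_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def bin_width_s(self) -> float:
        return self.bin_width_ms * 1e-3

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "InstrumentConfig":
        return cls(**d)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.

    ``dilution_factor`` converts single-molecule concentrations back to bulk
    incubation conditions (1e5 for aggregation experiments, 1e3 for fibril
    disaggregation).  ``stability_factors`` correct for the slight increase in
    detected oligomer numbers upon dilution (3x for type A, 1.5x for type B).
    ``m_tot_uM`` is the total monomer concentration of the bulk incubation,
    70 uM (1 mg/ml).
    """

    seed: int = 0
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    mode: str = "aggregation"  # or "disaggregation"
    dilution_factor: float | None = None
    stability_factors: dict[str, float] = field(
        default_factory=lambda: {"A": 3.0, "B": 1.5}
    )
    m_tot_uM: float = 70.0
    p_donor: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("aggregation", "disaggregation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.dilution_factor is None:
            object.__setattr__(
                self, "dilution_factor",
                1e5 if self.mode == "aggregation" else 1e3,
            )
        if self.m_tot_uM <= 0:
            raise ValueError("m_tot_uM must be positive")
        if not 0 <= self.p_donor <= 1:
            raise ValueError("p_donor must be in [0, 1]")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "instrument" in d and isinstance(d["instrument"], dict):
            d["instrument"] = InstrumentConfig.from_dict(d["instrument"])
        return cls(**d)

    def config_hash(self) -> str:
        """Stable short hash of the configuration for output stamping."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)
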