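"""Core domain types for swallow recordings.

A *swallow recording* bundles synchronized multi-site time series from a
combined pressure--impedance catheter study (optionally with fluoroscopy-
derived luminal diameter), together with the sensor geometry and bolus
metadata needed for regional and stratified analysis.

Axial convention: all positions are centimetres below the proximal
reference (the upper esophageal sphincter), increasing distally.  Regional
logic (proximal vs distal esophagus) is expressed in this single frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MechstateError",
    "FormatError",
    "SamplingError",
    "GeometryError",
    "DomainError",
    "ConfigError",
    "AlignmentError",
    "ThresholdError",
    "IncompleteEventError",
    "CHANNEL_KINDS",
    "CHANNEL_UNITS",
    "BOLUS_TYPES",
    "POSTURES",
    "ChannelTrace",
    "SensorGeometry",
    "SwallowRecording",
]


class MechstateError(Exception):
    """Base class for all package errors."""


class FormatError(MechstateError):
    """Malformed input file or unknown channel/field."""


class SamplingError(MechstateError):
    """Non-uniform or otherwise invalid sample timing."""


class GeometryError(MechstateError):
    """Invalid sensor geometry."""


class DomainError(MechstateError):
    """Value outside the physical domain of an operation."""


class ConfigError(MechstateError):
    """Invalid configuration value."""


class AlignmentError(MechstateError):
    """Traces cannot be placed on a common timebase."""


class ThresholdError(MechstateError):
    """Adaptive change thresholds could not be derived for a site."""


class IncompleteEventError(MechstateError):
    """Luminal opening was detected but no subsequent closure."""


CHANNEL_KINDS = ("pressure", "diameter", "impedance", "admittance")
CHANNEL_UNITS = {
    "pressure": "mmHg",
    "diameter": "mm",
    "impedance": "ohm",
    "admittance": "mS",
}
BOLUS_TYPES = ("liquid", "semisolid", "solid")
POSTURES = ("upright", "decubitus")

#: Tolerance on timestamp uniformity (seconds).
TIME_UNIFORMITY_TOL = 1e-6


@dataclass(frozen=True)
class ChannelTrace:
    """One uniformly sampled channel at one catheter site.

    Parameters
    ----------
    channel_kind : {"pressure", "diameter", "impedance", "admittance"}
    site_id : str
        Identifier of the catheter site (impedance-segment level).
    times : ndarray
        Seconds from the recording start, strictly increasing, uniform.
    values : ndarray
        Channel values in the fixed unit for the kind
        (mmHg, mm, ohm or mS).
    sampling_rate : float, optional
        Hz; inferred from ``times`` when omitted.
    """

    channel_kind: str
    site_id: str
    times: np.ndarray
    values: np.ndarray
    sampling_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.channel_kind not in CHANNEL_KINDS:
            raise FormatError(f"unknown channel_kind {self.channel_kind!r}")
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or times.shape != values.shape:
            raise FormatError("times and values must be 1-d arrays of equal length")
        if times.size < 2:
            raise SamplingError(
                f"trace ({self.site_id}, {self.channel_kind}) has fewer than 2 samples"
            )
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise SamplingError(
                f"times not strictly increasing for ({self.site_id}, {self.channel_kind})"
            )
        if np.ptp(dt) > TIME_UNIFORMITY_TOL:
            raise SamplingError(
                f"non-uniform sampling for ({self.site_id}, {self.channel_kind}): "
                f"dt ranges {dt.min():.6g}..{dt.max():.6g} s"
            )
        if not np.all(np.isfinite(values)):
            bad = int(np.flatnonzero(~np.isfinite(values))[0])
            raise FormatError(
                f"non-finite value at sample {bad} in ({self.site_id}, {self.channel_kind})"
            )
        if not self.sampling_rate:
            object.__setattr__(self, "sampling_rate", 1.0 / float(np.mean(dt)))

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def unit(self) -> str:
        return CHANNEL_UNITS[self.channel_kind]

    def with_values(self, values: np.ndarray, channel_kind: str | None = None) -> "ChannelTrace":
        """Copy of this trace with new values (and optionally a new kind)."""
        return ChannelTrace(
            channel_kind=channel_kind or self.channel_kind,
            site_id=self.site_id,
            times=self.times,
            values=np.asarray(values, dtype=float),
            sampling_rate=self.sampling_rate,
        )


def _check_increasing(name: str, positions) -> np.ndarray:
    arr = np.asarray(positions, dtype=float)
    if arr.size and np.any(np.diff(arr) <= 0):
        raise GeometryError(f"{name} must be strictly increasing (given {arr.tolist()})")
    return arr


@dataclass
class SensorGeometry:
    """Catheter sensor layout in the axial frame (cm below the UES).

    ``pressure_positions`` are nominally 1 cm apart and
    ``impedance_segment_centers`` 2 cm apart (adjoining 2 cm segments);
    deviations raise a warning only, since catheters vary.
    ``site_positions`` maps analyzable site ids to their axial position
    so that state maps and regional summaries can order sites spatially.
    """

    pressure_positions: np.ndarray
    impedance_segment_centers: np.ndarray
    catheter_diameter: float = 3.2
    transition_zone_position: float = 0.0
    egj_position: float = 0.0
    site_positions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pressure_positions = _check_increasing(
            "pressure_positions", self.pressure_positions
        )
        self.impedance_segment_centers = _check_increasing(
            "impedance_segment_centers", self.impedance_segment_centers
        )
        if self.catheter_diameter <= 0:
            raise GeometryError("catheter_diameter must be > 0 mm")
        self.site_positions = {str(k): float(v) for k, v in self.site_positions.items()}
        for name, arr, nominal in (
            ("pressure sensor", self.pressure_positions, 1.0),
            ("impedance segment", self.impedance_segment_centers, 2.0),
        ):
            if arr.size >= 2:
                spacing = np.diff(arr)
                if np.any(np.abs(spacing - nominal) > 1e-9):
                    warnings.warn(
                        f"{name} spacing deviates from the nominal {nominal:g} cm",
                        stacklevel=2,
                    )

    def region_of(self, position_cm: float) -> str:
        """``proximal`` (reference to transition zone) or ``distal``.

        A site exactly at the transition zone belongs to the distal
        region (half-open boundary on the proximal side).
        """
        return "proximal" if position_cm < self.transition_zone_position else "distal"


@dataclass
class SwallowRecording:
    """All traces for one swallow plus acquisition metadata.

    ``traces`` is keyed by ``(site_id, channel_kind)``.  Every analyzable
    site must carry a pressure trace and at least one luminal-geometry
    channel (diameter, impedance or admittance); all traces share the
    recording's time origin.
    """

    traces: dict
    geometry: SensorGeometry
    bolus_type: str = "liquid"
    posture: str = "upright"
    bolus_volume: float = 5.0
    subject_id: str = "subject"
    swallow_id: str = "swallow"

    def __post_init__(self) -> None:
        if not self.traces:
            raise FormatError("recording has no traces")
        if self.bolus_type not in BOLUS_TYPES:
            raise FormatError(f"unknown bolus_type {self.bolus_type!r}")
        if self.posture not in POSTURES:
            raise FormatError(f"unknown posture {self.posture!r}")
        for (site, kind), tr in self.traces.items():
            if (tr.site_id, tr.channel_kind) != (site, kind):
                raise FormatError(f"trace key {(site, kind)} does not match trace metadata")
        for site in self.sites():
            if (site, "pressure") not in self.traces:
                raise FormatError(f"site {site!r} has no pressure trace")
            if not any((site, k) in self.traces for k in ("diameter", "impedance", "admittance")):
                raise FormatError(f"site {site!r} has no luminal-geometry trace")

    def sites(self) -> list:
        """Site ids in insertion order."""
        seen: dict = {}
        for site, _ in self.traces:
            seen.setdefault(site, None)
        return list(seen)

    def trace(self, site_id: str, channel_kind: str) -> ChannelTrace:
        try:
            return self.traces[(site_id, channel_kind)]
        except KeyError:
            raise FormatError(f"no {channel_kind} trace for site {site_id!r}") from None

    def has(self, site_id: str, channel_kind: str) -> bool:
        return (site_id, channel_kind) in self.traces

    @property
    def stratum(self) -> tuple:
        return (self.bolus_type, self.posture)
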