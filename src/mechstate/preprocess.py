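"""Channel conversion, calibration, smoothing, alignment and gradients.

The classifier consumes *smoothed* traces on a common timebase and their
time derivatives.  The pipeline order is fixed and enforced by the
orchestration layer::

    impedance -> admittance  (unit inversion)
    diameter calibration     (magnification scale, catheter net width)
    align to pressure clock  (linear interpolation, no extrapolation)
    Gaussian smoothing       (0.25 s window)
    time derivative          (central differences)

Smoothing before differentiation keeps derivative noise from dominating
the percentile-based change thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AlignmentError,
    ChannelTrace,
    ConfigError,
    DomainError,
)

__all__ = [
    "PreprocessConfig",
    "impedance_to_admittance",
    "calibrate_diameter",
    "gaussian_kernel",
    "gaussian_smooth",
    "align_timebase",
    "time_derivative",
]

#: mS per inverse ohm: Y [mS] = ADMITTANCE_UNIT_SCALE / Z [ohm].
ADMITTANCE_UNIT_SCALE = 1000.0


@dataclass
class PreprocessConfig:
    """Preprocessing settings.

    smoothing_window
        Total Gaussian kernel support in seconds (default 0.25 s); the
        kernel standard deviation is ``window / 4`` (truncation at
        +/- 2 sigma).
    target_rate
        Hz of the common analysis timebase; the pressure channel defines
        the classifier clock (default 20 Hz).
    catheter_diameter
        Indwelling catheter width in mm subtracted during diameter
        calibration (default 3.2 mm), so a lumen fully closed on the
        catheter reads exactly 0 mm.
    """

    smoothing_window: float = 0.25
    target_rate: float = 20.0
    catheter_diameter: float = 3.2
    admittance_unit_scale: float = ADMITTANCE_UNIT_SCALE

    def __post_init__(self) -> None:
        if self.smoothing_window <= 0:
            raise ConfigError("smoothing_window must be > 0 s")
        if self.target_rate <= 0:
            raise ConfigError("target_rate must be > 0 Hz")


def impedance_to_admittance(trace: ChannelTrace) -> ChannelTrace:
    """Invert an impedance trace (ohm) into admittance (mS).

    Y = 1000 / Z.  Strictly decreasing in Z, so bolus-induced impedance
    drops appear as admittance rises tracking luminal opening.
    """
    if trace.channel_kind != "impedance":
        raise DomainError(f"expected an impedance trace, got {trace.channel_kind}")
    bad = np.flatnonzero(trace.values <= 0)
    if bad.size:
        raise DomainError(f"non-positive impedance at sample {int(bad[0])}")
    return trace.with_values(ADMITTANCE_UNIT_SCALE / trace.values, channel_kind="admittance")


def calibrate_diameter(
    raw: ChannelTrace, pixel_scale: float, catheter_diameter: float = 3.2
) -> ChannelTrace:
    """Scale raw fluoroscopic diameter and net out the catheter width.

    ``value = max(0, raw * pixel_scale - catheter_diameter)``.  A lumen
    fully closed on the catheter maps to exactly 0 mm; apparent
    sub-catheter diameters (measurement noise) clamp to 0 rather than
    going negative.
    """
    if raw.channel_kind != "diameter":
        raise DomainError(f"expected a diameter trace, got {raw.channel_kind}")
    if pixel_scale <= 0:
        raise DomainError("pixel_scale must be > 0 mm per raw unit")
    vals = np.maximum(0.0, raw.values * pixel_scale - catheter_diameter)
    return raw.with_values(vals)


def gaussian_kernel(window: float, sampling_rate: float) -> np.ndarray:
    """Discrete Gaussian kernel of total support ``window`` seconds.

    sigma = window / 4 (in time), truncated at +/- 2 sigma, weights
    normalized to sum 1.
    """
    if window < 2.0 / sampling_rate:
        raise ConfigError(
            f"smoothing window {window:g} s too small for sampling rate "
            f"{sampling_rate:g} Hz (need >= {2.0 / sampling_rate:g} s)"
        )
    sigma = window / 4.0 * sampling_rate  # in samples
    half = max(1, int(np.floor(2.0 * sigma + 1e-9)))
    x = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def gaussian_smooth(trace: ChannelTrace, window: float = 0.25) -> ChannelTrace:
    """Gaussian-smooth a trace; edges renormalize over available samples.

    Output length equals input length.  Because the kernel weights are
    nonnegative and renormalized, the output is bounded by the input's
    min and max and constants pass through unchanged.
    """
    w = gaussian_kernel(window, trace.sampling_rate)
    num = np.convolve(trace.values, w, mode="same")
    den = np.convolve(np.ones_like(trace.values), w, mode="same")
    return trace.with_values(num / den)


def align_timebase(
    traces, target_rate: float = 20.0, *, reference_kind: str = "pressure"
):
    """Linearly interpolate traces onto one uniform grid over their overlap.

    The grid starts at the latest trace start, steps at ``1/target_rate``
    and ends at the earliest trace end (no extrapolation).  The pressure
    channel defines the classifier clock, hence the default reference;
    the reference only matters insofar as all traces share the grid.
    """
    traces = list(traces)
    if not traces:
        raise AlignmentError("no traces to align")
    t0 = max(tr.times[0] for tr in traces)
    t1 = min(tr.times[-1] for tr in traces)
    if t1 <= t0:
        raise AlignmentError(f"traces do not overlap in time ({t0:g} s >= {t1:g} s)")
    n = int(np.floor((t1 - t0) * target_rate + 1e-9)) + 1
    if n < 2:
        raise AlignmentError("overlap shorter than two samples at the target rate")
    grid = t0 + np.arange(n) / target_rate
    out = []
    for tr in traces:
        vals = np.interp(grid, tr.times, tr.values)
        out.append(
            ChannelTrace(
                channel_kind=tr.channel_kind,
                site_id=tr.site_id,
                times=grid,
                values=vals,
                sampling_rate=target_rate,
            )
        )
    return out


def time_derivative(trace: ChannelTrace) -> ChannelTrace:
    """Gradient of a trace in units per second.

    Central differences on interior samples, one-sided at the ends
    (``numpy.gradient``); exact for quadratics on the interior.
    """
    if trace.times.size < 3:
        raise DomainError("need at least 3 samples for a time derivative")
    grad = np.gradient(trace.values, trace.times)
    return trace.with_values(grad)
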