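"""Luminal event detection and per-phase change thresholds.

The *luminal event* at a site is the interval from first lumen opening
(O) through maximal luminal extent (M) to final lumen closure (C),
detected from gradient-inflexion crossings of the luminal signal
(diameter or admittance):

* O — first sample whose gradient reaches the positive inflexion
  threshold (+2 mm/s for diameter, +1 mS/s for admittance);
* C — last sample whose gradient reaches the negative inflexion
  threshold (-2 mm/s / -1 mS/s);
* M — time of the maximum signal value within [O, C].

Between O and C, whether the lumen counts as increasing, decreasing or
static is decided by *change thresholds*: for diameter these adapt per
site and phase (the 10th percentile by magnitude of the opening-phase
and closing-phase gradients respectively), for admittance they are the
fixed +/-0.57 mS/s slopes.  Pressure change thresholds are always
+/-10 mmHg/s.

Double-peaked swallows: the principal event spans the first opening
crossing to the last closure crossing; intermediate re-crossings are
interior to one event ("first lumen opening" / "final lumen closure").
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import ChannelTrace, DomainError, ThresholdError

__all__ = [
    "EventStatus",
    "LuminalEvents",
    "ChangeThresholds",
    "DEFAULT_OPEN_THRESHOLDS",
    "detect_luminal_events",
    "derive_change_thresholds",
    "lumen_is_open",
]

#: Gradient inflexion thresholds for event detection, per signal kind.
DEFAULT_OPEN_THRESHOLDS = {
    "diameter": (2.0, -2.0),    # mm/s
    "admittance": (1.0, -1.0),  # mS/s
}

#: Fixed admittance change-slope magnitude (mS/s).
ADMITTANCE_CHANGE_SLOPE = 0.57

#: Pressure change thresholds (mmHg/s).
PRESSURE_INCREASE_THRESHOLD = 10.0
PRESSURE_DECREASE_THRESHOLD = -10.0

#: Minimum gradient samples per phase for adaptive thresholds.
MIN_PHASE_SAMPLES = 5


class EventStatus(str, Enum):
    DETECTED = "detected"
    NOT_DETECTED = "not_detected"
    INCOMPLETE = "incomplete"


@dataclass(frozen=True)
class LuminalEvents:
    """O/M/C times for one site, plus the detection thresholds used."""

    t_open: float
    t_max: float
    t_close: float
    open_threshold: float
    close_threshold: float
    signal_kind: str
    status: EventStatus = EventStatus.DETECTED

    def __post_init__(self) -> None:
        if self.status is EventStatus.DETECTED:
            if not (self.t_open < self.t_max < self.t_close):
                raise DomainError(
                    f"event times must satisfy O < M < C "
                    f"(got {self.t_open}, {self.t_max}, {self.t_close})"
                )
        if not (self.open_threshold > 0 > self.close_threshold):
            raise DomainError("open/close thresholds must have opposite signs")

    @property
    def detected(self) -> bool:
        return self.status is EventStatus.DETECTED


@dataclass(frozen=True)
class ChangeThresholds:
    """Per-sample change thresholds for the luminal and pressure signals."""

    increase_threshold: float
    decrease_threshold: float
    pressure_increase_threshold: float = PRESSURE_INCREASE_THRESHOLD
    pressure_decrease_threshold: float = PRESSURE_DECREASE_THRESHOLD
    method: str = "diameter_adaptive"

    def __post_init__(self) -> None:
        if not (self.increase_threshold > 0 > self.decrease_threshold):
            raise ThresholdError(
                f"change thresholds must straddle zero "
                f"(got +{self.increase_threshold:g}, {self.decrease_threshold:g})"
            )
        if not (
            self.pressure_increase_threshold > 0 > self.pressure_decrease_threshold
        ):
            raise ThresholdError("pressure thresholds must straddle zero")


def _not_detected(open_thr: float, close_thr: float, kind: str) -> LuminalEvents:
    return LuminalEvents(
        t_open=np.nan,
        t_max=np.nan,
        t_close=np.nan,
        open_threshold=open_thr,
        close_threshold=close_thr,
        signal_kind=kind,
        status=EventStatus.NOT_DETECTED,
    )


def detect_luminal_events(
    signal: ChannelTrace,
    gradient: ChannelTrace,
    open_thr: float | None = None,
    close_thr: float | None = None,
) -> LuminalEvents:
    """Detect the principal luminal event from a signal and its gradient.

    Returns a :class:`LuminalEvents` whose ``status`` is NOT_DETECTED
    when no sample crosses the opening threshold, and INCOMPLETE when
    opening is crossed but closure never follows (such sites are
    excluded from analysis downstream).

    With a flat signal maximum (e.g. a trapezoidal plateau), M is the
    midpoint of the maximal run — the symmetric tie-break.
    """
    kind = signal.channel_kind
    if open_thr is None or close_thr is None:
        try:
            d_open, d_close = DEFAULT_OPEN_THRESHOLDS[kind]
        except KeyError:
            raise DomainError(
                f"no default event thresholds for channel kind {kind!r}"
            ) from None
        open_thr = d_open if open_thr is None else open_thr
        close_thr = d_close if close_thr is None else close_thr
    if not (open_thr > 0 > close_thr):
        raise DomainError("open_thr must be > 0 > close_thr")
    if signal.times.shape != gradient.times.shape or np.any(
        np.abs(signal.times - gradient.times) > 1e-9
    ):
        raise DomainError("gradient is not aligned with the signal")

    g = gradient.values
    opening = np.flatnonzero(g >= open_thr)
    if opening.size == 0:
        return _not_detected(open_thr, close_thr, kind)
    i_open = int(opening[0])
    closing = np.flatnonzero(g <= close_thr)
    closing = closing[closing > i_open]
    incomplete = LuminalEvents(
        t_open=float(signal.times[i_open]),
        t_max=np.nan,
        t_close=np.nan,
        open_threshold=open_thr,
        close_threshold=close_thr,
        signal_kind=kind,
        status=EventStatus.INCOMPLETE,
    )
    if closing.size == 0:
        return incomplete
    i_close = int(closing[-1])
    window = signal.values[i_open : i_close + 1]
    peak = window.max()
    peak_idx = np.flatnonzero(window >= peak - 1e-12)
    i_max = i_open + int(round(float(np.mean([peak_idx[0], peak_idx[-1]]))))
    if not (i_open < i_max < i_close):
        return incomplete
    return LuminalEvents(
        t_open=float(signal.times[i_open]),
        t_max=float(signal.times[i_max]),
        t_close=float(signal.times[i_close]),
        open_threshold=float(open_thr),
        close_threshold=float(close_thr),
        signal_kind=kind,
    )


def derive_change_thresholds(
    gradient: ChannelTrace,
    events: LuminalEvents,
    method: str = "diameter_adaptive",
    *,
    percentile: float = 10.0,
    orientation: str = "magnitude",
    pressure_increase: float = PRESSURE_INCREASE_THRESHOLD,
    pressure_decrease: float = PRESSURE_DECREASE_THRESHOLD,
    min_phase_samples: int = MIN_PHASE_SAMPLES,
) -> ChangeThresholds:
    """Derive the per-site change thresholds for one luminal event.

    ``diameter_adaptive`` takes, in each phase, the 10th percentile of
    the gradient *by magnitude* (``orientation="magnitude"``, the
    default): the 10th percentile of |gradient| over the phase, signed
    positive for the opening phase and negative for the closing phase.
    When every phase gradient shares the phase's sign this equals the
    ascending 10th (opening) / 90th (closing) percentile of the signed
    gradients; unlike those, it keeps the required sign when noise
    pushes a few near-peak samples across zero.  ``orientation=
    "literal"`` instead takes the ascending 10th percentile of the
    signed gradients in both phases (the steepest decile of the closing
    phase).  Percentiles use linear interpolation between order
    statistics (``numpy.percentile`` default).

    ``admittance_fixed`` ignores the data and returns +/-0.57 mS/s.
    """
    if method == "admittance_fixed":
        return ChangeThresholds(
            increase_threshold=ADMITTANCE_CHANGE_SLOPE,
            decrease_threshold=-ADMITTANCE_CHANGE_SLOPE,
            pressure_increase_threshold=pressure_increase,
            pressure_decrease_threshold=pressure_decrease,
            method=method,
        )
    if method != "diameter_adaptive":
        raise DomainError(f"unknown change-threshold method {method!r}")
    if orientation not in ("magnitude", "literal"):
        raise DomainError(f"unknown percentile orientation {orientation!r}")
    if not events.detected:
        raise ThresholdError("cannot derive adaptive thresholds without an event")

    t = gradient.times
    g = gradient.values
    opening = g[(t >= events.t_open) & (t <= events.t_max)]
    closing = g[(t >= events.t_max) & (t <= events.t_close)]
    if opening.size < min_phase_samples or closing.size < min_phase_samples:
        raise ThresholdError(
            f"fewer than {min_phase_samples} gradient samples in a phase "
            f"(opening {opening.size}, closing {closing.size})"
        )
    if orientation == "magnitude":
        inc = float(np.percentile(np.abs(opening), percentile))
        dec = -float(np.percentile(np.abs(closing), percentile))
    else:
        inc = float(np.percentile(opening, percentile))
        dec = float(np.percentile(closing, percentile))
    if not (inc > 0 > dec):
        raise ThresholdError(
            f"adaptive thresholds did not straddle zero (+{inc:g}, {dec:g}); "
            f"site excluded"
        )
    return ChangeThresholds(
        increase_threshold=inc,
        decrease_threshold=dec,
        pressure_increase_threshold=pressure_increase,
        pressure_decrease_threshold=pressure_decrease,
        method=method,
    )


def lumen_is_open(t: float, events: LuminalEvents) -> bool:
    """True iff ``t_open <= t <= t_close`` (boundaries inclusive)."""
    if not events.detected:
        return False
    return bool(events.t_open <= t <= events.t_close)
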