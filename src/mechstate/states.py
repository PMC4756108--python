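"""The 12-state mechanical-state taxonomy and the per-sample classifier.

Each time sample at each site is assigned one of 12 mechanical states of
the circular muscle from the pair (lumen category, pressure category):

* lumen category — ``occluded`` outside the luminal event [O, C];
  inside it, ``increasing`` / ``decreasing`` / ``static`` by comparing
  the luminal-signal gradient against the site's change thresholds;
* pressure category — ``increasing`` / ``decreasing`` / ``static`` by
  comparing the pressure gradient against +/-10 mmHg/s.

The 4 x 3 category grid tiles exactly 12 distinct states, 8 active and
4 passive.  A gradient exactly at a threshold counts as change
(inclusive >=/<=), so "static" is the open interval between thresholds.

Active states reflect muscle doing work (contracting or relaxing
against or with load); passive states (occluded quiescence, distended
quiescence, passive dilatation, passive shortening) reflect the wall
following the bolus or resting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FormatError, SwallowRecording
from .events import (
    ChangeThresholds,
    EventStatus,
    LuminalEvents,
    detect_luminal_events,
    derive_change_thresholds,
)
from .preprocess import (
    align_timebase,
    gaussian_smooth,
    impedance_to_admittance,
    time_derivative,
)

__all__ = [
    "MechanicalState",
    "STATES",
    "STATE_BY_CODE",
    "STATE_CODES",
    "EPOCHS",
    "StateTimeline",
    "EpochDistribution",
    "categorize_pressure",
    "categorize_lumen",
    "state_from_categories",
    "classify_timeline",
    "epoch_distribution",
    "dominant_sequence",
    "state_table",
]

LUMEN_CATEGORIES = ("occluded", "static", "increasing", "decreasing")
PRESSURE_CATEGORIES = ("static", "increasing", "decreasing")
EPOCHS = ("Pre-O", "O-M", "M-C", "Post-C")


@dataclass(frozen=True)
class MechanicalState:
    code: str
    label: str
    activity: str  # "active" | "passive"
    lumen_category: str
    pressure_category: str


#: The 12 mechanical states, one per (lumen, pressure) grid cell.
STATES = (
    MechanicalState("oq", "occluded quiescence", "passive", "occluded", "static"),
    MechanicalState("oimc", "occluded isometric contraction", "active", "occluded", "increasing"),
    MechanicalState("oimr", "occluded isometric relaxation", "active", "occluded", "decreasing"),
    MechanicalState("dq", "distended quiescence", "passive", "static", "static"),
    MechanicalState("dipi", "distended isometric pressure increase", "active", "static", "increasing"),
    MechanicalState("dipd", "distended isometric pressure decrease", "active", "static", "decreasing"),
    MechanicalState("itr", "isotonic relaxation", "active", "increasing", "static"),
    MechanicalState("pd", "passive dilatation", "passive", "increasing", "increasing"),
    MechanicalState("atr", "auxotonic relaxation", "active", "increasing", "decreasing"),
    MechanicalState("itc", "isotonic contraction", "active", "decreasing", "static"),
    MechanicalState("atc", "auxotonic contraction", "active", "decreasing", "increasing"),
    MechanicalState("ps", "passive shortening", "passive", "decreasing", "decreasing"),
)

STATE_BY_CODE = {s.code: s for s in STATES}
STATE_CODES = tuple(s.code for s in STATES)
_GRID = {(s.lumen_category, s.pressure_category): s for s in STATES}

#: Code used in state maps for sites excluded from analysis.
EXCLUDED_CODE = "ex"


def state_table() -> pd.DataFrame:
    """Machine-readable state table (code, label, activity, categories)."""
    return pd.DataFrame(
        [(s.code, s.label, s.activity, s.lumen_category, s.pressure_category) for s in STATES],
        columns=["code", "label", "activity", "lumen_category", "pressure_category"],
    )


def categorize_pressure(p_gradient, thresholds: ChangeThresholds):
    """Pressure category per sample: thresholds are inclusive.

    Accepts a scalar or an array; returns the same shape of category
    strings.
    """
    g = np.asarray(p_gradient, dtype=float)
    cat = np.where(
        g >= thresholds.pressure_increase_threshold,
        "increasing",
        np.where(g <= thresholds.pressure_decrease_threshold, "decreasing", "static"),
    )
    return cat if g.ndim else str(cat)


def categorize_lumen(t, signal_gradient, events: LuminalEvents, thresholds: ChangeThresholds):
    """Lumen category per sample.

    Occluded outside [O, C] (inclusive interval); inside it, increasing
    / decreasing / static against the change thresholds (inclusive).
    The occlusion rule is interval-based, not a diameter == 0 test: the
    catheter occupies the resting lumen (diameter baseline is 0 by
    calibration) and admittance never reads "0 diameter".
    """
    t_arr = np.asarray(t, dtype=float)
    g = np.asarray(signal_gradient, dtype=float)
    if events.detected:
        open_mask = (t_arr >= events.t_open) & (t_arr <= events.t_close)
    else:
        open_mask = np.zeros(t_arr.shape, dtype=bool)
    cat = np.where(
        ~open_mask,
        "occluded",
        np.where(
            g >= thresholds.increase_threshold,
            "increasing",
            np.where(g <= thresholds.decrease_threshold, "decreasing", "static"),
        ),
    )
    return cat if t_arr.ndim else str(cat)


def state_from_categories(lumen_category: str, pressure_category: str) -> MechanicalState:
    """Grid lookup from a (lumen, pressure) category pair; total function."""
    try:
        return _GRID[(lumen_category, pressure_category)]
    except KeyError:
        raise FormatError(
            f"invalid category pair ({lumen_category!r}, {pressure_category!r})"
        ) from None


def _codes_from_categories(lumen_cats: np.ndarray, pressure_cats: np.ndarray) -> np.ndarray:
    codes = np.empty(lumen_cats.shape, dtype="<U4")
    for (lc, pc), st in _GRID.items():
        codes[(lumen_cats == lc) & (pressure_cats == pc)] = st.code
    return codes


@dataclass
class StateTimeline:
    """Per-sample state labels for one site and one method."""

    site_id: str
    method: str  # "diameter" | "admittance"
    times: np.ndarray
    states: np.ndarray  # state codes, one per sample
    events: LuminalEvents | None = None
    thresholds: ChangeThresholds | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype="<U4")
        if self.times.shape != self.states.shape:
            raise FormatError("times and states must have equal length")

    @property
    def n_samples(self) -> int:
        return int(self.times.size)


def classify_timeline(
    recording: SwallowRecording,
    site_id: str,
    method: str = "diameter",
    config: "RunConfig | None" = None,
) -> StateTimeline:
    """Run the full per-site pipeline and label every sample.

    Steps: select the pressure trace and the method's luminal signal
    (impedance is converted to admittance on the fly), align both onto
    the analysis timebase, Gaussian-smooth, differentiate, detect the
    luminal event, derive change thresholds, categorize per sample and
    look up the state grid.

    When no luminal event is detected the whole window is labelled
    occluded quiescence (for map rendering); such timelines carry the
    NOT_DETECTED event status and are excluded from epoch statistics.
    Incomplete events raise :class:`~mechstate.core.IncompleteEventError`
    and the site is excluded by the orchestration layer.
    """
    from .config import RunConfig  # local import to avoid a cycle

    cfg = config or RunConfig()
    pre = cfg.preprocess

    pressure = recording.trace(site_id, "pressure")
    if method == "diameter":
        signal = recording.trace(site_id, "diameter")
        open_thr, close_thr = cfg.diameter_open_threshold, cfg.diameter_close_threshold
        thr_method = "diameter_adaptive"
    elif method == "admittance":
        if recording.has(site_id, "admittance"):
            signal = recording.trace(site_id, "admittance")
        else:
            signal = impedance_to_admittance(recording.trace(site_id, "impedance"))
        open_thr, close_thr = cfg.admittance_open_threshold, cfg.admittance_close_threshold
        thr_method = "admittance_fixed"
    else:
        raise FormatError(f"unknown method {method!r}")

    pressure, signal = align_timebase([pressure, signal], pre.target_rate)
    pressure_s = gaussian_smooth(pressure, pre.smoothing_window)
    signal_s = gaussian_smooth(signal, pre.smoothing_window)
    p_grad = time_derivative(pressure_s)
    s_grad = time_derivative(signal_s)

    events = detect_luminal_events(signal_s, s_grad, open_thr, close_thr)
    if events.status is EventStatus.INCOMPLETE:
        from .core import IncompleteEventError

        raise IncompleteEventError(
            f"site {site_id!r}: opening detected at {events.t_open:.2f} s "
            f"but no closure followed"
        )
    if events.status is EventStatus.NOT_DETECTED:
        codes = np.full(signal_s.times.shape, "oq", dtype="<U4")
        return StateTimeline(site_id, method, signal_s.times, codes, events, None)

    thresholds = derive_change_thresholds(
        s_grad,
        events,
        thr_method,
        percentile=cfg.adaptive_percentile,
        orientation=cfg.percentile_orientation,
        pressure_increase=cfg.pressure_increase_threshold,
        pressure_decrease=cfg.pressure_decrease_threshold,
        min_phase_samples=cfg.min_phase_samples,
    )
    lum = categorize_lumen(signal_s.times, s_grad.values, events, thresholds)
    pc = categorize_pressure(p_grad.values, thresholds)
    codes = _codes_from_categories(np.asarray(lum), np.asarray(pc))
    return StateTimeline(site_id, method, signal_s.times, codes, events, thresholds)


@dataclass
class EpochDistribution:
    """Fraction of samples per state in each of the four epochs.

    ``proportions`` is a DataFrame indexed by epoch with one column per
    state code; each non-empty epoch's row sums to 1.  Epochs with no
    samples are listed in ``empty_epochs`` and hold NaN rows.
    """

    proportions: pd.DataFrame
    counts: pd.DataFrame
    empty_epochs: list = field(default_factory=list)


def epoch_distribution(timeline: StateTimeline) -> EpochDistribution:
    """Bin a timeline's states into the four luminal-event epochs.

    Epoch boundaries: [start, O), [O, M), [M, C), [C, end].  Requires a
    detected event.
    """
    ev = timeline.events
    if ev is None or not ev.detected:
        raise FormatError(
            f"site {timeline.site_id!r}: no luminal event; epochs undefined"
        )
    t = timeline.times
    edges = [t[0] - np.inf, ev.t_open, ev.t_max, ev.t_close, np.inf]
    counts = pd.DataFrame(0, index=list(EPOCHS), columns=list(STATE_CODES), dtype=int)
    for epoch, lo, hi in zip(EPOCHS, edges[:-1], edges[1:]):
        mask = (t >= lo) & (t < hi)
        if epoch == "Post-C":
            mask = t >= ev.t_close
        elif epoch == "M-C":
            mask = (t >= ev.t_max) & (t < ev.t_close)
        vals, n = np.unique(timeline.states[mask], return_counts=True)
        for v, c in zip(vals, n):
            counts.loc[epoch, v] = int(c)
    totals = counts.sum(axis=1)
    props = counts.div(totals.where(totals > 0), axis=0)
    empty = [e for e in EPOCHS if totals[e] == 0]
    return EpochDistribution(proportions=props, counts=counts, empty_epochs=empty)


def dominant_sequence(states, min_run: int = 3) -> list:
    """Ordered sequence of dominant states, transient flicker removed.

    Collapses the per-sample labels to their run-length sequence and
    drops runs shorter than ``min_run`` samples (default 3, i.e. 0.15 s
    at 20 Hz) before merging adjacent repeats.  Per-sample classification
    is instantaneous, so brief threshold chatter around category
    boundaries shows up as minor transient deviations from the canonical
    state order; this view reports the order itself.
    """
    states = np.asarray(states)
    if states.size == 0:
        return []
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [states.size]])
    seq = []
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            if not seq or seq[-1] != states[s]:
                seq.append(str(states[s]))
    return seq
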