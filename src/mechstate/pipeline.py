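"""End-to-end orchestration: recording -> timelines, epochs, concordance.

This is the layer that enforces the fixed preprocessing order
(convert -> calibrate -> align -> smooth -> differentiate), runs both
classification methods where the channels allow, and keeps the
"every analyzable site" accounting: sites whose luminal event is
incomplete or whose adaptive thresholds cannot be derived are excluded
and logged with a reason, not silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .concordance import ConcordanceResult, correlation_window, pearson_r, state_agreement
from .config import RunConfig
from .core import (
    DomainError,
    IncompleteEventError,
    SwallowRecording,
    ThresholdError,
)
from .events import EventStatus
from .preprocess import align_timebase, gaussian_smooth, impedance_to_admittance
from .states import StateTimeline, classify_timeline, epoch_distribution

log = logging.getLogger("mechstate")

__all__ = ["SiteOutcome", "SwallowAnalysis", "analyze_recording"]


@dataclass
class SiteOutcome:
    """Per-site, per-method bookkeeping row for the events table."""

    site_id: str
    method: str
    status: str
    t_open: float = np.nan
    t_max: float = np.nan
    t_close: float = np.nan
    inc_thr: float = np.nan
    dec_thr: float = np.nan
    reason: str = ""

    def as_row(self) -> dict:
        return {
            "site_id": self.site_id,
            "method": self.method,
            "t_open_s": self.t_open,
            "t_max_s": self.t_max,
            "t_close_s": self.t_close,
            "inc_thr": self.inc_thr,
            "dec_thr": self.dec_thr,
            "status": self.status,
        }


@dataclass
class SwallowAnalysis:
    """Everything computed for one swallow."""

    recording: SwallowRecording
    timelines: dict = field(default_factory=dict)  # (site, method) -> StateTimeline
    outcomes: list = field(default_factory=list)   # SiteOutcome
    distributions: dict = field(default_factory=dict)  # (site, method) -> EpochDistribution
    concordance: list = field(default_factory=list)    # ConcordanceResult
    agreement: dict = field(default_factory=dict)      # site -> percent

    @property
    def excluded_sites(self) -> list:
        return sorted(
            {o.site_id for o in self.outcomes if o.status not in ("detected", "not_detected")}
        )

    def mean_agreement(self) -> float:
        vals = list(self.agreement.values())
        return float(np.mean(vals)) if vals else np.nan


def _available_methods(rec: SwallowRecording, site: str, methods) -> list:
    out = []
    for m in methods:
        if m == "diameter" and rec.has(site, "diameter"):
            out.append(m)
        elif m == "admittance" and (
            rec.has(site, "admittance") or rec.has(site, "impedance")
        ):
            out.append(m)
    return out


def analyze_recording(
    rec: SwallowRecording,
    config: RunConfig | None = None,
    methods=("diameter", "admittance"),
) -> SwallowAnalysis:
    """Classify every analyzable site by every requested method.

    Computes per-site state timelines, epoch distributions, the
    diameter--admittance Pearson correlation over the luminal event
    window, and (where both methods ran) the inter-method state
    agreement.
    """
    cfg = config or RunConfig()
    result = SwallowAnalysis(recording=rec)

    for site in rec.sites():
        for method in _available_methods(rec, site, methods):
            try:
                tl = classify_timeline(rec, site, method, cfg)
            except IncompleteEventError as exc:
                log.warning("%s/%s excluded: %s", site, method, exc)
                result.outcomes.append(
                    SiteOutcome(site, method, "incomplete", reason=str(exc))
                )
                continue
            except ThresholdError as exc:
                log.warning("%s/%s excluded: %s", site, method, exc)
                result.outcomes.append(
                    SiteOutcome(site, method, "threshold_error", reason=str(exc))
                )
                continue
            result.timelines[(site, method)] = tl
            ev = tl.events
            if ev is not None and ev.status is EventStatus.DETECTED:
                thr = tl.thresholds
                result.outcomes.append(
                    SiteOutcome(
                        site,
                        method,
                        "detected",
                        ev.t_open,
                        ev.t_max,
                        ev.t_close,
                        thr.increase_threshold if thr else np.nan,
                        thr.decrease_threshold if thr else np.nan,
                    )
                )
                result.distributions[(site, method)] = epoch_distribution(tl)
            else:
                result.outcomes.append(SiteOutcome(site, method, "not_detected"))

        _site_concordance(rec, site, cfg, result)

    return result


def _site_concordance(rec, site, cfg, result) -> None:
    """Pearson r over the event window + inter-method agreement."""
    tl_d = result.timelines.get((site, "diameter"))
    tl_a = result.timelines.get((site, "admittance"))
    if tl_d is not None and tl_a is not None:
        try:
            result.agreement[site] = state_agreement(tl_d, tl_a)
        except DomainError as exc:
            log.warning("%s agreement skipped: %s", site, exc)

    if tl_d is None or tl_d.events is None or not tl_d.events.detected:
        return
    if not (rec.has(site, "admittance") or rec.has(site, "impedance")):
        return
    diameter = rec.trace(site, "diameter")
    adm = (
        rec.trace(site, "admittance")
        if rec.has(site, "admittance")
        else impedance_to_admittance(rec.trace(site, "impedance"))
    )
    d_al, a_al = align_timebase([diameter, adm], cfg.preprocess.target_rate)
    d_s = gaussian_smooth(d_al, cfg.preprocess.smoothing_window)
    a_s = gaussian_smooth(a_al, cfg.preprocess.smoothing_window)

    ev = tl_d.events
    start, end = correlation_window(ev, cfg.pad_fraction)
    mask = (d_s.times >= start) & (d_s.times <= end)
    n = int(np.count_nonzero(mask))
    if n < 3:
        log.warning("%s correlation skipped: window has %d samples", site, n)
        return
    inside = (d_s.times[mask] >= ev.t_open) & (d_s.times[mask] <= ev.t_close)
    try:
        r = pearson_r(d_s.values[mask], a_s.values[mask])
    except DomainError as exc:
        log.warning("%s correlation skipped: %s", site, exc)
        return
    result.concordance.append(
        ConcordanceResult(
            site_id=site,
            swallow_id=rec.swallow_id,
            pearson_r=r,
            n_samples=n,
            window=(float(d_s.times[mask][0]), float(d_s.times[mask][-1])),
            event_fraction=float(np.count_nonzero(inside)) / n,
            subject_id=rec.subject_id,
            bolus_type=rec.bolus_type,
            posture=rec.posture,
        )
    )
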