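"""Diameter--admittance concordance.

Two complementary measures of whether admittance can stand in for
fluoroscopic diameter:

* the Pearson correlation between the two signals over the luminal
  event window (the main event of opening and closing, padded so that
  event samples still make up >= 80% of the window);
* the percentage of time samples for which the diameter-based and
  admittance-based classifications produce exactly the same mechanical
  state.

Correlations are computed on the smoothed, aligned traces — the same
inputs the classifier sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import DomainError
from .events import LuminalEvents
from .states import StateTimeline

__all__ = [
    "ConcordanceResult",
    "CorrelationSummary",
    "correlation_window",
    "pearson_r",
    "state_agreement",
    "summarize_correlations",
]


@dataclass(frozen=True)
class ConcordanceResult:
    """Per-site, per-swallow diameter--admittance correlation record."""

    site_id: str
    swallow_id: str
    pearson_r: float
    n_samples: int
    window: tuple
    event_fraction: float
    subject_id: str = ""
    bolus_type: str = "liquid"
    posture: str = "upright"

    def __post_init__(self) -> None:
        if not np.isnan(self.pearson_r) and abs(self.pearson_r) > 1 + 1e-12:
            raise DomainError(f"|r| > 1: {self.pearson_r}")


@dataclass
class CorrelationSummary:
    """Location/scale of a set of r values plus the low-outlier rule.

    ``outlier_threshold`` is Q1 - 1.5 * IQR (quartiles by linear
    interpolation between order statistics); outliers are counted, never
    removed from the stored values.
    """

    mean: float | None
    median: float | None
    sd: float | None
    n: int
    outlier_threshold: float | None
    n_outliers: int
    stratum: tuple | None = None
    values: np.ndarray = field(default_factory=lambda: np.array([]))


def correlation_window(events: LuminalEvents, pad_fraction: float = 0.1) -> tuple:
    """Window [O - pad, C + pad] with pad = pad_fraction * (C - O).

    With the default pad of 10% on each side, event samples make up
    1 / 1.2 ~= 83% of the window before any clipping; callers clip to
    the recording and recompute the actual event fraction from samples.
    """
    if not events.detected:
        raise DomainError("cannot build a correlation window without an event")
    span = events.t_close - events.t_open
    pad = pad_fraction * span
    return (events.t_open - pad, events.t_close + pad)


def pearson_r(x, y) -> float:
    """Standard product-moment correlation of two equal-length arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise DomainError("need at least 3 samples for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for a constant input")
    return float(stats.pearsonr(x, y).statistic)


def state_agreement(a: StateTimeline, b: StateTimeline) -> float:
    """Percent of common samples with identical state codes.

    Requires the two timelines to share a timebase; the denominator is
    the samples where both methods produced a label.
    """
    if a.site_id != b.site_id:
        raise DomainError(f"site mismatch: {a.site_id!r} vs {b.site_id!r}")
    n = min(a.times.size, b.times.size)
    if n == 0:
        raise DomainError("no common samples")
    if np.any(np.abs(a.times[:n] - b.times[:n]) > 1e-6):
        raise DomainError("timelines are not on a common timebase")
    same = np.count_nonzero(a.states[:n] == b.states[:n])
    return 100.0 * same / n


def _summarize(values: np.ndarray, stratum=None) -> CorrelationSummary:
    values = np.asarray(values, dtype=float)
    n = int(values.size)
    if n == 0:
        return CorrelationSummary(None, None, None, 0, None, 0, stratum, values)
    q1, q3 = np.percentile(values, [25, 75])
    thr = float(q1 - 1.5 * (q3 - q1))
    return CorrelationSummary(
        mean=float(values.mean()),
        median=float(np.median(values)),
        sd=float(values.std(ddof=1)) if n > 1 else 0.0,
        n=n,
        outlier_threshold=thr,
        n_outliers=int(np.count_nonzero(values < thr)),
        stratum=stratum,
        values=values,
    )


def summarize_correlations(results) -> dict:
    """Overall and per-stratum (bolus_type, posture) correlation summaries.

    Returns a dict mapping ``"overall"`` and each observed stratum tuple
    to a :class:`CorrelationSummary`.  Strata never observed (e.g. solid
    boluses in the decubitus position, which the protocol does not
    administer) are simply absent, not zero-filled.
    """
    results = list(results)
    out = {"overall": _summarize(np.array([r.pearson_r for r in results]))}
    strata = {}
    for r in results:
        strata.setdefault((r.bolus_type, r.posture), []).append(r.pearson_r)
    for stratum, vals in strata.items():
        out[stratum] = _summarize(np.array(vals), stratum)
    return out
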