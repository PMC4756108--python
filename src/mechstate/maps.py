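"""Spatiotemporal mechanical-state maps and regional summaries.

A state map stacks per-site timelines into a (site x time) matrix of
state codes, ordered proximal to distal by axial position, the
spatiotemporal view of a swallow.  Regional summaries aggregate state
proportions over the proximal (reference to transition zone) and distal
(transition zone to EGJ) esophagus, per bolus-type x posture stratum,
optionally omitting the background state of occluded quiescence and
renormalizing the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeometryError, SensorGeometry
from .states import EXCLUDED_CODE, STATE_BY_CODE, STATE_CODES, StateTimeline

__all__ = [
    "StateMap",
    "RegionalSummary",
    "build_state_map",
    "regional_summary",
    "render_state_map",
    "STATE_COLORS",
]

#: Fixed palette keyed by state code, by activity family: quiescence in
#: grays/greens, relaxations in blues, contractions in oranges/reds,
#: passive dilatation in gray.  Excluded sites use the reserved white.
STATE_COLORS = {
    "oq": "#f0f0f0",
    "dq": "#a1d99b",
    "oimc": "#cb181d",
    "oimr": "#08519c",
    "itr": "#9ecae1",
    "itc": "#fd8d3c",
    "atc": "#fee391",
    "atr": "#4292c6",
    "dipi": "#df65b0",
    "dipd": "#c994c7",
    "pd": "#969696",
    "ps": "#636363",
    EXCLUDED_CODE: "#ffffff",
}


@dataclass
class StateMap:
    """State codes per (site, time), rows ordered proximal to distal."""

    site_ids: list
    positions: np.ndarray  # cm, increasing
    times: np.ndarray
    codes: np.ndarray  # shape (n_sites, n_times)
    pressure: np.ndarray | None = None  # optional overlay, same shape

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.codes = np.asarray(self.codes, dtype="<U4")
        if self.codes.shape != (len(self.site_ids), self.times.size):
            raise GeometryError("codes matrix shape does not match sites x times")
        if np.any(np.diff(self.positions) <= 0):
            raise GeometryError("map rows must be ordered by increasing position")


@dataclass
class RegionalSummary:
    """State proportions for one region and one stratum."""

    region: str  # "proximal" | "distal"
    stratum: tuple  # (bolus_type, posture)
    proportions: dict  # state code -> fraction over included states
    n_samples: int  # classified samples contributing (before omission)
    omitted: tuple = ()


def build_state_map(
    timelines,
    geometry: SensorGeometry,
    excluded_sites=(),
) -> StateMap:
    """Assemble per-site timelines into a map ordered by axial position.

    Sites in ``excluded_sites`` (e.g. incomplete luminal events) are
    rendered as rows of the reserved excluded code.  Site positions come
    from ``geometry.site_positions``.
    """
    timelines = list(timelines)
    if not timelines:
        raise GeometryError("no timelines to map")
    times = timelines[0].times
    for tl in timelines[1:]:
        if tl.times.size != times.size or np.any(np.abs(tl.times - times) > 1e-6):
            raise GeometryError("timelines do not share a timebase")

    rows = []
    for tl in timelines:
        if tl.site_id not in geometry.site_positions:
            raise GeometryError(f"no axial position for site {tl.site_id!r}")
        rows.append((geometry.site_positions[tl.site_id], tl.site_id, tl.states))
    for site in excluded_sites:
        if site not in geometry.site_positions:
            raise GeometryError(f"no axial position for excluded site {site!r}")
        rows.append(
            (
                geometry.site_positions[site],
                site,
                np.full(times.shape, EXCLUDED_CODE, dtype="<U4"),
            )
        )
    positions = np.array([r[0] for r in rows])
    if np.unique(positions).size != positions.size:
        raise GeometryError("duplicate site positions in map")
    order = np.argsort(positions)
    return StateMap(
        site_ids=[rows[i][1] for i in order],
        positions=positions[order],
        times=times,
        codes=np.vstack([rows[i][2] for i in order]),
    )


def regional_summary(
    maps,
    geometry: SensorGeometry,
    strata=None,
    omit=("oq",),
) -> list:
    """Per-region, per-stratum state proportions across a cohort of maps.

    ``maps`` is an iterable of ``(StateMap, (bolus_type, posture))``
    pairs; ``strata`` optionally restricts which strata are reported.
    Excluded-site rows never contribute.  States in ``omit`` (occluded
    quiescence by default, the background state) are dropped and the
    remaining proportions renormalized, which preserves the ratios of
    the remaining states.  Regions with no sites are absent from the
    output.
    """
    counts: dict = {}
    for smap, stratum in maps:
        if strata is not None and stratum not in strata:
            continue
        for pos, row in zip(smap.positions, smap.codes):
            region = geometry.region_of(pos)
            key = (region, tuple(stratum))
            tally = counts.setdefault(key, dict.fromkeys(STATE_CODES, 0))
            vals, n = np.unique(row, return_counts=True)
            for v, c in zip(vals, n):
                if v in tally:
                    tally[v] += int(c)

    out = []
    for (region, stratum), tally in sorted(counts.items()):
        total = sum(tally.values())
        kept = {k: v for k, v in tally.items() if k not in omit}
        kept_total = sum(kept.values())
        props = (
            {k: v / kept_total for k, v in kept.items()}
            if kept_total
            else {k: np.nan for k in kept}
        )
        out.append(
            RegionalSummary(
                region=region,
                stratum=stratum,
                proportions=props,
                n_samples=total,
                omitted=tuple(omit),
            )
        )
    return out


def render_state_map(smap: StateMap, out_path, dpi: int = 120) -> None:
    """Render a state map to an image with the fixed 12-state legend.

    Each horizontal strip is one catheter site; the optional pressure
    overlay is drawn as a line per strip.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    code_order = list(STATE_CODES) + [EXCLUDED_CODE]
    cmap = ListedColormap([STATE_COLORS[c] for c in code_order])
    index = {c: i for i, c in enumerate(code_order)}
    img = np.vectorize(index.get)(smap.codes)

    dt = smap.times[1] - smap.times[0] if smap.times.size > 1 else 1.0
    t_edges = np.append(smap.times, smap.times[-1] + dt)
    fig, ax = plt.subplots(figsize=(10, 0.5 * len(smap.site_ids) + 2))
    ax.pcolormesh(
        t_edges,
        np.arange(len(smap.site_ids) + 1),
        img,
        cmap=cmap,
        vmin=-0.5,
        vmax=len(code_order) - 0.5,
        shading="flat",
    )
    if smap.pressure is not None:
        p = smap.pressure
        scale = np.nanmax(np.abs(p)) or 1.0
        for i, row in enumerate(p):
            ax.plot(smap.times, i + 0.5 + 0.4 * row / scale, color="black", lw=0.6)
    ax.set_yticks(np.arange(len(smap.site_ids)) + 0.5)
    ax.set_yticklabels(
        [f"{s} ({x:g} cm)" for s, x in zip(smap.site_ids, smap.positions)]
    )
    ax.invert_yaxis()  # proximal at the top
    ax.set_xlabel("time (s)")
    handles = [
        Patch(facecolor=STATE_COLORS[c], edgecolor="k", label=f"{c}: {STATE_BY_CODE[c].label}")
        for c in STATE_CODES
    ] + [Patch(facecolor=STATE_COLORS[EXCLUDED_CODE], edgecolor="k", label="excluded site")]
    ax.legend(
        handles=handles, loc="upper left", bbox_to_anchor=(1.01, 1), fontsize=7
    )
    fig.tight_layout()
    fig.savefig(out_path, dpi=dpi)
    plt.close(fig)


def map_to_frame(smap: StateMap) -> pd.DataFrame:
    """Long-format export: (time_s, site_id, position_cm, state_code)."""
    frames = []
    for site, pos, row in zip(smap.site_ids, smap.positions, smap.codes):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": smap.times,
                    "site_id": site,
                    "position_cm": pos,
                    "state_code": row,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
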