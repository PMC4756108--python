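"""Reading and writing swallow recordings and analysis results.

Data dialect (matching the acquisition systems' comma-separated text
export): one long-format CSV per recording with header
``time_s,site_id,channel,value`` and one row per sample per channel.
Channel units are fixed per kind: pressure mmHg, diameter mm, impedance
ohm, admittance mS.  Decimal point, no thousands separators, UTF-8.

Each data file is accompanied by a YAML metadata file carrying the
sensor geometry (axial cm below the UES), catheter diameter, bolus
type/volume, posture and subject/swallow identifiers.  Impedance is
retained as impedance on read; conversion to admittance is an explicit
preprocessing step.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    CHANNEL_KINDS,
    ChannelTrace,
    FormatError,
    SensorGeometry,
    SwallowRecording,
)

__all__ = ["read_recording", "write_recording", "write_results"]

_DATA_COLUMNS = ["time_s", "site_id", "channel", "value"]


def _geometry_from_meta(meta: dict) -> SensorGeometry:
    try:
        g = meta["geometry"]
    except KeyError:
        raise FormatError("metadata file is missing the 'geometry' section") from None
    for key in ("pressure_positions_cm", "impedance_segment_centers_cm"):
        if key not in g:
            raise FormatError(f"metadata geometry is missing {key!r}")
    return SensorGeometry(
        pressure_positions=np.asarray(g["pressure_positions_cm"], dtype=float),
        impedance_segment_centers=np.asarray(
            g["impedance_segment_centers_cm"], dtype=float
        ),
        catheter_diameter=float(g.get("catheter_diameter_mm", 3.2)),
        transition_zone_position=float(g.get("transition_zone_position_cm", 0.0)),
        egj_position=float(g.get("egj_position_cm", 0.0)),
        site_positions=dict(g.get("site_positions_cm", {})),
    )


def read_recording(data_path, meta_path) -> SwallowRecording:
    """Read a recording from a long-format CSV plus a YAML metadata file."""
    df = pd.read_csv(data_path)
    missing = [c for c in _DATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{data_path}: missing required column(s) {', '.join(missing)}"
        )
    unknown = set(df["channel"].unique()) - set(CHANNEL_KINDS)
    if unknown:
        raise FormatError(f"{data_path}: unknown channel kind(s) {sorted(unknown)}")

    meta = yaml.safe_load(Path(meta_path).read_text())
    if not isinstance(meta, dict):
        raise FormatError(f"{meta_path}: metadata must be a mapping")
    geometry = _geometry_from_meta(meta)

    traces = {}
    for (site, kind), grp in df.groupby(["site_id", "channel"], sort=False):
        grp = grp.sort_values("time_s")
        traces[(str(site), str(kind))] = ChannelTrace(
            channel_kind=str(kind),
            site_id=str(site),
            times=grp["time_s"].to_numpy(dtype=float),
            values=grp["value"].to_numpy(dtype=float),
        )
    return SwallowRecording(
        traces=traces,
        geometry=geometry,
        bolus_type=str(meta.get("bolus_type", "liquid")),
        posture=str(meta.get("posture", "upright")),
        bolus_volume=float(meta.get("bolus_volume_ml", 5.0)),
        subject_id=str(meta.get("subject_id", "subject")),
        swallow_id=str(meta.get("swallow_id", "swallow")),
    )


def write_recording(rec: SwallowRecording, data_path, meta_path) -> None:
    """Write a recording; ``read_recording`` round-trips it exactly.

    Values are serialized with full float precision (repr), so the
    round-trip reproduces all fields to better than 1e-9 relative
    tolerance.
    """
    frames = []
    for (site, kind), tr in rec.traces.items():
        frames.append(
            pd.DataFrame(
                {
                    "time_s": tr.times,
                    "site_id": site,
                    "channel": kind,
                    "value": tr.values,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(data_path, index=False, float_format="%.12g")

    g = rec.geometry
    meta = {
        "subject_id": rec.subject_id,
        "swallow_id": rec.swallow_id,
        "bolus_type": rec.bolus_type,
        "posture": rec.posture,
        "bolus_volume_ml": float(rec.bolus_volume),
        "geometry": {
            "pressure_positions_cm": [float(x) for x in g.pressure_positions],
            "impedance_segment_centers_cm": [
                float(x) for x in g.impedance_segment_centers
            ],
            "catheter_diameter_mm": float(g.catheter_diameter),
            "transition_zone_position_cm": float(g.transition_zone_position),
            "egj_position_cm": float(g.egj_position),
            "site_positions_cm": {k: float(v) for k, v in g.site_positions.items()},
        },
    }
    Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def write_results(timelines, events_rows, distributions, concordance, out_dir) -> None:
    """Emit result tables as delimited text plus a structured run summary.

    * ``states.csv`` — (time_s, site_id, method, state_code) per sample;
    * ``events.csv`` — per-site O/M/C times, thresholds and status;
    * ``epochs.csv`` — per-epoch state proportions per site/method;
    * ``concordance.csv`` — per-site correlation and window bookkeeping;
    * ``summary.yaml`` — counts and overall statistics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    state_frames = [
        pd.DataFrame(
            {
                "time_s": tl.times,
                "site_id": tl.site_id,
                "method": tl.method,
                "state_code": tl.states,
            }
        )
        for tl in timelines
    ]
    states_df = (
        pd.concat(state_frames, ignore_index=True)
        if state_frames
        else pd.DataFrame(columns=["time_s", "site_id", "method", "state_code"])
    )
    states_df.to_csv(out / "states.csv", index=False, float_format="%.12g")

    ev_cols = [
        "site_id",
        "method",
        "t_open_s",
        "t_max_s",
        "t_close_s",
        "inc_thr",
        "dec_thr",
        "status",
    ]
    pd.DataFrame(list(events_rows), columns=ev_cols).to_csv(
        out / "events.csv", index=False, float_format="%.12g"
    )

    dist_frames = []
    for site_id, method, dist in distributions:
        d = dist.proportions.reset_index(names="epoch")
        d.insert(0, "method", method)
        d.insert(0, "site_id", site_id)
        dist_frames.append(d)
    if dist_frames:
        pd.concat(dist_frames, ignore_index=True).to_csv(
            out / "epochs.csv", index=False, float_format="%.12g"
        )
    else:
        (out / "epochs.csv").write_text("site_id,method,epoch\n")

    conc_cols = [
        "subject_id",
        "swallow_id",
        "site_id",
        "r",
        "n",
        "window_start_s",
        "window_end_s",
        "event_fraction",
        "bolus_type",
        "posture",
    ]
    conc_df = pd.DataFrame(list(concordance), columns=conc_cols)
    conc_df.to_csv(out / "concordance.csv", index=False, float_format="%.12g")

    if len(conc_df):
        summary_stats = {
            "n": int(len(conc_df)),
            "r_mean": float(conc_df["r"].mean()),
            "r_median": float(conc_df["r"].median()),
            "r_sd": float(conc_df["r"].std(ddof=1)) if len(conc_df) > 1 else 0.0,
        }
    else:
        summary_stats = {"n": 0, "r_mean": None, "r_median": None, "r_sd": None}
    summary = {
        "n_timelines": len(list(timelines)),
        "correlations": summary_stats,
    }
    (out / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=False))
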