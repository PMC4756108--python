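"""Domain-type validation and recording round-trip through the CSV dialect."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechstate import read_recording, write_recording, write_results
from mechstate.core import (
    ChannelTrace,
    FormatError,
    GeometryError,
    SamplingError,
    SensorGeometry,
    SwallowRecording,
)
from mechstate.states import StateTimeline

from conftest import make_geometry, make_recording, make_trace


class TestChannelTrace:
    def test_rejects_time_gap(self):
        t = np.arange(20) / 20.0
        t[10:] += 3 / 20.0  # 3-sample gap
        with pytest.raises(SamplingError):
            ChannelTrace("pressure", "s1", t, np.zeros(20))

    def test_rejects_nonfinite_values(self):
        vals = np.zeros(20)
        vals[7] = np.nan
        with pytest.raises(FormatError, match="sample 7"):
            make_trace(values=vals, n=20)

    def test_rejects_short_trace(self):
        with pytest.raises(SamplingError):
            ChannelTrace("pressure", "s1", np.array([0.0]), np.array([1.0]))

    def test_infers_sampling_rate(self):
        assert make_trace(rate=25.0, n=10).sampling_rate == pytest.approx(25.0)


class TestSensorGeometry:
    def test_rejects_decreasing_positions(self):
        with pytest.raises(GeometryError):
            make_geometry(pressure_positions=[3.0, 2.0, 1.0])

    def test_rejects_nonpositive_catheter(self):
        with pytest.raises(GeometryError):
            make_geometry(catheter_diameter=0.0)

    def test_warns_on_offnominal_spacing(self):
        with pytest.warns(UserWarning, match="spacing deviates"):
            make_geometry(pressure_positions=[0.0, 2.5, 5.0])

    def test_transition_zone_boundary_is_distal(self):
        g = make_geometry()
        assert g.region_of(g.transition_zone_position) == "distal"
        assert g.region_of(g.transition_zone_position - 0.1) == "proximal"


class TestSwallowRecording:
    def test_requires_pressure_per_site(self):
        rec = make_recording()
        traces = {k: v for k, v in rec.traces.items() if k[1] != "pressure"}
        with pytest.raises(FormatError, match="no pressure"):
            SwallowRecording(traces=traces, geometry=rec.geometry)

    def test_requires_luminal_channel_per_site(self):
        rec = make_recording()
        traces = {k: v for k, v in rec.traces.items() if k[1] == "pressure"}
        with pytest.raises(FormatError, match="luminal"):
            SwallowRecording(traces=traces, geometry=rec.geometry)

    def test_rejects_empty(self):
        with pytest.raises(FormatError):
            SwallowRecording(traces={}, geometry=make_geometry())


class TestRecordingRoundTrip:
    def test_two_site_recording_round_trips(self, tmp_path):
        rec = make_recording(sites=("s1", "s2"))
        write_recording(rec, tmp_path / "d.csv", tmp_path / "d.meta.yaml")
        back = read_recording(tmp_path / "d.csv", tmp_path / "d.meta.yaml")
        assert len(back.traces) == 4
        for key, tr in rec.traces.items():
            np.testing.assert_allclose(back.traces[key].values, tr.values, rtol=1e-9)
            np.testing.assert_allclose(back.traces[key].times, tr.times, rtol=1e-9)
        assert back.geometry.site_positions == rec.geometry.site_positions

    def test_admittance_channel_tagged(self, tmp_path):
        rec = make_recording(channels=("pressure", "admittance"))
        write_recording(rec, tmp_path / "d.csv", tmp_path / "d.meta.yaml")
        text = (tmp_path / "d.csv").read_text()
        assert "admittance" in text
        back = read_recording(tmp_path / "d.csv", tmp_path / "d.meta.yaml")
        assert ("s1", "admittance") in back.traces

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        n_sites=st.integers(1, 3),
        n=st.integers(5, 40),
        rate=st.sampled_from([20.0, 25.0, 50.0]),
        seed=st.integers(0, 2**16),
    )
    def test_round_trip_identity_property(self, tmp_path_factory, n_sites, n, rate, seed):
        rng = np.random.default_rng(seed)
        sites = tuple(f"s{i}" for i in range(n_sites))
        traces = {}
        for site in sites:
            for kind, lo, hi in (("pressure", -50, 150), ("diameter", 0, 30)):
                traces[(site, kind)] = make_trace(
                    kind, site, n, rate, rng.uniform(lo, hi, n)
                )
        rec = SwallowRecording(
            traces=traces,
            geometry=make_geometry(
                site_positions={s: 2.0 * (i + 1) for i, s in enumerate(sites)}
            ),
            bolus_type="semisolid",
            posture="decubitus",
        )
        d = tmp_path_factory.mktemp("rt")
        write_recording(rec, d / "r.csv", d / "r.meta.yaml")
        back = read_recording(d / "r.csv", d / "r.meta.yaml")
        assert set(back.traces) == set(rec.traces)
        for key in rec.traces:
            np.testing.assert_allclose(
                back.traces[key].values, rec.traces[key].values, rtol=1e-9
            )
        assert (back.bolus_type, back.posture) == ("semisolid", "decubitus")


class TestReadValidation:
    def test_missing_column_named(self, tmp_path):
        (tmp_path / "bad.csv").write_text("time_s,site_id,value\n0,s1,1\n")
        (tmp_path / "m.yaml").write_text(_meta_yaml())
        with pytest.raises(FormatError, match="channel"):
            read_recording(tmp_path / "bad.csv", tmp_path / "m.yaml")

    def test_unknown_channel_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text(
            "time_s,site_id,channel,value\n0,s1,flow,1\n0.05,s1,flow,1\n"
        )
        (tmp_path / "m.yaml").write_text(_meta_yaml())
        with pytest.raises(FormatError, match="flow"):
            read_recording(tmp_path / "bad.csv", tmp_path / "m.yaml")

    def test_time_gap_rejected(self, tmp_path):
        rows = ["time_s,site_id,channel,value"]
        times = list(np.arange(10) / 20.0) + list(np.arange(13, 20) / 20.0)
        for t in times:
            rows.append(f"{t},s1,pressure,1.0")
            rows.append(f"{t},s1,diameter,0.0")
        (tmp_path / "gap.csv").write_text("\n".join(rows) + "\n")
        (tmp_path / "m.yaml").write_text(_meta_yaml())
        with pytest.raises(SamplingError):
            read_recording(tmp_path / "gap.csv", tmp_path / "m.yaml")

    def test_decreasing_geometry_rejected(self, tmp_path):
        (tmp_path / "d.csv").write_text(
            "time_s,site_id,channel,value\n"
            "0,s1,pressure,1\n0.05,s1,pressure,1\n"
            "0,s1,diameter,0\n0.05,s1,diameter,0\n"
        )
        (tmp_path / "m.yaml").write_text(_meta_yaml(pressure="[5.0, 4.0, 3.0]"))
        with pytest.raises(GeometryError):
            read_recording(tmp_path / "d.csv", tmp_path / "m.yaml")


def _meta_yaml(pressure="[0.0, 1.0, 2.0]"):
    return (
        "subject_id: t\nswallow_id: t\nbolus_type: liquid\nposture: upright\n"
        "bolus_volume_ml: 5.0\n"
        "geometry:\n"
        f"  pressure_positions_cm: {pressure}\n"
        "  impedance_segment_centers_cm: [1.0]\n"
        "  catheter_diameter_mm: 3.2\n"
    )


class TestWriteResults:
    def test_timeline_rows_and_method_tags(self, tmp_path):
        t = np.arange(100) / 20.0
        tls = [
            StateTimeline("s1", "diameter", t, np.full(100, "oq")),
            StateTimeline("s1", "admittance", t, np.full(100, "oq")),
        ]
        write_results(tls, [], [], [], tmp_path)
        import pandas as pd

        df = pd.read_csv(tmp_path / "states.csv")
        assert len(df) == 200
        assert set(df.columns) == {"time_s", "site_id", "method", "state_code"}
        assert set(df["method"]) == {"diameter", "admittance"}

    def test_empty_concordance_summary(self, tmp_path):
        write_results([], [], [], [], tmp_path)
        import yaml

        summary = yaml.safe_load((tmp_path / "summary.yaml").read_text())
        assert summary["correlations"]["n"] == 0
        assert summary["correlations"]["r_mean"] is None
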