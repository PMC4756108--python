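"""State taxonomy, per-sample classification and epoch distributions."""

import numpy as np
import pytest

from mechstate import RunConfig, classify_timeline, epoch_distribution, generate_swallow
from mechstate.core import ChannelTrace, SensorGeometry, SwallowRecording
from mechstate.events import ChangeThresholds, LuminalEvents
from mechstate.states import (
    EPOCHS,
    STATE_BY_CODE,
    STATE_CODES,
    STATES,
    categorize_lumen,
    categorize_pressure,
    dominant_sequence,
    state_from_categories,
    state_table,
)
from mechstate.synth import SwallowScenario

from conftest import make_geometry, make_trace

LUMEN = ("occluded", "static", "increasing", "decreasing")
PRESSURE = ("static", "increasing", "decreasing")


class TestTaxonomy:
    def test_grid_tiles_twelve_distinct_states(self):
        codes = {state_from_categories(l, p).code for l in LUMEN for p in PRESSURE}
        assert len(codes) == 12
        assert codes == set(STATE_CODES)

    def test_eight_active_four_passive(self):
        active = [s for s in STATES if s.activity == "active"]
        passive = [s for s in STATES if s.activity == "passive"]
        assert len(active) == 8
        assert {s.code for s in passive} == {"oq", "dq", "pd", "ps"}

    def test_state_table_machine_readable(self):
        df = state_table()
        assert len(df) == 12
        assert df["code"].is_unique
        assert set(df.columns) >= {"code", "label", "activity", "lumen_category"}

    @pytest.mark.parametrize(
        "lumen,pressure,code",
        [
            ("increasing", "increasing", "pd"),   # bolus distends the wall
            ("increasing", "static", "itr"),      # lumen opens, pressure flat
            ("occluded", "static", "oq"),
            ("decreasing", "increasing", "atc"),
            ("decreasing", "static", "itc"),
            ("occluded", "increasing", "oimc"),
            ("occluded", "decreasing", "oimr"),
            ("static", "static", "dq"),
        ],
    )
    def test_named_grid_cells(self, lumen, pressure, code):
        assert state_from_categories(lumen, pressure).code == code

    def test_oracle_equivalence_on_random_pairs(self):
        """Grid lookup equals an independent nested-conditional classifier."""

        def brute_force(lumen, pressure):
            if lumen == "occluded":
                if pressure == "increasing":
                    return "oimc"
                if pressure == "decreasing":
                    return "oimr"
                return "oq"
            if lumen == "static":
                if pressure == "increasing":
                    return "dipi"
                if pressure == "decreasing":
                    return "dipd"
                return "dq"
            if lumen == "increasing":
                if pressure == "increasing":
                    return "pd"
                if pressure == "decreasing":
                    return "atr"
                return "itr"
            if pressure == "increasing":
                return "atc"
            if pressure == "decreasing":
                return "ps"
            return "itc"

        rng = np.random.default_rng(42)
        for _ in range(1000):
            l = LUMEN[rng.integers(4)]
            p = PRESSURE[rng.integers(3)]
            assert state_from_categories(l, p).code == brute_force(l, p)


def _thr(inc=2.0, dec=-2.0):
    return ChangeThresholds(inc, dec)


class TestCategorization:
    def test_pressure_thresholds_inclusive(self):
        thr = _thr()
        assert categorize_pressure(15.0, thr) == "increasing"
        assert categorize_pressure(10.0, thr) == "increasing"  # boundary
        assert categorize_pressure(0.0, thr) == "static"
        assert categorize_pressure(-10.0, thr) == "decreasing"  # boundary
        assert categorize_pressure(-9.99, thr) == "static"

    def test_lumen_interval_and_thresholds(self):
        ev = LuminalEvents(5.0, 7.0, 11.0, 2.0, -2.0, "diameter")
        thr = _thr()
        assert categorize_lumen(4.9, 5.0, ev, thr) == "occluded"
        assert categorize_lumen(6.0, 2.0, ev, thr) == "increasing"  # boundary
        assert categorize_lumen(6.0, 1.99, ev, thr) == "static"
        assert categorize_lumen(8.0, -2.0, ev, thr) == "decreasing"
        assert categorize_lumen(11.05, -5.0, ev, thr) == "occluded"


class TestClassifyTimeline:
    def test_canonical_distal_sequence(self, distal_noiseless):
        rec, _ = distal_noiseless
        tl = classify_timeline(rec, "seg00", "diameter")
        assert dominant_sequence(tl.states) == [
            "oq", "itr", "dq", "itc", "atc", "oimc", "oimr", "oq",
        ]

    def test_bolus_pressure_ramp_inserts_passive_dilatation(self, proximal_noiseless):
        rec, _ = proximal_noiseless
        tl = classify_timeline(rec, "seg00", "diameter")
        assert dominant_sequence(tl.states) == [
            "oq", "pd", "itr", "dq", "itc", "atc", "oimc", "oimr", "oq",
        ]

    def test_flat_recording_all_occluded_quiescence(self):
        n = 100
        traces = {
            ("s1", "pressure"): make_trace("pressure", values=np.full(n, 5.0), n=n),
            ("s1", "diameter"): make_trace("diameter", values=np.zeros(n), n=n),
        }
        rec = SwallowRecording(
            traces=traces, geometry=make_geometry(site_positions={"s1": 4.0})
        )
        tl = classify_timeline(rec, "s1", "diameter")
        assert set(tl.states) == {"oq"}
        assert not tl.events.detected

    def test_classifier_deterministic(self, distal_noiseless):
        rec, _ = distal_noiseless
        a = classify_timeline(rec, "seg02", "diameter")
        b = classify_timeline(rec, "seg02", "diameter")
        np.testing.assert_array_equal(a.states, b.states)

    def test_diameter_and_admittance_methods_agree(self, distal_noiseless):
        from mechstate.concordance import state_agreement

        rec, _ = distal_noiseless
        d = classify_timeline(rec, "seg01", "diameter")
        a = classify_timeline(rec, "seg01", "admittance")
        assert state_agreement(d, a) >= 95.0


class TestEpochDistribution:
    def test_proportions_sum_to_one(self, distal_noiseless):
        rec, _ = distal_noiseless
        dist = epoch_distribution(classify_timeline(rec, "seg04", "diameter"))
        sums = dist.proportions.sum(axis=1)
        for epoch in EPOCHS:
            if epoch not in dist.empty_epochs:
                assert sums[epoch] == pytest.approx(1.0, abs=1e-9)

    def test_pre_opening_epoch_is_quiescent(self, distal_noiseless):
        rec, _ = distal_noiseless
        dist = epoch_distribution(classify_timeline(rec, "seg00", "diameter"))
        assert dist.proportions.loc["Pre-O", "oq"] == pytest.approx(1.0)

    def test_opening_dominated_by_isotonic_relaxation(self, distal_noiseless):
        rec, _ = distal_noiseless
        dist = epoch_distribution(classify_timeline(rec, "seg00", "diameter"))
        assert dist.proportions.loc["O-M", "itr"] > 0.5
        closing = dist.proportions.loc["M-C", ["itc", "atc"]].sum()
        assert closing > 0.5

    def test_counts_conserve_samples(self, distal_noiseless):
        rec, _ = distal_noiseless
        tl = classify_timeline(rec, "seg03", "diameter")
        dist = epoch_distribution(tl)
        assert dist.counts.to_numpy().sum() == tl.n_samples


class TestDominantSequence:
    def test_flicker_shorter_than_min_run_collapsed(self):
        states = ["oq"] * 10 + ["itc"] * 2 + ["itr"] * 10 + ["oq"] * 10
        assert dominant_sequence(states, min_run=3) == ["oq", "itr", "oq"]

    def test_adjacent_repeats_merged(self):
        states = ["oq"] * 5 + ["itr"] * 1 + ["oq"] * 5
        assert dominant_sequence(states, min_run=3) == ["oq"]

    def test_empty(self):
        assert dominant_sequence([]) == []
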