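import warnings

import numpy as np
import pytest

from mechstate import SwallowScenario, generate_swallow
from mechstate.core import ChannelTrace, SensorGeometry, SwallowRecording


@pytest.fixture(autouse=True)
def _quiet_geometry_warnings():
    # Synthetic geometries use 2 cm site spacing for every channel, which
    # triggers the nominal-spacing advisory; irrelevant to most tests.
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*spacing deviates.*")
        yield


def make_trace(kind="pressure", site="s1", n=50, rate=20.0, values=None, t0=0.0):
    t = t0 + np.arange(n) / rate
    if values is None:
        values = np.zeros(n)
    return ChannelTrace(kind, site, t, np.asarray(values, dtype=float))


def make_geometry(**kw):
    kw.setdefault("pressure_positions", np.arange(0.0, 25.0))
    kw.setdefault("impedance_segment_centers", np.arange(2.0, 18.0, 2.0))
    kw.setdefault("transition_zone_position", 7.0)
    kw.setdefault("egj_position", 24.0)
    return SensorGeometry(**kw)


def make_recording(n=50, rate=20.0, sites=("s1",), channels=("pressure", "impedance")):
    traces = {}
    rng = np.random.default_rng(0)
    for site in sites:
        for kind in channels:
            base = 500.0 if kind == "impedance" else 5.0
            traces[(site, kind)] = make_trace(
                kind, site, n, rate, base + rng.normal(0, 0.1, n)
            )
    geom = make_geometry(
        site_positions={s: 4.0 + 2.0 * i for i, s in enumerate(sites)}
    )
    return SwallowRecording(traces=traces, geometry=geom)


@pytest.fixture(scope="session")
def distal_noiseless():
    """Canonical distal swallow, no noise: Fig-1-style state sequence."""
    scen = SwallowScenario.distal(noise_sd=0.0, seed=1)
    return generate_swallow(scen)


@pytest.fixture(scope="session")
def proximal_noiseless():
    """Bolus-pressure ramp enabled: passive dilatation during opening."""
    scen = SwallowScenario.proximal(noise_sd=0.0, seed=2)
    return generate_swallow(scen)
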