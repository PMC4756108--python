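"""Seedable synthetic swallow generator with analytic ground truth.

The generator emits phenomenological swallow waveforms sufficient to
exercise the whole pipeline without clinical recordings:

* an occluded baseline (diameter exactly 0 mm — the catheter occupies
  the resting lumen, so calibration reads occlusion as 0 by
  construction);
* a propagating luminal opening pulse (trapezoid with a short plateau
  by default, or raised-cosine) delayed per site by position /
  peristaltic velocity;
* an optional bolus-pressure ramp during opening (proximal sites by
  default), which produces passive dilatation as the bolus distends the
  non-relaxing striated-muscle wall;
* a trailing peristaltic contraction pressure wave whose upstroke
  begins during late closure (auxotonic contraction) and peaks just
  after closure (occluded isometric contraction, then relaxation);
* admittance coupled monotonically to diameter, with an optional
  elevated post-closure baseline offset, and impedance as its inverse.

Noise is band-limited Gaussian (default 0.5 s correlation time),
scaled for the lumen channels by the aperture (floor 0.2 of the nominal
SD when occluded): a fluoroscopically occluded lumen reads a stable 0,
and margin-tracking error grows with the open aperture.  ``noise_sd``
is the nominal SD as a fraction of the channel range.

Ground truth (per-site O/M/C times and per-sample state codes) is
computed from the *noiseless, unsmoothed* waveforms pushed through the
same event rules, adaptive thresholds and state grid the classifier
uses — well defined without circularity at noise 0, since the
classifier sees smoothed (and possibly noisy) data instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import RunConfig
from .core import (
    ChannelTrace,
    ConfigError,
    SensorGeometry,
    SwallowRecording,
)
from .events import detect_luminal_events, derive_change_thresholds
from .states import _codes_from_categories, categorize_lumen, categorize_pressure

__all__ = [
    "SwallowScenario",
    "GroundTruth",
    "generate_swallow",
    "generate_cohort",
    "COHORT_STRATA",
]

#: Protocol strata: bolus type x posture, without solid x decubitus
#: (solid boluses are not administered lying down).
COHORT_STRATA = (
    ("liquid", "upright"),
    ("semisolid", "upright"),
    ("solid", "upright"),
    ("liquid", "decubitus"),
    ("semisolid", "decubitus"),
)

#: Per-stratum tweaks: thicker boluses push harder (larger bolus-pressure
#: ramp) and dwell longer (longer opening pulse).
_STRATUM_TWEAKS = {
    "liquid": dict(ramp=0.0, stretch=0.0),
    "semisolid": dict(ramp=8.0, stretch=0.4),
    "solid": dict(ramp=14.0, stretch=0.8),
}


@dataclass
class SwallowScenario:
    """Parameters of one synthetic swallow.

    Geometry defaults match the catheter protocol scale: 20 Hz
    sampling, 3.2 mm catheter, 2 cm impedance segments, 20 s records,
    eight sites spanning the esophageal body (three proximal of the
    transition zone, five distal).  The canonical distal preset
    (:meth:`distal`) restricts to eight distal sites, where luminal
    opening occurs by isotonic relaxation with no bolus-pressure ramp.
    """

    # Geometry / timing.
    n_sites: int = 8
    site_start_cm: float = 2.0
    site_spacing_cm: float = 2.0
    transition_zone_cm: float = 7.0
    egj_cm: float = 24.0
    duration: float = 20.0
    sampling_rate: float = 20.0
    catheter_diameter: float = 3.2

    # Propagation.
    peristaltic_velocity: float = 3.0  # cm/s
    swallow_start: float = 1.5        # s before the first site's arrival offset

    # Opening pulse.  The short plateau gives distended quiescence a
    # resolvable dwell and pins the maximal-extent time against noise.
    opening_shape: str = "trapezoid"  # or "raised_cosine"
    peak_diameter: float = 12.0  # mm
    rise_duration: float = 2.0   # s
    plateau_duration: float = 0.2
    fall_duration: float = 2.0

    # Bolus-pressure ramp during opening (passive dilatation driver).
    bolus_pressure_ramp_proximal: float = 15.0  # mmHg
    bolus_pressure_ramp_distal: float = 0.0
    ramp_rise: float = 1.0   # s
    ramp_lead: float = 0.1   # s before luminal opening
    baseline_pressure: float = 5.0  # mmHg

    # Trailing contraction wave.
    contraction_peak: float = 100.0  # mmHg
    contraction_rise: float = 1.2    # s
    contraction_fall: float = 1.8
    contraction_lead: float = 0.8    # s: upstroke onset before closure
    post_closure_relaxation: float = 3.0  # s, ramp decay constant

    # Admittance coupling Y = y0 + k1 d + k2 d^2 (+ post-closure offset).
    admittance_y0: float = 2.0   # mS
    admittance_k1: float = 1.0   # mS/mm
    admittance_k2: float = 0.05  # mS/mm^2
    admittance_post_offset: float = 0.0  # mS

    # Noise.  2% of channel range emulates modest measurement noise on
    # a clean clinical recording; set 0 for analytic checks.
    noise_sd: float = 0.02           # fraction of channel range
    noise_correlation_time: float = 0.5  # s
    noise_floor: float = 0.2         # occluded-lumen fraction of nominal SD

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        for name in ("rise_duration", "fall_duration", "ramp_rise",
                     "contraction_rise", "contraction_fall", "duration"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.plateau_duration < 0:
            raise ConfigError("plateau_duration must be >= 0")
        if self.peristaltic_velocity <= 0:
            raise ConfigError("peristaltic_velocity must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.opening_shape not in ("raised_cosine", "trapezoid"):
            raise ConfigError(f"unknown opening_shape {self.opening_shape!r}")

    # -- presets -----------------------------------------------------

    @classmethod
    def distal(cls, **kw) -> "SwallowScenario":
        """Eight distal-esophagus sites, no bolus-pressure ramp."""
        kw.setdefault("site_start_cm", 8.0)
        kw.setdefault("bolus_pressure_ramp_proximal", 0.0)
        kw.setdefault("bolus_pressure_ramp_distal", 0.0)
        return cls(**kw)

    @classmethod
    def proximal(cls, **kw) -> "SwallowScenario":
        """Sites with the bolus-pressure ramp enabled everywhere."""
        kw.setdefault("site_start_cm", 8.0)
        kw.setdefault("bolus_pressure_ramp_distal", 15.0)
        return cls(**kw)

    # -- derived quantities ------------------------------------------

    @property
    def site_positions(self) -> np.ndarray:
        return self.site_start_cm + self.site_spacing_cm * np.arange(self.n_sites)

    @property
    def pulse_duration(self) -> float:
        return self.rise_duration + self.plateau_duration + self.fall_duration

    def arrival(self, position_cm: float) -> float:
        """Physical luminal-opening onset at a site (s)."""
        return self.swallow_start + position_cm / self.peristaltic_velocity

    def ramp_amplitude(self, position_cm: float) -> float:
        if position_cm < self.transition_zone_cm:
            return self.bolus_pressure_ramp_proximal
        return self.bolus_pressure_ramp_distal


@dataclass
class GroundTruth:
    """Noiseless-truth events and per-sample states per site.

    ``events`` holds diameter-based O/M/C from the noiseless discrete
    gradient; ``states`` the per-sample codes from the same category
    grid the classifier uses; ``physical`` the (open, close) times at
    which the noiseless diameter leaves / returns to 0.
    """

    times: np.ndarray
    events: dict = field(default_factory=dict)   # site_id -> LuminalEvents
    states: dict = field(default_factory=dict)   # site_id -> codes array
    physical: dict = field(default_factory=dict)  # site_id -> (t_open, t_close)


# -- waveform primitives ---------------------------------------------


def _raised_cosine_pulse(t, t0, rise, plateau, fall, peak):
    d = np.zeros_like(t)
    tau = t - t0
    m = (tau >= 0) & (tau < rise)
    d[m] = peak / 2.0 * (1 - np.cos(np.pi * tau[m] / rise))
    m = (tau >= rise) & (tau < rise + plateau)
    d[m] = peak
    m = (tau >= rise + plateau) & (tau < rise + plateau + fall)
    d[m] = peak / 2.0 * (1 + np.cos(np.pi * (tau[m] - rise - plateau) / fall))
    return d


def _trapezoid_pulse(t, t0, rise, plateau, fall, peak):
    tau = t - t0
    up = np.clip(tau / rise, 0.0, 1.0)
    down = np.clip((rise + plateau + fall - tau) / fall, 0.0, 1.0)
    return peak * np.minimum(up, down) * (tau >= 0) * (tau <= rise + plateau + fall)


def _smooth_step(t, t0, width):
    """Raised-cosine step 0 -> 1 over [t0, t0 + width]."""
    x = np.clip((t - t0) / width, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * x))


def _band_limited_noise(rng, n, dt, correlation_time):
    """Unit-SD Gaussian noise with a Gaussian autocorrelation."""
    white = rng.standard_normal(n + 1)  # +1 keeps streams distinct per channel
    white = white[:n]
    sigma = max(correlation_time / dt, 1e-6)
    half = int(np.ceil(4 * sigma))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    k /= np.sqrt(np.sum(k**2))  # preserves unit variance for white input
    padded = np.pad(white, half, mode="reflect")
    return np.convolve(padded, k, mode="valid")


# -- per-site noiseless components -----------------------------------


def _site_waveforms(scenario: SwallowScenario, t: np.ndarray, position_cm: float):
    s = scenario
    a = s.arrival(position_cm)
    close = a + s.pulse_duration

    pulse = _raised_cosine_pulse if s.opening_shape == "raised_cosine" else _trapezoid_pulse
    diameter = pulse(t, a, s.rise_duration, s.plateau_duration, s.fall_duration, s.peak_diameter)

    pressure = np.full_like(t, s.baseline_pressure)
    amp = s.ramp_amplitude(position_cm)
    if amp > 0:
        ramp = amp * _smooth_step(t, a - s.ramp_lead, s.ramp_rise)
        decay = t >= close
        ramp[decay] *= np.exp(-(t[decay] - close) / s.post_closure_relaxation)
        pressure = pressure + ramp
    onset = close - s.contraction_lead
    contraction = s.contraction_peak * np.where(
        t < onset + s.contraction_rise,
        _smooth_step(t, onset, s.contraction_rise),
        1.0 - _smooth_step(t, onset + s.contraction_rise, s.contraction_fall),
    )
    pressure = pressure + contraction

    admittance = s.admittance_y0 + s.admittance_k1 * diameter + s.admittance_k2 * diameter**2
    if s.admittance_post_offset:
        admittance = admittance + s.admittance_post_offset * _smooth_step(t, close, 1.0)
    return diameter, pressure, admittance, (a, close)


def _truth_for_site(times, diameter, pressure, config: RunConfig, site_id: str):
    """Events and states from noiseless, unsmoothed waveforms."""
    d_tr = ChannelTrace("diameter", site_id, times, diameter)
    p_tr = ChannelTrace("pressure", site_id, times, pressure)
    d_grad = d_tr.with_values(np.gradient(diameter, times))
    p_grad = np.gradient(pressure, times)
    events = detect_luminal_events(
        d_tr, d_grad, config.diameter_open_threshold, config.diameter_close_threshold
    )
    if not events.detected:
        codes = np.full(times.shape, "oq", dtype="<U4")
        return events, codes
    thresholds = derive_change_thresholds(
        d_grad,
        events,
        "diameter_adaptive",
        percentile=config.adaptive_percentile,
        orientation=config.percentile_orientation,
    )
    lum = categorize_lumen(times, d_grad.values, events, thresholds)
    pc = categorize_pressure(p_grad, thresholds)
    return events, _codes_from_categories(np.asarray(lum), np.asarray(pc))


# -- public generators -----------------------------------------------


def generate_swallow(
    scenario: SwallowScenario,
    *,
    subject_id: str = "synthetic",
    swallow_id: str = "sw000",
    bolus_type: str = "liquid",
    posture: str = "upright",
    config: RunConfig | None = None,
):
    """Generate one synthetic swallow recording plus its ground truth.

    Returns ``(SwallowRecording, GroundTruth)``.  The recording carries
    pressure, diameter and impedance traces per site (admittance is an
    explicit preprocessing conversion downstream).  The same seed gives
    identical output.
    """
    s = scenario
    cfg = config or RunConfig()
    rng = np.random.default_rng(s.seed)
    n = int(round(s.duration * s.sampling_rate))
    t = np.arange(n) / s.sampling_rate
    dt = 1.0 / s.sampling_rate

    positions = s.site_positions
    site_ids = [f"seg{i:02d}" for i in range(s.n_sites)]
    geometry = SensorGeometry(
        pressure_positions=np.arange(0.0, s.egj_cm + 1.0, 1.0),
        impedance_segment_centers=positions,
        catheter_diameter=s.catheter_diameter,
        transition_zone_position=s.transition_zone_cm,
        egj_position=s.egj_cm,
        site_positions=dict(zip(site_ids, positions.tolist())),
    )

    y_range = s.admittance_k1 * s.peak_diameter + s.admittance_k2 * s.peak_diameter**2
    truth = GroundTruth(times=t)
    traces = {}
    for site_id, pos in zip(site_ids, positions):
        d0, p0, y0, phys = _site_waveforms(s, t, pos)
        truth.events[site_id], truth.states[site_id] = _truth_for_site(
            t, d0, p0, cfg, site_id
        )
        truth.physical[site_id] = phys

        if s.noise_sd > 0:
            gate = s.noise_floor + (1 - s.noise_floor) * d0 / s.peak_diameter
            d = d0 + s.noise_sd * s.peak_diameter * gate * _band_limited_noise(
                rng, n, dt, s.noise_correlation_time
            )
            d = np.maximum(0.0, d)
            p = p0 + s.noise_sd * s.contraction_peak * _band_limited_noise(
                rng, n, dt, s.noise_correlation_time
            )
            y = y0 + s.noise_sd * y_range * gate * _band_limited_noise(
                rng, n, dt, s.noise_correlation_time
            )
            y = np.maximum(0.1, y)
        else:
            d, p, y = d0, p0, y0

        traces[(site_id, "pressure")] = ChannelTrace("pressure", site_id, t, p)
        traces[(site_id, "diameter")] = ChannelTrace("diameter", site_id, t, d)
        traces[(site_id, "impedance")] = ChannelTrace("impedance", site_id, t, 1000.0 / y)

    rec = SwallowRecording(
        traces=traces,
        geometry=geometry,
        bolus_type=bolus_type,
        posture=posture,
        bolus_volume=5.0,
        subject_id=subject_id,
        swallow_id=swallow_id,
    )
    return rec, truth


def stratum_scenario(base: SwallowScenario, bolus_type: str, seed: int) -> SwallowScenario:
    """Apply the bolus-consistency preset to a base scenario."""
    tweak = _STRATUM_TWEAKS[bolus_type]
    return replace(
        base,
        bolus_pressure_ramp_proximal=base.bolus_pressure_ramp_proximal + tweak["ramp"],
        bolus_pressure_ramp_distal=(
            base.bolus_pressure_ramp_distal + tweak["ramp"]
            if base.bolus_pressure_ramp_distal > 0
            else base.bolus_pressure_ramp_distal
        ),
        rise_duration=base.rise_duration + tweak["stretch"] / 2,
        fall_duration=base.fall_duration + tweak["stretch"] / 2,
        seed=seed,
    )


def generate_cohort(
    n_swallows: int,
    base_scenario: SwallowScenario | None = None,
    seed: int = 0,
    strata=COHORT_STRATA,
    config: RunConfig | None = None,
):
    """Generate a cohort of independent seeded swallows across strata.

    Strata are cycled in protocol order; the solid x decubitus stratum
    is never generated.  Returns a list of ``(SwallowRecording,
    GroundTruth)``.
    """
    if n_swallows < 1:
        raise ConfigError("n_swallows must be >= 1")
    base = base_scenario or SwallowScenario()
    strata = [s for s in strata if s != ("solid", "decubitus")]
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_swallows)
    out = []
    for i in range(n_swallows):
        bolus, posture = strata[i % len(strata)]
        scen = stratum_scenario(base, bolus, int(child_seeds[i]))
        rec, truth = generate_swallow(
            scen,
            subject_id=f"subj{i % 9:02d}",
            swallow_id=f"sw{i:03d}",
            bolus_type=bolus,
            posture=posture,
            config=config,
        )
        out.append((rec, truth))
    return out
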