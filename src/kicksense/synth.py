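"""Synthetic IMU session generator.

Real shot/pass datasets for instrumented football boots are proprietary, so
the package ships a generator that reproduces the *statistical structure* the
detection pipeline relies on, without claiming biomechanical fidelity:

* a gait/standing/running background with a harmonic stride pattern,
* ball-contact events built from three cues: a damped accelerometer impact
  (shots saturate the ±16 g range), a high-frequency gyroscope transient at
  contact (what survives the 20 Hz high-pass used for candidate selection),
  and a sagittal half-sine leg swing on ``gx`` ending at contact, preceded by
  a small counter-swing so the last zero crossing before contact marks the
  kick-phase onset,
* session-level class imbalance (null ≫ pass ≫ shot),
* the three-clap synchronization burst at both ends of a recording.

Amplitude ranges per contact type are free parameters of the generator, not
estimates of real data. Two named regimes are provided: the *separable*
default (class amplitude ranges disjoint) and a *confusable* regime in which
kick-phase signal sums overlap across classes while instantaneous impact
morphology still differs — the regime in which feature-sum classifiers
degrade but sequence models keep discriminating.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ACCEL_FULL_SCALE,
    BallContactEvent,
    SensorStream,
    Session,
    FINE_TYPES,
    map_contact_to_class,
)

__all__ = [
    "EventTemplate",
    "SynthConfig",
    "SyncTruth",
    "generate_session",
    "inject_sync_pattern",
    "make_benchmark_split",
    "counts_for_class_ratio",
    "separable_config",
    "confusable_config",
]


@dataclass(frozen=True)
class EventTemplate:
    """Morphology parameters for one ball-contact type.

    Amplitude fields are (low, high) sampling ranges; accel in g, gyro in
    °/s, durations in seconds. ``swing_duration`` is the length of the
    pre-contact sagittal half-sine; the template guarantees a sign change of
    ``gx`` at its onset (the kick-phase start).
    """

    fine_type: str
    accel_amp: tuple[float, float]
    gyro_transient_amp: tuple[float, float]
    swing_amp: tuple[float, float]
    swing_duration: tuple[float, float]
    impact_tau: tuple[float, float] = (0.025, 0.035)  # impact decay range (s)
    transient_freq: float = 45.0  # Hz, survives the 20 Hz high-pass

    def saturates(self) -> bool:
        return self.accel_amp[0] >= ACCEL_FULL_SCALE


# Separable defaults: per-class ranges are disjoint on every cue. Transient
# frequency grows with impact hardness (stiffer contact -> higher-frequency
# ringing), a cue that survives integration only weakly.
_SEPARABLE_TEMPLATES: dict[str, EventTemplate] = {
    "shot": EventTemplate(
        "shot", (18.0, 26.0), (700.0, 1200.0), (900.0, 1400.0), (0.26, 0.34),
        impact_tau=(0.025, 0.035), transient_freq=55.0,
    ),
    "long pass": EventTemplate(
        "long pass", (8.0, 12.0), (350.0, 600.0), (500.0, 800.0), (0.24, 0.32),
        impact_tau=(0.030, 0.050), transient_freq=42.0,
    ),
    "short pass medial": EventTemplate(
        "short pass medial", (7.0, 11.0), (300.0, 550.0), (450.0, 750.0), (0.22, 0.30),
        impact_tau=(0.030, 0.050), transient_freq=40.0,
    ),
    "short pass other": EventTemplate(
        "short pass other", (6.0, 10.0), (280.0, 500.0), (400.0, 700.0), (0.22, 0.30),
        impact_tau=(0.035, 0.055), transient_freq=40.0,
    ),
    "strong contact": EventTemplate(
        "strong contact", (3.5, 6.0), (140.0, 240.0), (200.0, 350.0), (0.12, 0.18),
        impact_tau=(0.040, 0.060), transient_freq=32.0,
    ),
    "light contact": EventTemplate(
        "light contact", (1.5, 3.0), (70.0, 130.0), (80.0, 160.0), (0.08, 0.12),
        impact_tau=(0.030, 0.050), transient_freq=28.0,
    ),
    # agile movement burst without ball contact (change of direction): no
    # impact transient, only low/mid-frequency body rotation
    "none": EventTemplate("none", (0.0, 0.0), (0.0, 0.0), (250.0, 500.0), (0.4, 0.8)),
    # contact that happened off-camera: pass-like morphology, wide range
    "unknown": EventTemplate(
        "unknown", (5.0, 12.0), (250.0, 600.0), (350.0, 800.0), (0.20, 0.32),
        impact_tau=(0.030, 0.055), transient_freq=40.0,
    ),
}

# Confusable regime: everything the absolute-sum features integrate —
# kick-phase swing amplitude x duration and impact amplitude x decay —
# overlaps heavily across shot / pass / strong-contact (low-intensity shots
# vs hard long passes). Instantaneous morphology (peak height, saturation
# plateau, ringing frequency) still differs, so shape-aware models keep a
# handle the sum-features lose.
_CONFUSABLE_OVERRIDES: dict[str, dict] = {
    "shot": {"accel_amp": (10.0, 26.0), "impact_tau": (0.015, 0.045),
             "swing_amp": (450.0, 1100.0), "swing_duration": (0.18, 0.34),
             "gyro_transient_amp": (350.0, 900.0)},
    "long pass": {"accel_amp": (8.0, 16.0), "impact_tau": (0.030, 0.070),
                  "swing_amp": (450.0, 1100.0), "swing_duration": (0.18, 0.34),
                  "gyro_transient_amp": (300.0, 800.0)},
    "short pass medial": {"accel_amp": (6.0, 14.0), "impact_tau": (0.030, 0.070),
                          "swing_amp": (300.0, 900.0), "swing_duration": (0.16, 0.32),
                          "gyro_transient_amp": (250.0, 700.0)},
    "short pass other": {"accel_amp": (5.0, 13.0), "impact_tau": (0.035, 0.075),
                         "swing_amp": (300.0, 900.0), "swing_duration": (0.16, 0.32),
                         "gyro_transient_amp": (220.0, 650.0)},
    "strong contact": {"accel_amp": (3.0, 9.0), "impact_tau": (0.040, 0.090),
                       "swing_amp": (200.0, 750.0), "swing_duration": (0.14, 0.28),
                       "gyro_transient_amp": (140.0, 450.0)},
}

_DEFAULT_COUNTS = {
    "shot": 3,
    "short pass medial": 4,
    "short pass other": 3,
    "long pass": 3,
    "strong contact": 4,
    "light contact": 8,
    "none": 5,
    "unknown": 0,
}


@dataclass
class SynthConfig:
    """Configuration of one synthetic session.

    ``background_mix`` gives (standing, walking, running) fractions;
    ``amplitude_spread`` widens every template range around its centre
    (field sessions use > 1); ``confusable`` switches to the overlapping
    kick-phase regime described in the module docstring.
    """

    seed: int = 0
    duration_s: float = 120.0
    counts: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_COUNTS))
    background_mix: tuple[float, float, float] = (0.3, 0.4, 0.3)
    cadence_hz: float = 2.2
    noise_level: float = 1.0
    min_spacing_s: float = 2.0
    amplitude_spread: float = 1.0
    confusable: bool = False
    feet: tuple[str, ...] = ("right",)
    setting: str = "lab"
    session_id: str = "synth-000"
    rate: float = 200.0
    include_sync: bool = False

    def __post_init__(self) -> None:
        if self.min_spacing_s < 0.3:
            raise ValueError(
                "min_spacing_s below 0.3 s — closer than the closest observed "
                "spacing between dribble contacts"
            )
        for fine, n in self.counts.items():
            if fine not in FINE_TYPES:
                raise ValueError(f"unknown fine_type {fine!r} in counts")
            if n < 0:
                raise ValueError("event counts must be >= 0")
        if abs(sum(self.background_mix) - 1.0) > 1e-9:
            raise ValueError("background_mix fractions must sum to 1")


def templates_for(config: SynthConfig) -> dict[str, EventTemplate]:
    """Resolve the event templates for a config (regime + spread applied)."""
    out = {}
    for fine, tpl in _SEPARABLE_TEMPLATES.items():
        fields = dataclasses.asdict(tpl)
        if config.confusable and fine in _CONFUSABLE_OVERRIDES:
            fields.update(_CONFUSABLE_OVERRIDES[fine])
        for key in ("accel_amp", "gyro_transient_amp", "swing_amp"):
            lo, hi = fields[key]
            mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
            half *= config.amplitude_spread
            fields[key] = (max(0.0, mid - half), mid + half)
        out[fine] = EventTemplate(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in fields.items()})
    return out


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def _background(n: int, rate: float, config: SynthConfig, rng: np.random.Generator):
    """Piecewise standing/walking/running background, ~4 s segments."""
    accel = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    accel[:, 2] = 1.0  # gravity along the vertical sensor axis
    t = np.arange(n) / rate
    seg_len = int(4.0 * rate)
    states = ("standing", "walking", "running")
    i = 0
    while i < n:
        j = min(n, i + seg_len)
        state = rng.choice(states, p=config.background_mix)
        ts = t[i:j]
        if state != "standing":
            cadence = config.cadence_hz * rng.uniform(0.9, 1.1)
            if state == "running":
                cadence *= 1.4
                a_amp, g_amp = rng.uniform(1.5, 2.5), rng.uniform(180.0, 280.0)
            else:
                a_amp, g_amp = rng.uniform(0.4, 0.8), rng.uniform(60.0, 110.0)
            phase = rng.uniform(0, 2 * np.pi)
            stride = np.sin(2 * np.pi * cadence * ts + phase)
            stride2 = 0.4 * np.sin(2 * np.pi * 2 * cadence * ts + 2 * phase)
            accel[i:j, 2] += a_amp * (stride + stride2)
            accel[i:j, 0] += 0.5 * a_amp * np.sin(2 * np.pi * cadence * ts + phase + 1.0)
            gyro[i:j, 0] += g_amp * stride
            gyro[i:j, 1] += 0.5 * g_amp * np.sin(2 * np.pi * cadence * ts + phase + 0.7)
            gyro[i:j, 2] += 0.3 * g_amp * stride2
        i = j
    accel += rng.normal(0.0, 0.05 * config.noise_level, (n, 3))
    gyro += rng.normal(0.0, 3.0 * config.noise_level, (n, 3))
    return accel, gyro


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def _add_event(accel, gyro, rate, idx, tpl: EventTemplate, rng) -> dict:
    """Embed one contact at sample ``idx``; returns ground-truth detail."""
    n = accel.shape[0]
    t = np.arange(n) / rate
    tc = idx / rate
    amp_a = rng.uniform(*tpl.accel_amp)
    amp_g = rng.uniform(*tpl.gyro_transient_amp)
    amp_sw = rng.uniform(*tpl.swing_amp)
    t_sw = rng.uniform(*tpl.swing_duration)

    # sagittal swing: small counter-swing then half-sine ending at contact;
    # guarantees a gx sign change at the kick-phase onset tc - t_sw
    t0 = tc - t_sw
    pre0 = max(0.0, t0 - 0.4 * t_sw)
    m = (t >= t0) & (t < tc)
    gyro[m, 0] += amp_sw * np.sin(np.pi * (t[m] - t0) / t_sw)
    m_pre = (t >= pre0) & (t < t0)
    if t0 > pre0:
        gyro[m_pre, 0] -= 0.25 * amp_sw * np.sin(np.pi * (t[m_pre] - pre0) / (t0 - pre0))

    tau = rng.uniform(*tpl.impact_tau)
    if amp_a > 0:
        # impact: damped oscillation with random axis distribution
        m_ev = (t >= tc) & (t < tc + 6 * tau)
        tr = t[m_ev] - tc
        shape = np.exp(-tr / tau) * np.cos(2 * np.pi * 0.6 * tpl.transient_freq * tr)
        w = np.abs(rng.normal(size=3))
        w = w / np.max(w)
        sgn = rng.choice([-1.0, 1.0], size=3)
        for k in range(3):
            accel[m_ev, k] += sgn[k] * w[k] * amp_a * shape
        # contact transient on the gyroscope (all axes, gx strongest); fixed
        # frequency band — class identity lives in amplitude here, while the
        # class-dependent ringing frequency is an accelerometer cue
        tshape = np.exp(-tr / 0.04) * np.sin(2 * np.pi * 45.0 * tr)
        wg = np.array([1.0, *np.abs(rng.normal(0.5, 0.2, size=2))])
        for k in range(3):
            gyro[m_ev, k] += wg[k] * amp_g * tshape
    return {
        "contact_index": int(idx),
        "phase_start_time": float(t0),
        "accel_amp": float(amp_a),
        "impact_tau": float(tau),
        "gyro_transient_amp": float(amp_g),
        "swing_amp": float(amp_sw),
        "swing_duration": float(t_sw),
    }


def _place_event_times(config: SynthConfig, n_events: int, rng) -> np.ndarray:
    """Event times with guaranteed >= min_spacing_s separation."""
    margin = 1.5  # keep full 2 s analysis windows inside the stream
    jitter = 0.5 * config.min_spacing_s
    pitch = config.min_spacing_s + jitter
    usable = config.duration_s - 2 * margin
    n_slots = int(usable / pitch)
    if n_events > n_slots:
        raise ValueError(
            f"{n_events} events do not fit in {config.duration_s:.0f} s at "
            f"min spacing {config.min_spacing_s:.2f} s ({n_slots} slots)"
        )
    slots = rng.choice(n_slots, size=n_events, replace=False)
    times = margin + slots * pitch + rng.uniform(0.0, jitter, size=n_events)
    return np.sort(times)


def generate_session(config: SynthConfig) -> Session:
    """Generate one labelled session; deterministic given ``config.seed``.

    The returned session carries a ``ground_truth`` attribute: a dict with
    per-event morphology details and (if ``include_sync``) the injected clap
    times.
    """
    rng = np.random.default_rng(config.seed)
    tpls = templates_for(config)
    rate = config.rate
    n = int(round(config.duration_s * rate))
    t = np.arange(n) / rate

    fine_list: list[str] = []
    for fine, cnt in config.counts.items():
        fine_list.extend([fine] * cnt)
    rng.shuffle(fine_list)

    streams: dict[str, SensorStream] = {}
    events: list[BallContactEvent] = []
    truth: dict = {"events": [], "sync": {}}
    per_foot = {
        foot: [fine for k, fine in enumerate(fine_list)
               if k % len(config.feet) == config.feet.index(foot)]
        for foot in config.feet
    }
    for foot in config.feet:
        accel, gyro = _background(n, rate, config, rng)
        fines = per_foot[foot]
        times = _place_event_times(config, len(fines), rng)
        for fine, te in zip(fines, times):
            idx = int(round(te * rate))
            detail = _add_event(accel, gyro, rate, idx, tpls[fine], rng)
            detail.update(fine_type=fine, foot=foot, time=idx / rate)
            truth["events"].append(detail)
            events.append(
                BallContactEvent(time=idx / rate, fine_type=fine, foot=foot)
            )
        np.clip(accel, -ACCEL_FULL_SCALE, ACCEL_FULL_SCALE, out=accel)
        np.clip(gyro, -2000.0, 2000.0, out=gyro)
        stream = SensorStream(t.copy(), accel, gyro, nominal_rate=rate)
        if config.include_sync:
            stream, sync_truth = inject_sync_pattern(stream, rng=rng)
            truth["sync"][foot] = sync_truth
        streams[foot] = stream

    session = Session(
        session_id=config.session_id,
        setting=config.setting,
        streams=streams,
        events=events,
        nominal_rate=rate,
    )
    session.ground_truth = truth  # type: ignore[attr-defined]
    return session


# ---------------------------------------------------------------------------
# synchronization pattern
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyncTruth:
    """Ground-truth clap peak times (s) for the leading/trailing bursts."""

    start_peaks: tuple[float, ...]
    end_peaks: tuple[float, ...]


def inject_sync_pattern(
    stream: SensorStream,
    at_start: bool = True,
    at_end: bool = True,
    clap_amp: float = 12.0,
    clap_spacing: float = 0.4,
    n_claps: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[SensorStream, SyncTruth]:
    """Insert three-clap bursts (rod clapped to the ground) on all accel axes.

    Each clap is a short damped impulse of ``clap_amp`` g on every
    accelerometer axis. Returns the modified stream and the true peak times.
    """
    if n_claps < 1:
        raise ValueError("n_claps must be >= 1")
    if not (at_start or at_end):
        raise ValueError("at least one of at_start/at_end must be set")
    rng = rng or np.random.default_rng(0)
    rate = stream.nominal_rate
    burst_len = (n_claps - 1) * clap_spacing + 0.3
    need = (at_start + at_end) * (burst_len + 0.5)
    if stream.duration < need + 1.0:
        raise ValueError(
            f"stream of {stream.duration:.1f} s too short for sync bursts "
            f"({need + 1.0:.1f} s required)"
        )
    accel = stream.accel.copy()
    t = stream.sample_times - stream.sample_times[0]
    n = len(t)

    def _burst(first_time: float) -> tuple[float, ...]:
        peaks = []
        for k in range(n_claps):
            tc = first_time + k * clap_spacing
            idx = int(round(tc * rate))
            length = min(int(0.06 * rate), n - idx)
            tr = np.arange(length) / rate
            shape = np.exp(-tr / 0.012) * np.cos(2 * np.pi * 35.0 * tr)
            amp = clap_amp * rng.uniform(0.95, 1.05)
            for ax in range(3):
                accel[idx:idx + length, ax] += amp * shape
            peaks.append(idx / rate + stream.sample_times[0])
        return tuple(peaks)

    start_peaks: tuple[float, ...] = ()
    end_peaks: tuple[float, ...] = ()
    if at_start:
        start_peaks = _burst(0.25)
    if at_end:
        end_peaks = _burst(t[-1] - burst_len - 0.25)
    np.clip(accel, -ACCEL_FULL_SCALE, ACCEL_FULL_SCALE, out=accel)
    out = dataclasses.replace(stream, accel=accel)
    return out, SyncTruth(start_peaks=start_peaks, end_peaks=end_peaks)


# ---------------------------------------------------------------------------
# benchmark construction
# ---------------------------------------------------------------------------

def counts_for_class_ratio(
    ratio: dict[str, int], total: int
) -> dict[str, int]:
    """Per-fine-type counts whose class sums follow ``ratio`` (shot:pass:null).

    Pass events are spread over the three pass types, null over
    light/strong/none, using largest-remainder rounding so the class totals
    are exact to +-1 event.
    """
    denom = sum(ratio.values())
    class_totals = {c: ratio[c] * total / denom for c in ratio}
    split = {
        "shot": {"shot": 1.0},
        "pass": {"short pass medial": 0.4, "short pass other": 0.35, "long pass": 0.25},
        "null": {"light contact": 0.45, "strong contact": 0.3, "none": 0.25},
    }
    counts: dict[str, int] = {}
    for cls, fines in split.items():
        target = class_totals[cls]
        raw = {f: target * w for f, w in fines.items()}
        floored = {f: int(v) for f, v in raw.items()}
        rem = int(round(target)) - sum(floored.values())
        order = sorted(raw, key=lambda f: raw[f] - floored[f], reverse=True)
        for f in order[:rem]:
            floored[f] += 1
        counts.update(floored)
    return counts


def _field_variant(config: SynthConfig) -> SynthConfig:
    """Field sessions: wider technique variation, more agile movement."""
    counts = dict(config.counts)
    counts["none"] = counts.get("none", 0) + 4
    return dataclasses.replace(
        config,
        counts=counts,
        amplitude_spread=config.amplitude_spread * 1.8,
        background_mix=(0.15, 0.35, 0.5),
        setting="field",
    )


def make_benchmark_split(
    config: SynthConfig,
    n_train: int = 6,
    n_lab_test: int = 3,
    n_field_test: int = 3,
) -> dict[str, list[Session]]:
    """Disjoint train / lab-test / field-test session sets.

    Lab sessions follow ``config``; field sessions use a wider
    amplitude-spread variant with a more agile background. Session seeds are
    derived from ``config.seed`` so the split is reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(
        n_train + n_lab_test + n_field_test)]
    out: dict[str, list[Session]] = {"train": [], "lab_test": [], "field_test": []}
    k = 0
    for split, count, fieldlike in (
        ("train", n_train, False),
        ("lab_test", n_lab_test, False),
        ("field_test", n_field_test, True),
    ):
        for i in range(count):
            cfg = _field_variant(config) if fieldlike else config
            cfg = dataclasses.replace(
                cfg, seed=seeds[k], session_id=f"{split}-{i:03d}"
            )
            out[split].append(generate_session(cfg))
            k += 1
    return out


def separable_config(**kwargs) -> SynthConfig:
    """Default regime: disjoint class amplitude ranges."""
    return SynthConfig(confusable=False, **kwargs)


def confusable_config(**kwargs) -> SynthConfig:
    """Overlapping kick-phase regime (hard for absolute-sum features)."""
    return SynthConfig(confusable=True, **kwargs)
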