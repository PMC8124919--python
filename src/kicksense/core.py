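"""Core domain types for in-shoe IMU ball-contact detection.

A recording session consists of one 6-channel inertial stream per instrumented
foot (tri-axial accelerometer, full scale ±16 g; tri-axial gyroscope, full
scale ±2000 °/s; nominally 200 Hz) plus a list of expert-labelled ball-contact
events. Channel order is fixed throughout the package as

    (ax, ay, az, gx, gy, gz)

where ``gx`` carries the sagittal-plane angular velocity of the foot — the
axis on which the forward leg swing of a kick is visible. All times are in
seconds, windows are half-open ``[start, end)`` and sample indices are
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ACCEL_FULL_SCALE",
    "GYRO_FULL_SCALE",
    "SATURATION_G",
    "CHANNEL_NAMES",
    "FINE_TYPES",
    "CLASS_LABELS",
    "SensorStream",
    "BallContactEvent",
    "Session",
    "ParseError",
    "map_contact_to_class",
    "scale_stream",
    "unscale_stream",
    "read_session",
    "write_session",
]

ACCEL_FULL_SCALE = 16.0  # g
GYRO_FULL_SCALE = 2000.0  # °/s
#: accelerometer samples at or above this magnitude are treated as saturated
#: (synthesis and QC only; the classifier never thresholds on it)
SATURATION_G = 15.9

CHANNEL_NAMES = ("ax", "ay", "az", "gx", "gy", "gz")

#: fine-grained ball-contact taxonomy and its three-class (+excluded) image
FINE_TYPES = (
    "none",
    "light contact",
    "strong contact",
    "short pass medial",
    "short pass other",
    "long pass",
    "shot",
    "unknown",
)

_CLASS_OF_FINE = {
    "none": "null",
    "light contact": "null",
    "strong contact": "null",
    "short pass medial": "pass",
    "short pass other": "pass",
    "long pass": "pass",
    "shot": "shot",
    "unknown": "excluded",
}

CLASS_LABELS = ("shot", "pass", "null", "excluded")


class ParseError(ValueError):
    """Raised when a session on disk violates the documented layout."""


def map_contact_to_class(fine_type: str) -> str:
    """Map a fine-grained ball-contact type to its class label.

    ``none``, ``light contact`` and ``strong contact`` are null; the three
    pass variants are pass; ``shot`` is shot; ``unknown`` (player not visible
    on the labelling video) is excluded from training and evaluation.
    """
    try:
        return _CLASS_OF_FINE[fine_type]
    except KeyError:
        raise ValueError(
            f"unrecognized ball-contact type {fine_type!r}; "
            f"expected one of {FINE_TYPES}"
        ) from None


@dataclass
class SensorStream:
    """Uniformly sampled 6-channel IMU time series for one foot.

    ``accel`` is (n, 3) in g, ``gyro`` is (n, 3) in °/s — or both in
    dimensionless full-scale units in [-1, 1] when ``scaled`` is True.
    """

    sample_times: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    nominal_rate: float = 200.0
    scaled: bool = False

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.sample_times.shape[0]
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError(
                f"shape mismatch: times {n}, accel {self.accel.shape}, "
                f"gyro {self.gyro.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.sample_times.shape[0]

    @property
    def duration(self) -> float:
        if self.n_samples == 0:
            return 0.0
        return float(self.sample_times[-1] - self.sample_times[0])

    @property
    def data(self) -> np.ndarray:
        """(n, 6) array in the fixed (ax, ay, az, gx, gy, gz) order."""
        return np.concatenate([self.accel, self.gyro], axis=1)


@dataclass(frozen=True)
class BallContactEvent:
    """A labelled ball contact: time (s), fine type, foot, derived class."""

    time: float
    fine_type: str
    foot: str = "right"
    class_label: str = field(default="", compare=True)

    def __post_init__(self) -> None:
        derived = map_contact_to_class(self.fine_type)
        if self.class_label and self.class_label != derived:
            raise ValueError(
                f"class_label {self.class_label!r} inconsistent with "
                f"fine_type {self.fine_type!r} (expected {derived!r})"
            )
        object.__setattr__(self, "class_label", derived)


@dataclass
class Session:
    """One recording: per-foot streams, sorted labelled events, provenance."""

    session_id: str
    setting: str  # "lab" | "field"
    streams: dict[str, SensorStream]
    events: list[BallContactEvent]
    nominal_rate: float = 200.0

    def __post_init__(self) -> None:
        if self.setting not in ("lab", "field"):
            raise ValueError(f"setting must be 'lab' or 'field', got {self.setting!r}")
        self.events = sorted(self.events, key=lambda e: e.time)
        for ev in self.events:
            if ev.foot not in self.streams:
                raise ValueError(f"event foot {ev.foot!r} has no stream")
            st = self.streams[ev.foot]
            if st.n_samples and not (
                st.sample_times[0] <= ev.time <= st.sample_times[-1]
            ):
                raise ValueError(
                    f"event at t={ev.time:.3f}s outside stream range "
                    f"[{st.sample_times[0]:.3f}, {st.sample_times[-1]:.3f}]"
                )

    @property
    def duration_minutes(self) -> float:
        if not self.streams:
            return 0.0
        return max(s.duration for s in self.streams.values()) / 60.0

    def events_for_foot(self, foot: str) -> list[BallContactEvent]:
        return [e for e in self.events if e.foot == foot]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASS_LABELS}
        for ev in self.events:
            counts[ev.class_label] += 1
        return counts


# relative overshoot beyond full scale tolerated (and clipped) before scaling
_CLIP_RTOL = 1e-6


def scale_stream(stream: SensorStream) -> SensorStream:
    """Scale a physical-unit stream to [-1, 1] by the sensor full-scale values.

    Dividing by the fixed full scale (16 g, 2000 °/s) — rather than a
    per-session min-max — keeps scaling session-independent and preserves the
    meaning of accelerometer saturation: a saturated shot impact maps to ±1
    in every session.
    """
    if stream.scaled:
        raise ValueError("stream is already scaled")
    for name, arr, fs in (
        ("accel", stream.accel, ACCEL_FULL_SCALE),
        ("gyro", stream.gyro, GYRO_FULL_SCALE),
    ):
        limit = fs * (1.0 + _CLIP_RTOL)
        if np.any(np.abs(arr) > limit):
            worst = float(np.max(np.abs(arr)))
            raise ValueError(
                f"{name} sample magnitude {worst:g} exceeds full scale {fs:g}"
            )
    accel = np.clip(stream.accel / ACCEL_FULL_SCALE, -1.0, 1.0)
    gyro = np.clip(stream.gyro / GYRO_FULL_SCALE, -1.0, 1.0)
    return replace(stream, accel=accel, gyro=gyro, scaled=True)


def unscale_stream(stream: SensorStream) -> SensorStream:
    """Inverse of :func:`scale_stream` (exact up to the clipping tolerance)."""
    if not stream.scaled:
        raise ValueError("stream is not scaled")
    return replace(
        stream,
        accel=stream.accel * ACCEL_FULL_SCALE,
        gyro=stream.gyro * GYRO_FULL_SCALE,
        scaled=False,
    )


# ---------------------------------------------------------------------------
# session storage: one directory per session
#
#   meta.yaml              session_id, setting, nominal_rate, scaled
#   <foot>.csv             t,ax,ay,az,gx,gy,gz
#   labels.csv             time_s,foot,contact_type
# ---------------------------------------------------------------------------

_SENSOR_HEADER = ["t", *CHANNEL_NAMES]
_LABEL_HEADER = ["time_s", "foot", "contact_type"]


def write_session(session: Session, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "session_id": session.session_id,
        "setting": session.setting,
        "nominal_rate": float(session.nominal_rate),
        "scaled": bool(next(iter(session.streams.values())).scaled)
        if session.streams
        else False,
        "feet": sorted(session.streams),
    }
    (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    for foot, stream in session.streams.items():
        df = pd.DataFrame(
            np.column_stack([stream.sample_times, stream.data]),
            columns=_SENSOR_HEADER,
        )
        df.to_csv(path / f"{foot}.csv", index=False, float_format="%.6f")
    labels = pd.DataFrame(
        [(f"{e.time:.6f}", e.foot, e.fine_type) for e in session.events],
        columns=_LABEL_HEADER,
    )
    labels.to_csv(path / "labels.csv", index=False)
    return path


def _read_stream_csv(csv_path: Path, nominal_rate: float, scaled: bool) -> SensorStream:
    df = pd.read_csv(csv_path)
    missing = [c for c in _SENSOR_HEADER if c not in df.columns]
    if missing:
        raise ParseError(f"{csv_path.name}: missing channel column(s) {missing}")
    t = df["t"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ParseError(f"{csv_path.name}: non-monotone time axis")
    return SensorStream(
        sample_times=t,
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        nominal_rate=nominal_rate,
        scaled=scaled,
    )


def read_session(path: str | Path) -> Session:
    path = Path(path)
    meta_path = path / "meta.yaml"
    if not meta_path.exists():
        raise ParseError(f"{path}: missing meta.yaml")
    meta = yaml.safe_load(meta_path.read_text())
    rate = float(meta.get("nominal_rate", 200.0))
    scaled = bool(meta.get("scaled", False))
    streams: dict[str, SensorStream] = {}
    for foot in meta.get("feet", ("left", "right")):
        csv_path = path / f"{foot}.csv"
        if csv_path.exists():
            streams[foot] = _read_stream_csv(csv_path, rate, scaled)
    if not streams:
        raise ParseError(f"{path}: no per-foot sensor CSV found")

    labels_path = path / "labels.csv"
    events: list[BallContactEvent] = []
    if labels_path.exists():
        df = pd.read_csv(labels_path)
        missing = [c for c in _LABEL_HEADER if c not in df.columns]
        if missing:
            raise ParseError(f"labels.csv: missing column(s) {missing}")
        for i, row in df.iterrows():
            fine = str(row["contact_type"])
            if fine not in FINE_TYPES:
                raise ParseError(
                    f"labels.csv row {i}: unknown contact_type {fine!r}"
                )
            events.append(
                BallContactEvent(
                    time=float(row["time_s"]), fine_type=fine, foot=str(row["foot"])
                )
            )
    try:
        return Session(
            session_id=str(meta["session_id"]),
            setting=str(meta["setting"]),
            streams=streams,
            events=events,
            nominal_rate=rate,
        )
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
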