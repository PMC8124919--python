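"""Clap-based synchronization and resampling to a uniform 200 Hz axis.

Recordings are synchronized to video by clapping a rod holding all sensors to
the ground three times at the start and end of a session: three high peaks on
every accelerometer axis. A deterministic rule detects these bursts (a burst
qualifies only when three super-threshold peaks occur within a bounded span
on *all* accelerometer axes simultaneously), the true sampling rate is
estimated from the sample count between the bursts and the video-derived
duration, and the streams are interpolated onto a uniform target grid.

The clap amplitude threshold (8 g) and burst span (2 s) are module defaults
chosen for the synthetic claps, not measured constants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .core import ACCEL_FULL_SCALE, SensorStream

__all__ = [
    "SyncResult",
    "SyncError",
    "detect_sync_claps",
    "estimate_sampling_rate",
    "resample_to_uniform",
]

CLAP_THRESHOLD_G = 8.0
BURST_SPAN_S = 2.0
RATE_BAND = 0.05  # accepted relative deviation of estimated rate from target


class SyncError(RuntimeError):
    """Raised when fewer than two qualifying clap bursts are found."""


@dataclass(frozen=True)
class SyncResult:
    """First-peak sample indices of the two bursts and the estimated rate."""

    start_index: int
    end_index: int
    estimated_rate: float | None = None

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("end burst must follow start burst")


def _local_peaks(x: np.ndarray, height: float, min_dist: int) -> np.ndarray:
    """Strict local maxima above ``height``, greedily thinned by distance."""
    cand = np.flatnonzero(
        (x[1:-1] > height) & (x[1:-1] >= x[:-2]) & (x[1:-1] > x[2:])
    ) + 1
    if cand.size == 0:
        return cand
    order = cand[np.argsort(-x[cand], kind="stable")]
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_dist for j in kept):
            kept.append(int(i))
    return np.array(sorted(kept), dtype=int)


def detect_sync_claps(
    stream: SensorStream,
    threshold_g: float = CLAP_THRESHOLD_G,
    burst_span_s: float = BURST_SPAN_S,
    n_claps: int = 3,
) -> SyncResult:
    """Locate the leading and trailing three-clap bursts.

    A clap drives every accelerometer axis simultaneously, so the pointwise
    minimum across axis magnitudes exceeds the threshold only during claps.
    Peaks of that minimum are clustered; a cluster of >= ``n_claps`` peaks
    spanning at most ``burst_span_s`` qualifies as a burst. Returns the
    first-peak index of the first and last qualifying bursts.
    """
    thr = threshold_g / ACCEL_FULL_SCALE if stream.scaled else threshold_g
    rate = stream.nominal_rate
    allaxis = np.min(np.abs(stream.accel), axis=1)
    min_dist = max(1, int(0.15 * rate))
    peaks = _local_peaks(allaxis, thr, min_dist)

    bursts: list[int] = []
    span = burst_span_s * rate
    i = 0
    while i < peaks.size:
        j = i
        while j + 1 < peaks.size and peaks[j + 1] - peaks[i] <= span:
            j += 1
        if j - i + 1 >= n_claps:
            bursts.append(int(peaks[i]))
        i = j + 1
    if len(bursts) < 2:
        raise SyncError(
            f"sync failed: found {len(bursts)} qualifying burst(s), need 2"
        )
    return SyncResult(start_index=bursts[0], end_index=bursts[-1])


def estimate_sampling_rate(n_samples_between: float, video_duration_s: float) -> float:
    """True sampling rate from inter-burst sample count and video duration."""
    if n_samples_between <= 0 or video_duration_s <= 0:
        raise ValueError("sample count and video duration must be positive")
    return n_samples_between / video_duration_s


def resample_to_uniform(
    stream: SensorStream,
    estimated_rate: float,
    target_rate: float = 200.0,
    rate_band: float = RATE_BAND,
    method: str = "linear",
) -> SensorStream:
    """Resample onto a uniform ``target_rate`` grid given the true rate.

    The recorded index axis is reinterpreted as time ``i / estimated_rate``
    and every channel is interpolated (linearly by default) onto a uniform
    grid. Duration is preserved within one sample period.
    """
    if abs(estimated_rate - target_rate) > rate_band * target_rate:
        raise ValueError(
            f"estimated rate {estimated_rate:.2f} Hz outside the plausibility "
            f"band ±{100 * rate_band:.0f}% of {target_rate:.0f} Hz"
        )
    if method != "linear":
        raise ValueError(f"unknown interpolation method {method!r}")
    n = stream.n_samples
    true_t = stream.sample_times[0] + np.arange(n) / estimated_rate
    duration = (n - 1) / estimated_rate
    n_out = int(np.floor(duration * target_rate + 1e-9)) + 1
    new_t = stream.sample_times[0] + np.arange(n_out) / target_rate
    accel = np.column_stack(
        [np.interp(new_t, true_t, stream.accel[:, k]) for k in range(3)]
    )
    gyro = np.column_stack(
        [np.interp(new_t, true_t, stream.gyro[:, k]) for k in range(3)]
    )
    return dataclasses.replace(
        stream, sample_times=new_t, accel=accel, gyro=gyro, nominal_rate=target_rate
    )
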