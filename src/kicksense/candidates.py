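"""Moving-window segmentation and peak-based candidate selection.

The classifiers only ever see *candidate* windows: 2 s blocks centered on
peaks of the signal magnitude vector (SMV) of the high-pass-filtered
gyroscope. Low-activity windows — standing, walking, most running — carry no
super-threshold SMV peak and are rejected before classification.

Filter and peak parameters default to the deployed values: 2nd-order
Butterworth high-pass at 20 Hz, peak threshold 0.3·max(SMV) per window,
minimum peak distance 300 samples (1.5 s). The relative threshold alone
cannot reject anything (every window attains its own maximum), so an
absolute activity floor ``min_height`` is applied on top; its default,
0.025 in full-scale gyroscope units (50 °/s), sits well above gait residue
after the 20 Hz high-pass and well below any ball-contact transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, lfilter, filtfilt

from .core import GYRO_FULL_SCALE, BallContactEvent, SensorStream, Session

__all__ = [
    "CandidateParams",
    "CandidateWindow",
    "CandidateSelection",
    "highpass_gyro",
    "smv",
    "moving_windows",
    "detect_peaks",
    "select_candidates",
]

#: label precedence when several events fall into one 1 s label window
_PRECEDENCE = ("shot", "pass", "null")


@dataclass(frozen=True)
class CandidateParams:
    cutoff_hz: float = 20.0
    order: int = 2
    threshold_frac: float = 0.3
    min_distance: int = 300  # samples (1.5 s)
    window_len: int = 400  # samples (2 s)
    overlap: float = 0.25
    label_window_s: float = 1.0
    merge_distance: int = 100  # samples (0.5 s, closest detectable spacing)
    min_height: float = 0.025  # scaled units; activity floor
    zero_phase: bool = False  # causal by default (deployable)


@dataclass
class CandidateWindow:
    """A 2 s signal block centered on a detected SMV peak."""

    session_id: str
    foot: str
    center_index: int
    block: np.ndarray  # (window_len, 6), scaled units
    label: str  # shot | pass | null | excluded
    fine_type: str  # representative fine type ("none" if no labelled event)
    events: tuple[BallContactEvent, ...] = ()
    smv_peak: float = 0.0
    edge_padded: bool = False


@dataclass
class CandidateSelection:
    candidates: list[CandidateWindow]
    windows_total: int
    windows_with_peaks: int

    @property
    def windows_rejected(self) -> int:
        return self.windows_total - self.windows_with_peaks

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)


def highpass_gyro(
    stream_or_gyro: SensorStream | np.ndarray,
    cutoff_hz: float = 20.0,
    order: int = 2,
    rate: float = 200.0,
    zero_phase: bool = False,
) -> np.ndarray:
    """Butterworth high-pass of the gyroscope channels.

    Causal by default: zero-phase (forward-backward) filtering is available
    but shifts no samples only at the price of non-deployability.
    """
    if isinstance(stream_or_gyro, SensorStream):
        gyro = stream_or_gyro.gyro
        rate = stream_or_gyro.nominal_rate
    else:
        gyro = np.asarray(stream_or_gyro, dtype=float)
    warmup = 3 * (order + 1)
    if gyro.shape[0] < warmup:
        raise ValueError(
            f"stream of {gyro.shape[0]} samples shorter than filter warm-up "
            f"({warmup} samples)"
        )
    b, a = butter(order, cutoff_hz, btype="highpass", fs=rate)
    if zero_phase:
        return filtfilt(b, a, gyro, axis=0)
    return lfilter(b, a, gyro, axis=0)


def smv(gyro: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm across the three gyroscope axes."""
    gyro = np.asarray(gyro, dtype=float)
    if gyro.ndim != 2 or gyro.shape[1] != 3:
        raise ValueError(f"expected (n, 3) gyro array, got shape {gyro.shape}")
    return np.sqrt(np.sum(gyro * gyro, axis=1))


def moving_windows(
    stream_or_n: SensorStream | int,
    window_len: int = 400,
    overlap: float = 0.25,
) -> np.ndarray:
    """Start indices of the moving windows (stride = len·(1−overlap)).

    The trailing partial window is dropped.
    """
    n = stream_or_n.n_samples if isinstance(stream_or_n, SensorStream) else int(stream_or_n)
    stride = int(round(window_len * (1.0 - overlap)))
    if n < window_len:
        return np.array([], dtype=int)
    return np.arange(0, n - window_len + 1, stride)


def detect_peaks(
    smv_window: np.ndarray,
    threshold_frac: float = 0.3,
    min_distance: int = 300,
    min_height: float = 0.0,
) -> np.ndarray:
    """SMV peaks: local maxima above max(frac·window-max, min_height).

    Kept peaks are greedily thinned so that any two are >= ``min_distance``
    apart, highest first; among equal heights the earliest index wins. An
    all-zero window yields no peaks.
    """
    x = np.asarray(smv_window, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int)
    peak_max = float(np.max(x))
    if peak_max <= 0.0:
        return np.array([], dtype=int)
    thr = max(threshold_frac * peak_max, min_height)
    interior = (x[1:-1] >= x[:-2]) & (x[1:-1] > x[2:]) & (x[1:-1] >= thr)
    cand = np.flatnonzero(interior) + 1
    if cand.size == 0:
        return cand
    order = cand[np.argsort(-x[cand], kind="stable")]  # ties -> earliest
    kept: list[int] = []
    for i in order:
        if all(abs(int(i) - j) >= min_distance for j in kept):
            kept.append(int(i))
    return np.array(sorted(kept), dtype=int)


def _label_for_peak(
    events: list[BallContactEvent],
    peak_time: float,
    half_window: float,
) -> tuple[str, str, tuple[BallContactEvent, ...]]:
    """Assign (label, representative fine type, events) for one peak.

    The label comes only from events within the 1 s window around the peak,
    with precedence shot > pass > null; a window whose only events are
    ``unknown`` contacts is excluded; a window with no labelled events is a
    null instance (fine type ``none``).
    """
    inside = tuple(
        e for e in events if peak_time - half_window <= e.time < peak_time + half_window
    )
    if not inside:
        return "null", "none", ()
    for cls in _PRECEDENCE:
        hits = [e for e in inside if e.class_label == cls]
        if hits:
            best = min(hits, key=lambda e: abs(e.time - peak_time))
            return cls, best.fine_type, inside
    return "excluded", "unknown", inside


def _extract_block(data: np.ndarray, center: int, window_len: int):
    """Centered block with symmetric zero-padding at stream edges."""
    half = window_len // 2
    start, end = center - half, center + half
    pad_l, pad_r = max(0, -start), max(0, end - data.shape[0])
    block = data[max(0, start) : min(data.shape[0], end)]
    if pad_l or pad_r:
        block = np.pad(block, ((pad_l, pad_r), (0, 0)))
    return block, bool(pad_l or pad_r)


def select_candidates(
    session: Session,
    params: CandidateParams = CandidateParams(),
) -> CandidateSelection:
    """Run the full candidate-selection pass over every foot of a session.

    The SMV is computed once per stream from the high-passed gyroscope; peaks
    are detected inside each moving window; duplicate peaks from overlapping
    windows (within ``merge_distance`` samples) are merged keeping the larger
    SMV. Each surviving peak yields one centered, zero-padded-if-needed
    candidate block with its ground-truth label.
    """
    candidates: list[CandidateWindow] = []
    windows_total = 0
    windows_with_peaks = 0
    for foot in sorted(session.streams):
        stream = session.streams[foot]
        floor = params.min_height if stream.scaled else params.min_height * GYRO_FULL_SCALE
        filtered = highpass_gyro(
            stream, params.cutoff_hz, params.order, zero_phase=params.zero_phase
        )
        magnitude = smv(filtered)
        starts = moving_windows(stream, params.window_len, params.overlap)
        windows_total += len(starts)
        peak_by_index: dict[int, float] = {}
        for s in starts:
            w = magnitude[s : s + params.window_len]
            local = detect_peaks(
                w, params.threshold_frac, params.min_distance, floor
            )
            if local.size:
                windows_with_peaks += 1
            for p in local:
                gi = int(s + p)
                peak_by_index[gi] = max(peak_by_index.get(gi, 0.0), float(magnitude[gi]))
        # cross-window dedup: keep the larger-SMV peak of any pair closer
        # than merge_distance
        order = sorted(peak_by_index, key=lambda i: (-peak_by_index[i], i))
        kept: list[int] = []
        for i in order:
            if all(abs(i - j) >= params.merge_distance for j in kept):
                kept.append(i)
        events = session.events_for_foot(foot)
        rate = stream.nominal_rate
        for center in sorted(kept):
            label, fine, inside = _label_for_peak(
                events, stream.sample_times[0] + center / rate,
                params.label_window_s / 2.0,
            )
            block, padded = _extract_block(stream.data, center, params.window_len)
            candidates.append(
                CandidateWindow(
                    session_id=session.session_id,
                    foot=foot,
                    center_index=center,
                    block=block,
                    label=label,
                    fine_type=fine,
                    events=inside,
                    smv_peak=peak_by_index[center],
                    edge_padded=padded,
                )
            )
    return CandidateSelection(candidates, windows_total, windows_with_peaks)
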