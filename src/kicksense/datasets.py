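"""Window datasets for training and benchmarking the classifiers.

Training follows the segmented protocol: one fixed-length window centered on
each labelled ball contact, on scaled signals, with the session id carried
along so cross-validation and train/validation splits never mix a session.
Windows whose label is ``excluded`` (contact not visible on video) are
dropped; pure-locomotion ``none`` events are excluded from *training* by
default — training nulls are hard ball-contact nulls — but kept in
evaluation datasets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .core import Session, scale_stream
from .synth import SynthConfig, generate_session

__all__ = ["WindowDataset", "segmented_windows", "make_window_benchmark",
           "BENCHMARK_COUNTS", "scaled"]


@dataclass
class WindowDataset:
    """Labelled (N, 400, 6) windows with provenance."""

    x: np.ndarray
    y: np.ndarray  # class labels (str)
    fine: np.ndarray  # fine-grained contact types (str)
    session_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.x)

    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    @staticmethod
    def concatenate(parts: list["WindowDataset"]) -> "WindowDataset":
        return WindowDataset(
            x=np.concatenate([p.x for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            fine=np.concatenate([p.fine for p in parts]),
            session_ids=np.concatenate([p.session_ids for p in parts]),
        )


def scaled(session: Session) -> Session:
    """Full-scale-scaled copy of a session (no-op if already scaled)."""
    if all(s.scaled for s in session.streams.values()):
        return session
    return dataclasses.replace(
        session,
        streams={f: scale_stream(s) for f, s in session.streams.items()},
        events=list(session.events),
    )


_scaled = scaled


def segmented_windows(
    sessions: list[Session],
    window_len: int = 400,
    include_none: bool = False,
) -> WindowDataset:
    """One centered window per labelled, non-excluded ball contact."""
    X, y, fine, sid = [], [], [], []
    for session in map(_scaled, sessions):
        for ev in session.events:
            if ev.class_label == "excluded":
                continue
            if ev.fine_type == "none" and not include_none:
                continue
            stream = session.streams[ev.foot]
            center = int(round((ev.time - stream.sample_times[0]) * stream.nominal_rate))
            half = window_len // 2
            start = min(max(0, center - half), max(0, stream.n_samples - window_len))
            X.append(stream.data[start : start + window_len])
            y.append(ev.class_label)
            fine.append(ev.fine_type)
            sid.append(session.session_id)
    if not X:
        raise ValueError("no usable labelled contacts in the given sessions")
    return WindowDataset(
        x=np.asarray(X), y=np.asarray(y), fine=np.asarray(fine),
        session_ids=np.asarray(sid),
    )


#: per-session event counts of the window benchmarks (~35 events/session,
#: null > pass > shot)
BENCHMARK_COUNTS = {
    "shot": 6,
    "short pass medial": 4,
    "short pass other": 3,
    "long pass": 3,
    "strong contact": 5,
    "light contact": 6,
    "none": 8,
    "unknown": 0,
}


def make_window_benchmark(
    seed: int = 0,
    n_sessions: int = 16,
    n_val_sessions: int = 4,
    confusable: bool = False,
    include_none: bool = True,
) -> tuple[WindowDataset, WindowDataset, list[Session]]:
    """Segmented-window benchmark with a grouped train/validation split.

    Generates ``n_sessions`` sessions (~35 events each), holds out the last
    ``n_val_sessions`` whole sessions for validation, and returns
    (train, validation, sessions). ``confusable`` switches the generator to
    the overlapping kick-phase regime.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_sessions)]
    sessions = []
    for i, s in enumerate(seeds):
        cfg = SynthConfig(
            seed=s,
            duration_s=130.0,
            counts=dict(BENCHMARK_COUNTS),
            confusable=confusable,
            session_id=f"bench-{i:03d}",
        )
        sessions.append(generate_session(cfg))
    train = segmented_windows(sessions[:-n_val_sessions], include_none=include_none)
    val = segmented_windows(sessions[-n_val_sessions:], include_none=include_none)
    return train, val, sessions
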