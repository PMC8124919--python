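"""Feature-based linear-SVM baseline from the laboratory literature.

The classifier operates on six hand-crafted features per 2 s window: the
absolute sum of each accelerometer and gyroscope channel over the *kick
phase*. The kick phase is found biomechanically — ball contact at the
maximum sagittal angular acceleration (largest first difference of ``gx``),
phase onset at the last zero crossing of ``gx`` before contact (start of
the leg acceleration). Features are computed on scaled signals.

Training follows the original protocol: random under-sampling to the
minority class, a linear one-vs-rest SVM, and selection of the cost
parameter C from the grid {2^N, N = −10…10} by the best mean weighted
F1 over session-grouped 5-fold cross-validation, then a refit on all data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import f1_score
from sklearn.model_selection import GroupKFold
from sklearn.svm import LinearSVC

__all__ = [
    "DegenerateWindowError",
    "KickPhase",
    "C_GRID",
    "find_ball_contact",
    "find_phase_start",
    "extract_features",
    "undersample",
    "train_svm",
    "predict_svm",
    "SvmModel",
]

log = logging.getLogger(__name__)

#: cost grid searched during cross-validation
C_GRID = tuple(2.0 ** n for n in range(-10, 11))

_SAGITTAL = 3  # gx column in the fixed channel order


class DegenerateWindowError(ValueError):
    """Raised when the sagittal gyro channel is constant (no kick phase)."""


@dataclass(frozen=True)
class KickPhase:
    """Leg-acceleration onset and ball-contact sample indices in a window."""

    start: int
    contact: int

    def __post_init__(self) -> None:
        if not self.start < self.contact:
            raise ValueError("kick phase start must precede ball contact")


def find_ball_contact(window: np.ndarray) -> int:
    """Ball-contact index: maximum first difference of the sagittal gyro.

    The first difference at 200 Hz approximates the sagittal angular
    acceleration; ties resolve to the earliest index.
    """
    gx = np.asarray(window)[:, _SAGITTAL]
    if np.ptp(gx) == 0.0:
        raise DegenerateWindowError("sagittal gyro channel is constant")
    d = np.diff(gx)
    return int(np.argmax(d)) + 1


def find_phase_start(window: np.ndarray, contact: int) -> int:
    """Largest index < contact where the sagittal gyro crosses zero.

    A crossing is an exact zero sample or a sign change between adjacent
    samples (in which case the index after the change is returned). Without
    any crossing the window start is used and a warning logged.
    """
    gx = np.asarray(window)[:, _SAGITTAL]
    if not 0 < contact < len(gx):
        raise ValueError(f"contact index {contact} outside window")
    for k in range(contact - 1, -1, -1):
        if gx[k] == 0.0:
            return k
        if k > 0 and gx[k] * gx[k - 1] < 0.0:
            return k
    log.warning("no zero crossing before contact; kick phase starts at window start")
    return 0


def extract_features(window: np.ndarray, phase: KickPhase | None = None) -> np.ndarray:
    """Six absolute-sum features over the kick phase, one per channel.

    The sum runs over the closed interval [start, contact].
    """
    window = np.asarray(window)
    if phase is None:
        contact = find_ball_contact(window)
        start = find_phase_start(window, contact)
        if start == contact:
            start = max(0, contact - 1)
        phase = KickPhase(start=start, contact=contact)
    seg = window[phase.start : phase.contact + 1]
    return np.abs(seg).sum(axis=0)


def undersample(
    labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a balanced subset: every class kept at the minority count."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    n_min = int(counts.min())
    keep: list[np.ndarray] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    return np.sort(np.concatenate(keep))


@dataclass
class SvmModel:
    clf: LinearSVC
    best_c: float
    cv_scores: dict[float, float]

    def predict_classes(self, windows: np.ndarray) -> list[str]:
        """Classify a batch of (400, 6) windows; degenerate windows → null."""
        out: list[str] = []
        for w in np.asarray(windows):
            out.append(predict_svm(self, w))
        return out


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    sessions: np.ndarray,
    seed: int = 0,
    c_grid: tuple[float, ...] = C_GRID,
    n_folds: int = 5,
) -> SvmModel:
    """Grid-search C over session-grouped folds, refit on everything.

    Under-sampling to the minority class happens once, before the CV split,
    driven by ``seed``. Folds never mix samples of one session between train
    and validation. Raises if any of the three classes is absent.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    sessions = np.asarray(sessions)
    present = set(labels)
    missing = {"shot", "pass", "null"} - present
    if missing:
        raise ValueError(f"class(es) absent from training data: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    keep = undersample(labels, rng)
    X, y, groups = features[keep], labels[keep], sessions[keep]

    n_groups = len(np.unique(groups))
    if n_groups < 2:
        raise ValueError("grouped cross-validation needs >= 2 sessions")
    splitter = GroupKFold(n_splits=min(n_folds, n_groups))

    cv_scores: dict[float, float] = {}
    for c in c_grid:
        scores = []
        for tr, va in splitter.split(X, y, groups):
            if len(set(y[tr])) < 2:
                continue
            clf = LinearSVC(C=c, max_iter=20000)
            clf.fit(X[tr], y[tr])
            scores.append(f1_score(y[va], clf.predict(X[va]), average="weighted"))
        cv_scores[c] = float(np.mean(scores)) if scores else 0.0
    best_c = max(cv_scores, key=lambda c: (cv_scores[c], -c))
    final = LinearSVC(C=best_c, max_iter=20000)
    final.fit(X, y)
    return SvmModel(clf=final, best_c=best_c, cv_scores=cv_scores)


def predict_svm(model: SvmModel, window: np.ndarray) -> str:
    """Predict shot/pass/null for one window; degenerate windows fall back
    to null (logged), mirroring the pipeline's scoring rule."""
    try:
        feats = extract_features(window)
    except DegenerateWindowError:
        log.info("degenerate window (constant sagittal gyro) scored as null")
        return "null"
    return str(model.clf.predict(feats[None, :])[0])
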