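"""Metrics and evaluation scenarios.

Per-class F1 is the harmonic mean of precision and recall; the headline
score is the support-weighted mean F1 over (shot, pass, null). Sensitivity
of class c is TP_c / (TP_c + FN_c). The *fine-grained confusion matrix*
tabulates predicted class against the detailed ball-contact type and
normalizes each column (true ball contact), so a perfect classifier puts a
single 1 in each nonempty column.

Three scenarios mirror the path from laboratory to real-world evaluation:

* ``segmented_lab`` — one centered 2 s window per labelled contact of lab
  sessions; no candidate selection.
* ``window_lab`` / ``window_field`` — moving windows over the whole stream,
  peak-based candidate selection, classification of candidates only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .candidates import CandidateParams, CandidateSelection, select_candidates
from .core import FINE_TYPES, Session, map_contact_to_class, scale_stream

__all__ = [
    "ClassCounts",
    "EvaluationReport",
    "counts_from_predictions",
    "f1_class",
    "f1_weighted",
    "sensitivity_class",
    "fine_grained_confusion",
    "run_segmented_scenario",
    "run_window_scenario",
    "GroundTruthOracle",
]

CLASSES = ("shot", "pass", "null")
#: column order of the fine-grained matrix (evaluable contact types)
FINE_ORDER = tuple(f for f in FINE_TYPES if f != "unknown")


@dataclass(frozen=True)
class ClassCounts:
    """Contingency counts of one class."""

    tp: int = 0
    fn: int = 0
    fp: int = 0

    @property
    def support(self) -> int:
        return self.tp + self.fn


def counts_from_predictions(
    y_true, y_pred, classes: tuple[str, ...] = CLASSES
) -> dict[str, ClassCounts]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/label length mismatch")
    out = {}
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        out[c] = ClassCounts(tp=tp, fn=fn, fp=fp)
    return out


def f1_class(counts: ClassCounts) -> float:
    """F1 = 2PR/(P+R) with the 0/0 → 0 convention."""
    p_den = counts.tp + counts.fp
    r_den = counts.tp + counts.fn
    precision = counts.tp / p_den if p_den else 0.0
    recall = counts.tp / r_den if r_den else 0.0
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def f1_weighted(all_counts: dict[str, ClassCounts]) -> float:
    """Support-weighted mean of per-class F1; empty classes carry zero weight."""
    weights = {c: cc.support for c, cc in all_counts.items()}
    total = sum(weights.values())
    if total == 0:
        raise ValueError("weighted F1 undefined: all class supports are zero")
    return sum(weights[c] * f1_class(cc) for c, cc in all_counts.items()) / total


def sensitivity_class(counts: ClassCounts) -> float | None:
    """TP / (TP + FN); None when the class has no support."""
    if counts.support == 0:
        return None
    return counts.tp / counts.support


def fine_grained_confusion(
    predictions,
    fine_types,
    classes: tuple[str, ...] = CLASSES,
    fine_order: tuple[str, ...] = FINE_ORDER,
) -> pd.DataFrame:
    """Column-normalized matrix: rows = predicted class, columns = true
    ball-contact type. ``unknown`` (excluded) samples must be dropped by the
    caller; empty columns stay at zero."""
    predictions = list(predictions)
    fine_types = list(fine_types)
    if len(predictions) != len(fine_types):
        raise ValueError("prediction/fine-type length mismatch")
    mat = pd.DataFrame(0.0, index=list(classes), columns=list(fine_order))
    for pred, fine in zip(predictions, fine_types):
        if fine not in fine_order:
            raise ValueError(f"unknown ball-contact type {fine!r}")
        if pred not in classes:
            raise ValueError(f"unknown predicted class {pred!r}")
        mat.loc[pred, fine] += 1.0
    sums = mat.sum(axis=0)
    nonempty = sums > 0
    mat.loc[:, nonempty] = mat.loc[:, nonempty] / sums[nonempty]
    return mat


@dataclass
class EvaluationReport:
    scenario: str
    weighted_f1: float | None
    sensitivity: dict[str, float | None]
    fine_matrix: pd.DataFrame | None
    candidate_stats: dict[str, int] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    n_evaluated: int = 0

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "weighted_f1": self.weighted_f1,
            "sensitivity": self.sensitivity,
            "fine_matrix": None
            if self.fine_matrix is None
            else {
                "classes": list(self.fine_matrix.index),
                "fine_types": list(self.fine_matrix.columns),
                "values": self.fine_matrix.to_numpy().tolist(),
            },
            "candidate_stats": self.candidate_stats,
            "n_evaluated": self.n_evaluated,
            "config": self.config,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def render_text(self) -> str:
        lines = [f"scenario: {self.scenario}",
                 f"evaluated windows: {self.n_evaluated}",
                 f"weighted F1: "
                 f"{'n/a' if self.weighted_f1 is None else f'{self.weighted_f1:.3f}'}"]
        for c, s in self.sensitivity.items():
            lines.append(f"sensitivity[{c}]: {'n/a' if s is None else f'{s:.3f}'}")
        if self.candidate_stats:
            lines.append(f"candidate stats: {self.candidate_stats}")
        if self.fine_matrix is not None:
            lines.append(self.fine_matrix.round(3).to_string())
        return "\n".join(lines)


class GroundTruthOracle:
    """Reference classifier that echoes the true labels it is handed.

    Used to validate scenario plumbing: with this model every scenario must
    report weighted F1 = 1 and unit sensitivities.
    """

    def predict_classes(self, x, meta=None) -> list[str]:
        if meta is None:
            raise ValueError("oracle needs the ground-truth meta list")
        return list(meta)


def _predict(model, x: np.ndarray, truth: list[str]) -> list[str]:
    if isinstance(model, GroundTruthOracle):
        return model.predict_classes(x, meta=truth)
    return model.predict_classes(x)


def _report_from(scenario, y_true, y_pred, fines, stats, config) -> EvaluationReport:
    counts = counts_from_predictions(y_true, y_pred)
    try:
        wf1 = f1_weighted(counts)
    except ValueError:
        wf1 = None
    sens = {c: sensitivity_class(cc) for c, cc in counts.items()}
    mat = fine_grained_confusion(y_pred, fines) if y_pred else None
    return EvaluationReport(
        scenario=scenario,
        weighted_f1=wf1,
        sensitivity=sens,
        fine_matrix=mat,
        candidate_stats=stats,
        config=config,
        n_evaluated=len(y_pred),
    )


def _scaled(session: Session) -> Session:
    if all(s.scaled for s in session.streams.values()):
        return session
    return dataclasses.replace(
        session,
        streams={f: scale_stream(s) for f, s in session.streams.items()},
        events=list(session.events),
    )


def run_segmented_scenario(
    model,
    sessions: list[Session],
    window_len: int = 400,
) -> EvaluationReport:
    """One centered window per labelled ball contact; excluded labels dropped."""
    X, y_true, fines = [], [], []
    for session in map(_scaled, sessions):
        for ev in session.events:
            if map_contact_to_class(ev.fine_type) == "excluded":
                continue
            stream = session.streams[ev.foot]
            center = int(round((ev.time - stream.sample_times[0]) * stream.nominal_rate))
            half = window_len // 2
            start = min(max(0, center - half), max(0, stream.n_samples - window_len))
            X.append(stream.data[start : start + window_len])
            y_true.append(ev.class_label)
            fines.append(ev.fine_type)
    if not X:
        raise ValueError("no labelled ball contacts to evaluate")
    y_pred = _predict(model, np.asarray(X), y_true)
    return _report_from("segmented_lab", y_true, y_pred, fines, {}, {})


def run_window_scenario(
    model,
    sessions: list[Session],
    params: CandidateParams = CandidateParams(),
    scenario: str = "window_lab",
) -> EvaluationReport:
    """Moving windows → candidate selection → classification of candidates.

    Candidates whose only events are unobserved (``unknown``) contacts are
    excluded from the metrics; candidate-selection statistics are reported
    alongside.
    """
    X, y_true, fines = [], [], []
    stats = {
        "windows_total": 0,
        "windows_rejected": 0,
        "candidates": 0,
        "excluded_candidates": 0,
        "labelled_contacts_in_candidates": 0,
    }
    for session in map(_scaled, sessions):
        sel: CandidateSelection = select_candidates(session, params)
        stats["windows_total"] += sel.windows_total
        stats["windows_rejected"] += sel.windows_rejected
        stats["candidates"] += len(sel)
        for cand in sel:
            stats["labelled_contacts_in_candidates"] += len(cand.events)
            if cand.label == "excluded":
                stats["excluded_candidates"] += 1
                continue
            X.append(cand.block)
            y_true.append(cand.label)
            fines.append(cand.fine_type)
    config = {"candidate_params": dataclasses.asdict(params)}
    if not X:
        return EvaluationReport(
            scenario=scenario, weighted_f1=None,
            sensitivity={c: None for c in CLASSES}, fine_matrix=None,
            candidate_stats=stats, config=config, n_evaluated=0,
        )
    y_pred = _predict(model, np.asarray(X), y_true)
    return _report_from(scenario, y_true, y_pred, fines, stats, config)
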