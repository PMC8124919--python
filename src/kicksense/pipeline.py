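"""End-to-end orchestration: generate → preprocess → candidates → train →
evaluate, fully seed-deterministic.

Each stage logs its counts (sessions, windows, rejected, candidates,
per-class totals); reports for every requested scenario are written as JSON
with the resolved configuration embedded.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from .candidates import select_candidates
from .config import PipelineConfig
from .core import Session, scale_stream
from .datasets import WindowDataset, segmented_windows
from .evaluation import EvaluationReport, run_segmented_scenario, run_window_scenario
from .nn import build_cnn, build_convlstm, build_lstm, train_model
from .svm import extract_features, train_svm
from .synth import make_benchmark_split

log = logging.getLogger("kicksense.pipeline")

__all__ = ["run_pipeline", "train_classifier", "PipelineError"]

_BUILDERS = {"cnn": build_cnn, "lstm": build_lstm, "convlstm": build_convlstm}


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def _scaled(session: Session) -> Session:
    return dataclasses.replace(
        session,
        streams={f: scale_stream(s) for f, s in session.streams.items()},
        events=list(session.events),
    )


def train_classifier(arch: str, train_ds: WindowDataset, val_ds: WindowDataset,
                     config: PipelineConfig):
    """Train the requested architecture; returns (model, history-or-None)."""
    if arch == "svm":
        feats = np.array([extract_features(w) for w in train_ds.x])
        model = train_svm(feats, train_ds.y, train_ds.session_ids, seed=config.seed)
        return model, None
    if arch not in _BUILDERS:
        raise ValueError(f"unknown architecture {arch!r}")
    spec = _BUILDERS[arch](seed=config.seed, **config.model)
    history = train_model(spec, train_ds.x, train_ds.y, val_ds.x, val_ds.y,
                          config.train_config())
    return spec, history


def run_pipeline(config: PipelineConfig) -> dict[str, EvaluationReport]:
    """Run the full pipeline and return {scenario: report}.

    Artifacts (reports, history) land in ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        split = make_benchmark_split(
            config.synth_config(),
            n_train=config.n_train_sessions,
            n_lab_test=config.n_lab_test_sessions,
            n_field_test=config.n_field_test_sessions,
        )
    except Exception as exc:
        raise PipelineError("generate", exc) from exc
    for name, sessions in split.items():
        counts: dict[str, int] = {}
        for s in sessions:
            for c, n in s.class_counts().items():
                counts[c] = counts.get(c, 0) + n
        log.info("%s: %d sessions, per-class events %s", name, len(sessions), counts)

    try:
        train_sessions = [_scaled(s) for s in split["train"]]
        lab_test = [_scaled(s) for s in split["lab_test"]]
        field_test = [_scaled(s) for s in split["field_test"]]
    except Exception as exc:
        raise PipelineError("preprocess", exc) from exc

    try:
        n_hold = max(1, len(train_sessions) // 4)
        train_ds = segmented_windows(train_sessions[:-n_hold])
        val_ds = segmented_windows(train_sessions[-n_hold:])
        log.info("training windows %d %s / validation %d", len(train_ds),
                 train_ds.class_counts(), len(val_ds))
    except Exception as exc:
        raise PipelineError("segment", exc) from exc

    params = config.candidate_params()
    for name, sessions in (("lab_test", lab_test), ("field_test", field_test)):
        sel_counts = [select_candidates(s, params) for s in sessions]
        total = sum(c.windows_total for c in sel_counts)
        rejected = sum(c.windows_rejected for c in sel_counts)
        n_cand = sum(len(c) for c in sel_counts)
        log.info("%s candidate selection: windows=%d rejected=%d candidates=%d",
                 name, total, rejected, n_cand)

    try:
        model, history = train_classifier(config.arch, train_ds, val_ds, config)
        if history is not None:
            (out_dir / "history.json").write_text(json.dumps(history, indent=2))
    except Exception as exc:
        raise PipelineError("train", exc) from exc

    reports: dict[str, EvaluationReport] = {}
    resolved = config.resolved()
    try:
        for scenario in config.scenarios:
            if scenario == "segmented_lab":
                rep = run_segmented_scenario(model, lab_test)
            elif scenario == "window_lab":
                rep = run_window_scenario(model, lab_test, params, scenario)
            elif scenario == "window_field":
                rep = run_window_scenario(model, field_test, params, scenario)
            else:
                raise ValueError(f"unknown scenario {scenario!r}")
            rep.config = {**rep.config, "pipeline": resolved}
            reports[scenario] = rep
            (out_dir / f"report_{scenario}.json").write_text(rep.to_json())
            log.info("%s: weighted F1 %s", scenario,
                     "n/a" if rep.weighted_f1 is None else f"{rep.weighted_f1:.3f}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("evaluate", exc) from exc
    return reports
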