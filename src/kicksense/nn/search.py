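"""Random hyperparameter search over the published search spaces.

The original models were tuned with 500 trials of Bayesian optimization;
the shipped defaults in :mod:`kicksense.nn.models` are those optima. This
module provides a desk-scale random-search replacement over the same
spaces, with session-grouped cross-validation handled by the caller-supplied
fold objective and median pruning of unpromising trials after their first
fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "SearchSpace",
    "CNN_SPACE",
    "LSTM_SPACE",
    "CONVLSTM_SPACE",
    "hyperparameter_search",
]

# (kind, spec): categorical -> tuple of choices, loguniform -> (low, high)
SearchSpace = dict[str, tuple[str, tuple]]

CNN_SPACE: SearchSpace = {
    "filter1": ("categorical", (64, 128, 256, 512)),
    "filter2": ("categorical", (16, 32, 64, 128, 256)),
    "filter3": ("categorical", (16, 32, 64, 128, 256)),
    "poolsize": ("categorical", (2, 3, 4, 5)),
    "kernelsize": ("categorical", (2, 3, 4)),
    "dropout1": ("loguniform", (0.01, 1.0)),
    "dropout2": ("loguniform", (0.01, 1.0)),
    "dropout3": ("loguniform", (0.01, 1.0)),
    "learning_rate": ("loguniform", (0.001, 0.1)),
}

LSTM_SPACE: SearchSpace = {
    "units": ("categorical", (64, 128, 256, 512)),
    "l1": ("loguniform", (0.0001, 0.1)),
    "l2": ("loguniform", (0.0001, 0.1)),
    "clipvalue": ("loguniform", (0.1, 0.8)),
    "learning_rate": ("loguniform", (0.001, 0.1)),
}

CONVLSTM_SPACE: SearchSpace = {
    "filter": ("categorical", (16, 32, 64, 128, 256)),
    "kernelsize": ("categorical", (2, 3, 4)),
    "dropout": ("loguniform", (0.01, 1.0)),
    "num_segments": ("categorical", (2, 4, 5, 8, 10)),
    "learning_rate": ("loguniform", (0.001, 0.1)),
}


def _sample(space: SearchSpace, rng: np.random.Generator) -> dict:
    cfg = {}
    for name, (kind, spec) in space.items():
        if kind == "categorical":
            cfg[name] = spec[rng.integers(len(spec))]
        elif kind == "loguniform":
            lo, hi = spec
            cfg[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            raise ValueError(f"unknown sampling kind {kind!r}")
    return cfg


@dataclass
class Trial:
    config: dict
    fold_scores: list[float] = field(default_factory=list)
    pruned: bool = False

    @property
    def score(self) -> float:
        return float(np.mean(self.fold_scores)) if self.fold_scores else -np.inf


def hyperparameter_search(
    space: SearchSpace,
    budget: int,
    fold_objective: Callable[[dict, int], float],
    n_folds: int = 5,
    seed: int = 0,
    prune: bool = True,
) -> tuple[dict, list[Trial]]:
    """Maximize the mean fold score over ``budget`` sampled configs.

    ``fold_objective(config, fold) -> score`` evaluates one grouped-CV fold
    (weighted F1 by convention). With ``prune``, a trial whose first-fold
    score falls below the running median of earlier first-fold scores skips
    its remaining folds. Returns the best config and the full trial log.
    """
    if not space:
        raise ValueError("empty search space")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    first_scores: list[float] = []
    for _ in range(budget):
        trial = Trial(config=_sample(space, rng))
        s0 = fold_objective(trial.config, 0)
        trial.fold_scores.append(s0)
        if prune and first_scores and s0 < float(np.median(first_scores)):
            trial.pruned = True
        first_scores.append(s0)
        if not trial.pruned:
            for fold in range(1, n_folds):
                trial.fold_scores.append(fold_objective(trial.config, fold))
        trials.append(trial)
    best = max(trials, key=lambda t: t.score)
    return best.config, trials
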