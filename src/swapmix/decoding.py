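"""Cue decoding and its generalization from correct to swap trials.

A regularized linear classifier is trained to decode the cue (upper vs
lower cued) from population activity on likely-correct trials
(p_correct > 0.6); its cross-validated accuracy on those trials is the
baseline.  The same decoder is then applied to likely-swap trials
(p_swap > 0.4).  If correct and swap trials share the cue
representation, the decoder generalizes (gap ~ 0); if swap trials carry
a flipped cue representation, swap accuracy approaches one minus the
correct-trial accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score


@dataclass
class DecoderReport:
    """Cross-validated cue-decoding accuracies and the generalization gap."""

    accuracy_correct: float
    accuracy_swap: float | None = None
    n_correct: int = 0
    n_swap: int = 0
    window_time: float | None = None

    @property
    def gap(self) -> float | None:
        """Swap-trial minus correct-trial accuracy (negative = failure to
        generalize below the cross-validated baseline)."""
        if self.accuracy_swap is None:
            return None
        return self.accuracy_swap - self.accuracy_correct


class CueDecoder:
    """sklearn-style wrapper: L2 logistic regression for the binary cue.

    fit(activity, trials, behav) trains on likely-correct trials
    (p_correct_post > p_correct_min) with balanced class weights and
    records the stratified 5-fold cross-validated accuracy in
    ``cv_accuracy_``; ``generalization`` then scores likely-swap trials.
    """

    def __init__(self, p_correct_min=0.6, p_swap_min=0.4, C=1.0, n_folds=5, seed=0):
        self.p_correct_min = p_correct_min
        self.p_swap_min = p_swap_min
        self.C = C
        self.n_folds = n_folds
        self.seed = seed

    def get_params(self, deep=True):
        return {"p_correct_min": self.p_correct_min, "p_swap_min": self.p_swap_min,
                "C": self.C, "n_folds": self.n_folds, "seed": self.seed}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _clf(self):
        return LogisticRegression(C=self.C, class_weight="balanced", max_iter=2000)

    def fit(self, activity, trials: pd.DataFrame, behav: pd.DataFrame):
        activity = np.asarray(activity, dtype=float)
        mask = behav["p_correct_post"].to_numpy() > self.p_correct_min
        X = activity[mask]
        y = trials["c"].to_numpy()[mask]
        if len(np.unique(y)) < 2:
            raise ValueError("likely-correct trials contain a single cue class")
        cv = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                             random_state=self.seed)
        self.cv_accuracy_ = float(
            cross_val_score(self._clf(), X, y, cv=cv, scoring="accuracy").mean()
        )
        self.classifier_ = self._clf().fit(X, y)
        self.n_correct_ = int(mask.sum())
        return self

    def predict(self, activity) -> np.ndarray:
        return self.classifier_.predict(np.asarray(activity, dtype=float))

    def generalization(self, activity, trials: pd.DataFrame,
                       behav: pd.DataFrame) -> DecoderReport:
        """Accuracy on likely-swap trials and the swap-minus-correct gap."""
        if not hasattr(self, "classifier_"):
            raise RuntimeError("not fitted")
        activity = np.asarray(activity, dtype=float)
        mask = behav["p_swap_post"].to_numpy() > self.p_swap_min
        if mask.sum() == 0:
            raise ValueError("no likely-swap trials to evaluate")
        acc = float(
            (self.predict(activity[mask]) == trials["c"].to_numpy()[mask]).mean()
        )
        return DecoderReport(
            accuracy_correct=self.cv_accuracy_, accuracy_swap=acc,
            n_correct=self.n_correct_, n_swap=int(mask.sum()),
        )


def train_cue_decoder(activity, trials, behav, *, p_correct_min=0.6,
                      p_swap_min=0.4, seed=0) -> CueDecoder:
    """Train the cue decoder on likely-correct trials (thin wrapper)."""
    return CueDecoder(p_correct_min=p_correct_min, p_swap_min=p_swap_min,
                      seed=seed).fit(activity, trials, behav)


def decoder_generalization_gap(decoder: CueDecoder, activity, trials,
                               behav) -> DecoderReport:
    """Evaluate a trained decoder on likely-swap trials (thin wrapper)."""
    return decoder.generalization(activity, trials, behav)
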