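"""Adaptive selection of a single augmenting screening question.

Given a text-based risk predictor, the algorithm decides — from the text
alone — which one of the 20 checklist questions (if any) is worth asking,
then predicts risk from the text plus the answer.

For each candidate question ``j`` three regression trees are involved:

* the *text tree*, fit on text features only;
* the *augmented tree* for ``j``, fit on text features plus the recorded
  binary answer to ``j`` (appended as the last feature column);
* the *selection tree* for ``j``, a second-stage predictor trained to
  estimate whether asking ``j`` would move the prediction further in the
  correct direction than the text-only score.

The selection tree's inputs are, per child: (1) the text-only score, (2) the
augmented score with the answer forced negative, (3) the augmented score
with the answer forced positive, and (4) leaf-variance information from the
three predictors at the leaf where the child lands (see ``f4_mode``). Its
training label is 1 iff the augmented score computed with the child's
*actual* answer is strictly more extreme in the right direction than the
text-only score (ties count as no improvement).

At prediction time all 20 selection trees are evaluated; if every decision
score is below ``decision_threshold`` (default 0.5) no question is asked and
the text-only score is returned, otherwise the question with the highest
decision score is asked (ties broken toward the lowest index) and the
augmented tree for that question produces the final score.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .tree import VarianceRegressionTree, _dense

__all__ = [
    "NO_QUESTION",
    "label_selection_example",
    "QuestionSelector",
    "question_contribution_rates",
]

#: Sentinel for "ask no question" in integer arrays of chosen indices.
NO_QUESTION = -1

F4_MODES = ("three_leaf_variances", "mean_leaf_variance", "variance_of_outputs")


def label_selection_example(y, text_score, augmented_score) -> np.ndarray:
    """Selection-tree training label(s).

    1 iff the augmented score (computed with the true answer) is strictly
    more extreme than the text score in the direction of the true label:
    higher for positives, lower for negatives. Ties give 0.
    """
    y = np.asarray(y)
    t = np.asarray(text_score, dtype=np.float64)
    a = np.asarray(augmented_score, dtype=np.float64)
    up = (y == 1) & (a > t)
    down = (y == 0) & (a < t)
    return (up | down).astype(np.int64)


class QuestionSelector(BaseEstimator):
    """Single-question augmentation of a text-based risk predictor.

    Parameters
    ----------
    n_questions : int, default 20
        Number of candidate augmenting questions.
    decision_threshold : float, default 0.5
        A question is asked iff some selection-tree score reaches this value.
    f4_mode : str
        How leaf variances of the three first-stage predictors enter the
        selection features: ``"three_leaf_variances"`` (three features, the
        default), ``"mean_leaf_variance"`` (their mean, one feature) or
        ``"variance_of_outputs"`` (population variance of the three scores,
        one feature).
    max_depth, min_samples_leaf, min_variance_reduction :
        Hyperparameters shared by every tree (first and second stage).
    random_state : int or None
        Accepted for interface symmetry; fitting is deterministic.

    Attributes
    ----------
    text_tree_ : VarianceRegressionTree
    augmented_trees_ : list of VarianceRegressionTree, one per question
    selection_trees_ : list of VarianceRegressionTree, one per question
    """

    def __init__(
        self,
        n_questions: int = 20,
        decision_threshold: float = 0.5,
        f4_mode: str = "three_leaf_variances",
        max_depth: int = 4,
        min_samples_leaf: int = 5,
        min_variance_reduction: float = 0.0,
        random_state: int | None = None,
    ):
        self.n_questions = n_questions
        self.decision_threshold = decision_threshold
        self.f4_mode = f4_mode
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.min_variance_reduction = min_variance_reduction
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _tree(self) -> VarianceRegressionTree:
        return VarianceRegressionTree(
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            min_variance_reduction=self.min_variance_reduction,
            random_state=self.random_state,
        )

    def _selection_features(self, f1, v1, f2, v2, f3, v3) -> np.ndarray:
        """Stack the selection-tree inputs; column layout depends on f4_mode."""
        scores = np.column_stack([f1, f2, f3])
        if self.f4_mode == "three_leaf_variances":
            f4 = np.column_stack([v1, v2, v3])
        elif self.f4_mode == "mean_leaf_variance":
            f4 = np.column_stack([v1, v2, v3]).mean(axis=1, keepdims=True)
        elif self.f4_mode == "variance_of_outputs":
            f4 = scores.var(axis=1, keepdims=True)
        else:
            raise ValueError(
                f"f4_mode must be one of {F4_MODES}, got {self.f4_mode!r}"
            )
        return np.hstack([scores, f4])

    @staticmethod
    def _augment(X: np.ndarray, answers: np.ndarray) -> np.ndarray:
        """Text features with one answer column appended last."""
        return np.hstack([X, np.asarray(answers, dtype=np.float64).reshape(-1, 1)])

    def _question_features(self, X: np.ndarray, j: int):
        """Per-sample selection features for question j on fitted trees."""
        f1, v1 = self.text_tree_.predict_with_variance(X)
        aug = self.augmented_trees_[j]
        n = X.shape[0]
        f2, v2 = aug.predict_with_variance(self._augment(X, np.zeros(n)))
        f3, v3 = aug.predict_with_variance(self._augment(X, np.ones(n)))
        return self._selection_features(f1, v1, f2, v2, f3, v3)

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, answers) -> "QuestionSelector":
        """Fit text tree, per-question augmented trees and selection trees.

        Parameters
        ----------
        X : array-like (n_samples, n_text_features)
            Vectorized narratives.
        y : array-like (n_samples,)
            Binary outcome labels; both classes must be present.
        answers : array-like (n_samples, n_questions)
            Recorded binary answers, coded 1 = at-risk answer.
        """
        X = _dense(X)
        y = np.asarray(y, dtype=np.int64).ravel()
        answers = _dense(answers)
        if answers.shape != (X.shape[0], self.n_questions):
            raise ValueError(
                f"answers must have shape (n_samples, {self.n_questions}), "
                f"got {answers.shape}"
            )
        if len(np.unique(y)) < 2:
            raise ValueError(
                "outcome labels are single-class; the selection task is undefined"
            )
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.f4_mode not in F4_MODES:
            raise ValueError(f"f4_mode must be one of {F4_MODES}")

        self.text_tree_ = self._tree().fit(X, y)
        f1, v1 = self.text_tree_.predict_with_variance(X)
        n = X.shape[0]
        zeros, ones = np.zeros(n), np.ones(n)

        self.augmented_trees_ = []
        self.selection_trees_ = []
        for j in range(self.n_questions):
            aug = self._tree().fit(self._augment(X, answers[:, j]), y)
            f2, v2 = aug.predict_with_variance(self._augment(X, zeros))
            f3, v3 = aug.predict_with_variance(self._augment(X, ones))
            s_true = aug.predict(self._augment(X, answers[:, j]))
            labels = label_selection_example(y, f1, s_true)
            feats = self._selection_features(f1, v1, f2, v2, f3, v3)
            sel = self._tree().fit(feats, labels)
            self.augmented_trees_.append(aug)
            self.selection_trees_.append(sel)
        self.n_features_in_ = X.shape[1]
        return self

    # -- inference ---------------------------------------------------------

    def selection_scores(self, X) -> np.ndarray:
        """Decision score of every selection tree: shape (n_samples, n_questions)."""
        check_is_fitted(self, "text_tree_")
        X = _dense(X)
        out = np.empty((X.shape[0], self.n_questions))
        for j in range(self.n_questions):
            out[:, j] = self.selection_trees_[j].predict(self._question_features(X, j))
        return out

    def choose_question(self, X) -> np.ndarray:
        """Chosen question index per sample (0-based), or NO_QUESTION (-1).

        No question is asked iff every decision score is below the
        threshold; otherwise the argmax wins, ties toward the lowest index.
        """
        scores = self.selection_scores(X)
        chosen = np.argmax(scores, axis=1)  # first max: lowest index on ties
        none_mask = np.all(scores < self.decision_threshold, axis=1)
        chosen[none_mask] = NO_QUESTION
        return chosen

    def predict_risk(self, X, chosen, answers=None) -> np.ndarray:
        """Final risk scores given chosen questions and their answers.

        ``chosen`` holds per-sample question indices (or ``NO_QUESTION``);
        ``answers`` must supply a binary answer wherever a question was
        chosen (it may be a full (n, n_questions) matrix or a 1-d vector of
        the chosen answers).
        """
        check_is_fitted(self, "text_tree_")
        X = _dense(X)
        chosen = np.asarray(chosen, dtype=np.int64).ravel()
        out = np.empty(X.shape[0])
        answers_arr = None if answers is None else np.asarray(answers, dtype=np.float64)
        for i in range(X.shape[0]):
            j = chosen[i]
            if j == NO_QUESTION:
                out[i] = self.text_tree_.predict(X[i : i + 1])[0]
                continue
            if answers_arr is None:
                raise ValueError(
                    f"sample {i}: question {j + 1} chosen but no answer supplied"
                )
            if answers_arr.ndim == 2:
                ans = answers_arr[i, j]
            else:
                ans = answers_arr[i]
            if np.isnan(ans):
                raise ValueError(
                    f"sample {i}: question {j + 1} chosen but answer is missing"
                )
            row = self._augment(X[i : i + 1], np.array([ans]))
            out[i] = self.augmented_trees_[j].predict(row)[0]
        return out

    # -- serialization -----------------------------------------------------

    def save(self, directory) -> None:
        """Serialize the model bundle (JSON) to a directory."""
        check_is_fitted(self, "text_tree_")
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        payload = {
            "params": self.get_params(),
            "n_features": int(self.n_features_in_),
            "text_tree": self.text_tree_.to_dict(),
            "augmented_trees": [t.to_dict() for t in self.augmented_trees_],
            "selection_trees": [t.to_dict() for t in self.selection_trees_],
        }
        with open(d / "selector.json", "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, directory) -> "QuestionSelector":
        with open(Path(directory) / "selector.json") as fh:
            payload = json.load(fh)
        model = cls(**payload["params"])
        model.text_tree_ = VarianceRegressionTree.from_dict(payload["text_tree"])
        model.augmented_trees_ = [
            VarianceRegressionTree.from_dict(t) for t in payload["augmented_trees"]
        ]
        model.selection_trees_ = [
            VarianceRegressionTree.from_dict(t) for t in payload["selection_trees"]
        ]
        model.n_features_in_ = payload["n_features"]
        return model


def question_contribution_rates(chosen, n_questions: int = 20) -> np.ndarray:
    """Fraction of children for whom each question was chosen.

    Returns ``n_questions + 1`` fractions summing to 1; the last entry is
    the no-question fraction.
    """
    chosen = np.asarray(chosen, dtype=np.int64).ravel()
    if chosen.size == 0:
        raise ValueError("no choices supplied")
    out = np.zeros(n_questions + 1)
    for j in chosen:
        out[n_questions if j == NO_QUESTION else j] += 1
    return out / chosen.size
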