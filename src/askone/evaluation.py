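"""Leave-one-out evaluation, AUC, and the paired Friedman comparison.

The pipeline's accuracy is estimated by leave-one-out: for each child the
vocabulary, text tree, augmented trees and selection trees are all refit on
the remaining children (no leakage), the held-out child's question (if any)
is chosen, and the final score recorded. Held-out scores are pooled and
ranked together for a single AUC per outcome (per-fold AUC is undefined for
single examples).

The text-only versus text-plus-question comparison across outcomes uses the
Friedman rank test, implemented here because the two-method case (k = 2) is
needed; an exact within-block permutation p-value is available as an option.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_auc_score

from .selection import NO_QUESTION, QuestionSelector
from .text import TextFeaturizer, tokenize

__all__ = [
    "auc",
    "friedman_test",
    "loo_evaluate",
    "selection_tree_cv_auc",
    "summarize_loo",
]


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling.

    Equals the probability that a random positive outranks a random
    negative, counting ties as one half.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def friedman_test(
    matrix,
    method: str = "chi2",
    max_exact: int = 200_000,
    n_permutations: int = 20_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Friedman rank test over a blocks x methods matrix.

    Uses midranks within blocks and the tie-corrected chi-square statistic
    (df = k - 1). ``method="permutation"`` instead computes the p-value by
    permuting values within blocks — exact when the number of arrangements
    is at most ``max_exact``, Monte Carlo otherwise.

    Degenerate input (every block completely tied, e.g. identical columns)
    yields statistic 0 and p = 1 with a warning.
    """
    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 blocks and 2 methods")
    n, k = X.shape

    def statistic(M: np.ndarray) -> float:
        ranks = np.apply_along_axis(scipy.stats.rankdata, 1, M)
        col_sums = ranks.sum(axis=0)
        denom = (ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0
        if denom <= 0:
            return np.nan
        return float((k - 1) * ((col_sums - n * (k + 1) / 2.0) ** 2).sum() / denom)

    stat = statistic(X)
    if np.isnan(stat):
        warnings.warn(
            "Friedman test degenerate: all blocks completely tied; p = 1",
            stacklevel=2,
        )
        return 0.0, 1.0

    if method == "chi2":
        return stat, float(scipy.stats.chi2.sf(stat, k - 1))
    if method != "permutation":
        raise ValueError("method must be 'chi2' or 'permutation'")

    n_arrangements = math.factorial(k) ** n if k < 10 else math.inf
    perms = list(itertools.permutations(range(k)))
    if n_arrangements <= max_exact:
        count = total = 0
        for combo in itertools.product(perms, repeat=n):
            M = np.array([X[i, list(p)] for i, p in enumerate(combo)])
            s = statistic(M)
            total += 1
            if not np.isnan(s) and s >= stat - 1e-12:
                count += 1
        return stat, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        M = np.array([X[i, rng.permutation(k)] for i in range(n)])
        s = statistic(M)
        if not np.isnan(s) and s >= stat - 1e-12:
            count += 1
    return stat, (count + 1) / (n_permutations + 1)


def loo_evaluate(
    texts,
    answers,
    labels,
    featurizer: TextFeaturizer | None = None,
    selector: QuestionSelector | None = None,
    adaptive: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-out evaluation of the adaptive question pipeline.

    For each held-out child the full pipeline — vocabulary, text tree,
    augmented trees, selection trees — is refit on the other children. With
    ``adaptive=False`` only the text tree is fit (text-only baseline).

    Returns a frame with one row per child: ``text_score``,
    ``chosen_question`` (0-based, -1 = none), ``answer`` given, the
    ``final_score`` used for ranking, and the true ``label``.
    """
    n = len(texts)
    if n < 3:
        raise ValueError("cohort must have at least 3 children")
    labels = np.asarray(labels, dtype=np.int64).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")
    answers = np.asarray(answers, dtype=np.float64)
    featurizer = featurizer if featurizer is not None else TextFeaturizer()
    selector = selector if selector is not None else QuestionSelector()
    selector = selector.set_params(random_state=seed)

    # Tokenize once; each fold re-derives its vocabulary from token streams.
    token_docs = [tokenize(t) if isinstance(t, str) else list(t) for t in texts]

    rows = []
    idx = np.arange(n)
    for i in range(n):
        train = idx[idx != i]
        fz = clone_featurizer(featurizer)
        Xtr = fz.fit_transform([token_docs[t] for t in train]).toarray()
        xte = fz.transform([token_docs[i]]).toarray()
        ytr = labels[train]
        if len(np.unique(ytr)) < 2:
            # single-class training fold (tiny cohorts): the selection task
            # is undefined, so fall back to the constant text-only score
            score = float(ytr.mean())
            rows.append(
                {
                    "child": i,
                    "text_score": score,
                    "chosen_question": NO_QUESTION,
                    "answer": np.nan,
                    "final_score": score,
                    "label": int(labels[i]),
                }
            )
            continue
        if adaptive:
            model = clone_selector(selector)
            model.fit(Xtr, ytr, answers[train])
            text_score = float(model.text_tree_.predict(xte)[0])
            j = int(model.choose_question(xte)[0])
            if j == NO_QUESTION:
                ans = np.nan
                final = text_score
            else:
                ans = float(answers[i, j])
                final = float(
                    model.predict_risk(xte, np.array([j]), np.array([ans]))[0]
                )
        else:
            tree = QuestionSelector(
                max_depth=selector.max_depth,
                min_samples_leaf=selector.min_samples_leaf,
                min_variance_reduction=selector.min_variance_reduction,
            )._tree()
            tree.fit(Xtr, ytr)
            text_score = float(tree.predict(xte)[0])
            j, ans, final = NO_QUESTION, np.nan, text_score
        rows.append(
            {
                "child": i,
                "text_score": text_score,
                "chosen_question": j,
                "answer": ans,
                "final_score": final,
                "label": int(labels[i]),
            }
        )
    return pd.DataFrame(rows)


def selection_tree_cv_auc(
    X,
    y,
    answers,
    question: int,
    selector: QuestionSelector | None = None,
    n_splits: int = 10,
    seed: int = 0,
) -> float:
    """K-fold CV AUC of one question's second-stage selection predictor.

    Measures how well the selection tree for ``question`` predicts its own
    training target — "would asking this question move the score the right
    way?" — on held-out children. This evaluates the second-stage predictor
    itself; the primary pipeline protocol remains leave-one-out.
    """
    from sklearn.model_selection import StratifiedKFold

    selector = selector if selector is not None else QuestionSelector()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64).ravel()
    answers = np.asarray(answers, dtype=np.float64)

    scores = np.empty(len(y))
    targets = np.empty(len(y), dtype=np.int64)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        model = clone_selector(selector)
        model.fit(X[train], y[train], answers[train])
        feats = model._question_features(X[test], question)
        scores[test] = model.selection_trees_[question].predict(feats)
        aug = model.augmented_trees_[question]
        s_true = aug.predict(model._augment(X[test], answers[test, question]))
        f1 = model.text_tree_.predict(X[test])
        from .selection import label_selection_example

        targets[test] = label_selection_example(y[test], f1, s_true)
    if len(np.unique(targets)) < 2:
        raise ValueError("selection targets are single-class under CV")
    return auc(scores, targets)


def clone_featurizer(fz: TextFeaturizer) -> TextFeaturizer:
    return TextFeaturizer(**fz.get_params())


def clone_selector(sel: QuestionSelector) -> QuestionSelector:
    return QuestionSelector(**sel.get_params())


def summarize_loo(result: pd.DataFrame, n_questions: int = 20) -> dict:
    """Pooled AUCs and question-contribution fractions from a LOO result."""
    from .selection import question_contribution_rates

    rates = question_contribution_rates(
        result["chosen_question"].to_numpy(), n_questions
    )
    return {
        "auc_text": auc(result["text_score"], result["label"]),
        "auc_final": auc(result["final_score"], result["label"]),
        "fraction_no_question": float(rates[-1]),
        "question_rates": {f"Q{j + 1}": float(rates[j]) for j in range(n_questions)},
    }
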