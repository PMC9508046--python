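"""Rank-based ROC-AUC, one-vs-one multiclass AUC, and concordance analysis."""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["binary_auc", "multiclass_ovo_auc", "concordance_analysis"]


def binary_auc(y_true, scores, positive_class=1) -> float:
    """Rank-based ROC-AUC of ``scores`` for ``positive_class``.

    Equals the Mann-Whitney U statistic divided by n_pos * n_neg; tied scores
    contribute 1/2. Invariant under strictly monotone transforms of the score.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("y_true and scores must have the same length")
    pos = y == positive_class
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("binary_auc requires both classes to be present")
    ranks = rankdata(s)  # average ranks handle ties -> 1/2 contribution
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def multiclass_ovo_auc(y_true, probabilities: pd.DataFrame) -> float:
    """One-vs-one multiclass AUC.

    For each unordered pair of classes the data are restricted to members of
    those two classes and the two directed AUCs (each class's probability
    column as score for that class) are averaged; the final value is the mean
    over all pairs. With exactly two classes this reduces to ``binary_auc``.

    Parameters
    ----------
    y_true : array-like
        True class labels.
    probabilities : DataFrame
        One column per class (column labels are the class labels), one row
        per observation.
    """
    y = np.asarray(y_true)
    classes = list(probabilities.columns)
    present = [c for c in classes if np.any(y == c)]
    if len(present) < 2:
        raise ValueError("multiclass_ovo_auc requires at least two classes present")
    pair_aucs = []
    for a, b in itertools.combinations(classes, 2):
        mask = (y == a) | (y == b)
        if not (np.any(y == a) and np.any(y == b)):
            warnings.warn(f"class pair ({a}, {b}) has an empty class; pair skipped")
            continue
        y_ab = y[mask]
        auc_a = binary_auc(y_ab, probabilities.loc[mask, a].to_numpy(), positive_class=a)
        auc_b = binary_auc(y_ab, probabilities.loc[mask, b].to_numpy(), positive_class=b)
        pair_aucs.append((auc_a + auc_b) / 2.0)
    return float(np.mean(pair_aucs))


def concordance_analysis(predictions: pd.DataFrame) -> dict[str, float]:
    """Concordance / under- / over-estimation percentages on ordinal grades.

    ``under`` counts predictions of a better (lower) grade than the clinical
    one, ``over`` a worse (higher) grade. Percentages sum to 100.
    """
    if len(predictions) == 0:
        raise ValueError("concordance_analysis requires at least one prediction")
    true = np.asarray(predictions["true_class"])
    pred = np.asarray(predictions["predicted_class"])
    n = len(true)
    return {
        "concordant_pct": 100.0 * float(np.sum(pred == true)) / n,
        "under_pct": 100.0 * float(np.sum(pred < true)) / n,
        "over_pct": 100.0 * float(np.sum(pred > true)) / n,
    }
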