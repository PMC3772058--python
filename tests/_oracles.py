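"""Naive reference implementations used as independent test oracles.

These literally transcribe the prediction rules with Python sets and full
scans, independent of the vectorized package code paths.
"""

from __future__ import annotations

import numpy as np


def oracle_predict(profiles, y, query, exclude=None):
    """Literal set-scanning implementation of the three prediction rules.

    ``profiles`` is a list of target-index sets, ``query`` a set. Returns
    (identical, lower, upper, value) with None/NaN conventions matching
    timma.core.PredictionDetail.
    """
    idx = [i for i in range(len(profiles)) if i != exclude]
    query = set(query)
    eq = [i for i in idx if set(profiles[i]) == query]
    if eq:
        val = float(np.mean([y[i] for i in eq]))
        return val, None, None, val

    subs = [i for i in idx if set(profiles[i]) <= query]
    lower = None
    if subs:
        best = max(y[i] for i in subs)
        k = min(i for i in subs if y[i] == best)  # lowest index on ties
        pool = [y[k]] + [
            y[j]
            for j in subs
            if set(profiles[j]) >= set(profiles[k]) and y[j] < y[k]
        ]
        lower = float(np.mean(pool))

    sups = [i for i in idx if set(profiles[i]) >= query]
    upper = None
    if sups:
        worst = min(y[i] for i in sups)
        k = min(i for i in sups if y[i] == worst)
        pool = [y[k]] + [
            y[j]
            for j in sups
            if set(profiles[j]) <= set(profiles[k]) and y[j] > y[k]
        ]
        upper = float(np.mean(pool))

    if lower is not None and upper is not None:
        value = (lower + upper) / 2.0
    elif lower is not None:
        value = lower
    elif upper is not None:
        value = upper
    else:
        value = float("nan")
    return None, lower, upper, value


def oracle_pkim(profiles, y, query, exclude=None):
    """Independent transcription of the probabilistic baseline rule."""
    idx = [i for i in range(len(profiles)) if i != exclude]
    query = set(query)
    subs = [i for i in idx if set(profiles[i]) <= query]
    sups = [i for i in idx if set(profiles[i]) >= query]
    if not subs or not sups:
        return float("nan")
    est = np.mean([y[i] for i in subs]) - np.mean([1.0 - y[i] for i in sups])
    return float(min(1.0, max(0.0, est)))


def profiles_from_matrix(X):
    X = np.asarray(X)
    return [set(np.flatnonzero(row)) for row in X]


def oracle_auc(scores, labels):
    """AUC by exhaustive pair counting with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_kendall_tau_b(x, y):
    """Kendall tau-b by exhaustive concordant/discordant pair counting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom
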