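"""Predicted efficacy matrices, synergy scores and synthetic-lethality scores.

Given a fitted model (binary profiles restricted to the selected target set
``S*`` plus training efficacies), this module enumerates the predicted
efficacy of every combinatorial inhibition state over ``S*``, scores target
and drug pairs for synergy against an independence null, and scores target
pairs for synthetic lethality by comparing the fit of parallel, series and
singleton pathway structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import predict_state

__all__ = [
    "EfficacyMatrix",
    "SyntheticLethalityScore",
    "enumerate_efficacy_matrix",
    "synergy_target_pair",
    "synergy_drug_pair",
    "synergy_table",
    "bliss_null",
    "synthetic_lethality_score",
    "rank_synthetic_lethal_partners",
    "roc_sensitive_drugs",
]

SYNERGY_NULLS = ("bliss", "product")


@dataclass
class EfficacyMatrix:
    """Map from target-inhibition states over ``S*`` to predicted efficacies.

    States are encoded as bitmasks over ``targets`` (bit ``i`` set = target
    ``i`` inhibited). ``values[mask]`` is the predicted efficacy, NaN for
    non-identifiable states. In ``pairwise`` mode only states of Hamming
    weight <= 2 are enumerated.
    """

    targets: tuple
    values: dict
    mode: str = "full"
    threshold: float | None = None

    def mask(self, subset) -> int:
        idx = {t: i for i, t in enumerate(self.targets)}
        m = 0
        for t in subset:
            if t not in idx:
                raise KeyError(f"unknown target {t!r}")
            m |= 1 << idx[t]
        return m

    def efficacy(self, subset) -> float:
        """Predicted efficacy of inhibiting exactly the given target subset."""
        return self.values[self.mask(subset)]

    def to_pairwise_frame(self) -> pd.DataFrame:
        """Target x target matrix: diagonal = single, off-diagonal = pairwise."""
        m = len(self.targets)
        out = np.full((m, m), np.nan)
        for i in range(m):
            out[i, i] = self.values.get(1 << i, np.nan)
            for j in range(i + 1, m):
                v = self.values.get((1 << i) | (1 << j), np.nan)
                out[i, j] = out[j, i] = v
        return pd.DataFrame(out, index=self.targets, columns=self.targets)


def enumerate_efficacy_matrix(X_S, y, targets=None, mode: str = "full") -> EfficacyMatrix:
    """Predict the efficacy of every inhibition state over the selected targets.

    ``X_S`` are the training profiles already restricted to ``S*``. In
    ``full`` mode all ``2^|S*|`` states are enumerated (guarded to
    ``|S*| <= 20``); in ``pairwise`` mode only the empty, single and
    pairwise states.
    """
    if isinstance(X_S, pd.DataFrame):
        if targets is None:
            targets = tuple(str(c) for c in X_S.columns)
        arr = X_S.to_numpy(dtype=np.int8)
    else:
        arr = np.asarray(X_S, dtype=np.int8)
        if targets is None:
            targets = tuple(range(arr.shape[1]))
    targets = tuple(targets)
    m = len(targets)
    if mode == "full":
        if m > 20:
            raise ValueError(f"full enumeration limited to 20 targets, got {m}")
        masks = range(2**m)
    elif mode == "pairwise":
        masks = [0] + [1 << i for i in range(m)] + [
            (1 << i) | (1 << j) for i, j in combinations(range(m), 2)
        ]
    else:
        raise ValueError(f"mode must be 'full' or 'pairwise', got {mode!r}")
    values = {}
    state = np.zeros(m, dtype=np.int8)
    for mask in masks:
        for i in range(m):
            state[i] = (mask >> i) & 1
        values[mask] = predict_state(arr, y, state).value
    return EfficacyMatrix(targets=targets, values=values, mode=mode)


def bliss_null(y_a: float, y_b: float) -> float:
    """Expected combination efficacy under Bliss independence.

    On the [0, 1] efficacy scale independence of the two single-target
    effects gives ``y_A + y_B - y_A * y_B`` (multiplicative on survival
    fractions).
    """
    return y_a + y_b - y_a * y_b


def synergy_target_pair(M: EfficacyMatrix, a, b, null: str = "bliss") -> float:
    """Synergy score of a target pair: observed pair efficacy minus the null.

    Positive scores indicate synergy, negative antagonism. ``null='bliss'``
    (default) uses Bliss independence; ``null='product'`` uses the pure
    product ``y_A * y_B``. NaN when any of the three efficacies is
    non-identifiable.
    """
    if null not in SYNERGY_NULLS:
        raise ValueError(f"null must be one of {SYNERGY_NULLS}, got {null!r}")
    y_a = M.efficacy([a])
    y_b = M.efficacy([b])
    y_ab = M.efficacy([a, b]) if a != b else y_a
    if any(np.isnan(v) for v in (y_a, y_b, y_ab)):
        return float("nan")
    expected = bliss_null(y_a, y_b) if null == "bliss" else y_a * y_b
    return float(y_ab - expected)


def synergy_drug_pair(M: EfficacyMatrix, T1, T2, null: str = "bliss") -> float:
    """Drug-pair synergy: mean target-pair synergy over the cross pairs.

    ``T1`` and ``T2`` are the two drugs' target sets intersected with
    ``S*``. Within-node pairs (a == b) are skipped, as are non-identifiable
    pairs; NaN when no valid pair remains.
    """
    T1, T2 = list(T1), list(T2)
    if not T1 or not T2:
        raise ValueError("drug target sets must be non-empty within S*")
    scores = [
        synergy_target_pair(M, a, b, null=null) for a in T1 for b in T2 if a != b
    ]
    scores = [s for s in scores if not np.isnan(s)]
    return float(np.mean(scores)) if scores else float("nan")


def synergy_table(M: EfficacyMatrix, null: str = "bliss") -> pd.DataFrame:
    """All target-pair synergy scores as a tidy symmetric table."""
    rows = []
    for a, b in combinations(M.targets, 2):
        rows.append(
            {
                "target_a": a,
                "target_b": b,
                "efficacy_a": M.efficacy([a]),
                "efficacy_b": M.efficacy([b]),
                "efficacy_ab": M.efficacy([a, b]),
                "synergy": synergy_target_pair(M, a, b, null=null),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SyntheticLethalityScore:
    """Structural-model comparison for one target pair.

    Drugs are grouped by their inhibition state over the pair (00, 01, 10,
    11) and each candidate pathway structure pools these states; the fit of
    a structure is the within-group total sum of squares (TSS) of the drug
    efficacies. ``score = min(TSS_series, TSS_singleton) / TSS_parallel``:
    the larger the score, the better the parallel (AND) structure explains
    the data relative to its competitors, i.e. the stronger the synthetic
    lethality. ``inf`` when the parallel model fits perfectly.
    """

    pair: tuple
    tss_parallel: float
    tss_series: float
    tss_singleton: float
    score: float
    reason: str | None = None


def _pooled_tss(y: np.ndarray, groups) -> float | None:
    """Within-group sum of squared deviations; None if a group is empty."""
    tss = 0.0
    for g in groups:
        if not g.any():
            return None
        v = y[g]
        tss += float(((v - v.mean()) ** 2).sum())
    return tss


def synthetic_lethality_score(X, y, a, b) -> SyntheticLethalityScore:
    """Score the target pair (a, b) for synthetic lethality.

    Structures compared (state groups pooled over drugs):

    * parallel: {11} vs {00, 01, 10} -- only joint inhibition is lethal;
    * series:   {01, 10, 11} vs {00} -- either single inhibition suffices;
    * singleton: the better of splitting on A alone or on B alone.
    """
    if isinstance(X, pd.DataFrame):
        xa = X[a].to_numpy(dtype=np.int8)
        xb = X[b].to_numpy(dtype=np.int8)
    else:
        arr = np.asarray(X, dtype=np.int8)
        xa, xb = arr[:, a], arr[:, b]
    y = np.asarray(y, dtype=float)
    both = (xa == 1) & (xb == 1)

    tss_par = _pooled_tss(y, [both, ~both])
    tss_ser = _pooled_tss(y, [(xa == 1) | (xb == 1), (xa == 0) & (xb == 0)])
    tss_a = _pooled_tss(y, [xa == 1, xa == 0])
    tss_b = _pooled_tss(y, [xb == 1, xb == 0])
    singles = [t for t in (tss_a, tss_b) if t is not None]
    tss_single = min(singles) if singles else None

    if tss_par is None or tss_ser is None or tss_single is None:
        return SyntheticLethalityScore(
            pair=(a, b),
            tss_parallel=np.nan if tss_par is None else tss_par,
            tss_series=np.nan if tss_ser is None else tss_ser,
            tss_singleton=np.nan if tss_single is None else tss_single,
            score=float("nan"),
            reason="empty inhibition-state group",
        )
    if tss_par == 0.0:
        score = float("inf")
    else:
        score = min(tss_ser, tss_single) / tss_par
    return SyntheticLethalityScore(
        pair=(a, b),
        tss_parallel=tss_par,
        tss_series=tss_ser,
        tss_singleton=tss_single,
        score=float(score),
    )


def rank_synthetic_lethal_partners(X, y, anchor) -> pd.DataFrame:
    """Rank targets by synthetic-lethality score with a fixed anchor target.

    The baseline is the (anchor, anchor) self-pair; only partners scoring
    strictly above the baseline are returned, ranked with ties sharing a
    rank (targets inhibited by the same drug set score identically).
    """
    if isinstance(X, pd.DataFrame):
        targets = [str(c) for c in X.columns]
        if str(anchor) not in targets:
            raise KeyError(f"anchor target {anchor!r} not in matrix")
    else:
        targets = list(range(np.asarray(X).shape[1]))
    baseline = synthetic_lethality_score(X, y, anchor, anchor)
    rows = []
    for t in targets:
        if t == anchor:
            continue
        s = synthetic_lethality_score(X, y, anchor, t)
        rows.append({"target": t, "score": s.score, "reason": s.reason})
    df = pd.DataFrame(rows)
    df["baseline"] = baseline.score
    above = df[df["score"] > baseline.score].copy()
    above = above.sort_values("score", ascending=False, kind="stable")
    above["rank"] = (
        above["score"].rank(method="min", ascending=False).astype(int)
    )
    return above.reset_index(drop=True)


def roc_sensitive_drugs(predictions, labels):
    """ROC curve and AUC for classifying sensitive drugs from predictions.

    Predictions pooled across binarization thresholds can be passed
    directly. Ties are handled by the midrank convention (identical
    predictions for all drugs give AUC 0.5). Returns
    ``(fpr, tpr, thresholds, auc)``.
    """
    from sklearn.metrics import roc_auc_score, roc_curve

    labels = np.asarray(labels)
    predictions = np.asarray(predictions, dtype=float)
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must contain exactly two classes")
    fpr, tpr, thr = roc_curve(labels, predictions)
    auc = float(roc_auc_score(labels, predictions))
    return fpr, tpr, thr, auc
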