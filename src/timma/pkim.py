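"""Probabilistic kinase inhibition map (PKIM) baseline predictor.

PKIM is the predecessor set-theoretic predictor (Pal & Berlow) used here as
the comparison baseline. Its estimate for a queried target-inhibition state
is the treatment efficacy accumulated from training drugs whose profiles are
subsets of the query, relative to the loss of efficacy observed in its
superset profiles; the published algebra is not reproduced verbatim, so this
module implements the verbal semantics as

``estimate = mean(y | profile subset of query) - mean(1 - y | profile
superset of query)``, clipped to [0, 1],

with subset/superset taken non-strictly. The estimate requires *both*
families to be non-empty; otherwise PKIM is non-determinable (NaN). This
re-implementation is validated for internal consistency against a second,
literal set-scanning coding in the test suite.
"""

from __future__ import annotations

import numpy as np

from .core import _as_binary_array, apply_na_policy, subset_relations

__all__ = ["pkim_predict", "pkim_loo_predictions", "greedy_select"]


def pkim_predict(X, y, state, exclude: int | None = None) -> float:
    """PKIM estimate for one inhibition state; NaN when non-determinable."""
    arr = _as_binary_array(X)
    y = np.asarray(y, dtype=float)
    q = np.asarray(state, dtype=np.int8)
    if q.shape != (arr.shape[1],):
        raise ValueError(
            f"state has {q.size} entries but the model has {arr.shape[1]} targets"
        )
    keep = np.ones(arr.shape[0], dtype=bool)
    if exclude is not None:
        keep[exclude] = False
    arr, y = arr[keep], y[keep]
    is_sub = (arr <= q).all(axis=1)
    is_sup = (arr >= q).all(axis=1)
    if not is_sub.any() or not is_sup.any():
        return float("nan")
    estimate = y[is_sub].mean() - (1.0 - y[is_sup]).mean()
    return float(np.clip(estimate, 0.0, 1.0))


def pkim_loo_predictions(subof: np.ndarray, y) -> np.ndarray:
    """Vectorized leave-one-out PKIM predictions (NaN where non-determinable)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    off = ~np.eye(n, dtype=bool)
    Sub = subof.T & off  # Sub[i, j]: profile j subset of profile i (the query)
    Sup = subof & off
    n_sub = Sub.sum(axis=1)
    n_sup = Sup.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        est = (Sub @ y) / n_sub - (Sup @ (1.0 - y)) / n_sup
    pred = np.clip(est, 0.0, 1.0)
    pred[(n_sub == 0) | (n_sup == 0)] = np.nan
    return pred


def greedy_select(
    X,
    y,
    max_k: int | None = None,
    rule: str = "pkim",
    na_policy: str = "midpoint",
    tol: float = 1e-12,
):
    """Strictly-forward greedy target selection (the PKIM search strategy).

    Starts from the best single target by LOO error and keeps adding the
    best-improving target until no addition strictly decreases the error
    (or ``max_k`` is reached). Greedy search cannot revisit earlier
    decisions and may get trapped in local optima; it serves as the
    baseline against the floating search in :mod:`timma.selection`.

    Returns a :class:`timma.selection.SelectionResult`.
    """
    from .selection import _forward_search

    return _forward_search(
        X, y, rule=rule, max_k=max_k, na_policy=na_policy, tol=tol, floating=False
    )
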