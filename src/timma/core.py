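"""Set-theoretic efficacy prediction engine.

The engine predicts the anticancer efficacy of an arbitrary target-inhibition
state from a panel of training drugs with known binary inhibition profiles
and scaled efficacies. Three rules are applied in order of precedence:

identical-set rule
    If one or more training drugs inhibit exactly the queried target set,
    the prediction is the mean of their efficacies.

maximization (lower-bound) rule
    Among training drugs whose profiles are *subsets* of the query, take the
    drug ``k_max`` with the highest efficacy. Its efficacy is averaged with
    the efficacies of other subset-profile drugs that are supersets of
    ``T(k_max)`` yet less efficacious, yielding a lower bound: inhibiting a
    superset of a successful drug's targets cannot be less effective.

minimization (upper-bound) rule
    Symmetrically, among superset-profile drugs take the least efficacious
    drug ``k_min`` and average in superset-profile drugs that are subsets of
    ``T(k_min)`` with higher efficacy, yielding an upper bound: inhibiting a
    subset of an unsuccessful drug's targets cannot be more effective.

When both bounds exist the prediction is their average; with a single bound
the prediction equals that bound; with neither the state is non-identifiable
(NaN). Ties in the ``k_max``/``k_min`` choice are broken by the lowest drug
index, and all averaging is a single arithmetic mean over the qualifying
drugs, which makes predictions independent of drug ordering for tie-free
efficacies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PredictionDetail",
    "subset_relations",
    "extend_relations",
    "predict_state",
    "timma_loo_predictions",
    "loo_error",
    "apply_na_policy",
]

NA_POLICIES = ("midpoint", "skip", "worst")


@dataclass(frozen=True)
class PredictionDetail:
    """Full account of a single-state efficacy prediction.

    ``identical`` is the identical-set estimate (rule of first precedence);
    ``lower``/``upper`` are the maximization/minimization bounds. ``value``
    is the final prediction, NaN when the state is non-identifiable.
    """

    identical: float | None
    lower: float | None
    upper: float | None
    value: float

    @property
    def identifiable(self) -> bool:
        return not np.isnan(self.value)


def _as_binary_array(X) -> np.ndarray:
    raw = np.asarray(X)
    if raw.ndim != 2:
        raise ValueError("X must be a 2-D drugs x targets matrix")
    arr = raw.astype(np.int8)
    if not np.array_equal(arr, raw) or not np.isin(arr, (0, 1)).all():
        raise ValueError("X must be binary (0/1)")
    return arr


def subset_relations(X) -> np.ndarray:
    """Pairwise subset relations between drug profiles.

    Returns a boolean matrix ``R`` with ``R[a, b]`` true iff profile ``a``
    is a subset of (or equal to) profile ``b``. Computed by one integer
    matrix product: ``a`` is a subset of ``b`` iff no target is inhibited by
    ``a`` but not ``b``.
    """
    arr = _as_binary_array(X).astype(np.int32)
    violations = arr @ (1 - arr).T
    return violations == 0


def extend_relations(subof: np.ndarray, col) -> np.ndarray:
    """Subset relations after appending one target column to the profile set.

    ``a`` remains a subset of ``b`` under ``S + {t}`` iff it was under ``S``
    and ``x_a[t] <= x_b[t]``. This is the incremental update used during
    forward selection; it equals recomputation from scratch.
    """
    c = np.asarray(col, dtype=np.int8)
    return subof & (c[:, None] <= c[None, :])


def predict_state(X, y, state, exclude: int | None = None) -> PredictionDetail:
    """Predict the efficacy of one target-inhibition ``state``.

    Parameters
    ----------
    X : (n_drugs, n_targets) binary array
        Training inhibition profiles (already restricted to the selected
        target set).
    y : (n_drugs,) array
        Scaled training efficacies.
    state : (n_targets,) binary array
        Queried inhibition state over the same targets.
    exclude : int, optional
        Index of one training drug to leave out (for LOO evaluation).
    """
    arr = _as_binary_array(X)
    y = np.asarray(y, dtype=float)
    q = np.asarray(state, dtype=np.int8)
    if q.shape != (arr.shape[1],):
        raise ValueError(
            f"state has {q.size} entries but the model has {arr.shape[1]} targets"
        )
    if not np.isin(q, (0, 1)).all():
        raise ValueError("state must be binary (0/1)")
    keep = np.ones(arr.shape[0], dtype=bool)
    if exclude is not None:
        keep[exclude] = False
    arr, y = arr[keep], y[keep]

    eq = (arr == q).all(axis=1)
    if eq.any():
        val = float(y[eq].mean())
        return PredictionDetail(identical=val, lower=None, upper=None, value=val)

    is_sub = (arr <= q).all(axis=1)  # profile subset of query
    is_sup = (arr >= q).all(axis=1)  # profile superset of query

    lower = None
    if is_sub.any():
        sub_idx = np.flatnonzero(is_sub)
        k = sub_idx[int(np.argmax(y[sub_idx]))]  # ties -> lowest index
        qual = is_sub & (arr >= arr[k]).all(axis=1) & (y < y[k])
        lower = float((y[k] + y[qual].sum()) / (1 + int(qual.sum())))

    upper = None
    if is_sup.any():
        sup_idx = np.flatnonzero(is_sup)
        k = sup_idx[int(np.argmin(y[sup_idx]))]
        qual = is_sup & (arr <= arr[k]).all(axis=1) & (y > y[k])
        upper = float((y[k] + y[qual].sum()) / (1 + int(qual.sum())))

    if lower is not None and upper is not None:
        value = 0.5 * (lower + upper)
    elif lower is not None:
        value = lower
    elif upper is not None:
        value = upper
    else:
        value = float("nan")
    return PredictionDetail(identical=None, lower=lower, upper=upper, value=value)


def timma_loo_predictions(subof: np.ndarray, y) -> np.ndarray:
    """Leave-one-out predictions for every training drug, vectorized.

    ``subof`` is the pairwise relation matrix from :func:`subset_relations`
    for the profiles restricted to the selected target set. Returns one
    prediction per drug (NaN where non-identifiable), each computed with
    that drug held out.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    eq = subof & subof.T
    np.fill_diagonal(eq, False)
    # Sub[i, j]: profile j is a subset of query (= profile of drug i); Sup symmetric.
    Sub = subof.T & ~np.eye(n, dtype=bool)
    Sup = subof & ~np.eye(n, dtype=bool)

    pred = np.full(n, np.nan)
    has_eq = eq.any(axis=1)
    if has_eq.any():
        pred[has_eq] = (eq @ y)[has_eq] / eq.sum(axis=1)[has_eq]

    rest = ~has_eq
    if not rest.any():
        return pred

    sub_any = Sub.any(axis=1)
    sup_any = Sup.any(axis=1)

    # Lower bound (maximization rule): argmax over subset profiles.
    ymask = np.where(Sub, y, -np.inf)
    k_max = ymask.argmax(axis=1)  # first occurrence on ties -> lowest index
    y_k = y[k_max]
    # qualifying j: subset of query, superset of profile(k_max), lower efficacy
    qual = Sub & subof[k_max, :] & (y[None, :] < y_k[:, None])
    lower = (qual @ y + y_k) / (qual.sum(axis=1) + 1)

    # Upper bound (minimization rule): argmin over superset profiles.
    ymask = np.where(Sup, y, np.inf)
    k_min = ymask.argmin(axis=1)
    y_k = y[k_min]
    qual = Sup & subof.T[k_min, :] & (y[None, :] > y_k[:, None])
    upper = (qual @ y + y_k) / (qual.sum(axis=1) + 1)

    both = rest & sub_any & sup_any
    pred[both] = 0.5 * (lower[both] + upper[both])
    lo_only = rest & sub_any & ~sup_any
    pred[lo_only] = lower[lo_only]
    up_only = rest & ~sub_any & sup_any
    pred[up_only] = upper[up_only]
    return pred


def apply_na_policy(pred: np.ndarray, y, na_policy: str = "midpoint") -> np.ndarray:
    """Per-drug absolute LOO errors under a policy for non-identifiable drugs.

    ``midpoint``: a non-identifiable prediction contributes ``|y - 0.5|``
    (the maximally uninformative guess); ``worst``: contributes 1;
    ``skip``: contributes nothing (dropped from the average).
    """
    y = np.asarray(y, dtype=float)
    errs = np.abs(pred - y)
    na = np.isnan(pred)
    if na_policy == "midpoint":
        errs[na] = np.abs(y[na] - 0.5)
    elif na_policy == "worst":
        errs[na] = 1.0
    elif na_policy == "skip":
        errs = errs[~na]
        if errs.size == 0:
            return np.array([np.nan])
    else:
        raise ValueError(f"na_policy must be one of {NA_POLICIES}, got {na_policy!r}")
    return errs


def loo_error(
    X=None,
    y=None,
    *,
    subof: np.ndarray | None = None,
    rule: str = "timma",
    na_policy: str = "midpoint",
) -> float:
    """Mean absolute leave-one-out prediction error over all drugs.

    This is the model-selection objective: each drug's efficacy is predicted
    from the remaining drugs and the absolute errors are averaged. Pass a
    precomputed relation matrix via ``subof`` to avoid recomputation during
    selection sweeps.
    """
    if subof is None:
        if X is None:
            raise ValueError("either X or subof must be given")
        subof = subset_relations(X)
    y = np.asarray(y, dtype=float)
    if y.size != subof.shape[0]:
        raise ValueError("y length does not match the number of drugs")
    if y.size < 2:
        raise ValueError("LOO evaluation needs at least 2 drugs")
    if rule == "timma":
        pred = timma_loo_predictions(subof, y)
    elif rule == "pkim":
        from .pkim import pkim_loo_predictions

        pred = pkim_loo_predictions(subof, y)
    else:
        raise ValueError(f"rule must be 'timma' or 'pkim', got {rule!r}")
    return float(np.mean(apply_na_policy(pred, y, na_policy)))
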