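"""Cancer-specific target-set selection.

The selection objective is the mean absolute leave-one-out (LOO) prediction
error of the model restricted to a candidate target set. Three search
strategies are provided:

* :func:`sffs_select` -- modified sequential forward floating search (SFFS):
  forward inclusion of the error-minimizing target, followed by conditional
  backward exclusion steps that are kept only when they strictly beat the
  best error previously achieved at the smaller cardinality. Floating
  exclusions let the search revisit smaller set sizes and escape the local
  optima that trap purely greedy search.
* :func:`exhaustive_select` -- global optimum by enumeration (small
  candidate pools only); the oracle for optimality experiments.
* :func:`timma.pkim.greedy_select` -- strictly-forward greedy baseline.

All strategies share tie-breaking by lowest column index and a strict
improvement criterion with absolute tolerance 1e-12 to avoid floating-point
livelock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import extend_relations, loo_error, subset_relations

__all__ = [
    "SelectionResult",
    "SelectionDistribution",
    "sffs_select",
    "exhaustive_select",
    "selection_ci",
]

_TOL = 1e-12
_MAX_MOVES = 100_000


@dataclass
class SelectionResult:
    """Outcome of one target-selection run.

    ``selected`` holds target names (or column indices for plain arrays),
    ``loo_error`` the objective value of the selected set, ``trace`` the
    ordered list of accepted moves ``(action, target, error)``, and
    ``best_by_cardinality`` the best error seen at each set size during the
    whole run.
    """

    selected: tuple
    loo_error: float
    trace: list = field(default_factory=list)
    best_by_cardinality: dict = field(default_factory=dict)

    @property
    def selected_indices(self) -> tuple:
        return tuple(self._indices) if hasattr(self, "_indices") else self.selected


@dataclass
class SelectionDistribution:
    """Results of repeated selection runs from random starts."""

    results: list
    mean_error: float
    ci_low: float
    ci_high: float


def _prepare(X, candidates):
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        arr = X.to_numpy(dtype=np.int8)
    else:
        arr = np.asarray(X, dtype=np.int8)
        names = list(range(arr.shape[1]))
    if candidates is None:
        cand = list(range(arr.shape[1]))
    else:
        if isinstance(X, pd.DataFrame) and candidates and isinstance(
            next(iter(candidates)), str
        ):
            lookup = {n: i for i, n in enumerate(names)}
            cand = [lookup[c] for c in candidates]
        else:
            cand = [int(c) for c in candidates]
    return arr, names, cand


def _objective_factory(arr, y, rule, na_policy):
    y = np.asarray(y, dtype=float)
    cache: dict[frozenset, float] = {}

    def objective(cols: tuple, subof=None) -> float:
        key = frozenset(cols)
        if key in cache:
            return cache[key]
        if subof is None:
            subof = subset_relations(arr[:, list(cols)])
        err = loo_error(y=y, subof=subof, rule=rule, na_policy=na_policy)
        cache[key] = err
        return err

    return objective


def _forward_search(
    X,
    y,
    rule: str = "timma",
    start=None,
    max_k: int | None = None,
    candidates=None,
    na_policy: str = "midpoint",
    tol: float = _TOL,
    floating: bool = True,
) -> SelectionResult:
    """Shared forward-selection engine (floating=True gives SFFS)."""
    arr, names, cand = _prepare(X, candidates)
    if not cand:
        raise ValueError("no candidate targets")
    if max_k is None:
        max_k = min(len(cand), 64)
    objective = _objective_factory(arr, y, rule, na_policy)

    trace: list[tuple] = []
    best_by_card: dict[int, float] = {}

    def record_best(k: int, err: float):
        if err < best_by_card.get(k, np.inf):
            best_by_card[k] = err

    # Initialization: best single target (exhaustive over singletons).
    if start is not None:
        _, _, start_idx = _prepare(X, start)
        S = list(start_idx)
        err = objective(tuple(S))
    else:
        singles = [(objective((t,)), t) for t in cand]
        err, t0 = min(singles, key=lambda p: (p[0], p[1]))
        for e1, t in singles:
            record_best(1, e1)
        S = [t0]
    record_best(len(S), err)
    trace.append(("init", tuple(names[t] for t in S), err))
    best_S, best_err = list(S), err

    # Cached subset relations for the current S, updated incrementally on
    # inclusion; equals from-scratch recomputation (asserted in tests).
    subof_S = subset_relations(arr[:, S])

    moves = 0
    while True:
        moves += 1
        if moves > _MAX_MOVES:
            raise RuntimeError("selection did not terminate (move limit reached)")
        # --- Inclusion ---
        if len(S) >= max_k:
            break
        remaining = [t for t in cand if t not in S]
        if not remaining:
            break
        scored = []
        for t in remaining:
            sub_t = extend_relations(subof_S, arr[:, t])
            scored.append((objective(tuple(S) + (t,), subof=sub_t), t, sub_t))
        e_inc, t_inc, sub_inc = min(scored, key=lambda p: (p[0], p[1]))
        if not e_inc < err - tol:
            break
        S.append(t_inc)
        subof_S = sub_inc
        err = e_inc
        record_best(len(S), err)
        trace.append(("include", names[t_inc], err))
        if err < best_err:
            best_S, best_err = list(S), err

        if not floating:
            continue

        # --- Conditional exclusion ---
        if len(S) < 2:
            continue
        excl = [(objective(tuple(v for v in S if v != r)), r) for r in S]
        e_r, r = min(excl, key=lambda p: (p[0], p[1]))
        if r == t_inc:
            continue
        if e_r < best_by_card.get(len(S) - 1, np.inf) - tol:
            S.remove(r)
            err = e_r
            subof_S = subset_relations(arr[:, S])
            record_best(len(S), err)
            trace.append(("exclude", names[r], err))
            if err < best_err:
                best_S, best_err = list(S), err
            # --- Continuation of conditional exclusion ---
            while len(S) >= 2:
                excl = [(objective(tuple(v for v in S if v != r2)), r2) for r2 in S]
                e_r2, r2 = min(excl, key=lambda p: (p[0], p[1]))
                if e_r2 < best_by_card.get(len(S) - 1, np.inf) - tol:
                    S.remove(r2)
                    err = e_r2
                    subof_S = subset_relations(arr[:, S])
                    record_best(len(S), err)
                    trace.append(("exclude", names[r2], err))
                    if err < best_err:
                        best_S, best_err = list(S), err
                else:
                    break

    result = SelectionResult(
        selected=tuple(names[t] for t in best_S),
        loo_error=float(best_err),
        trace=trace,
        best_by_cardinality=dict(sorted(best_by_card.items())),
    )
    result._indices = tuple(best_S)
    return result


def sffs_select(
    X,
    y,
    rule: str = "timma",
    start=None,
    max_k: int | None = None,
    candidates=None,
    na_policy: str = "midpoint",
    tol: float = _TOL,
) -> SelectionResult:
    """Select a target set by sequential forward floating search.

    Parameters
    ----------
    X : DataFrame or array (n_drugs, n_targets), binary
    y : array of scaled efficacies
    rule : "timma" or "pkim"
        Prediction rule used inside the LOO objective.
    start : optional initial target set (default: best single target)
    max_k : maximal set size (default min(n_targets, 64))
    candidates : optional restriction of the candidate target pool
    """
    return _forward_search(
        X,
        y,
        rule=rule,
        start=start,
        max_k=max_k,
        candidates=candidates,
        na_policy=na_policy,
        tol=tol,
        floating=True,
    )


def exhaustive_select(
    X,
    y,
    candidates=None,
    max_k: int | None = None,
    rule: str = "timma",
    na_policy: str = "midpoint",
) -> SelectionResult:
    """Globally optimal target set by enumeration of all non-empty subsets.

    Guarded to candidate pools of at most 20 targets; use
    :func:`sffs_select` beyond that.
    """
    arr, names, cand = _prepare(X, candidates)
    if len(cand) > 20:
        raise ValueError(
            f"{len(cand)} candidates: exhaustive enumeration is limited to 20 "
            "targets; use sffs_select instead"
        )
    if max_k is None:
        max_k = len(cand)
    objective = _objective_factory(arr, y, rule, na_policy)
    best_err, best_set = np.inf, None
    best_by_card: dict[int, float] = {}
    for k in range(1, max_k + 1):
        for cols in combinations(cand, k):
            e = objective(cols)
            if e < best_by_card.get(k, np.inf):
                best_by_card[k] = e
            if e < best_err:
                best_err, best_set = e, cols
    result = SelectionResult(
        selected=tuple(names[t] for t in best_set),
        loo_error=float(best_err),
        trace=[("init", tuple(names[t] for t in best_set), float(best_err))],
        best_by_cardinality=best_by_card,
    )
    result._indices = tuple(best_set)
    return result


def selection_ci(
    X,
    y,
    n_starts: int = 50,
    seed: int | None = None,
    rule: str = "timma",
    max_k: int | None = None,
    na_policy: str = "midpoint",
) -> SelectionDistribution:
    """Empirical distribution of SFFS results from random single-target starts.

    Used to derive confidence intervals for the selected-model error; the
    same seed reproduces the same distribution exactly.
    """
    arr, names, cand = _prepare(X, None)
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(cand), size=n_starts)
    results = [
        sffs_select(
            X, y, rule=rule, start=[cand[s]], max_k=max_k, na_policy=na_policy
        )
        for s in starts
    ]
    errors = np.array([r.loo_error for r in results])
    lo, hi = np.percentile(errors, [2.5, 97.5])
    return SelectionDistribution(
        results=results,
        mean_error=float(errors.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
    )
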