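"""Scikit-learn style estimators wrapping the prediction engine and selection.

:class:`TimmaRegressor` is the primary model: it selects a cancer-specific
target set minimizing the mean leave-one-out error (floating search by
default) and predicts the efficacy of arbitrary binary inhibition profiles
with the identical-set / maximization / minimization rules.
:class:`PkimRegressor` is the probabilistic baseline with greedy selection.
Both compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import core, pkim, selection

__all__ = ["TimmaRegressor", "PkimRegressor"]


class _SetRuleRegressor(RegressorMixin, BaseEstimator):
    """Shared fit/predict machinery for the set-theoretic rule regressors."""

    _rule: str = ""

    def __init__(
        self,
        select: str | None = "sffs",
        max_targets: int | None = None,
        na_policy: str = "midpoint",
        na_fill: float = 0.5,
    ):
        self.select = select
        self.max_targets = max_targets
        self.na_policy = na_policy
        self.na_fill = na_fill

    def _validate_X(self, X, fit: bool):
        if isinstance(X, pd.DataFrame):
            names = np.asarray([str(c) for c in X.columns], dtype=object)
            arr = X.to_numpy()
        else:
            arr = np.asarray(X)
            names = None
        raw = np.asarray(arr)
        if raw.ndim != 2:
            raise ValueError("X must be 2-D (drugs x targets)")
        arr = raw.astype(np.int8)
        if not np.array_equal(arr, raw) or not np.isin(arr, (0, 1)).all():
            raise ValueError("X must be a binary inhibition matrix")
        if fit:
            self.n_features_in_ = arr.shape[1]
            if names is not None:
                self.feature_names_in_ = names
        elif arr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {arr.shape[1]} targets, expected {self.n_features_in_}"
            )
        return arr

    def fit(self, X, y):
        """Select the target set (per ``select``) and store the training panel."""
        arr = self._validate_X(X, fit=True)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != arr.shape[0]:
            raise ValueError("X and y have different numbers of drugs")
        if np.nanmin(y) < 0 or np.nanmax(y) > 1:
            raise ValueError("y must hold scaled efficacies in [0, 1]")
        if self.select is None:
            idx = tuple(range(arr.shape[1]))
            err = core.loo_error(
                arr, y, rule=self._rule, na_policy=self.na_policy
            )
            result = None
        else:
            if self.select == "sffs":
                result = selection.sffs_select(
                    arr, y, rule=self._rule, max_k=self.max_targets,
                    na_policy=self.na_policy,
                )
            elif self.select == "greedy":
                result = pkim.greedy_select(
                    arr, y, rule=self._rule, max_k=self.max_targets,
                    na_policy=self.na_policy,
                )
            elif self.select == "exhaustive":
                result = selection.exhaustive_select(
                    arr, y, rule=self._rule, max_k=self.max_targets,
                    na_policy=self.na_policy,
                )
            else:
                raise ValueError(
                    "select must be 'sffs', 'greedy', 'exhaustive' or None"
                )
            idx = result.selected_indices
            err = result.loo_error
        self.selected_idx_ = tuple(int(i) for i in idx)
        if hasattr(self, "feature_names_in_"):
            self.selected_targets_ = tuple(
                self.feature_names_in_[i] for i in self.selected_idx_
            )
        else:
            self.selected_targets_ = self.selected_idx_
        self.loo_error_ = float(err)
        self.selection_result_ = result
        self.X_ = arr[:, list(self.selected_idx_)]
        self.y_ = y
        return self

    def _predict_row(self, state: np.ndarray) -> float:
        raise NotImplementedError

    def predict(self, X):
        """Predicted efficacy for each row's inhibition profile.

        Profiles are restricted to the selected target set;
        non-identifiable states are filled with ``na_fill``.
        """
        check_is_fitted(self, "X_")
        arr = self._validate_X(X, fit=False)
        states = arr[:, list(self.selected_idx_)]
        out = np.array([self._predict_row(s) for s in states])
        out[np.isnan(out)] = self.na_fill
        return out


class TimmaRegressor(_SetRuleRegressor):
    """Efficacy regressor using identical-set, maximization and minimization rules.

    Parameters
    ----------
    select : {'sffs', 'greedy', 'exhaustive', None}, default 'sffs'
        Target-selection strategy minimizing the LOO error; None keeps all
        targets.
    max_targets : int, optional
        Upper bound on the selected set size.
    na_policy : {'midpoint', 'skip', 'worst'}
        Contribution of non-identifiable LOO predictions to the selection
        objective.
    na_fill : float, default 0.5
        Value returned by :meth:`predict` for non-identifiable states.

    Attributes
    ----------
    selected_targets_ : tuple
        Selected target names (column indices for plain arrays).
    loo_error_ : float
        Mean absolute LOO error of the selected model.
    """

    _rule = "timma"

    def _predict_row(self, state):
        return core.predict_state(self.X_, self.y_, state).value

    def predict_detail(self, subset_or_state) -> core.PredictionDetail:
        """Full :class:`~timma.core.PredictionDetail` for one state.

        Accepts either a binary state vector over the selected targets or a
        collection of selected-target names.
        """
        check_is_fitted(self, "X_")
        state = np.asarray(subset_or_state)
        if state.dtype.kind not in "biu":
            members = set(map(str, subset_or_state))
            unknown = members - set(map(str, self.selected_targets_))
            if unknown:
                raise KeyError(f"unknown target(s): {sorted(unknown)}")
            state = np.array(
                [1 if str(t) in members else 0 for t in self.selected_targets_],
                dtype=np.int8,
            )
        return core.predict_state(self.X_, self.y_, state)

    def efficacy_matrix(self, mode: str = "full"):
        """Enumerate the predicted efficacy matrix over the selected targets."""
        from .scoring import enumerate_efficacy_matrix

        check_is_fitted(self, "X_")
        return enumerate_efficacy_matrix(
            self.X_, self.y_, targets=self.selected_targets_, mode=mode
        )


class PkimRegressor(_SetRuleRegressor):
    """Probabilistic baseline regressor (subset/superset averaging rule).

    Non-determinable states (missing subset or superset family) predict
    ``na_fill``. Defaults to the strictly-forward greedy selection this
    baseline was historically paired with.
    """

    _rule = "pkim"

    def __init__(
        self,
        select: str | None = "greedy",
        max_targets: int | None = None,
        na_policy: str = "midpoint",
        na_fill: float = 0.5,
    ):
        super().__init__(
            select=select, max_targets=max_targets, na_policy=na_policy,
            na_fill=na_fill,
        )

    def _predict_row(self, state):
        return pkim.pkim_predict(self.X_, self.y_, state)
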