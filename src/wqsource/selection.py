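"""Minimal-parameter WQI surrogate models (WQI_min selection).

Parameters are ranked by forest feature importance; nested prefix subsets
of size k are then used to fit fresh forests predicting the WQI, and each
sub-model is scored on a shared held-out split.  The report mirrors the
usual selection-table layout: parameter subset, cumulative feature
importance (the subset's summed importance from the all-parameter model),
and R^2 / MSE / MAE / MAPE on the test split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .forest import (
    Forest,
    ImportanceVector,
    Metrics,
    TreeParams,
    feature_importance,
    fit_forest,
    regression_metrics,
    split_indices,
)

__all__ = ["SelectionReport", "rank_parameters", "build_wqimin_models", "select_best"]


@dataclass
class SelectionReport:
    ranking: tuple[str, ...]
    importance: ImportanceVector
    rows: pd.DataFrame          # one row per subset, plus the all-parameter reference
    chosen: tuple[str, ...] | None = None

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def rank_parameters(importance: ImportanceVector) -> tuple[str, ...]:
    """Parameters in descending importance; ties broken alphabetically."""
    if not importance.defined:
        raise ValueError("importance vector is undefined (no splits in the forest)")
    order = sorted(zip(importance.names, importance.values), key=lambda t: (-t[1], t[0]))
    return tuple(name for name, _ in order)


def build_wqimin_models(
    features: pd.DataFrame,
    wqi_values: np.ndarray | pd.Series,
    ranking: Sequence[str],
    k_values: Sequence[int],
    importance: ImportanceVector | None = None,
    n_trees: int = 500,
    params: TreeParams | None = None,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> SelectionReport:
    """Fit one surrogate forest per prefix subset and the full reference model.

    The same train/test partition is reused across every subset so the rows
    are directly comparable.  If ``importance`` is omitted it is computed
    from the reference model; the "feature importance" column is always the
    subset sum of the all-parameter model's normalized importances.
    """
    y = np.asarray(wqi_values, dtype=float)
    names = list(features.columns)
    ranking = tuple(ranking)
    if any(k > len(names) for k in k_values):
        raise ValueError("subset size exceeds the number of parameters")
    if set(ranking) - set(names):
        raise ValueError("ranking names parameters absent from the feature table")

    train, test = split_indices(len(features), test_fraction=test_fraction, seed=seed)
    X = features.to_numpy(dtype=float)

    def fit_eval(cols: Sequence[str], fit_seed: int) -> tuple[Forest, Metrics]:
        ix = [names.index(c) for c in cols]
        forest = fit_forest(
            X[np.ix_(train, ix)], y[train], n_trees=n_trees, params=params, seed=fit_seed,
            feature_names=cols,
        )
        pred = forest.predict(X[np.ix_(test, ix)])
        return forest, regression_metrics(y[test], pred)

    reference, ref_metrics = fit_eval(names, seed + 1)
    if importance is None:
        importance = feature_importance(reference)
    imp = importance.as_dict()

    rows = []
    for k in sorted(set(int(k) for k in k_values)):
        subset = ranking[:k]
        _, metrics = fit_eval(list(subset), seed + 1 + k)
        rows.append(
            {
                "parameters": " + ".join(subset),
                "k": k,
                "feature_importance": float(sum(imp[c] for c in subset)),
                **metrics.as_dict(),
            }
        )
    rows.append(
        {
            "parameters": "all",
            "k": len(names),
            "feature_importance": float(sum(imp.values())),
            **ref_metrics.as_dict(),
        }
    )
    return SelectionReport(ranking=ranking, importance=importance, rows=pd.DataFrame(rows))


def select_best(report: SelectionReport, tolerance: float = 0.0) -> tuple[str, ...]:
    """Smallest subset whose four metrics are all within ``tolerance`` of the best.

    "Best" is taken per metric over the candidate subsets (highest R^2,
    lowest MSE/MAE/MAPE).  With zero tolerance this returns the
    metric-optimal row; if no row is simultaneously best on every metric,
    R^2 decides (smallest subset among ties).
    """
    rows = report.rows[report.rows["parameters"] != "all"]
    if rows.empty:
        rows = report.rows
    best_r2 = rows["r2"].max()
    best_low = {m: rows[m].min() for m in ("mse", "mae", "mape")}
    for _, row in rows.sort_values("k").iterrows():
        if row["r2"] >= best_r2 - tolerance and all(
            row[m] <= best_low[m] + tolerance for m in ("mse", "mae", "mape")
        ):
            chosen = tuple(report.ranking[: int(row["k"])])
            report.chosen = chosen
            return chosen
    fallback = rows.sort_values(["r2", "k"], ascending=[False, True]).iloc[0]
    chosen = tuple(report.ranking[: int(fallback["k"])])
    report.chosen = chosen
    return chosen
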