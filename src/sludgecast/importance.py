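"""Interpreting trained networks: Garson connection-weight importance.

Garson's method attributes a share of a single-hidden-layer network's
behaviour to each input: c_ij = |w_ij|*|v_j| per (input i, hidden unit j),
normalised within each hidden unit and summed over units, then normalised
over inputs to yield importances that sum to 1 (biases are ignored).
Factor-importance profiles across many target models are clustered with
k-means, ranked by median or mean, and related to the shape (skewness,
excess kurtosis) of the factor distributions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .ann import PredictiveModel
from .community import linear_fit
from .tables import EnvTable


def garson_weights(model: PredictiveModel, factor_ids: list[str] | None = None) -> pd.Series:
    """Garson connection-weight importance per input factor.

    Returns a Series summing to 1. Hidden units with all-zero input weights
    contribute nothing; a fully zero weight matrix has undefined importance.
    """
    c = np.abs(model.W) * np.abs(model.v)[None, :]
    col = c.sum(axis=0)
    if not np.any(col > 0):
        raise ValueError("all connection weights are zero; importance undefined")
    r = np.divide(c, col, out=np.zeros_like(c), where=col > 0)
    s = r.sum(axis=1)
    imp = s / s.sum()
    if factor_ids is None:
        factor_ids = model.columns or [f"x{i}" for i in range(len(imp))]
    return pd.Series(imp, index=factor_ids, name="importance")


def importance_matrix(
    models: dict[str, PredictiveModel], factor_ids: list[str] | None = None
) -> pd.DataFrame:
    """Stack Garson profiles of several target models: targets x factors."""
    return pd.DataFrame(
        {tid: garson_weights(m, factor_ids) for tid, m in models.items()}
    ).T


def cluster_factor_weights(
    weights: pd.DataFrame, k: int = 3, seed: int = 0, n_restarts: int = 10
) -> pd.Series:
    """k-means cluster factors by their importance profiles across targets.

    ``weights`` is targets x factors; each factor is a point in target space.
    Best of ``n_restarts`` initialisations by within-cluster sum of squares;
    labels are 1..k and only the partition (not label identity) is meaningful.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > weights.shape[1]:
        raise ValueError("k exceeds the number of factors")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(weights.to_numpy().T) + 1
    return pd.Series(labels, index=weights.columns, name="cluster")


def rank_factors(weights: pd.DataFrame, statistic: str = "median") -> list[str]:
    """Factors in descending order of median (or mean) importance.

    Ties are broken lexicographically by factor id.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if weights.empty:
        raise ValueError("empty weight matrix")
    agg = weights.median(axis=0) if statistic == "median" else weights.mean(axis=0)
    order = sorted(agg.index, key=lambda f: (-agg[f], f))
    return list(order)


def weight_distribution_analysis(
    env_normalized: EnvTable, mean_importance: pd.Series
) -> tuple[pd.DataFrame, dict, dict]:
    """Relate factor-distribution shape to mean importance weight.

    Computes bias-corrected sample skewness and excess kurtosis (normal -> 0)
    of every normalised factor, then ordinary least-squares fits of
    importance on each statistic. Zero-variance factors get NaN statistics
    and are excluded from the fits.

    Returns (per-factor table, skewness fit, kurtosis fit); fits are the
    dicts produced by :func:`sludgecast.community.linear_fit`.
    """
    if not env_normalized.normalized:
        raise ValueError("environmental table must be normalized first")
    vals = env_normalized.values
    if vals.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    rows = []
    for f in vals.columns:
        x = vals[f].to_numpy(dtype=float)
        if np.std(x) == 0:
            sk = ku = np.nan
        else:
            sk = float(stats.skew(x, bias=False))
            ku = float(stats.kurtosis(x, bias=False))  # excess, normal -> 0
        rows.append(
            {
                "factor": f,
                "skewness": sk,
                "kurtosis": ku,
                "importance": float(mean_importance.get(f, np.nan)),
            }
        )
    table = pd.DataFrame(rows).set_index("factor")
    ok = table.dropna()

    def fit(col: str):
        if len(ok) < 3 or ok[col].nunique() < 2:
            return None
        return linear_fit(ok[col], ok["importance"])

    return table, fit("skewness"), fit("kurtosis")
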