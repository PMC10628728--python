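"""Phenotype preprocessing: normalizing transforms and covariate residualization.

Skewed exposure measures are mapped to normal scores by a rank-based
inverse-normal (Blom) transform; count-like problem scores are
log-transformed with a +1 offset (scores include 0).  Analysis variables
are then residualized on covariates by least squares and z-standardized,
which makes the Pearson correlation matrix of the residualized columns
the sufficient statistic for the downstream structural models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rank_inverse_normal", "log_transform_scores", "residualize_and_standardize"]


def rank_inverse_normal(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom rank-based inverse-normal transform.

    Returns Phi^-1((rank - 3/8) / (n + 1/4)) with ties given average
    ranks.  Invariant to any strictly monotone transform of the input.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if v.shape[0] < 3:
        raise ValueError("need at least 3 values")
    if np.unique(v).size == 1:
        raise ValueError("all values identical; rank transform undefined")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - offset) / (v.shape[0] + 1.0 - 2.0 * offset))


def log_transform_scores(values: np.ndarray) -> np.ndarray:
    """Natural log of (score + 1); the offset accommodates zero scores."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("scores must be nonnegative")
    return np.log1p(v)


def _covariate_design(table: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Design matrix with intercept; categorical columns become dummies."""
    cols = [np.ones(len(table))]
    for name in covariates:
        col = table[name]
        if col.dtype == object or str(col.dtype) == "category" or name == "site":
            dummies = pd.get_dummies(col, drop_first=True).to_numpy(float)
            cols.append(dummies)
        else:
            cols.append(col.to_numpy(float).reshape(-1, 1))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank deficient")
    return X


def residualize_and_standardize(
    table: pd.DataFrame,
    variables: list[str],
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Replace each variable by its z-scored least-squares residual.

    With no covariates this reduces to plain z-scoring.  The `site`
    column (or any non-numeric column) is expanded to dummy indicators.
    Raises if a variable is constant or exactly linear in the covariates
    (zero residual variance).
    """
    missing = [c for c in list(variables) + list(covariates or []) if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    n = len(table)
    if covariates:
        X = _covariate_design(table, list(covariates))
    else:
        X = np.ones((n, 1))

    out = {}
    for name in variables:
        y = table[name].to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = resid.std()
        if sd < 1e-12:
            raise ValueError(f"variable {name!r} has zero residual variance")
        out[name] = resid / sd
    return pd.DataFrame(out, index=table.index)
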