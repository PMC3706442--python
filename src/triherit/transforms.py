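"""Phenotype preparation: rank-based inverse-normal (van der Waerden)
normalization, covariate residualization, and the longitudinal composite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["van_der_waerden", "residualize", "composite_mean", "TransformError"]


class TransformError(ValueError):
    pass


def _as_array(y):
    if isinstance(y, pd.Series):
        return y.to_numpy(dtype=float), y.index
    return np.asarray(y, dtype=float), None


def _wrap(values, index):
    return pd.Series(values, index=index) if index is not None else values


def van_der_waerden(y):
    """Map ranks to standard-normal quantiles.

    A non-missing value with (average, for ties) rank ``r`` among ``n``
    non-missing values becomes ``Phi^{-1}(r / (n + 1))``.  Missing values
    are excluded from ranking and stay missing.
    """
    vals, index = _as_array(y)
    obs = ~np.isnan(vals)
    n = int(obs.sum())
    if n < 2:
        raise TransformError("van der Waerden transform needs >= 2 non-missing values")
    ranks = stats.rankdata(vals[obs], method="average")
    out = np.full_like(vals, np.nan)
    out[obs] = stats.norm.ppf(ranks / (n + 1))
    return _wrap(out, index)


def residualize(y, covariates):
    """OLS residuals of ``y`` on ``covariates`` (intercept always added).

    Rows with a missing phenotype are passed through as missing;
    covariates must be complete for the non-missing rows.  Rank-deficient
    covariate matrices are handled by least-squares pivoting with a
    warning.
    """
    vals, index = _as_array(y)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != vals.shape[0]:
        raise TransformError("covariate rows must align with phenotype entries")
    obs = ~np.isnan(vals)
    if obs.sum() < X.shape[1] + 1:
        raise TransformError("too few non-missing values for the covariate model")
    if np.isnan(X[obs]).any():
        raise TransformError("covariates must be complete where y is observed")
    Xo = np.column_stack([np.ones(int(obs.sum())), X[obs]])
    beta, _, rank, _ = np.linalg.lstsq(Xo, vals[obs], rcond=None)
    if rank < Xo.shape[1]:
        warnings.warn(
            f"covariate matrix rank {rank} < {Xo.shape[1]} columns; "
            "collinear columns resolved by least-squares pivoting",
            stacklevel=2,
        )
    out = np.full_like(vals, np.nan)
    out[obs] = vals[obs] - Xo @ beta
    return _wrap(out, index)


def composite_mean(y7, y9, y12):
    """Per-individual mean of the available age-specific scores.

    The composite is missing only when all three measurements are
    missing (the at-least-one-non-missing rule).
    """
    a7, index = _as_array(y7)
    a9, _ = _as_array(y9)
    a12, _ = _as_array(y12)
    Y = np.column_stack([a7, a9, a12])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmean(Y, axis=1)
    return _wrap(out, index)
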