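"""Genomic relatedness and single-component GREML.

The GRM follows the GCTA estimator: with sample allele frequency
``p_i`` and dosage ``x_ij``,

* off-diagonal ``A_jk = (1/m_jk) sum_i (x_ij - 2p_i)(x_ik - 2p_i) /
  (2 p_i (1 - p_i))`` over SNPs non-missing in both individuals, and
* diagonal ``A_jj = 1 + (1/m_j) sum_i (x_ij^2 - (1 + 2p_i) x_ij +
  2 p_i^2) / (2 p_i (1 - p_i))`` (the adjusted estimator, unbiased for 1
  under HWE).

GREML fits ``y = X b + g + e`` with ``Var(y) = s_g^2 A + s_e^2 I`` by
restricted maximum likelihood.  Because the model has a single variance
ratio, the restricted likelihood is profiled over the total variance and
maximized over ``h^2 = s_g^2 / (s_g^2 + s_e^2)`` on [0, 1] by a
1-dimensional search on the eigenbasis of the covariate-projected GRM —
globally robust, no iterative updates required.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize

from .datatypes import GenotypePanel, GRMatrix, GremlFit

__all__ = [
    "compute_grm",
    "prune_unrelated",
    "reml_h2",
    "reml_profile_deviance",
    "GrmError",
]

LOG2PI = math.log(2.0 * math.pi)


class GrmError(RuntimeError):
    pass


def compute_grm(panel: GenotypePanel) -> GRMatrix:
    """GCTA-style GRM with pairwise-complete SNP counts."""
    if panel.n_samples < 2:
        raise GrmError("GRM needs at least 2 samples")
    p = panel.allele_freq()
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if not poly.any():
        raise GrmError("all SNPs are monomorphic; GRM undefined")
    X = panel.dosages[poly]
    p = p[poly]
    denom = 2.0 * p * (1.0 - p)

    obs = ~np.isnan(X)
    W = np.where(obs, (X - 2 * p[:, None]) / np.sqrt(denom)[:, None], 0.0)
    obs_f = obs.astype(np.float64)  # float matmul hits BLAS; ints do not
    counts = np.rint(obs_f.T @ obs_f).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = (W.T @ W) / counts

    # adjusted diagonal
    Xf = np.where(obs, X, 0.0)
    num = (Xf * Xf - (1.0 + 2 * p[:, None]) * Xf + (2 * p * p)[:, None]) / denom[
        :, None
    ]
    num = np.where(obs, num, 0.0)
    m_j = obs.sum(axis=0)
    diag = 1.0 + num.sum(axis=0) / m_j
    np.fill_diagonal(A, diag)
    A = (A + A.T) / 2.0
    return GRMatrix(
        values=A, nsnp=counts, ids=panel.ids, call_rates=panel.sample_call_rate()
    )


def prune_unrelated(grm: GRMatrix, cutoff: float = 0.025) -> list:
    """Greedy unrelated-set selection.

    While any retained pair has relatedness above ``cutoff``, remove the
    individual participating in the most offending pairs (ties broken by
    lower call rate, then id order).  Mirrors the GCTA exclusion
    criterion for unrelated-sample analyses.
    """
    n = grm.n
    rel = grm.values.copy()
    np.fill_diagonal(rel, 0.0)
    active = np.ones(n, dtype=bool)
    call = grm.call_rates if grm.call_rates is not None else np.ones(n)
    while True:
        offending = (rel > cutoff) & active[:, None] & active[None, :]
        deg = offending.sum(axis=1)
        if deg.max(initial=0) == 0:
            break
        top = deg.max()
        cand = np.where(deg == top)[0]
        # lowest call rate first, then id order
        order = sorted(cand, key=lambda j: (call[j], str(grm.ids[j])))
        active[order[0]] = False
    return [grm.ids[j] for j in range(n) if active[j]]


# -------------------------------------------------------------------- REML


def _project_eigen(y, X, A):
    """Eigen-structure of the GRM in the covariate-orthogonal subspace.

    Returns ``(d, z)``: eigenvalues of ``Q' A Q`` and the rotated
    phenotype ``U' Q' y`` where ``Q`` spans the orthogonal complement of
    the column space of ``X``.
    """
    n, p = X.shape
    Qfull, _ = np.linalg.qr(np.asarray(X, dtype=float), mode="complete")
    Q = Qfull[:, p:]
    Astar = Q.T @ A @ Q
    d, U = np.linalg.eigh(Astar)
    z = U.T @ (Q.T @ y)
    return d, z


def reml_profile_deviance(h2: float, d: np.ndarray, z: np.ndarray) -> float:
    """Restricted deviance (-2 log RL, constant dropped) profiled over the
    total variance, as a function of the heritability ratio."""
    v = h2 * d + (1.0 - h2)
    if np.any(v <= 0):
        return np.inf
    k = d.size
    s2 = float(np.mean(z * z / v))
    if s2 <= 0:
        return np.inf
    return float(np.sum(np.log(v)) + k * math.log(s2) + k * (1.0 + LOG2PI))


def reml_h2(
    y,
    covariates,
    grm: GRMatrix,
    h2_bounds: tuple = (0.0, 1.0),
    unconstrained: bool = False,
) -> GremlFit:
    """Single-component GREML estimate of SNP heritability.

    ``y`` and ``covariates`` must be aligned with ``grm.ids`` (rows with
    missing phenotype are dropped together with their GRM rows).  An
    intercept is always included.  Standard error from the observed
    information (numerical second derivative of the profiled restricted
    deviance); boundary estimates are flagged.
    """
    y = np.asarray(y, dtype=float)
    n_all = grm.n
    if y.shape[0] != n_all:
        raise ValueError("phenotype length must match GRM dimension")
    X = (
        np.empty((n_all, 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float))
    )
    if X.ndim == 2 and X.shape[0] != n_all and X.shape[1] == n_all:
        X = X.T
    obs = ~np.isnan(y)
    if X.size:
        obs &= ~np.isnan(X).any(axis=1)
    idx = np.where(obs)[0]
    yo = y[idx]
    Xo = np.column_stack([np.ones(idx.size), X[idx]]) if X.size else np.ones(
        (idx.size, 1)
    )
    A = grm.values[np.ix_(idx, idx)]
    n, p = Xo.shape
    if n <= p + 2:
        raise ValueError("too few individuals for the covariate model")
    if np.var(yo) <= 0:
        raise ValueError("phenotype has non-positive variance")

    d, z = _project_eigen(yo, Xo, A)
    if np.ptp(d) < 1e-8:
        raise GrmError(
            "variance components confounded: GRM is numerically proportional "
            "to the identity in the residual subspace"
        )

    lo, hi = (-1.0, 2.0) if unconstrained else h2_bounds
    grid = np.linspace(lo, hi, 101)
    dev = np.array([reml_profile_deviance(h, d, z) for h in grid])
    i0 = int(np.argmin(dev))
    bl = grid[max(i0 - 1, 0)]
    bu = grid[min(i0 + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda h: reml_profile_deviance(h, d, z),
        bounds=(bl, bu),
        method="bounded",
        options={"xatol": 1e-12},
    )
    h2 = float(np.clip(res.x, lo, hi))
    if dev[i0] < res.fun:
        h2 = float(grid[i0])
    at_boundary = h2 <= lo + 1e-6 or h2 >= hi - 1e-6

    v = h2 * d + (1.0 - h2)
    s2_tot = float(np.mean(z * z / v))
    m2ll = reml_profile_deviance(h2, d, z)

    # observed information from the profiled deviance
    se = None
    step = 1e-4
    h_c = min(max(h2, lo + step), hi - step)
    f = lambda h: reml_profile_deviance(h, d, z)
    hess = (f(h_c + step) - 2 * f(h_c) + f(h_c - step)) / step**2
    if hess > 0:
        se = float(math.sqrt(2.0 / hess))

    return GremlFit(
        h2_snp=h2,
        se=se,
        sigma_g2=h2 * s2_tot,
        sigma_e2=(1.0 - h2) * s2_tot,
        loglik_restricted=-0.5 * m2ll,
        n_used=n,
        converged=True,
        at_boundary=at_boundary,
    )
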