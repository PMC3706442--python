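"""Twin variance-component analysis.

Implements intraclass correlations, the classical Falconer doubling
estimate with the cap-at-rMZ constraint, full-information maximum
likelihood (FIML) fitting of ACE / ADE / AE / CE / E models to MZ and DZ
pairs, and likelihood-ratio model comparison.

Model structure (standardized phenotypes): each co-twin's phenotype has
variance ``a2 + x2 + e2`` (``x2`` is ``c2`` or ``d2``), and the expected
within-pair covariance is ``a2 + x2`` for MZ pairs and
``0.5*a2 + c2`` (ACE) or ``0.5*a2 + 0.25*d2`` (ADE) for DZ pairs.  Pairs
with one missing member contribute their univariate marginal likelihood,
so singletons still inform the mean and total variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datatypes import TwinDataset, VarCompFit

__all__ = [
    "TwinCorrelations",
    "intraclass_correlation",
    "twin_correlations",
    "falconer_estimate",
    "fit_twin_model",
    "compare_models",
    "aic",
    "twins_from_summary",
    "EstimationError",
]

LOG2PI = math.log(2.0 * math.pi)

#: (A, C, D) covariance coefficients for DZ pairs; MZ pairs share all three.
DZ_COEF = {"a2": 0.5, "c2": 1.0, "d2": 0.25}

MODEL_MENU = {
    "ACE": ("a2", "c2", "e2"),
    "ADE": ("a2", "d2", "e2"),
    "AE": ("a2", "e2"),
    "CE": ("c2", "e2"),
    "E": ("e2",),
}


class EstimationError(RuntimeError):
    pass


@dataclass
class TwinCorrelations:
    r_mz: float
    r_dz: float
    se_mz: float
    se_dz: float
    n_mz: int
    n_dz: int


# ------------------------------------------------------------- correlations


def intraclass_correlation(pairs: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA intraclass correlation for complete twin pairs.

    ``pairs`` is an ``(n, 2)`` array.  Returns ``(icc, se)`` where the
    standard error is the Fisher-z delta approximation
    ``(1 - icc^2) / sqrt(n - 3)`` on the double-entry equivalent.
    """
    pairs = np.asarray(pairs, dtype=float)
    pairs = pairs[~np.isnan(pairs).any(axis=1)]
    n = pairs.shape[0]
    if n < 3:
        raise EstimationError("intraclass correlation needs >= 3 complete pairs")
    grand = pairs.mean()
    pair_means = pairs.mean(axis=1)
    # method-of-moments one-way ICC; algebraically equal to the Pearson
    # correlation of the double-entered data
    between2 = 2.0 * np.sum((pair_means - grand) ** 2)
    within = np.sum((pairs - pair_means[:, None]) ** 2)
    icc = (between2 - within) / (between2 + within)
    icc = float(np.clip(icc, -1.0, 1.0))
    se = (1.0 - icc**2) / math.sqrt(n - 3)
    return icc, se


def twin_correlations(data: TwinDataset) -> TwinCorrelations:
    """MZ and DZ intraclass correlations with standard errors."""
    out = {}
    for zyg in ("MZ", "DZ"):
        pairs = data.complete_pairs(zyg)
        r, se = intraclass_correlation(pairs)
        out[zyg] = (r, se, pairs.shape[0])
    return TwinCorrelations(
        r_mz=out["MZ"][0],
        r_dz=out["DZ"][0],
        se_mz=out["MZ"][1],
        se_dz=out["DZ"][1],
        n_mz=out["MZ"][2],
        n_dz=out["DZ"][2],
    )


# ----------------------------------------------------------------- Falconer


def falconer_estimate(r_mz: float, r_dz: float, constrain: bool = False) -> dict:
    """Falconer decomposition of twin correlations.

    Raw estimates: ``a2 = 2*(r_mz - r_dz)``, ``c2 = 2*r_dz - r_mz``,
    ``e2 = 1 - r_mz``.  A DZ correlation below half the MZ correlation
    signals non-additive variance and pushes the raw ``a2`` above
    ``r_mz`` (e.g. correlations 0.80 / 0.20 give 120% heritability); with
    ``constrain=True`` heritability is capped at the MZ correlation,
    ``c2`` is clamped to 0, and ``a2 + c2 = r_mz`` is preserved so the
    components remain a partition of the variance.
    """
    for r in (r_mz, r_dz):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    a2 = 2.0 * (r_mz - r_dz)
    c2 = 2.0 * r_dz - r_mz
    e2 = 1.0 - r_mz
    if constrain:
        c2 = min(max(c2, 0.0), max(r_mz, 0.0))
        a2 = r_mz - c2  # caps a2 at r_mz, keeps a2 + c2 = r_mz
    return {"a2": a2, "c2": c2, "e2": e2}


# --------------------------------------------------------------------- FIML


def _neg2ll(theta, model_comps, data_blocks):
    """-2 log likelihood; theta = (mu, v_total?, components...).

    Parameterization: ``mu`` plus one nonnegative variance per component;
    total variance is their sum.
    """
    mu = theta[0]
    comps = {c: v for c, v in zip(model_comps, theta[1:])}
    vt = float(sum(comps.values()))
    if vt <= 1e-10:
        return 1e12
    m2ll = 0.0
    for zyg, pairs, singles in data_blocks:
        cv = sum(
            v * (1.0 if zyg == "MZ" else DZ_COEF[c])
            for c, v in comps.items()
            if c != "e2"
        )
        det = vt * vt - cv * cv
        if det <= 1e-12 or vt <= 0:
            return 1e12
        if pairs.shape[0]:
            d1 = pairs[:, 0] - mu
            d2 = pairs[:, 1] - mu
            quad = (vt * (d1 * d1 + d2 * d2) - 2.0 * cv * d1 * d2) / det
            m2ll += pairs.shape[0] * (2.0 * LOG2PI + math.log(det)) + quad.sum()
        if singles.size:
            d = singles - mu
            m2ll += singles.size * (LOG2PI + math.log(vt)) + (d * d).sum() / vt
    return m2ll


def _prepare_blocks(data: TwinDataset):
    blocks = []
    n_pairs = n_ll = n_obs = 0
    for zyg in ("MZ", "DZ"):
        wide = data.pairs(zyg).to_numpy(dtype=float)
        complete = wide[~np.isnan(wide).any(axis=1)]
        one = wide[np.isnan(wide).sum(axis=1) == 1]
        singles = one[~np.isnan(one)]
        blocks.append((zyg, complete, singles))
        n_pairs += complete.shape[0]
        n_ll += complete.shape[0] + singles.size
        n_obs += 2 * complete.shape[0] + singles.size
    return blocks, n_pairs, n_ll, n_obs


def _fd_hessian(f, x, bounds_lo, step=1e-4):
    """Central finite-difference Hessian, shifting nodes inside bounds."""
    k = len(x)
    h = step * (1.0 + np.abs(x))
    base = np.array(x, dtype=float)
    # shift evaluation center away from an active lower bound
    center = np.maximum(base, bounds_lo + h)
    H = np.zeros((k, k))
    f0 = f(center)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (f(center + ei) - 2 * f0 + f(center - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(center + ei + ej)
                    - f(center + ei - ej)
                    - f(center - ei + ej)
                    + f(center - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def fit_twin_model(
    data: TwinDataset, model: str = "ACE", standardize: bool = True
) -> VarCompFit:
    """FIML fit of a twin variance-component model.

    Phenotypes are pooled-standardized first (so estimates are variance
    fractions); raw variances are optimized under nonnegativity bounds
    with a bounded quasi-Newton method (Nelder-Mead fallback), starting
    from the constrained Falconer decomposition.  Standard errors come
    from the finite-difference Hessian of the deviance via the delta
    method for the normalized fractions; estimates at the 0 boundary are
    flagged and their Hessian-based SEs reported untruncated.
    """
    if model not in MODEL_MENU:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODEL_MENU)}")
    comps = MODEL_MENU[model]

    table = data.table.copy()
    vals = table["phenotype"].to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    if standardize:
        mu0, sd0 = vals[obs].mean(), vals[obs].std(ddof=1)
        table["phenotype"] = (vals - mu0) / sd0
    work = TwinDataset(table)
    blocks, n_pairs, n_ll, n_obs = _prepare_blocks(work)
    for zyg, complete, _ in blocks:
        if complete.shape[0] < 20:
            raise EstimationError(
                f"need >= 20 complete {zyg} pairs for a stable fit"
            )

    # starting values from the constrained Falconer decomposition
    try:
        corr = twin_correlations(work)
        start = falconer_estimate(corr.r_mz, corr.r_dz, constrain=True)
    except EstimationError:
        start = {"a2": 0.3, "c2": 0.1, "e2": 0.6}
    start["d2"] = start.pop("c2", 0.0) if "d2" in comps else 0.0
    x0 = [0.0] + [max(start.get(c, 1.0 / len(comps)), 0.05) for c in comps]
    lo = np.array([-np.inf] + [0.0] * len(comps))
    bounds = [(None, None)] + [(0.0, 10.0)] * len(comps)

    obj = lambda th: _neg2ll(th, comps, blocks)
    clip = lambda th: np.where(np.isfinite(lo), np.maximum(th, lo), th)
    res = optimize.minimize(
        obj, x0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 2000},
    )
    # simplex fallback on the bound-clipped objective
    res2 = optimize.minimize(
        lambda th: obj(clip(th)), res.x, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 10000, "maxfev": 10000},
    )
    best = res2 if res2.fun < res.fun else res
    best_x = clip(best.x)
    minus2ll = float(obj(best_x))
    converged = bool(res.success or res2.success)

    raw = dict(zip(comps, best_x[1:]))
    total = sum(raw.values())
    estimates = {c: raw[c] / total for c in comps}
    at_boundary = any(raw[c] <= 1e-6 for c in comps)

    # delta-method SEs for the fractions from the deviance Hessian
    ses = None
    try:
        H = _fd_hessian(obj, best_x, lo)
        cov = 2.0 * np.linalg.inv(H)
        k = len(comps)
        J = np.zeros((k, k + 1))  # d fraction_i / d theta_j (theta_0 = mu)
        for i, ci in enumerate(comps):
            for j, cj in enumerate(comps):
                J[i, j + 1] = ((1.0 if i == j else 0.0) - estimates[ci]) / total
        frac_cov = J @ cov @ J.T
        var = np.diag(frac_cov)
        if np.all(var >= 0):
            ses = {c: float(math.sqrt(v)) for c, v in zip(comps, var)}
    except np.linalg.LinAlgError:
        ses = None

    n_free = 1 + len(comps)  # mean + variance components
    df = n_obs - n_free
    return VarCompFit(
        model=model,
        estimates={c: float(v) for c, v in estimates.items()},
        ses=ses,
        minus2ll=minus2ll,
        df=df,
        aic=aic(minus2ll, df),
        aic_parameters=minus2ll + 2.0 * n_free,
        n_pairs=n_pairs,
        n_ll=n_ll,
        n_obs=n_obs,
        n_free=n_free,
        at_boundary=at_boundary,
        converged=converged,
    )


# --------------------------------------------------------- model comparison


def aic(minus2ll: float, df: int) -> float:
    """Deviance-based information criterion ``-2LL - 2*df``.

    This is the residual-df convention used in the model-comparison
    tables this package mirrors; the textbook parameter-count form is
    available as :attr:`VarCompFit.aic_parameters`.
    """
    if df < 0:
        raise ValueError("df must be nonnegative")
    return minus2ll - 2.0 * df


def compare_models(full: VarCompFit, nested: VarCompFit) -> dict:
    """Likelihood-ratio comparison of a nested against a full model."""
    if nested.df <= full.df:
        raise ValueError("nested model must have more residual df than the full model")
    delta_df = nested.df - full.df
    delta_chi2 = nested.minus2ll - full.minus2ll
    if delta_chi2 < 0:
        # numerical noise: a nested model can't truly beat the full one
        delta_chi2 = max(delta_chi2, 0.0) if delta_chi2 > -1e-6 else delta_chi2
        delta_chi2 = max(delta_chi2, 0.0)
    p = float(stats.chi2.sf(delta_chi2, delta_df))
    return {
        "delta_chi2": float(delta_chi2),
        "delta_df": int(delta_df),
        "p": p,
        "delta_aic": nested.aic - full.aic,
    }


# ----------------------------------------------------- summary-moment data


def twins_from_summary(
    r_mz: float, n_mz: int, r_dz: float, n_dz: int, seed: int = 0
) -> TwinDataset:
    """Construct pair data whose *sample* moments equal given summaries.

    Draws standard-normal pairs and recolors them (whiten by the
    empirical Cholesky factor, recolor by the target's) so the sample
    correlation matrix of each zygosity group is exactly
    ``[[1, r], [r, 1]]`` with mean zero.  An ML fit to this data is the
    summary-likelihood fit implied by the printed correlations and pair
    counts.
    """
    rng = np.random.default_rng(seed)
    rows = []
    fam = 0
    for zyg, r, n in (("MZ", r_mz, n_mz), ("DZ", r_dz, n_dz)):
        Z = rng.standard_normal((n, 2))
        Z -= Z.mean(axis=0)
        emp = np.cov(Z, rowvar=False, ddof=1)
        target = np.array([[1.0, r], [r, 1.0]])
        Y = Z @ np.linalg.inv(np.linalg.cholesky(emp)).T @ np.linalg.cholesky(target).T
        fam_ids = np.arange(fam, fam + n)
        fam += n
        rows.append(
            dict(
                family_id=np.repeat(fam_ids, 2),
                zygosity=zyg,
                member=np.tile([1, 2], n),
                phenotype=Y.ravel(),
            )
        )
    import pandas as pd

    return TwinDataset(pd.concat([pd.DataFrame(r) for r in rows], ignore_index=True))
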