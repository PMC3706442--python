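"""Genome-wide association: per-SNP additive regression, the 1-df
longitudinal equal-effect score test, genomic control, and QQ /
Manhattan summaries.

The longitudinal test evaluates, per SNP, the hypothesis that the SNP
has the *same* additive effect on the phenotype at every age.  Under the
null (no SNP effect) the per-age means are modelled on covariates only;
each individual contributes through the ages at which they were
observed, so missingness in the outcomes is handled as a function of the
covariates (missing at random).  With ``Sigma`` the 3x3 cross-age
residual covariance and ``s(i)`` individual ``i``'s observed-age subset,
the efficient score for a common effect ``beta`` is

    U = sum_i (g_i 1)' Sigma_{s(i)}^{-1} r_i
    V = sum_i g_i^2 1' Sigma_{s(i)}^{-1} 1  -  I_bg I_gg^{-1} I_bg'

where ``r_i`` are the null (GLS) residuals and the second term of ``V``
removes the variance spent estimating the per-age covariate
coefficients.  ``U^2 / V`` is referred to chi-square with 1 df, and
reduces exactly to the squared univariate score statistic when each
individual is observed at a single age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AssocRecord, GenotypePanel

__all__ = [
    "snp_regression",
    "LongitudinalNull",
    "fit_longitudinal_null",
    "longitudinal_score_test",
    "longitudinal_scan",
    "genomic_control",
    "GcResult",
    "classify_tier",
    "qq_data",
    "manhattan_data",
    "GENOMEWIDE_P",
    "SUGGESTIVE_P",
    "CHI2_1DF_MEDIAN",
]

GENOMEWIDE_P = 5e-8
SUGGESTIVE_P = 5e-6
#: Median of the chi-square distribution with 1 df (genomic-control reference).
CHI2_1DF_MEDIAN = 0.45493642311957283


class MonomorphicError(ValueError):
    pass


# ------------------------------------------------------------ single-age OLS


def snp_regression(dosage, y, covariates=None):
    """Additive single-phenotype association by OLS.

    Returns ``(beta, se, p)`` for the dosage term with covariates (and an
    intercept) partialled out; two-sided p from the t statistic.
    """
    import statsmodels.api as sm

    g = np.asarray(dosage, dtype=float)
    yv = np.asarray(y, dtype=float)
    X = np.column_stack([g]) if covariates is None else np.column_stack(
        [g, np.asarray(covariates, dtype=float)]
    )
    obs = ~np.isnan(yv) & ~np.isnan(X).any(axis=1)
    if obs.sum() < 10:
        raise ValueError("need >= 10 complete cases")
    if np.var(g[obs]) == 0:
        raise MonomorphicError("dosage has zero variance")
    model = sm.OLS(yv[obs], sm.add_constant(X[obs], prepend=False))
    fit = model.fit()
    return float(fit.params[0]), float(fit.bse[0]), float(fit.pvalues[0])


# ------------------------------------------------------- longitudinal null


@dataclass
class LongitudinalNull:
    """Precomputed null structures shared by every SNP's score test."""

    sigma: np.ndarray          # (k, k) cross-age residual covariance
    u_i: np.ndarray            # (n,) 1' Sigma_s^-1 r_i per individual
    c_i: np.ndarray            # (n,) 1' Sigma_s^-1 1 per individual
    B: np.ndarray              # (n, k*p) rows t_i[a] * x_i per age block
    igg_chol: np.ndarray       # Cholesky factor of I_gamma_gamma
    n: int
    k: int
    p: int

    @property
    def M(self) -> np.ndarray:
        """B I_gg^{-1/2}: per-SNP variance correction is ||M' g||^2."""
        return np.linalg.solve(self.igg_chol, self.B.T).T


def fit_longitudinal_null(Y, covariates, gls_sweeps: int = 2) -> LongitudinalNull:
    """Fit the no-SNP null model for the longitudinal score test.

    ``Y`` is ``(n, k)`` phenotypes (NaN = missing; every row needs at
    least one observed age); ``covariates`` is ``(n, p0)`` and complete.
    Nuisance coefficients are initialized by per-age OLS and refined by
    GLS sweeps under the pooled pairwise-complete residual covariance so
    the score identity ``sum_i W_i' Sigma_s^{-1} r_i = 0`` holds at the
    final estimates.
    """
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    X0 = np.asarray(covariates, dtype=float)
    if X0.ndim == 1:
        X0 = X0[:, None]
    if np.isnan(X0).any():
        raise ValueError("covariates must be complete")
    X = np.column_stack([np.ones(n), X0])
    p = X.shape[1]
    obs = ~np.isnan(Y)
    if not obs.any(axis=1).all():
        raise ValueError("every individual needs >= 1 observed age")
    empty = obs.sum(axis=0) < p + 2
    if empty.any():
        warnings.warn(
            f"dropping {int(empty.sum())} age column(s) with too few "
            "observations from the null model",
            stacklevel=2,
        )
        Y = Y[:, ~empty]
        obs = obs[:, ~empty]
        k = Y.shape[1]

    # per-age OLS start
    gamma = np.zeros((p, k))
    for a in range(k):
        rows = obs[:, a]
        gamma[:, a], *_ = np.linalg.lstsq(X[rows], Y[rows, a], rcond=None)
    resid = np.where(obs, Y - X @ gamma, np.nan)
    sigma = _pairwise_cov(resid)

    patterns = _patterns(obs)
    for _ in range(gls_sweeps):
        gamma = _gls_gamma(Y, X, obs, sigma, patterns, k, p)
        resid = np.where(obs, Y - X @ gamma, np.nan)
        sigma = _pairwise_cov(resid)
    # final residuals under the final sigma
    gamma = _gls_gamma(Y, X, obs, sigma, patterns, k, p)
    resid = np.where(obs, Y - X @ gamma, np.nan)

    u_i = np.zeros(n)
    c_i = np.zeros(n)
    T = np.zeros((n, k))  # t_i: column sums of Sigma_s^-1 embedded in R^k
    for mask, rows in patterns.items():
        s = np.array(mask)
        sig_inv = np.linalg.inv(sigma[np.ix_(s, s)])
        colsum = sig_inv.sum(axis=0)
        r_block = resid[np.ix_(rows, s)]
        u_i[rows] = r_block @ colsum
        c_i[rows] = colsum.sum()
        T[np.ix_(rows, s)] = colsum

    # covariate-projection structures
    B = np.zeros((n, k * p))
    for a in range(k):
        B[:, a * p : (a + 1) * p] = T[:, [a]] * X
    Igg = np.zeros((k * p, k * p))
    for mask, rows in patterns.items():
        s = np.array(mask)
        sig_inv = np.linalg.inv(sigma[np.ix_(s, s)])
        Xr = X[rows]
        XtX = Xr.T @ Xr
        for ia, a in enumerate(s):
            for ib, b in enumerate(s):
                Igg[a * p : (a + 1) * p, b * p : (b + 1) * p] += sig_inv[ia, ib] * XtX
    igg_chol = np.linalg.cholesky(Igg)
    return LongitudinalNull(
        sigma=sigma, u_i=u_i, c_i=c_i, B=B, igg_chol=igg_chol, n=n, k=k, p=p
    )


def _patterns(obs: np.ndarray) -> dict:
    """Group individuals by observed-age pattern -> row indices."""
    out: dict = {}
    for i, row in enumerate(obs):
        key = tuple(np.where(row)[0])
        out.setdefault(key, []).append(i)
    return {k: np.array(v) for k, v in out.items()}


def _pairwise_cov(resid: np.ndarray) -> np.ndarray:
    """Pairwise-complete cross-age residual covariance (falls back to a
    diagonal working covariance if not positive definite)."""
    k = resid.shape[1]
    sigma = np.zeros((k, k))
    for a in range(k):
        xa = resid[:, a]
        sigma[a, a] = np.nanvar(xa, ddof=1)
    for a, b in combinations(range(k), 2):
        both = ~np.isnan(resid[:, a]) & ~np.isnan(resid[:, b])
        if both.sum() > 2:
            c = np.cov(resid[both, a], resid[both, b], ddof=1)[0, 1]
        else:
            c = 0.0
        sigma[a, b] = sigma[b, a] = c
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        warnings.warn(
            "pairwise residual covariance not positive definite; falling "
            "back to the independence working covariance",
            stacklevel=3,
        )
        sigma = np.diag(np.diag(sigma))
    return sigma


def _gls_gamma(Y, X, obs, sigma, patterns, k, p):
    """GLS estimate of the stacked per-age covariate coefficients."""
    lhs = np.zeros((k * p, k * p))
    rhs = np.zeros(k * p)
    for mask, rows in patterns.items():
        s = np.array(mask)
        sig_inv = np.linalg.inv(sigma[np.ix_(s, s)])
        Xr = X[rows]
        XtX = Xr.T @ Xr
        Yr = Y[np.ix_(rows, s)]
        XtY = Xr.T @ Yr  # (p, |s|)
        for ia, a in enumerate(s):
            for ib, b in enumerate(s):
                lhs[a * p : (a + 1) * p, b * p : (b + 1) * p] += sig_inv[ia, ib] * XtX
                rhs[a * p : (a + 1) * p] += sig_inv[ia, ib] * XtY[:, ib]
    return np.linalg.solve(lhs, rhs).reshape(k, p).T


# ----------------------------------------------------------- score testing


def _score_stats(G: np.ndarray, null: LongitudinalNull) -> np.ndarray:
    """Vectorized statistics for dosage matrix ``G`` of shape (m, n)."""
    U = G @ null.u_i
    M = null.M
    corr = (G @ M) ** 2
    V = (G * G) @ null.c_i - corr.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(V > 0, U * U / V, np.nan)


def longitudinal_score_test(
    dosage,
    Y,
    covariates,
    null: LongitudinalNull | None = None,
    meta: dict | None = None,
) -> AssocRecord:
    """1-df equal-effect-across-ages score test for a single SNP."""
    g = np.asarray(dosage, dtype=float)
    if np.nanvar(g) == 0:
        raise MonomorphicError("dosage is constant across individuals")
    if null is None:
        null = fit_longitudinal_null(Y, covariates)
    g = np.where(np.isnan(g), np.nanmean(g), g)
    stat = float(_score_stats(g[None, :], null)[0])
    p_raw = float(stats.chi2.sf(stat, 1))

    freq = float(np.nanmean(np.asarray(dosage, dtype=float)) / 2.0)
    meta = meta or {}
    ref, alt = meta.get("ref", "A"), meta.get("alt", "B")
    # risk allele: the one whose dosage pushes the phenotype up (sign of U)
    U = float(g @ null.u_i)
    if U >= 0:
        risk, risk_freq = alt, freq
    else:
        risk, risk_freq = ref, 1.0 - freq
    return AssocRecord(
        snp=meta.get("snp", "snp"),
        chrom=str(meta.get("chrom", "0")),
        pos=int(meta.get("pos", 0)),
        ref=ref if risk != ref else alt,
        risk_allele=risk,
        risk_allele_freq=risk_freq,
        score_stat=stat,
        p_raw=p_raw,
        imputed=bool(meta.get("imputed", False)),
        stratum=meta.get("stratum", "genotyped"),
    )


def longitudinal_scan(
    panel: GenotypePanel, Y, covariates, null: LongitudinalNull | None = None
) -> pd.DataFrame:
    """Run the longitudinal score test across every SNP of a panel.

    Returns a per-SNP table with the score statistic and raw p; genomic
    control is applied afterwards by :func:`genomic_control` per stratum.
    """
    if null is None:
        null = fit_longitudinal_null(Y, covariates)
    G = panel.dosages
    means = np.nanmean(G, axis=1)
    G = np.where(np.isnan(G), means[:, None], G)
    stat = _score_stats(G, null)
    var0 = G.std(axis=1) == 0
    stat[var0] = np.nan
    p_raw = stats.chi2.sf(stat, 1)
    freq = means / 2.0
    U = G @ null.u_i
    risk_is_alt = U >= 0
    out = panel.snps[["snp", "chrom", "pos", "ref", "alt", "imputed", "stratum"]].copy()
    out["risk_allele"] = np.where(risk_is_alt, out["alt"], out["ref"])
    out["risk_allele_freq"] = np.where(risk_is_alt, freq, 1.0 - freq)
    out["score_stat"] = stat
    out["p_raw"] = p_raw
    return out


# ----------------------------------------------------------- genomic control


@dataclass
class GcResult:
    lambda_gc: float
    stratum: str
    n: int
    stable: bool


def genomic_control(score_stats, stratum: str = "genotyped"):
    """Devlin-Roeder genomic control of 1-df statistics.

    ``lambda = median(stat) / 0.4549...``; statistics are divided by
    ``max(lambda, 1)`` (deflation is never applied) and re-referred to
    chi-square 1 df.  Returns ``(GcResult, adjusted_stats, p_gc)``.
    """
    s = np.asarray(score_stats, dtype=float)
    s = s[~np.isnan(s)]
    stable = s.size >= 100
    if not stable:
        warnings.warn(
            f"only {s.size} statistics in stratum {stratum!r}; "
            "lambda estimate is unstable",
            stacklevel=2,
        )
    lam = float(np.median(s) / CHI2_1DF_MEDIAN) if s.size else np.nan
    adj = np.asarray(score_stats, dtype=float) / max(lam, 1.0)
    p_gc = stats.chi2.sf(adj, 1)
    return GcResult(lambda_gc=lam, stratum=stratum, n=s.size, stable=stable), adj, p_gc


def classify_tier(p_gc: float) -> str:
    """Significance tier: genome-wide (< 5e-8), suggestive (< 5e-6), none."""
    if not 0 < p_gc <= 1:
        raise ValueError("p must lie in (0, 1]")
    if p_gc < GENOMEWIDE_P:
        return "genomewide"
    if p_gc < SUGGESTIVE_P:
        return "suggestive"
    return "none"


def apply_genomic_control(results: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Adjust a scan table by genomic control within each stratum."""
    out = results.copy()
    out["p_gc"] = np.nan
    gc_results = []
    for stratum, sub in out.groupby("stratum"):
        gc, _, p_gc = genomic_control(sub["score_stat"].to_numpy(), stratum=stratum)
        out.loc[sub.index, "p_gc"] = p_gc
        gc_results.append(gc)
    out["tier"] = [
        classify_tier(p) if np.isfinite(p) and p > 0 else "none" for p in out["p_gc"]
    ]
    return out, gc_results


# ------------------------------------------------------------ plot tables


def qq_data(p_values) -> pd.DataFrame:
    """Expected-vs-observed -log10 p with a 95% null band.

    The i-th order statistic of n uniform p-values is Beta(i, n+1-i);
    the band is its 2.5% / 97.5% quantiles.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[~np.isnan(p)]
    n = p.size
    if n == 0:
        raise ValueError("need at least one p value")
    i = np.arange(1, n + 1)
    expected = i / (n + 1.0)
    lo = stats.beta.ppf(0.025, i, n + 1 - i)
    hi = stats.beta.ppf(0.975, i, n + 1 - i)
    return pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(p),
            "band_low_neglog10": -np.log10(hi),
            "band_high_neglog10": -np.log10(lo),
        }
    )


def manhattan_data(records: pd.DataFrame) -> pd.DataFrame:
    """Sorted per-SNP table with a cumulative genome coordinate."""
    cols = ["snp", "chrom", "pos", "p_gc", "tier"]
    if records.empty:
        return pd.DataFrame(columns=cols + ["cum_pos", "neglog10_p"])
    df = records.copy()
    df["_chrom_key"] = df["chrom"].astype(str)
    df = df.sort_values(["_chrom_key", "pos"]).reset_index(drop=True)
    offset = 0
    cum = np.empty(len(df))
    for _, idx in df.groupby("_chrom_key", sort=True).groups.items():
        idx = np.asarray(sorted(idx))
        cum[idx] = df.loc[idx, "pos"] + offset
        offset = cum[idx].max() + 1
    df["cum_pos"] = cum
    df["neglog10_p"] = -np.log10(df["p_gc"])
    return df.drop(columns=["_chrom_key"])
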