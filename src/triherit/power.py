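"""Analytic and simulation-based power for detecting a quantitative
trait locus (QTL) with a 1-df additive association test.

For a QTL explaining a fraction ``q2`` of phenotypic variance in ``n``
unrelated individuals, the association chi-square has noncentrality
``NCP = n * q2 / (1 - q2)`` (the ``ratio`` convention; ``simple`` uses
``n * q2``).  Power at two-sided level ``alpha`` is the noncentral
chi-square (1 df) tail beyond the central quantile, equivalently
``Phi(sqrt(NCP) - sqrt(c)) + Phi(-sqrt(NCP) - sqrt(c))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerQuery", "qtl_power", "qtl_power_sim", "power_table"]


@dataclass(frozen=True)
class PowerQuery:
    n: int
    q2: float
    alpha: float
    ncp_convention: str = "ratio"

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0 <= self.q2 < 1:
            if self.q2 == 1 and self.ncp_convention == "ratio":
                raise ValueError("q2 = 1 undefined under the ratio convention")
            raise ValueError("q2 must lie in [0, 1)")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.ncp_convention not in ("ratio", "simple"):
            raise ValueError("ncp_convention must be 'ratio' or 'simple'")


def _ncp(query: PowerQuery) -> float:
    if query.ncp_convention == "ratio":
        return query.n * query.q2 / (1.0 - query.q2)
    return query.n * query.q2


def qtl_power(query: PowerQuery) -> float:
    """Exact noncentral chi-square (1 df) power."""
    if query.alpha >= 1.0:
        return 1.0
    c = stats.chi2.ppf(1.0 - query.alpha, 1)
    ncp = _ncp(query)
    if ncp == 0:
        return float(query.alpha)
    root_c, root_n = np.sqrt(c), np.sqrt(ncp)
    return float(stats.norm.cdf(root_n - root_c) + stats.norm.cdf(-root_n - root_c))


def qtl_power_sim(
    query: PowerQuery, reps: int = 2000, seed: int = 0, maf: float = 0.5
) -> tuple[float, float]:
    """Monte-Carlo power estimate with its standard error.

    Each replicate draws a biallelic genotype at frequency ``maf``, a
    phenotype ``y = beta*g + e`` with ``beta^2 Var(g) = q2`` and unit
    total variance, and applies the additive OLS test (the closed-form
    correlation t-test, algebraically identical to ``snp_regression``
    with no covariates).
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    n, q2 = query.n, query.q2
    var_g = 2.0 * maf * (1.0 - maf)
    beta = np.sqrt(q2 / var_g) if q2 > 0 else 0.0
    hits = 0
    block = max(1, int(2e7 // n))
    done = 0
    while done < reps:
        b = min(block, reps - done)
        G = rng.binomial(2, maf, size=(b, n)).astype(float)
        E = rng.normal(0.0, np.sqrt(1.0 - q2), size=(b, n))
        Y = beta * G + E
        Gc = G - G.mean(axis=1, keepdims=True)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        r = (Gc * Yc).sum(axis=1) / np.sqrt(
            (Gc**2).sum(axis=1) * (Yc**2).sum(axis=1)
        )
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
        hits += int(np.sum(p < query.alpha))
        done += b
    phat = hits / reps
    mc_se = float(np.sqrt(max(phat * (1 - phat), 1.0 / reps) / reps))
    return float(phat), mc_se


def power_table(ns, q2s, alphas, ncp_convention: str = "ratio"):
    """Analytic power over a grid; returns a tidy DataFrame."""
    import pandas as pd

    rows = [
        {
            "n": n,
            "q2": q2,
            "alpha": a,
            "power": qtl_power(PowerQuery(n, q2, a, ncp_convention)),
        }
        for n in ns
        for q2 in q2s
        for a in alphas
    ]
    return pd.DataFrame(rows)
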