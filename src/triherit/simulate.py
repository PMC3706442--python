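"""Synthetic cohort generator.

Emulates the statistical structure the downstream analyses assume: MZ/DZ
twin pairs under an ACE/ADE liability model, biallelic SNP panels in
Hardy-Weinberg equilibrium with optional two-or-more-subpopulation
stratification (Balding-Nichols), and longitudinal three-age phenotypes
in which every causal SNP has the *same* additive effect at each age,
with cross-age residual correlation, covariate effects and
missing-at-random dropout tied to those covariates.

All generators are deterministic under a fixed seed
(``numpy.random.default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import SNP_COLUMNS, GenotypePanel, TwinDataset

__all__ = [
    "TwinSimConfig",
    "GenoSimConfig",
    "PhenoSimConfig",
    "simulate_twins",
    "simulate_genotypes",
    "simulate_longitudinal_phenotypes",
]

#: Within-pair correlation of each latent factor, by zygosity.
#: A: additive genetic; C: shared environment; D: dominance; E: unique.
FACTOR_SHARING = {
    "MZ": {"A": 1.0, "C": 1.0, "D": 1.0},
    "DZ": {"A": 0.5, "C": 1.0, "D": 0.25},
}

AGES = (7, 9, 12)
COHORTS = (1994, 1995, 1996)


class ConfigError(ValueError):
    """Raised for an internally inconsistent simulation configuration."""


@dataclass(frozen=True)
class TwinSimConfig:
    """Variance-component layout for the twin simulator.

    ``a2 + c2 + d2 + e2`` must equal 1; at most one of ``c2`` (shared
    environment) and ``d2`` (dominance) may be nonzero, matching the
    ACE-or-ADE model menu of the twin design.
    """

    n_mz_pairs: int
    n_dz_pairs: int
    a2: float
    e2: float
    c2: float = 0.0
    d2: float = 0.0
    mean: float = 0.0
    sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        fracs = (self.a2, self.c2, self.d2, self.e2)
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigError("variance fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-12:
            raise ConfigError(f"variance fractions sum to {sum(fracs)}, not 1")
        if self.c2 > 0 and self.d2 > 0:
            raise ConfigError("at most one of c2 (ACE) and d2 (ADE) may be nonzero")
        if self.sd <= 0:
            raise ConfigError("sd must be positive")


@dataclass(frozen=True)
class GenoSimConfig:
    """SNP-panel layout: MAF spectrum, stratification, missingness."""

    n_individuals: int
    n_snps: int
    maf_range: tuple = (0.05, 0.5)
    n_subpops: int = 1
    fst: float = 0.0
    missing_rate: float = 0.0
    n_plates: int = 8
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.fst < 1):
            raise ConfigError("fst must lie in [0, 1)")
        if self.n_subpops == 1 and self.fst != 0:
            raise ConfigError("fst must be 0 with a single subpopulation")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class PhenoSimConfig:
    """Longitudinal phenotype layout.

    ``h2_snp`` is the expected fraction of phenotypic variance explained
    by the ``n_causal`` causal SNPs; the per-SNP effect is identical at
    every age.  ``missing_rates`` are marginal per-age missingness
    fractions realised through a logistic model in sex and cohort only
    (missing at random given those covariates).
    """

    n_causal: int
    h2_snp: float
    ages: tuple = AGES
    cross_age_corr: float = 0.5
    beta_covariates: tuple = (0.0, 0.0)  # (sex, cohort) effects on raw scale
    missing_rates: tuple = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.h2_snp <= 1):
            raise ConfigError("h2_snp must lie in [0, 1]")
        if not (-1 < self.cross_age_corr < 1):
            raise ConfigError("cross_age_corr must lie in (-1, 1)")
        if any(not (0 <= r < 1) for r in self.missing_rates):
            raise ConfigError("missing_rates must lie in [0, 1)")
        if len(self.missing_rates) != len(self.ages):
            raise ConfigError("one missing rate per age required")


def simulate_twins(config: TwinSimConfig) -> TwinDataset:
    """Draw MZ and DZ pair phenotypes from the Gaussian liability model.

    Each co-twin's standardized phenotype is
    ``y = sqrt(a2)*A + sqrt(c2)*C + sqrt(d2)*D + sqrt(e2)*E`` where the
    latent factors correlate within a pair according to
    :data:`FACTOR_SHARING` (A: 1 / 0.5 for MZ / DZ; D: 1 / 0.25; C: 1;
    E: independent).  Expected pair correlations are therefore
    ``a2 + c2 + d2`` (MZ) and ``0.5*a2 + c2 + 0.25*d2`` (DZ).
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    fam = 0
    for zyg, n_pairs in (("MZ", config.n_mz_pairs), ("DZ", config.n_dz_pairs)):
        share = FACTOR_SHARING[zyg]
        y = np.zeros((n_pairs, 2))
        for frac, label in ((config.a2, "A"), (config.c2, "C"), (config.d2, "D")):
            if frac == 0:
                continue
            r = share[label]
            common = rng.standard_normal((n_pairs, 1))
            unique = rng.standard_normal((n_pairs, 2))
            factor = np.sqrt(r) * common + np.sqrt(1.0 - r) * unique
            y += np.sqrt(frac) * factor
        if config.e2 > 0:
            y += np.sqrt(config.e2) * rng.standard_normal((n_pairs, 2))
        y = config.mean + config.sd * y
        fam_ids = np.arange(fam, fam + n_pairs)
        fam += n_pairs
        frames.append(
            pd.DataFrame(
                {
                    "family_id": np.repeat(fam_ids, 2),
                    "zygosity": zyg,
                    "member": np.tile([1, 2], n_pairs),
                    "phenotype": y.ravel(),
                }
            )
        )
    return TwinDataset(pd.concat(frames, ignore_index=True))


def simulate_genotypes(config: GenoSimConfig) -> GenotypePanel:
    """Draw a HWE SNP panel, optionally stratified (Balding-Nichols).

    Per SNP an ancestral frequency ``p`` is uniform on ``maf_range``;
    with more than one subpopulation, subpopulation frequencies are
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` (mean ``p``, divergence ``F``).
    Genotypes are ``Binomial(2, p_subpop)``; entries are set missing
    uniformly at ``missing_rate``; plates are assigned round-robin.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps
    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=m)

    subpop = rng.integers(0, config.n_subpops, size=n)
    if config.n_subpops > 1 and config.fst > 0:
        f = config.fst
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p_sub = rng.beta(a[:, None], b[:, None], size=(m, config.n_subpops))
        p_ind = p_sub[:, subpop]  # (m, n)
    else:
        p_ind = np.broadcast_to(p_anc[:, None], (m, n))

    dosages = rng.binomial(2, p_ind).astype(float)
    if config.missing_rate > 0:
        mask = rng.random((m, n)) < config.missing_rate
        dosages[mask] = np.nan

    snps = pd.DataFrame(
        {
            "snp": [f"rs{i:07d}" for i in range(m)],
            "chrom": (np.arange(m) % 22 + 1).astype(str),
            "pos": (np.arange(m) // 22 + 1) * 1000,
            "ref": "A",
            "alt": "G",
            "imputed": False,
            "stratum": "genotyped",
            "info": 1.0,
        }
    )[SNP_COLUMNS]
    plates = np.array([f"plate{(i % config.n_plates) + 1}" for i in range(n)])
    ids = [f"id{i:05d}" for i in range(n)]
    return GenotypePanel(ids=ids, snps=snps, dosages=dosages, plates=plates, subpop=subpop)


def simulate_longitudinal_phenotypes(
    panel: GenotypePanel, config: PhenoSimConfig
) -> pd.DataFrame:
    """Three-age phenotypes with a common per-SNP additive effect.

    A genetic score ``g_i = sum_k beta_k x_ik`` over ``n_causal``
    standardized SNPs (``beta_k ~ N(0, h2_snp / n_causal)``) enters every
    age identically; age-specific residuals are multivariate normal with
    pairwise correlation ``cross_age_corr`` and variance ``1 - h2_snp``,
    so the total phenotypic variance is 1 and ``Var(g) = h2_snp`` in
    expectation.  Covariate effects (sex, cohort) are added afterwards on
    the raw scale, and per-age missingness is a logistic function of sex
    and cohort only (MAR).

    Returns a table with columns
    ``id, sex, cohort, plate, true_g, y7, y9, y12`` (NaN = missing).
    """
    if config.n_causal > panel.n_snps:
        raise ConfigError(
            f"n_causal={config.n_causal} exceeds panel of {panel.n_snps} SNPs"
        )
    rng = np.random.default_rng(config.seed)
    n = panel.n_samples
    k = len(config.ages)

    g = np.zeros(n)
    if config.n_causal > 0 and config.h2_snp > 0:
        causal = rng.choice(panel.n_snps, size=config.n_causal, replace=False)
        X = panel.dosages[causal]
        p = np.nanmean(X, axis=1) / 2.0
        sd = np.sqrt(2 * p * (1 - p))
        ok = sd > 0
        X = X[ok]
        Xs = (np.nan_to_num(X, nan=(2 * p[ok])[:, None]) - 2 * p[ok][:, None]) / sd[
            ok
        ][:, None]
        beta = rng.normal(0.0, np.sqrt(config.h2_snp / config.n_causal), size=ok.sum())
        g = beta @ Xs

    r = config.cross_age_corr
    corr = np.full((k, k), r)
    np.fill_diagonal(corr, 1.0)
    resid = rng.multivariate_normal(
        np.zeros(k), (1.0 - config.h2_snp) * corr, size=n, method="cholesky"
    )
    Y = g[:, None] + resid

    sex = rng.integers(0, 2, size=n)
    cohort = rng.choice(COHORTS, size=n)
    b_sex, b_cohort = config.beta_covariates
    Y = Y + (b_sex * sex + b_cohort * (cohort - np.mean(COHORTS)))[:, None]

    # MAR dropout: logistic in centred sex and cohort, intercept chosen so the
    # marginal rate matches missing_rates per age.
    for j, rate in enumerate(config.missing_rates):
        if rate <= 0:
            continue
        eta = (
            np.log(rate / (1 - rate))
            + 0.8 * (sex - 0.5)
            + 0.5 * (cohort - np.mean(COHORTS))
        )
        miss = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
        Y[miss, j] = np.nan

    out = pd.DataFrame(
        {
            "id": panel.ids,
            "sex": sex,
            "cohort": cohort,
            "plate": panel.plates if panel.plates is not None else "plate1",
            "true_g": g,
        }
    )
    for j, age in enumerate(config.ages):
        out[f"y{age}"] = Y[:, j]
    return out
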