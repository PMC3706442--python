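"""Sample- and SNP-level genotype quality control, LD pruning, ancestry
PCA and the Tracy-Widom count of significant components.

SNP filters (fixed order: info, MAF, missingness, HWE, plate effect) use
strict boundary semantics — a SNP fails only when it is strictly beyond
the threshold (info < 0.975, MAF < 0.01, missingness > 0.02,
HWE p < 1e-20, plate p < 1e-6).  Imputed SNPs are judged by the tiered
info rule (>= 0.98 when imputed in both panels; >= 0.90 for the
second-array tier) instead of the genotyped info cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypePanel, GRMatrix

__all__ = [
    "SnpQCThresholds",
    "SampleQCThresholds",
    "QCReport",
    "hwe_test",
    "snp_filter",
    "sample_filter",
    "ld_prune",
    "pca",
    "tracy_widom_count",
]


@dataclass(frozen=True)
class SnpQCThresholds:
    info_min: float = 0.975
    maf_min: float = 0.01
    missing_max: float = 0.02
    hwe_p_min: float = 1e-20
    plate_p_min: float = 1e-6
    imputed_info_min: float = 0.98
    array2_info_min: float = 0.90

    def __post_init__(self):
        for name in ("info_min", "maf_min", "missing_max", "imputed_info_min",
                     "array2_info_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} outside (0, 1]")
        for name in ("hwe_p_min", "plate_p_min"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} outside (0, 1)")


@dataclass(frozen=True)
class SampleQCThresholds:
    call_rate_min: float = 0.97
    het_z_max: float = 3.0
    ibd_max: float = 0.05

    def __post_init__(self):
        if not 0 < self.call_rate_min <= 1:
            raise ValueError("call_rate_min outside (0, 1]")
        if not 0 < self.ibd_max < 1:
            raise ValueError("ibd_max outside (0, 1)")


@dataclass
class QCReport:
    """Pass/fail mask with one primary (first-failing) reason per item."""

    items: pd.DataFrame  # columns: item, passed, reason
    counts: dict = field(default_factory=dict)

    def __post_init__(self):
        failed = self.items[~self.items["passed"]]
        tally = failed["reason"].value_counts().to_dict()
        if not self.counts:
            self.counts = tally
        assert sum(self.counts.values()) == len(failed)

    @property
    def kept(self) -> list:
        return self.items.loc[self.items["passed"], "item"].tolist()

    @property
    def fraction_removed(self) -> float:
        return 1.0 - self.items["passed"].mean() if len(self.items) else 0.0


# ---------------------------------------------------------------------- HWE


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int, exact: bool = False):
    """Hardy-Weinberg test p-value from genotype counts.

    Default: Pearson chi-square with 1 df against expected counts under
    the estimated allele frequency.  ``exact=True`` uses the standard
    conditional exact test (sum of heterozygote-count probabilities no
    larger than the observed one).  Monomorphic SNPs return ``(1.0,
    True)``; otherwise the flag is ``False``.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n <= 0:
        raise ValueError("HWE test needs at least one genotype")
    n_alt = n_het + 2 * n_hom_alt
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0, True
    if exact:
        return _hwe_exact(n_het, min(n_alt, 2 * n - n_alt), n), False
    p = n_alt / (2.0 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, 1)), False


def _hwe_exact(n_het_obs: int, n_rare: int, n: int) -> float:
    """Exact HWE p: total probability of heterozygote counts at most as
    likely as the observed one, conditional on allele counts."""
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logprob = np.zeros_like(hets, dtype=float)
    for idx, h in enumerate(hets):
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        logprob[idx] = (
            h * math.log(2.0)
            + math.lgamma(n + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_common + 1)
            + math.lgamma(n_rare + 1)
            + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )
    prob = np.exp(logprob - logprob.max())
    prob /= prob.sum()
    obs_p = prob[hets == n_het_obs][0]
    return float(prob[prob <= obs_p * (1 + 1e-12)].sum())


def _genotype_counts(dosage_row: np.ndarray) -> tuple[int, int, int]:
    """Hard-call counts from (possibly fractional) dosages by rounding."""
    x = dosage_row[~np.isnan(dosage_row)]
    g = np.clip(np.rint(x), 0, 2).astype(int)
    return int(np.sum(g == 0)), int(np.sum(g == 1)), int(np.sum(g == 2))


# --------------------------------------------------------------- SNP filter


def _plate_effect_p(dosage_row: np.ndarray, plates: np.ndarray) -> float:
    """One-way ANOVA F-test of dosage on genotyping plate."""
    obs = ~np.isnan(dosage_row)
    groups = [
        dosage_row[obs & (plates == pl)]
        for pl in np.unique(plates)
    ]
    groups = [g for g in groups if g.size > 1]
    if len(groups) < 2 or all(np.var(g) == 0 for g in groups):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.f_oneway(*groups)
    return float(p) if np.isfinite(p) else 1.0


def snp_filter(
    panel: GenotypePanel,
    thresholds: SnpQCThresholds = SnpQCThresholds(),
    plate_test: bool = True,
) -> QCReport:
    """Apply the SNP quality filters in fixed order, recording the first
    failing rule per SNP."""
    t = thresholds
    maf = panel.maf()
    miss = panel.snp_missing_rate()
    info = panel.snps["info"].to_numpy(dtype=float)
    imputed = panel.snps["imputed"].to_numpy(dtype=bool)
    stratum = panel.snps["stratum"].to_numpy()

    records = []
    for i in range(panel.n_snps):
        reason = ""
        if imputed[i]:
            tier_min = (
                t.imputed_info_min if stratum[i] == "imputed-both" else t.array2_info_min
            )
            if info[i] < tier_min:
                reason = "info"
        elif info[i] < t.info_min:
            reason = "info"
        if not reason and maf[i] < t.maf_min:
            reason = "maf"
        if not reason and miss[i] > t.missing_max:
            reason = "missing"
        if not reason:
            p_hwe, _ = hwe_test(*_genotype_counts(panel.dosages[i]))
            if p_hwe < t.hwe_p_min:
                reason = "hwe"
        if not reason and plate_test and panel.plates is not None:
            if _plate_effect_p(panel.dosages[i], panel.plates) < t.plate_p_min:
                reason = "plate"
        records.append(
            {"item": panel.snps["snp"].iloc[i], "passed": not reason, "reason": reason}
        )
    return QCReport(items=pd.DataFrame(records))


# ------------------------------------------------------------ sample filter


def sample_filter(
    panel: GenotypePanel,
    thresholds: SampleQCThresholds = SampleQCThresholds(),
    grm: GRMatrix | None = None,
) -> QCReport:
    """Exclude samples on call rate, heterozygosity outliers, and then
    relatedness.

    Relatedness removal is iterative: while any retained pair exceeds
    ``ibd_max`` (GRM off-diagonal as the relatedness proxy), the member
    of the worst-offending pair with the lower call rate is dropped
    (ties broken by sample-id order).
    """
    t = thresholds
    call = panel.sample_call_rate()
    het = np.array(
        [
            np.mean(np.abs(col[~np.isnan(col)] - 1.0) < 0.5)
            for col in panel.dosages.T
        ]
    )
    het_sd = het.std(ddof=1) if panel.n_samples > 1 else 0.0
    het_z = (het - het.mean()) / het_sd if het_sd > 0 else np.zeros_like(het)

    reason = np.array([""] * panel.n_samples, dtype=object)
    reason[call < t.call_rate_min] = "call_rate"
    fail_het = (np.abs(het_z) > t.het_z_max) & (reason == "")
    reason[fail_het] = "heterozygosity"

    if grm is not None:
        if grm.ids != list(panel.ids):
            raise ValueError("GRM ids must align with panel samples")
        active = np.where(reason == "")[0]
        active_set = set(active.tolist())
        rel = grm.values
        while True:
            worst, worst_val = None, t.ibd_max
            idx = sorted(active_set)
            for ai, j in enumerate(idx):
                for k in idx[ai + 1 :]:
                    if rel[j, k] > worst_val:
                        worst_val = rel[j, k]
                        worst = (j, k)
            if worst is None:
                break
            j, k = worst
            if call[j] < call[k] or (call[j] == call[k] and panel.ids[j] > panel.ids[k]):
                drop = j
            else:
                drop = k
            reason[drop] = "relatedness"
            active_set.discard(drop)

    items = pd.DataFrame(
        {"item": panel.ids, "passed": reason == "", "reason": reason}
    )
    return QCReport(items=items)


# ----------------------------------------------------------------- pruning


def ld_prune(panel: GenotypePanel, r2_max: float = 0.2, window: int = 50) -> list:
    """Greedy left-to-right LD pruning.

    A SNP is dropped when its squared dosage correlation with any
    already-kept SNP among the previous ``window`` kept SNPs on the same
    chromosome exceeds ``r2_max``.  Zero-variance SNPs are skipped with a
    warning.
    """
    order = np.lexsort(
        (panel.snps["pos"].to_numpy(), panel.snps["chrom"].astype(str).to_numpy())
    )
    kept: list[int] = []
    kept_rows: list[np.ndarray] = []
    kept_chrom: list[str] = []
    chroms = panel.snps["chrom"].astype(str).to_numpy()
    for i in order:
        x = panel.dosages[i]
        obs = ~np.isnan(x)
        if np.nanvar(x) == 0 or obs.sum() < 3:
            warnings.warn(
                f"SNP {panel.snps['snp'].iloc[i]} has zero variance; skipped",
                stacklevel=2,
            )
            continue
        xc = np.where(obs, x, np.nanmean(x))
        drop = False
        for j in range(len(kept) - 1, max(len(kept) - 1 - window, -1), -1):
            if kept_chrom[j] != chroms[i]:
                break
            r = np.corrcoef(xc, kept_rows[j])[0, 1]
            if r * r > r2_max:
                drop = True
                break
        if not drop:
            kept.append(i)
            kept_rows.append(xc)
            kept_chrom.append(chroms[i])
    return [panel.snps["snp"].iloc[i] for i in kept]


# --------------------------------------------------------------------- PCA


def pca(panel: GenotypePanel, k: int = 8):
    """Ancestry principal components from frequency-standardized dosages.

    Missing dosages are mean-imputed; SNP ``i`` is standardized as
    ``(x - 2*p_i) / sqrt(2*p_i*(1 - p_i))``.  Returns ``(components,
    eigenvalues)`` where ``components`` is ``(n_samples, k)`` with
    orthonormal columns and ``eigenvalues`` is the full descending
    spectrum of the sample covariance across SNPs.
    """
    n = panel.n_samples
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n-1={n - 1}")
    p = panel.allele_freq()
    ok = (p > 0) & (p < 1)
    X = panel.dosages[ok]
    p = p[ok]
    X = np.where(np.isnan(X), (2 * p)[:, None], X)
    Z = (X - (2 * p)[:, None]) / np.sqrt(2 * p * (1 - p))[:, None]
    Z = Z - Z.mean(axis=1, keepdims=True)  # remove sample-mean so PCs are centered
    U, s, _ = np.linalg.svd(Z.T, full_matrices=False)
    eigenvalues = s**2 / Z.shape[0]
    return U[:, :k], eigenvalues


# ------------------------------------------------------------- Tracy-Widom

#: Tracy-Widom (TW1) critical values.
TW_CRITICAL = {0.05: 0.9793, 0.01: 2.0234, 0.001: 3.2724}


def tracy_widom_count(
    eigenvalues, n: int, m: int, alpha: float = 0.05
) -> int:
    """Sequential Tracy-Widom test for the number of significant PCs.

    Patterson-style procedure: at each step the leading remaining
    eigenvalue is normalized using an effective-marker-count estimated
    from the remaining spectrum's moments, converted to a TW statistic,
    and compared with the tabulated critical value; testing stops at the
    first non-significant eigenvalue.
    """
    if alpha not in TW_CRITICAL:
        raise ValueError(f"alpha must be one of {sorted(TW_CRITICAL)}")
    crit = TW_CRITICAL[alpha]
    lam = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    lam = lam[lam > 1e-12]
    count = 0
    while lam.size >= 3:
        k = lam.size
        s1, s2 = lam.sum(), np.sum(lam**2)
        denom = (k - 1) * s2 - s1 * s1
        if denom <= 0:
            break
        # moment-based effective marker count corrects for residual LD; it
        # cannot exceed the actual marker count (minus already-claimed PCs)
        n_eff = (k + 1) * s1 * s1 / denom
        n_eff = min(n_eff, m - count) if m else n_eff
        if n_eff <= 1:
            break
        ell = k * lam[0] / s1
        a, b = math.sqrt(n_eff - 1), math.sqrt(k)
        mu = (a + b) ** 2 / n_eff
        sigma = (a + b) / n_eff * (1.0 / a + 1.0 / b) ** (1.0 / 3.0)
        x = (ell - mu) / sigma
        if x > crit:
            count += 1
            lam = lam[1:]
        else:
            break
    return count
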