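"""Shared in-memory containers for the analysis pipeline.

The pipeline moves three kinds of data between stages: a dosage-level
genotype panel, family-structured twin phenotypes, and a genomic
relatedness matrix (GRM).  Each is a thin dataclass around numpy/pandas
objects with the integrity checks the downstream stages rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "TwinDataset",
    "GRMatrix",
    "VarCompFit",
    "GremlFit",
    "AssocRecord",
]

#: Metadata columns every SNP table carries, in order.
SNP_COLUMNS = ["snp", "chrom", "pos", "ref", "alt", "imputed", "stratum", "info"]

#: Genomic-control strata (how a SNP's genotype was obtained).
STRATA = ("genotyped", "imputed-one", "imputed-both")


@dataclass
class GenotypePanel:
    """Biallelic SNP dosages for a set of individuals.

    Parameters
    ----------
    ids
        Sample identifiers, one per column of ``dosages``.
    snps
        Per-SNP metadata table with columns ``snp, chrom, pos, ref, alt,
        imputed, stratum, info``; one row per row of ``dosages``.
    dosages
        ``(n_snps, n_samples)`` array of alternate-allele dosages in
        ``[0, 2]``; missing entries are ``NaN``.
    plates
        Genotyping-plate label per sample (batch covariate for QC).
    subpop
        Optional true subpopulation label per sample (simulation ground
        truth; never consumed by the analyses).
    """

    ids: list
    snps: pd.DataFrame
    dosages: np.ndarray
    plates: np.ndarray | None = None
    subpop: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-d (snps x samples) array")
        m, n = self.dosages.shape
        if len(self.snps) != m:
            raise ValueError(f"snps table has {len(self.snps)} rows for {m} dosage rows")
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} sample ids for {n} dosage columns")
        missing = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"snps table missing columns {missing}")
        if self.plates is not None:
            self.plates = np.asarray(self.plates)
            if self.plates.shape[0] != n:
                raise ValueError("plates must have one label per sample")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[0]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=1) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def snp_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def subset_snps(self, mask_or_index) -> "GenotypePanel":
        idx = np.asarray(mask_or_index)
        return GenotypePanel(
            ids=self.ids,
            snps=self.snps.iloc[idx].reset_index(drop=True)
            if idx.dtype != bool
            else self.snps.loc[idx].reset_index(drop=True),
            dosages=self.dosages[idx],
            plates=self.plates,
            subpop=self.subpop,
        )

    def subset_samples(self, keep_ids) -> "GenotypePanel":
        pos = [self.ids.index(i) for i in keep_ids]
        return GenotypePanel(
            ids=[self.ids[i] for i in pos],
            snps=self.snps,
            dosages=self.dosages[:, pos],
            plates=None if self.plates is None else self.plates[pos],
            subpop=None if self.subpop is None else self.subpop[pos],
        )


@dataclass
class TwinDataset:
    """Long-format twin phenotypes: one row per co-twin.

    ``table`` columns: ``family_id, zygosity, member, phenotype`` with
    ``zygosity`` in {"MZ", "DZ"} and ``member`` in {1, 2}.  Missing
    phenotypes are ``NaN``; a pair with one missing member contributes a
    singleton to full-information fits.
    """

    table: pd.DataFrame

    REQUIRED = ("family_id", "zygosity", "member", "phenotype")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"twin table missing columns {missing}")
        bad = set(self.table["zygosity"].unique()) - {"MZ", "DZ"}
        if bad:
            raise ValueError(f"unknown zygosity labels {bad}")

    def pairs(self, zygosity: str) -> pd.DataFrame:
        """Wide table (``y1``, ``y2``) for one zygosity group."""
        sub = self.table[self.table["zygosity"] == zygosity]
        wide = sub.pivot_table(
            index="family_id", columns="member", values="phenotype", dropna=False
        )
        wide = wide.rename(columns={1: "y1", 2: "y2"})
        for col in ("y1", "y2"):
            if col not in wide.columns:
                wide[col] = np.nan
        return wide[["y1", "y2"]]

    def complete_pairs(self, zygosity: str) -> np.ndarray:
        wide = self.pairs(zygosity)
        return wide.dropna().to_numpy()

    def values(self) -> np.ndarray:
        """All non-missing phenotype values (pooled)."""
        v = self.table["phenotype"].to_numpy(dtype=float)
        return v[~np.isnan(v)]


@dataclass
class GRMatrix:
    """Genomic relatedness matrix with per-pair SNP counts.

    ``values`` is symmetric ``n x n``; ``nsnp[j, k]`` counts SNPs
    non-missing in both ``j`` and ``k`` (GCTA semantics).  ``call_rates``
    carries per-sample genotyping call rates used to break relatedness
    ties during pruning.
    """

    values: np.ndarray
    nsnp: np.ndarray
    ids: list
    call_rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nsnp = np.asarray(self.nsnp)
        self.ids = list(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("GRM must be symmetric within 1e-12")

    @property
    def n(self) -> int:
        return len(self.ids)

    def off_diagonals(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class VarCompFit:
    """Standardized twin variance-component fit.

    ``estimates`` maps component labels (``a2`` and ``c2``/``d2``/``e2``)
    to variance fractions summing to 1; ``ses`` are delta-method standard
    errors (``None`` when the Hessian was not positive definite).  ``aic``
    follows the deviance-minus-2-df convention used in the reported model
    comparison tables; ``aic_parameters`` is the textbook
    ``-2LL + 2 * n_parameters``.
    """

    model: str
    estimates: dict
    ses: dict | None
    minus2ll: float
    df: int
    aic: float
    aic_parameters: float
    n_pairs: int
    n_ll: int
    n_obs: int
    n_free: int
    at_boundary: bool = False
    converged: bool = True


@dataclass
class GremlFit:
    """Single-component GREML fit of SNP heritability."""

    h2_snp: float
    se: float | None
    sigma_g2: float
    sigma_e2: float
    loglik_restricted: float
    n_used: int
    converged: bool
    at_boundary: bool = False


@dataclass
class AssocRecord:
    """Per-SNP association result from the 1-df longitudinal score test."""

    snp: str
    chrom: str
    pos: int
    ref: str
    risk_allele: str
    risk_allele_freq: float
    score_stat: float
    p_raw: float
    p_gc: float | None = None
    tier: str = "none"
    imputed: bool = False
    stratum: str = "genotyped"
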