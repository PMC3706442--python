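"""On-disk formats: dosage matrices (TSV and VCF/DS), phenotype and twin
tables, and GCTA-style text GRM files.

Everything is plain text.  VCF output is VCFv4.2 with a per-genotype
``DS`` (dosage) field and is read back through :mod:`cyvcf2`.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datatypes import SNP_COLUMNS, GenotypePanel, GRMatrix, TwinDataset

__all__ = [
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_vcf",
    "read_vcf",
    "write_phenotypes",
    "read_phenotypes",
    "write_twins",
    "read_twins",
    "write_grm",
    "read_grm",
    "write_panel",
]

NA = "NA"


class IntegrityError(ValueError):
    """Raised when tables that must share ids disagree."""


# ---------------------------------------------------------------- dosage TSV


def write_dosage_tsv(panel: GenotypePanel, path: str) -> None:
    """Rows = SNPs; metadata columns then one dosage column per sample."""
    df = panel.snps.copy()
    dos = pd.DataFrame(panel.dosages, columns=panel.ids)
    out = pd.concat([df.reset_index(drop=True), dos.reset_index(drop=True)], axis=1)
    header = "#plates=" + ",".join(
        map(str, panel.plates if panel.plates is not None else [])
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        out.to_csv(fh, sep="\t", index=False, na_rep=NA, float_format="%.6g")


def read_dosage_tsv(path: str) -> GenotypePanel:
    with open(path) as fh:
        first = fh.readline().strip()
        plates = None
        if first.startswith("#plates="):
            body = first[len("#plates=") :]
            plates = np.array(body.split(",")) if body else None
            df = pd.read_csv(fh, sep="\t", na_values=[NA])
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", na_values=[NA])
    meta = df[SNP_COLUMNS].copy()
    meta = meta.astype(
        {"chrom": str, "pos": int, "imputed": bool, "info": float}
    )
    sample_cols = [c for c in df.columns if c not in SNP_COLUMNS]
    dosages = df[sample_cols].to_numpy(dtype=float)
    return GenotypePanel(ids=sample_cols, snps=meta, dosages=dosages, plates=plates)


# ---------------------------------------------------------------------- VCF


def write_vcf(panel: GenotypePanel, path: str) -> None:
    """VCFv4.2 with INFO fields for provenance and a FORMAT DS field.

    Records are sorted by (chrom, pos); positions are 1-based per the
    format contract.
    """
    order = np.lexsort(
        (panel.snps["pos"].to_numpy(), panel.snps["chrom"].astype(str).to_numpy())
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(panel.snps["chrom"].astype(str).iloc[order]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=IMP,Number=0,Type=Flag,Description="Imputed SNP">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Info score">\n')
        fh.write(
            '##INFO=<ID=STRATUM,Number=1,Type=String,Description="GC stratum">\n'
        )
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.ids)
            + "\n"
        )
        for i in order:
            rec = panel.snps.iloc[i]
            info = f"INFO={rec['info']:.4g};STRATUM={rec['stratum']}"
            if rec["imputed"]:
                info = "IMP;" + info
            ds = "\t".join(
                "." if np.isnan(d) else f"{d:.4g}" for d in panel.dosages[i]
            )
            fh.write(
                f"{rec['chrom']}\t{int(rec['pos'])}\t{rec['snp']}\t{rec['ref']}\t"
                f"{rec['alt']}\t.\tPASS\t{info}\tDS\t{ds}\n"
            )


def read_vcf(path: str) -> GenotypePanel:
    """Read a dosage VCF through cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    ids = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        rows.append(
            {
                "snp": var.ID,
                "chrom": str(var.CHROM),
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "imputed": bool(var.INFO.get("IMP") is not None),
                "stratum": var.INFO.get("STRATUM") or "genotyped",
                "info": float(var.INFO.get("INFO") or 1.0),
            }
        )
        ds = var.format("DS")
        dosages.append(np.asarray(ds, dtype=float).ravel())
    snps = pd.DataFrame(rows)[SNP_COLUMNS]
    return GenotypePanel(ids=ids, snps=snps, dosages=np.array(dosages))


# -------------------------------------------------------- phenotypes / twins

PHENO_COLUMNS = ["id", "sex", "cohort", "plate", "y7", "y9", "y12"]


def write_phenotypes(pheno: pd.DataFrame, path: str, header_note: str = "") -> None:
    cols = [c for c in PHENO_COLUMNS if c in pheno.columns]
    extra = [c for c in pheno.columns if c not in cols and c != "true_g"]
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"#{header_note}\n")
        pheno[cols + extra].to_csv(fh, sep="\t", index=False, na_rep=NA)


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], comment="#")


def write_twins(twins: TwinDataset, path: str) -> None:
    twins.table.rename(columns={"phenotype": "y_composite"}).to_csv(
        path, sep="\t", index=False, na_rep=NA
    )


def read_twins(path: str) -> TwinDataset:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    return TwinDataset(df.rename(columns={"y_composite": "phenotype"}))


# ----------------------------------------------------------------- GRM text


def write_grm(grm: GRMatrix, prefix: str) -> None:
    """GCTA-compatible text pair: ``<prefix>.grm.id`` and ``<prefix>.grm``.

    The triangle file holds 1-based ``row col nsnp value`` lines over the
    lower triangle including the diagonal.
    """
    with open(prefix + ".grm.id", "w") as fh:
        for i in grm.ids:
            fh.write(f"{i}\t{i}\n")
    with open(prefix + ".grm", "w") as fh:
        for j in range(grm.n):
            for k in range(j + 1):
                fh.write(
                    f"{j + 1}\t{k + 1}\t{int(grm.nsnp[j, k])}\t"
                    f"{grm.values[j, k]:.10g}\n"
                )


def read_grm(prefix: str) -> GRMatrix:
    ids = []
    with open(prefix + ".grm.id") as fh:
        for line in fh:
            parts = line.split()
            if parts:
                ids.append(parts[1])
    n = len(ids)
    values = np.zeros((n, n))
    nsnp = np.zeros((n, n), dtype=int)
    with open(prefix + ".grm") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            j, k = int(parts[0]) - 1, int(parts[1]) - 1
            if not (0 <= k <= j < n):
                raise ValueError(
                    f"{prefix}.grm line {lineno}: indices ({j + 1},{k + 1}) "
                    f"out of range for {n} ids"
                )
            nsnp[j, k] = nsnp[k, j] = int(parts[2])
            values[j, k] = values[k, j] = float(parts[3])
    return GRMatrix(values=values, nsnp=nsnp, ids=ids)


# ------------------------------------------------------------- panel bundle


def write_panel(
    panel: GenotypePanel,
    phenotypes: pd.DataFrame,
    out_dir: str,
    vcf: bool = False,
    twins: TwinDataset | None = None,
) -> dict:
    """Write the full simulated bundle to ``out_dir``; returns the paths.

    Raises :class:`IntegrityError` when the phenotype table's ids do not
    match the panel's sample ids.
    """
    if list(phenotypes["id"]) != list(panel.ids):
        raise IntegrityError("phenotype ids do not match panel sample ids")
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    if vcf:
        paths["genotypes"] = os.path.join(out_dir, "genotypes.vcf")
        write_vcf(panel, paths["genotypes"])
    else:
        paths["genotypes"] = os.path.join(out_dir, "dosages.tsv")
        write_dosage_tsv(panel, paths["genotypes"])
    paths["phenotypes"] = os.path.join(out_dir, "phenotypes.tsv")
    write_phenotypes(phenotypes, paths["phenotypes"])
    if twins is not None:
        paths["twins"] = os.path.join(out_dir, "twins.tsv")
        write_twins(twins, paths["twins"])
    return paths
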