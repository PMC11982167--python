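"""Readers and writers for genotype, phenotype and result tables.

Genotypes round-trip through three formats: VCF v4.2 (read via cyvcf2,
written as plain text with homozygous diploid GT calls), PLINK text
.ped/.map, and a TSV dosage matrix (lines x SNPs) paired with a SNP-map
TSV. All numeric TSVs use a header row, '.' for undefined values and a
locale-independent decimal point.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, SNP_COLUMNS

__all__ = [
    "read_genotypes", "write_genotypes",
    "read_vcf", "write_vcf", "read_plink", "write_plink",
    "read_dosage_tsv", "write_dosage_tsv", "write_tsv", "read_tsv",
]


# ---------------------------------------------------------------------------
# generic TSV
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(geno: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF v4.2 with GT calls (0/0, 0/1, 1/1, ./.)."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(geno.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(l) for l in geno.lines) + "\n")
        snps = geno.snps
        for j in range(geno.n_snps):
            calls = "\t".join(
                code.get(geno.dosage[i, j], "./.")
                if not np.isnan(geno.dosage[i, j]) else "./."
                for i in range(geno.n_lines))
            fh.write(f"{snps['chrom'][j]}\t{snps['pos_bp'][j]}\t{snps['snp_id'][j]}"
                     f"\t{snps['allele_ref'][j]}\t{snps['allele_alt'][j]}"
                     f"\t.\t.\t.\tGT\t{calls}\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read biallelic sites from a VCF into alt-dosage codes."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    lines = list(vcf.samples)
    ids, chroms, pos, ref, alt, rows = [], [], [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        g = var.genotype.array()[:, :2].astype(float)
        g[g < 0] = np.nan
        rows.append(g.sum(axis=1))
    vcf.close()
    if n_multi:
        import logging
        logging.getLogger(__name__).info("skipped %d multi-allelic sites", n_multi)
    snps = pd.DataFrame({
        "snp_id": ids, "chrom": chroms, "pos_bp": np.array(pos, dtype=np.int64),
        "pos_cm": np.array(pos, dtype=float) / 4.5e6,
        "allele_ref": ref, "allele_alt": alt,
    })
    return GenotypeMatrix(lines=lines, snps=snps,
                          dosage=np.column_stack(rows) if rows else
                          np.empty((len(lines), 0)))


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

def write_plink(geno: GenotypeMatrix, prefix: str) -> None:
    """Write PLINK .ped/.map; alleles per call, '0 0' for missing."""
    snps = geno.snps
    with open(prefix + ".map", "w") as fh:
        for j in range(geno.n_snps):
            fh.write(f"{snps['chrom'][j]}\t{snps['snp_id'][j]}"
                     f"\t{snps['pos_cm'][j]:.6f}\t{snps['pos_bp'][j]}\n")
    ref = snps["allele_ref"].to_numpy()
    alt = snps["allele_alt"].to_numpy()
    with open(prefix + ".ped", "w") as fh:
        for i, line in enumerate(geno.lines):
            alleles = []
            for j in range(geno.n_snps):
                d = geno.dosage[i, j]
                if np.isnan(d):
                    alleles += ["0", "0"]
                elif d == 0:
                    alleles += [ref[j], ref[j]]
                elif d == 1:
                    alleles += [ref[j], alt[j]]
                else:
                    alleles += [alt[j], alt[j]]
            fh.write(f"{line} {line} 0 0 0 -9 " + " ".join(alleles) + "\n")


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read PLINK text .ped/.map.

    .ped does not record allele roles, so ref/alt are assigned
    alphabetically (deterministic); dosage round-trips exactly whenever the
    reference allele sorts before the alternate, as in files this package
    writes."""
    mp = pd.read_csv(prefix + ".map", sep=r"\s+", header=None,
                     names=["chrom", "snp_id", "pos_cm", "pos_bp"])
    ped = pd.read_csv(prefix + ".ped", sep=r"\s+", header=None, dtype=str)
    m = len(mp)
    if ped.shape[1] != 6 + 2 * m:
        raise ValueError(f"{prefix}.ped has {ped.shape[1]} columns, "
                         f"expected {6 + 2 * m}")
    lines = ped.iloc[:, 1].tolist()
    a1 = ped.iloc[:, 6::2].to_numpy(dtype=object)
    a2 = ped.iloc[:, 7::2].to_numpy(dtype=object)
    dosage = np.full((len(lines), m), np.nan)
    refs, alts = [], []
    for j in range(m):
        col = np.concatenate([a1[:, j], a2[:, j]])
        seen = sorted(set(col) - {"0"})
        if len(seen) > 2:
            raise ValueError(f"SNP {mp['snp_id'][j]!r} has >2 alleles")
        ref = seen[0] if seen else "A"
        alt = seen[1] if len(seen) > 1 else ("G" if ref != "G" else "A")
        refs.append(ref)
        alts.append(alt)
        ok = (a1[:, j] != "0") & (a2[:, j] != "0")
        dosage[ok, j] = (a1[ok, j] == alt).astype(float) + (a2[ok, j] == alt)
    snps = mp.assign(allele_ref=refs, allele_alt=alts)[SNP_COLUMNS]
    snps["pos_bp"] = snps["pos_bp"].astype(np.int64)
    return GenotypeMatrix(lines=lines, snps=snps, dosage=dosage)


# ---------------------------------------------------------------------------
# TSV dosage
# ---------------------------------------------------------------------------

def write_dosage_tsv(geno: GenotypeMatrix, path: str, map_path: str | None = None) -> None:
    df = pd.DataFrame(geno.dosage, columns=geno.snps["snp_id"])
    df.insert(0, "line_id", geno.lines)
    write_tsv(df, path)
    write_tsv(geno.snps, map_path or _map_path(path))


def _map_path(path: str) -> str:
    base, _ = os.path.splitext(path)
    return base + ".snpmap.tsv"


def read_dosage_tsv(path: str, map_path: str | None = None) -> GenotypeMatrix:
    df = read_tsv(path)
    snps = read_tsv(map_path or _map_path(path))
    lines = df["line_id"].tolist()
    dosage = df.drop(columns="line_id").to_numpy(dtype=float)
    order = {s: j for j, s in enumerate(df.columns[1:])}
    snps = snps.sort_values("snp_id", key=lambda s: s.map(order)).reset_index(drop=True)
    return GenotypeMatrix(lines=lines, snps=snps[SNP_COLUMNS], dosage=dosage)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_genotypes(path: str, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes; format inferred from the extension when omitted."""
    if format is None:
        if path.endswith(".vcf") or path.endswith(".vcf.gz"):
            format = "vcf"
        elif path.endswith(".ped") or os.path.exists(path + ".ped"):
            format = "plink_text"
        else:
            format = "tsv"
    if format == "vcf":
        return read_vcf(path)
    if format == "plink_text":
        return read_plink(path[:-4] if path.endswith(".ped") else path)
    if format == "tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(geno: GenotypeMatrix, path: str, format: str = "tsv") -> None:
    if format == "vcf":
        write_vcf(geno, path)
    elif format == "plink_text":
        write_plink(geno, path[:-4] if path.endswith(".ped") else path)
    elif format == "tsv":
        write_dosage_tsv(geno, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
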