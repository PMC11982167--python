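"""Core containers shared across the pipeline.

Genotypes live in a :class:`GenotypeMatrix`: a lines x SNPs dosage array
(count of the alternate allele, 0/1/2, NaN = missing call) plus a SNP map
(chromosome, physical bp, genetic cM, alleles). Phenotypes move through the
pipeline as plain pandas DataFrames with documented column contracts:

* plot table  — env, row, col, rep, line_id, element, value
* BLUE table  — env, element, line_id, blue, se
* association — snp_id, chr, pos_bp, pos_cm, allele_alt, allele_ref,
                af, n, beta, se, t, p
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

SNP_COLUMNS = ["snp_id", "chrom", "pos_bp", "pos_cm", "allele_ref", "allele_alt"]

PLOT_COLUMNS = ["env", "row", "col", "rep", "line_id", "element", "value"]
BLUE_COLUMNS = ["env", "element", "line_id", "blue", "se"]
ASSOC_COLUMNS = [
    "snp_id", "chr", "pos_bp", "pos_cm", "allele_alt", "allele_ref",
    "af", "n", "beta", "se", "t", "p",
]


def natural_chrom_key(label: str) -> tuple:
    """Sort key putting 1A < 1B < ... < 7D and 2 < 10 where numeric."""
    s = str(label)
    num = ""
    for ch in s:
        if ch.isdigit():
            num += ch
        else:
            break
    return (int(num) if num else np.inf, s[len(num):], s)


@dataclass
class GenotypeMatrix:
    """Lines x SNPs alt-allele dosages with a SNP map.

    Parameters
    ----------
    lines
        Line identifiers, one per dosage row.
    snps
        DataFrame with columns ``snp_id, chrom, pos_bp, pos_cm,
        allele_ref, allele_alt``; ``pos_bp`` strictly increasing within
        each chromosome.
    dosage
        float array, shape (n_lines, n_snps); values in {0, 1, 2} or NaN.
    """

    lines: list
    snps: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.lines = list(self.lines)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.lines), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.lines)} lines x {len(self.snps)} SNPs"
            )
        missing = set(SNP_COLUMNS) - set(self.snps.columns)
        if missing:
            raise ValueError(f"SNP map lacks columns: {sorted(missing)}")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("duplicated snp_id in SNP map")
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        for _, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if (np.diff(pos) <= 0).any():
                raise ValueError("pos_bp not strictly increasing within a chromosome")

    # -- basic geometry -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def line_index(self, ids: Sequence) -> np.ndarray:
        lookup = {l: i for i, l in enumerate(self.lines)}
        try:
            return np.array([lookup[l] for l in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"line {exc.args[0]!r} not in genotype matrix") from None

    # -- per-SNP summaries ----------------------------------------------
    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def line_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=1)

    # -- subsetting ------------------------------------------------------
    def subset(self, line_mask=None, snp_mask=None) -> "GenotypeMatrix":
        """Return a view-free copy restricted to boolean/index masks."""
        li = np.arange(self.n_lines) if line_mask is None else np.flatnonzero(line_mask) \
            if np.asarray(line_mask).dtype == bool else np.asarray(line_mask, dtype=int)
        si = np.arange(self.n_snps) if snp_mask is None else np.flatnonzero(snp_mask) \
            if np.asarray(snp_mask).dtype == bool else np.asarray(snp_mask, dtype=int)
        return GenotypeMatrix(
            lines=[self.lines[i] for i in li],
            snps=self.snps.iloc[si].reset_index(drop=True),
            dosage=self.dosage[np.ix_(li, si)].copy(),
        )

    def subset_lines(self, ids: Sequence) -> "GenotypeMatrix":
        return self.subset(line_mask=self.line_index(ids))

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.lines), self.snps.copy(), self.dosage.copy())


@dataclass
class TraitArchitecture:
    """Ground-truth genetic architecture behind a simulated trait panel.

    ``qtl_effects`` holds one row per QTL SNP and one column per element
    (additive effect per alt-allele copy, on the scale where the plot-level
    residual SD is 1); ``genetic_values`` the resulting line x element true
    genetic values.
    """

    elements: list
    group1: list
    group2: list
    qtl_effects: pd.DataFrame          # index snp_id, columns elements
    qtl_flags: pd.DataFrame            # index snp_id, columns kind/antagonistic
    genetic_values: pd.DataFrame       # index line_id, columns elements
    h2_target: dict
    rg_within: float
    rg_between: float
    env_scalers: dict = field(default_factory=dict)

    def scaler(self, env: str) -> float:
        return float(self.env_scalers.get(env, 1.0))


@dataclass
class QcReport:
    """Counts emitted by the genotype QC / imputation stage."""

    n_lines_removed: int = 0
    n_snps_removed_callrate: int = 0
    n_snps_removed_maf: int = 0
    n_imputed_cells: int = 0
    n_fallback_cells: int = 0
    imputation_concordance: float = float("nan")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


@dataclass
class Grm:
    """Genomic relatedness matrix with its line labels."""

    lines: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.lines)
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square with one row per line")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    def subset_lines(self, ids: Sequence) -> "Grm":
        lookup = {l: i for i, l in enumerate(self.lines)}
        idx = np.array([lookup[l] for l in ids], dtype=int)
        return Grm(list(ids), self.values[np.ix_(idx, idx)].copy())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.lines, columns=self.lines)
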