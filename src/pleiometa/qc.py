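"""Genotype quality control and LD-kNN imputation.

The filtering pipeline follows the usual array-genotyping order: lines with
over 40% missing calls are dropped first (missingness counted on the
unfiltered SNP set), then SNPs with call rate below 60% and minor-allele
frequency below 5% are removed. All thresholds are strict inequalities.

Remaining missing calls are filled by LD-kNN imputation: for each SNP the
``l_snps`` markers in highest LD with it define a local genotype space; a
line's missing call is voted on by its ``k_neighbors`` nearest lines in that
space (Manhattan distance, inverse-distance weights). Accuracy is
reported from masking cross-validation (hide a fraction of observed calls,
re-impute, count matches).
"""

from __future__ import annotations

import numpy as np

from ._rng import substream
from .datatypes import GenotypeMatrix, QcReport

__all__ = ["snp_maf", "filter_lines", "filter_snps", "impute_ld_knn", "run_qc"]


def snp_maf(dosages: np.ndarray) -> float:
    """Minor-allele frequency of one SNP from dosages in {0,1,2,NaN}.

    The alt-allele frequency is sum(dosage) / (2 * n_nonmissing); the MAF is
    the folded frequency min(p, 1-p).
    """
    d = np.asarray(dosages, dtype=float)
    obs = d[~np.isnan(d)]
    if obs.size == 0:
        raise ValueError("all dosages missing")
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


def filter_lines(geno: GenotypeMatrix, max_missing: float = 0.40):
    """Drop lines with missing fraction strictly greater than ``max_missing``."""
    miss = geno.line_missing_rate()
    keep = miss <= max_missing
    if not keep.any():
        raise ValueError("all lines exceed the missingness threshold")
    report = QcReport(n_lines_removed=int((~keep).sum()))
    out = geno.subset(line_mask=keep) if not keep.all() else geno.copy()
    return out, report


def filter_snps(geno: GenotypeMatrix, min_call_rate: float = 0.60,
                min_maf: float = 0.05):
    """Drop SNPs with call rate < ``min_call_rate``, then MAF < ``min_maf``."""
    cr = geno.call_rate()
    keep_cr = cr >= min_call_rate
    n_cr = int((~keep_cr).sum())
    step1 = geno.subset(snp_mask=keep_cr) if not keep_cr.all() else geno
    maf = step1.maf()
    keep_maf = maf >= min_maf
    n_maf = int((~keep_maf).sum())
    if not keep_maf.any():
        raise ValueError("all SNPs removed by QC filters")
    out = step1.subset(snp_mask=keep_maf) if not keep_maf.all() else step1.copy()
    report = QcReport(n_snps_removed_callrate=n_cr, n_snps_removed_maf=n_maf)
    return out, report


def _ld_rank(dosage_filled: np.ndarray) -> np.ndarray:
    """r2 between all SNP pairs on mean-filled dosages (ranking only)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(dosage_filled, rowvar=False)
    c = np.nan_to_num(c, nan=0.0)
    return c * c


def _impute_cells(dosage: np.ndarray, mask: np.ndarray, top_ld: np.ndarray,
                  k_neighbors: int):
    """Fill cells flagged in ``mask`` in-place; returns fallback count.

    ``top_ld[s]`` lists the SNP indices used as the local space for SNP s.
    """
    n_fallback = 0
    obs = ~np.isnan(dosage)
    for s in np.flatnonzero(mask.any(axis=0)):
        targets = np.flatnonzero(mask[:, s])
        donors = np.flatnonzero(obs[:, s] & ~mask[:, s])
        if donors.size == 0:
            dosage[targets, s] = 0.0
            n_fallback += targets.size
            continue
        ctx = top_ld[s]
        A = dosage[np.ix_(targets, ctx)]          # queries
        B = dosage[np.ix_(donors, ctx)]           # donors
        diff = np.abs(A[:, None, :] - B[None, :, :])
        valid = ~np.isnan(diff)
        diff = np.where(valid, diff, 0.0)
        n_valid = valid.sum(axis=2)
        # mean absolute difference over jointly observed context SNPs
        dist = diff.sum(axis=2) / np.maximum(n_valid, 1)
        dist[n_valid == 0] = np.inf
        k = min(k_neighbors, donors.size)
        for qi, t in enumerate(targets):
            drow = dist[qi]
            # stable k nearest: sort by (distance, donor order)
            nearest = np.lexsort((np.arange(donors.size), drow))[:k]
            dd = drow[nearest]
            if not np.isfinite(dd).any():
                vals = dosage[donors, s]
                uniq, cnt = np.unique(vals, return_counts=True)
                dosage[t, s] = uniq[np.argmax(cnt)]
                n_fallback += 1
                continue
            w = 1.0 / (dd[np.isfinite(dd)] + 1e-9)
            votes = {}
            for wv, di in zip(w, nearest[np.isfinite(dd)]):
                g = dosage[donors[di], s]
                votes[g] = votes.get(g, 0.0) + wv
            # highest weight wins; ties broken toward the lower dosage
            dosage[t, s] = min(votes, key=lambda g: (-votes[g], g))
    return n_fallback


def impute_ld_knn(geno: GenotypeMatrix, k_neighbors: int = 5, l_snps: int = 30,
                  cv_fraction: float = 0.01, seed: int = 0):
    """LD-kNN imputation of all missing calls, with masking cross-validation.

    Returns a complete GenotypeMatrix and a QcReport whose
    ``imputation_concordance`` is the fraction of deliberately hidden
    observed calls recovered exactly.
    """
    if geno.n_snps < 2:
        raise ValueError("need at least 2 SNPs for LD-kNN imputation")
    dosage = geno.dosage.copy()
    missing = np.isnan(dosage)
    n_missing = int(missing.sum())

    col_mean = np.nanmean(dosage, axis=0)
    filled = np.where(missing, col_mean[None, :], dosage)
    r2 = _ld_rank(filled)
    np.fill_diagonal(r2, -1.0)
    l_eff = min(l_snps, geno.n_snps - 1)
    # top-l LD partners per SNP (ties resolved by SNP order via stable sort)
    top_ld = np.argsort(-r2, axis=1, kind="stable")[:, :l_eff]

    # masking cross-validation on observed cells
    rng = substream(seed, "impute-cv")
    obs_idx = np.flatnonzero(~missing.ravel())
    concordance = float("nan")
    if obs_idx.size and cv_fraction > 0:
        n_mask = max(1, int(round(cv_fraction * obs_idx.size)))
        hide = rng.choice(obs_idx, size=n_mask, replace=False)
        cv = dosage.copy()
        truth = cv.ravel()[hide].copy()
        cv.ravel()[hide] = np.nan
        cv_mask = np.zeros_like(missing)
        cv_mask.ravel()[hide] = True
        _impute_cells(cv, cv_mask | missing, top_ld, k_neighbors)
        concordance = float(np.mean(cv.ravel()[hide] == truth))

    n_fallback = _impute_cells(dosage, missing, top_ld, k_neighbors)
    out = GenotypeMatrix(list(geno.lines), geno.snps.copy(), dosage)
    report = QcReport(n_imputed_cells=n_missing, n_fallback_cells=n_fallback,
                      imputation_concordance=concordance)
    return out, report


def run_qc(geno: GenotypeMatrix, max_missing: float = 0.40,
           min_call_rate: float = 0.60, min_maf: float = 0.05,
           k_neighbors: int = 5, l_snps: int = 30, seed: int = 0):
    """Full QC pipeline: line filter, SNP filters, LD-kNN imputation."""
    g1, rep_lines = filter_lines(geno, max_missing)
    g2, rep_snps = filter_snps(g1, min_call_rate, min_maf)
    g3, rep_imp = impute_ld_knn(g2, k_neighbors, l_snps, seed=seed)
    report = QcReport(
        n_lines_removed=rep_lines.n_lines_removed,
        n_snps_removed_callrate=rep_snps.n_snps_removed_callrate,
        n_snps_removed_maf=rep_snps.n_snps_removed_maf,
        n_imputed_cells=rep_imp.n_imputed_cells,
        n_fallback_cells=rep_imp.n_fallback_cells,
        imputation_concordance=rep_imp.imputation_concordance,
    )
    return g3, report
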