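"""Univariate mixed-linear-model association scans.

Model per SNP:  y = mu + x beta + alpha + eps, with the polygenic effect
alpha ~ N(0, lambda * tau^-1 * G) controlling relatedness; lambda = vg/ve is
either re-estimated by REML for every SNP (exact mixed model, the default)
or fixed at the null-model estimate (fast approximation). One
eigendecomposition of the GRM reduces every REML evaluation to weighted
least squares in the rotated basis, and the whole SNP panel is processed
with vectorised grid + golden-section refinement of lambda.

Effect sizes are reported per alt-allele copy, so signs are comparable
across analyses; the test is a Wald t with n - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import GenotypeMatrix, Grm

__all__ = ["MLMScan", "fit_null", "scan", "NullModelFit"]

_LAMBDA_GRID = np.logspace(-5, 5, 61)
_PHI = (np.sqrt(5) - 1) / 2


@dataclass
class NullModelFit:
    lambda_ratio: float
    loglik: float
    converged: bool


class MLMScan:
    """Association scan engine for one analysis (one phenotype vector).

    Parameters
    ----------
    y
        Phenotype (BLUEs) for a set of lines; NaN entries are dropped.
    geno
        Complete genotype matrix covering at least those lines.
    grm
        GRM covering the same lines (sub-setting is taken care of).
    lines
        Line ids aligning ``y``; defaults to ``geno.lines``.
    """

    def __init__(self, y, geno: GenotypeMatrix, grm: Grm, lines=None):
        lines = list(lines) if lines is not None else list(geno.lines)
        y = np.asarray(y, dtype=float)
        if y.size != len(lines):
            raise ValueError("phenotype length does not match line list")
        ok = ~np.isnan(y)
        self.lines = [l for l, o in zip(lines, ok) if o]
        self.y = y[ok]
        self.n = self.y.size
        if self.n < 10:
            raise ValueError("fewer than 10 lines with phenotypes")
        sub = geno.subset_lines(self.lines)
        if np.isnan(sub.dosage).any():
            raise ValueError("scan requires imputed (complete) genotypes")
        self.geno = sub
        G = grm.subset_lines(self.lines).values
        d, U = np.linalg.eigh(G)
        self.d = np.clip(d, 0.0, None)
        self.ystar = U.T @ self.y
        self.ones_star = U.T @ np.ones(self.n)
        self.Xstar = U.T @ sub.dosage            # n x m rotated dosages

    # -- core weighted-regression sums (vectorised over SNPs) -------------
    def _sums(self, lam, Xs):
        """Per-SNP REML pieces at per-SNP lambda ``lam`` (scalar or m-vector)."""
        lam = np.asarray(lam, dtype=float)
        if lam.ndim == 0:
            w = 1.0 / (lam * self.d + 1.0)           # n
            W = w[:, None]
        else:
            W = 1.0 / (lam[None, :] * self.d[:, None] + 1.0)   # n x m
            w = None
        o, ys = self.ones_star, self.ystar
        if W.shape[1] == 1 or w is not None:
            s11 = np.sum(w * o * o)
            s1y = np.sum(w * o * ys)
            syy = np.sum(w * ys * ys)
            s1x = (w * o) @ Xs
            sxy = (w * ys) @ Xs
            sxx = w @ (Xs * Xs)
            logc = np.log(lam * self.d + 1.0).sum()
            logc = np.full(Xs.shape[1], logc)
        else:
            s11 = np.einsum("i,ij->j", o * o, W)
            s1y = np.einsum("i,ij->j", o * ys, W)
            syy = np.einsum("i,ij->j", ys * ys, W)
            s1x = np.einsum("ij,ij->j", (o[:, None] * Xs), W)
            sxy = np.einsum("ij,ij->j", (ys[:, None] * Xs), W)
            sxx = np.einsum("ij,ij->j", (Xs * Xs), W)
            logc = np.log(lam[None, :] * self.d[:, None] + 1.0).sum(axis=0)
        det = s11 * sxx - s1x ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = (s11 * sxy - s1x * s1y) / det
            mu = (sxx * s1y - s1x * sxy) / det
            rss = syy - mu * s1y - beta * sxy
        return beta, rss, det, s11, logc

    def _reml_ll(self, lam, Xs):
        beta, rss, det, s11, logc = self._sums(lam, Xs)
        dof = self.n - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            s2 = rss / dof
            ll = -0.5 * (dof * (np.log(2 * np.pi * s2) + 1.0) + logc + np.log(det))
        return np.where((rss > 0) & (det > 0), ll, -np.inf)

    # -- null model -------------------------------------------------------
    def fit_null(self) -> NullModelFit:
        """REML estimate of lambda under the intercept-only model."""
        o, ys, d = self.ones_star, self.ystar, self.d

        def ll(lam):
            c = lam * d + 1.0
            w = 1.0 / c
            s11 = np.sum(w * o * o)
            s1y = np.sum(w * o * ys)
            syy = np.sum(w * ys * ys)
            rss = syy - s1y ** 2 / s11
            dof = self.n - 1
            if rss <= 0 or s11 <= 0:
                return -np.inf
            s2 = rss / dof
            return -0.5 * (dof * (np.log(2 * np.pi * s2) + 1.0)
                           + np.log(c).sum() + np.log(s11))

        grid_ll = np.array([ll(l) for l in _LAMBDA_GRID])
        j = int(np.argmax(grid_ll))
        lo = _LAMBDA_GRID[max(j - 1, 0)]
        hi = _LAMBDA_GRID[min(j + 1, len(_LAMBDA_GRID) - 1)]
        res = optimize.minimize_scalar(lambda t: -ll(np.exp(t)),
                                       bounds=(np.log(lo), np.log(hi)),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        lam = float(np.exp(res.x))
        best_ll = ll(lam)
        # allow the boundary lambda -> 0
        ll0 = ll(0.0)
        if ll0 >= best_ll:
            lam, best_ll = 0.0, ll0
        return NullModelFit(lambda_ratio=lam, loglik=float(best_ll),
                            converged=bool(res.success))

    # -- scan -------------------------------------------------------------
    def scan(self, mode: str = "per_snp_lambda", refine_iters: int = 40
             ) -> pd.DataFrame:
        """Run the association scan; returns the fixed-column table."""
        if mode not in ("per_snp_lambda", "null_lambda"):
            raise ValueError("mode must be 'per_snp_lambda' or 'null_lambda'")
        m = self.geno.n_snps
        sd = self.geno.dosage.std(axis=0)
        poly = sd > 0
        Xs = self.Xstar

        if mode == "null_lambda":
            lam_opt = np.full(m, self.fit_null().lambda_ratio)
        else:
            grid = np.concatenate([[0.0], _LAMBDA_GRID])
            lls = np.stack([self._reml_ll(l, Xs) for l in grid])  # g x m
            j = np.argmax(lls, axis=0)
            lo = np.log(np.maximum(grid[np.maximum(j - 1, 0)], 1e-8))
            hi = np.log(np.maximum(grid[np.minimum(j + 1, grid.size - 1)], 1e-7))
            # vectorised golden-section on log-lambda per SNP
            a, b = lo, hi
            c1 = b - _PHI * (b - a)
            c2 = a + _PHI * (b - a)
            f1 = self._reml_ll(np.exp(c1), Xs)
            f2 = self._reml_ll(np.exp(c2), Xs)
            for _ in range(refine_iters):
                take1 = f1 >= f2
                b = np.where(take1, c2, b)
                a = np.where(take1, a, c1)
                c1 = b - _PHI * (b - a)
                c2 = a + _PHI * (b - a)
                f1 = self._reml_ll(np.exp(c1), Xs)
                f2 = self._reml_ll(np.exp(c2), Xs)
            lam_ref = np.exp((a + b) / 2)
            ll_ref = self._reml_ll(lam_ref, Xs)
            ll_grid = lls[j, np.arange(m)]
            lam_grid = grid[j]
            lam_opt = np.where(ll_ref >= ll_grid, lam_ref, lam_grid)

        beta, rss, det, s11, _ = self._sums(lam_opt, Xs)
        dof = self.n - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            s2 = rss / dof
            se = np.sqrt(s2 * s11 / det)
            t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), dof)

        out = pd.DataFrame({
            "snp_id": self.geno.snps["snp_id"],
            "chr": self.geno.snps["chrom"],
            "pos_bp": self.geno.snps["pos_bp"],
            "pos_cm": self.geno.snps["pos_cm"],
            "allele_alt": self.geno.snps["allele_alt"],
            "allele_ref": self.geno.snps["allele_ref"],
            "af": self.geno.alt_freq(),
            "n": self.n,
            "beta": beta,
            "se": se,
            "t": t,
            "p": np.clip(p, np.nextafter(0, 1), 1.0),
            "lambda": lam_opt,
            "flag": np.where(poly, "", "monomorphic"),
        })
        # monomorphic SNPs keep the matrix rectangular: null record
        mono = ~poly
        if mono.any():
            out.loc[mono, ["beta", "t"]] = 0.0
            out.loc[mono, "se"] = np.nan
            out.loc[mono, "p"] = 1.0
        return out


def fit_null(y, grm: Grm, lines=None) -> NullModelFit:
    """Intercept-only REML fit of the variance ratio lambda = vg/ve."""
    y = np.asarray(y, dtype=float)
    lines = list(lines) if lines is not None else list(grm.lines)
    ok = ~np.isnan(y)
    kept = [l for l, o in zip(lines, ok) if o]
    G = grm.subset_lines(kept).values
    dummy = _NullOnly(y[ok], G)
    return dummy.fit_null()


class _NullOnly(MLMScan):
    """MLMScan specialised to the covariate-only model (no genotypes)."""

    def __init__(self, y, G):
        self.y = np.asarray(y, dtype=float)
        self.n = self.y.size
        d, U = np.linalg.eigh(G)
        self.d = np.clip(d, 0.0, None)
        self.ystar = U.T @ self.y
        self.ones_star = U.T @ np.ones(self.n)


def scan(y, geno: GenotypeMatrix, grm: Grm, lines=None,
         mode: str = "per_snp_lambda") -> pd.DataFrame:
    """Convenience wrapper: build an MLMScan and run it."""
    return MLMScan(y, geno, grm, lines=lines).scan(mode=mode)
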