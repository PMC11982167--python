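"""Linkage-disequilibrium decay, background LD, and block size.

LD between two SNPs is the squared Pearson correlation of their dosages
(genotypic r2; phase is unknown in an inbred panel and unnecessary).
The decay analysis regresses intra-chromosomal r2 on physical distance with
a local *quadratic* (degree-2 loess) smoother; the background (critical) LD
is the 99th percentile of r2 between inter-chromosomal pairs; the average
LD-block size is the distance where the smoothed decay curve first falls to
the background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .datatypes import GenotypeMatrix

__all__ = [
    "pair_r2", "sample_intra_pairs", "background_ld", "loess_decay",
    "block_size", "DecayCurve", "ld_summary",
]


def pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over lines observed for both SNPs; raises if either SNP is
    monomorphic on that intersection.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[ok], y[ok]
    if xs.size < 2 or xs.std() == 0 or ys.std() == 0:
        raise ValueError("r2 undefined: monomorphic SNP on shared lines")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def _pairwise_r2(dosage: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """Vectorised r2 for index pairs (ia[k], ib[k]) of a complete matrix."""
    X = dosage - dosage.mean(axis=0)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = X / sd[None, :]
    num = np.einsum("ij,ij->j", Z[:, ia], Z[:, ib]) / dosage.shape[0]
    return num ** 2


def sample_intra_pairs(geno: GenotypeMatrix, max_pairs_per_chrom: int = 200_000,
                       seed: int = 0) -> pd.DataFrame:
    """Sample same-chromosome SNP pairs with their distances and r2.

    All pairs are used when a chromosome has fewer than the cap, otherwise a
    uniform random subset. Returns columns snp_a, snp_b, chrom, dist_bp, r2.
    """
    if np.isnan(geno.dosage).any():
        raise ValueError("LD analysis requires a complete dosage matrix")
    rng = substream(seed, "ld-intra-pairs")
    frames = []
    for chrom, grp in geno.snps.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        m = idx.size
        total = m * (m - 1) // 2
        if total == 0:
            continue
        if total <= max_pairs_per_chrom:
            ia, ib = np.triu_indices(m, k=1)
        else:
            flat = rng.choice(total, size=max_pairs_per_chrom, replace=False)
            # unrank upper-triangle pair index
            ia = (m - 2 - np.floor(
                np.sqrt(-8 * flat + 4 * m * (m - 1) - 7) / 2 - 0.5)).astype(int)
            ib = (flat + ia + 1 - m * (m - 1) // 2
                  + (m - ia) * (m - ia - 1) // 2).astype(int)
        a, b = idx[ia], idx[ib]
        pos = geno.snps["pos_bp"].to_numpy()
        sd = geno.dosage.std(axis=0)
        poly = (sd[a] > 0) & (sd[b] > 0)
        a, b = a[poly], b[poly]
        frames.append(pd.DataFrame({
            "snp_a": geno.snps["snp_id"].to_numpy()[a],
            "snp_b": geno.snps["snp_id"].to_numpy()[b],
            "chrom": chrom,
            "dist_bp": np.abs(pos[a] - pos[b]),
            "r2": _pairwise_r2(geno.dosage, a, b),
        }))
    if not frames:
        raise ValueError("no intra-chromosomal pairs available")
    return pd.concat(frames, ignore_index=True)


def background_ld(geno: GenotypeMatrix, n_pairs: int = 100_000,
                  quantile: float = 0.99, seed: int = 0) -> float:
    """Critical r2: the given quantile of inter-chromosomal pair r2.

    r2 above this level between unlinked loci would arise by sampling noise
    alone less than ``1 - quantile`` of the time, so intra-chromosomal r2
    above it is attributed to linkage. Uses the linear-interpolation
    quantile convention.
    """
    chroms = geno.snps["chrom"].to_numpy()
    if len(set(chroms)) < 2:
        raise ValueError("background LD needs at least two chromosomes")
    if np.isnan(geno.dosage).any():
        raise ValueError("LD analysis requires a complete dosage matrix")
    rng = substream(seed, "ld-inter-pairs")
    sd = geno.dosage.std(axis=0)
    ia = rng.integers(0, geno.n_snps, size=2 * n_pairs)
    ib = rng.integers(0, geno.n_snps, size=2 * n_pairs)
    ok = (chroms[ia] != chroms[ib]) & (sd[ia] > 0) & (sd[ib] > 0)
    ia, ib = ia[ok][:n_pairs], ib[ok][:n_pairs]
    if ia.size == 0:
        raise ValueError("no inter-chromosomal pairs sampled")
    r2 = _pairwise_r2(geno.dosage, ia, ib)
    return float(np.quantile(r2, quantile))


@dataclass
class DecayCurve:
    """Loess-smoothed r2 decay over distance, with background and block size."""

    grid: np.ndarray
    smoothed_r2: np.ndarray
    span: float
    degree: int = 2
    background: float = float("nan")
    block_size_bp: float = float("nan")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dist_bp": self.grid, "r2_smooth": self.smoothed_r2})


def _loess_quadratic(x: np.ndarray, y: np.ndarray, grid: np.ndarray,
                     span: float) -> np.ndarray:
    """Degree-2 loess with tricube weights on the nearest span-fraction."""
    n = x.size
    k = max(int(np.ceil(span * n)), 5)
    k = min(k, n)
    out = np.empty(grid.size)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    for i, g in enumerate(grid):
        d = np.abs(xs - g)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = max(d.max(), 1.0)
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        sel = w > 0
        t = (xs[sel] - g) / h       # scaled for conditioning
        W = w[sel]
        B = np.column_stack([np.ones(t.size), t, t * t])
        A = B * W[:, None]
        coef, *_ = np.linalg.lstsq(A.T @ B, A.T @ ys[sel], rcond=None)
        out[i] = coef[0]
    return out


def loess_decay(pairs: pd.DataFrame, span: float = 0.5,
                grid_points: int = 200) -> DecayCurve:
    """Smooth r2 against distance with a local quadratic fit.

    The fitted curve is evaluated on a uniform distance grid from 0 to the
    maximum observed distance. A span too small to support local quadratic
    fits is widened automatically.
    """
    x = pairs["dist_bp"].to_numpy(dtype=float)
    y = pairs["r2"].to_numpy(dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 intra-chromosomal pairs")
    min_span = 10.0 / x.size
    if span < min_span:
        span = min_span
    grid = np.linspace(0.0, x.max(), grid_points)
    smoothed = np.clip(_loess_quadratic(x, y, grid, span), 0.0, None)
    return DecayCurve(grid=grid, smoothed_r2=smoothed, span=span)


def block_size(curve: DecayCurve) -> float:
    """Distance where the smoothed curve first reaches the background LD.

    Linearly interpolated between the straddling grid points; NaN when the
    curve never falls to the background (reported explicitly upstream).
    """
    bg = curve.background
    if not np.isfinite(bg):
        raise ValueError("decay curve has no background LD attached")
    below = curve.smoothed_r2 <= bg
    if not below.any():
        return float("nan")
    j = int(np.argmax(below))
    if j == 0:
        return 0.0
    x0, x1 = curve.grid[j - 1], curve.grid[j]
    y0, y1 = curve.smoothed_r2[j - 1], curve.smoothed_r2[j]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - bg) / (y0 - y1) * (x1 - x0))


def ld_summary(geno: GenotypeMatrix, span: float = 0.5, quantile: float = 0.99,
               max_pairs_per_chrom: int = 200_000, n_inter_pairs: int = 100_000,
               seed: int = 0):
    """End-to-end LD stage: pairs, background, decay curve, block size."""
    pairs = sample_intra_pairs(geno, max_pairs_per_chrom, seed=seed)
    bg = background_ld(geno, n_inter_pairs, quantile, seed=seed)
    curve = loess_decay(pairs, span=span)
    curve.background = bg
    curve.block_size_bp = block_size(curve)
    return pairs, curve
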