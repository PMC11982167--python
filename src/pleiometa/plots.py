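"""Manhattan and LD-decay plots."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import natural_chrom_key
from .ld import DecayCurve

__all__ = ["manhattan_plot", "decay_plot"]


def manhattan_plot(meta_table: pd.DataFrame, snps: pd.DataFrame,
                   threshold: float | None = None, ax=None, title: str = ""):
    """-log10(p) against cumulative genome position, coloured by chromosome."""
    import matplotlib.pyplot as plt

    df = meta_table.merge(snps[["snp_id", "chrom", "pos_bp"]], on="snp_id")
    chroms = sorted(df["chrom"].unique(), key=natural_chrom_key)
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks = []
    for k, chrom in enumerate(chroms):
        grp = df[df["chrom"] == chrom].sort_values("pos_bp")
        x = grp["pos_bp"].to_numpy() + offset
        ax.scatter(x, grp["minus_log10_p"], s=4,
                   color="C0" if k % 2 == 0 else "C1", rasterized=True)
        ticks.append((offset + x.max()) / 2 if len(x) else offset)
        offset = x.max() if len(x) else offset
    if threshold is not None:
        ax.axhline(-np.log10(threshold), ls="--", color="grey", lw=1)
    ax.set_xticks(ticks, chroms)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    if title:
        ax.set_title(title)
    return ax


def decay_plot(pairs: pd.DataFrame, curve: DecayCurve, ax=None,
               max_points: int = 20_000, seed: int = 0):
    """Scatter of pair r2 over distance with the loess curve and background."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    show = pairs
    if len(pairs) > max_points:
        show = pairs.sample(max_points, random_state=seed)
    ax.scatter(show["dist_bp"] / 1e6, show["r2"], s=2, alpha=0.15,
               color="grey", rasterized=True)
    ax.plot(curve.grid / 1e6, curve.smoothed_r2, color="C3", lw=2,
            label="degree-2 loess")
    if np.isfinite(curve.background):
        ax.axhline(curve.background, ls="--", color="C0",
                   label=f"background $r^2$ = {curve.background:.3f}")
    if np.isfinite(curve.block_size_bp):
        ax.axvline(curve.block_size_bp / 1e6, ls=":", color="C2",
                   label=f"block size = {curve.block_size_bp / 1e6:.1f} Mb")
    ax.set_xlabel("distance (Mb)")
    ax.set_ylabel(r"$r^2$")
    ax.legend(frameon=False, fontsize=8)
    return ax
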