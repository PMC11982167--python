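"""Genomic relatedness matrix (GRM).

The GRM is the allele-frequency-standardised cross-product of centred
dosages,

    G_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

with p_i the alt-allele frequency estimated from the analysed lines.
Under random mating this scales relatedness so the diagonal is ~1 in
expectation for unrelated individuals.
"""

from __future__ import annotations

import struct

import numpy as np

from .datatypes import GenotypeMatrix, Grm

__all__ = ["compute_grm", "stabilize", "write_gcta_grm"]


def compute_grm(geno: GenotypeMatrix, maf_floor: float = 0.0) -> Grm:
    """Standardised-dosage GRM over all SNPs with MAF > ``maf_floor``.

    Requires a complete (imputed) dosage matrix; monomorphic SNPs are
    always skipped (they carry no relatedness information).
    """
    if np.isnan(geno.dosage).any():
        raise ValueError("GRM requires a complete dosage matrix; impute first")
    p = geno.alt_freq()
    maf = np.minimum(p, 1 - p)
    keep = maf > maf_floor if maf_floor > 0 else maf > 0
    if not keep.any():
        raise ValueError("no polymorphic SNPs above the MAF floor")
    X = geno.dosage[:, keep]
    pk = p[keep]
    W = (X - 2 * pk[None, :]) / np.sqrt(2 * pk * (1 - pk))[None, :]
    G = (W @ W.T) / keep.sum()
    return Grm(list(geno.lines), G)


def stabilize(grm: Grm, epsilon: float = 1e-6) -> Grm:
    """Shift the diagonal by ``epsilon`` if the smallest eigenvalue is negative.

    Keeps downstream Cholesky/eigen factorisations well posed for
    rank-deficient panels (more lines than SNPs); eigenvalues move by at
    most ``epsilon - min_eig``.
    """
    w = np.linalg.eigvalsh(grm.values)
    if w[0] >= 0:
        return grm
    shifted = grm.values + (epsilon - w[0]) * np.eye(len(grm.lines))
    return Grm(list(grm.lines), shifted)


def write_gcta_grm(grm: Grm, prefix: str) -> None:
    """Write GCTA-compatible ``.grm.bin`` / ``.grm.N.bin`` / ``.grm.id``."""
    n = len(grm.lines)
    tri = grm.values[np.tril_indices(n)]
    with open(prefix + ".grm.bin", "wb") as fh:
        fh.write(struct.pack(f"<{tri.size}f", *tri.astype(np.float32)))
    with open(prefix + ".grm.N.bin", "wb") as fh:
        fh.write(struct.pack("<f", 1.0) * tri.size)
    with open(prefix + ".grm.id", "w") as fh:
        for line in grm.lines:
            fh.write(f"{line}\t{line}\n")
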