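"""Shared fixtures: small synthetic panels built at test time."""

import numpy as np
import pandas as pd
import pytest

from pleiometa.datatypes import GenotypeMatrix
from pleiometa.grm import compute_grm, stabilize
from pleiometa.simulate import simulate_genotypes


def hwe_genotypes(n_lines, n_snps, seed=0, n_chrom=1, maf_low=0.1):
    """Random-mating (HWE) dosages with independent SNPs: the idealised
    panel used for GRM / GREML sampling checks."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, 1 - maf_low, n_snps)
    dosage = rng.binomial(2, p, size=(n_lines, n_snps)).astype(float)
    per = n_snps // n_chrom
    chroms = np.repeat([f"{i + 1}A" for i in range(n_chrom)],
                       [per] * (n_chrom - 1) + [n_snps - per * (n_chrom - 1)])
    pos = np.concatenate([np.arange(1, (chroms == c).sum() + 1) * 1000
                          for c in dict.fromkeys(chroms)])
    snps = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(n_snps)],
        "chrom": chroms, "pos_bp": pos, "pos_cm": pos / 4.5e6,
        "allele_ref": "A", "allele_alt": "G",
    })
    return GenotypeMatrix([f"L{i:03d}" for i in range(n_lines)], snps, dosage)


@pytest.fixture(scope="session")
def tiny_panel():
    """30 lines x 40 independent SNPs plus its GRM (oracle-scale)."""
    geno = hwe_genotypes(30, 40, seed=11)
    return geno, stabilize(compute_grm(geno))


@pytest.fixture(scope="session")
def mid_panel():
    """200 lines x 500 independent SNPs plus GRM (recovery-scale)."""
    geno = hwe_genotypes(200, 500, seed=7)
    return geno, stabilize(compute_grm(geno))


@pytest.fixture(scope="session")
def inbred_panel():
    """Inbred haplotype-mosaic panel with ~7 Mb LD blocks, two chromosomes."""
    return simulate_genotypes(
        250, [("1A", 300, 100_000_000), ("2B", 300, 100_000_000)], seed=3)
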