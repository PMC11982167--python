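"""Synthetic germplasm, trait architectures, and field trials.

The generator emulates the statistical structure of an inbred bread-wheat
pre-breeding panel phenotyped for grain element concentrations:

* fully homozygous lines built by copying founder haplotypes along each
  chromosome (a Markov mosaic whose segment length sets the LD scale, tuned
  so the r2 decay curve crosses the background near 7 Mb);
* 13 element traits in two blocks with positive within-block and negative
  between-block genetic correlations, driven by shared, private and
  antagonistic pleiotropic QTL;
* randomised complete-block field trials, some on a reduced line subset,
  with replicate effects, smooth row/column polynomial trends and iid
  plot residuals.

All outputs are deterministic functions of one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .datatypes import GenotypeMatrix, TraitArchitecture, PLOT_COLUMNS

__all__ = [
    "ELEMENTS", "GROUP1", "GROUP2", "EnvSpec",
    "default_chrom_plan", "simulate_genotypes", "simulate_architecture",
    "simulate_trials", "default_env_plan",
]

# The 13 grain elements and the two correlation groups used throughout:
# group one macro-accumulators (Ca, Co, K, Na) versus the second group
# (Cu, Fe, Mg, Mn, Mo, Ni, P, Zn, plus B, which clusters weakly and is
# assigned to group two for the meta-analysis design).
ELEMENTS = ["B", "Ca", "Co", "Cu", "Fe", "K", "Mg", "Mn", "Mo", "Na", "Ni", "P", "Zn"]
GROUP1 = ["Ca", "Co", "K", "Na"]
GROUP2 = [e for e in ELEMENTS if e not in GROUP1]

# bp per cM used only for reporting genetic positions.
BP_PER_CM = 4.5e6

# Founder-copying LD: allele correlation decays roughly as exp(-2 d / ld_scale),
# so r2 ~ exp(-4 d / ld_scale) falls to a ~0.02 background near d ~ ld_scale.
DEFAULT_LD_SCALE = 7.0e6


def default_chrom_plan(n_chrom: int = 3, snps_per_chrom: int = 400,
                       length_bp: int = 120_000_000) -> list:
    """A desk-scale stand-in for the 21 wheat chromosomes."""
    labels = ["1A", "1B", "1D", "2A", "2B", "2D", "3A"]
    return [(labels[i % len(labels)] if n_chrom <= len(labels) else f"chr{i + 1}",
             snps_per_chrom, length_bp) for i in range(n_chrom)]


def _mosaic(rng: np.random.Generator, n_rows: int, n_snps: int,
            keep_prob: np.ndarray, fresh: np.ndarray) -> np.ndarray:
    """Markov mosaic: each row keeps its previous value with keep_prob[j],
    else takes fresh[row, j]. keep_prob[0] is ignored (always fresh)."""
    refresh = rng.random((n_rows, n_snps)) >= keep_prob[None, :]
    refresh[:, 0] = True
    idx = np.where(refresh, np.arange(n_snps)[None, :], 0)
    last = np.maximum.accumulate(idx, axis=1)
    return fresh[np.arange(n_rows)[:, None], last]


def simulate_genotypes(
    n_lines: int,
    chrom_plan: Sequence | None = None,
    ld_scale: float = DEFAULT_LD_SCALE,
    maf_min: float = 0.05,
    missing_rate: float = 0.0,
    n_founders: int = 30,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate fully homozygous inbred-line dosages with block LD.

    Per chromosome, ``n_founders`` founder haplotypes are drawn as Markov
    mosaics of fresh Bernoulli alleles (segment scale ``ld_scale`` bp); each
    line is a Markov mosaic over founder identities with the same scale, and
    its haplotype is doubled, so dosages are 0/2 (plus NaN for missing).
    SNPs whose realised panel MAF falls below ``maf_min`` are dropped.

    ``chrom_plan`` is a sequence of ``(label, n_snps, length_bp)``.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if ld_scale <= 0:
        raise ValueError("ld_scale must be positive")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if maf_min >= 0.5:
        raise ValueError("maf_min must be < 0.5")
    if chrom_plan is None:
        chrom_plan = default_chrom_plan()

    rng = substream(seed, "genotypes")
    snp_frames, hap_cols = [], []
    for chrom, n_snps, length_bp in chrom_plan:
        if n_snps < 1 or length_bp < n_snps:
            raise ValueError(f"bad chromosome plan entry for {chrom!r}")
        pos = np.sort(rng.choice(np.int64(length_bp), size=n_snps, replace=False)) + 1
        gaps = np.diff(pos, prepend=pos[0]).astype(float)
        keep = np.exp(-gaps / ld_scale)

        # founder haplotypes: mosaic of fresh alleles at per-SNP frequencies
        p = rng.uniform(0.1, 0.9, size=n_snps)
        fresh_alleles = (rng.random((n_founders, n_snps)) < p[None, :]).astype(np.int8)
        founders = _mosaic(rng, n_founders, n_snps, keep, fresh_alleles)

        # line haplotypes: mosaic over founder identity, then doubled
        fresh_ids = rng.integers(0, n_founders, size=(n_lines, n_snps))
        founder_of = _mosaic(rng, n_lines, n_snps, keep, fresh_ids)
        hap = founders[founder_of, np.arange(n_snps)[None, :]]
        hap_cols.append(hap)

        snp_frames.append(pd.DataFrame({
            "snp_id": [f"{chrom}_{bp}" for bp in pos],
            "chrom": chrom,
            "pos_bp": pos.astype(np.int64),
            "pos_cm": pos / BP_PER_CM,
            "allele_ref": "A",
            "allele_alt": "G",
        }))

    dosage = 2.0 * np.concatenate(hap_cols, axis=1).astype(float)
    snps = pd.concat(snp_frames, ignore_index=True)

    if missing_rate > 0:
        mask = substream(seed, "genotype-missing").random(dosage.shape) < missing_rate
        dosage[mask] = np.nan

    geno = GenotypeMatrix(
        lines=[f"L{i + 1:04d}" for i in range(n_lines)], snps=snps, dosage=dosage,
    )
    keep_snp = geno.maf() >= maf_min
    return geno.subset(snp_mask=keep_snp) if not keep_snp.all() else geno


def simulate_architecture(
    geno: GenotypeMatrix,
    elements: Sequence | None = None,
    group1: Sequence | None = None,
    n_shared: int = 10,
    n_private: int = 2,
    n_antagonistic: int = 1,
    h2_target: float | dict = 0.42,
    rg_within: float = 0.45,
    rg_between: float = -0.20,
    maf_min: float = 0.05,
    seed: int = 0,
) -> TraitArchitecture:
    """Draw pleiotropic QTL and per-element effects with target correlations.

    Shared QTL load on two correlated group factors so the expected genetic
    correlation is ``rg_within`` inside each group and ``rg_between`` across
    groups; each element also receives ``n_private`` exclusive QTL and
    ``n_antagonistic`` loci get strictly opposite effect signs in the two
    groups. Effects are rescaled per element so the variance of line genetic
    values equals ``h2 / (1 - h2)`` (unit plot residual variance).
    """
    elements = list(elements) if elements is not None else list(ELEMENTS)
    group1 = list(group1) if group1 is not None else [e for e in GROUP1 if e in elements]
    if not set(group1) <= set(elements):
        raise ValueError("group1 must be a subset of elements")
    group2 = [e for e in elements if e not in group1]
    h2 = {e: float(h2_target) for e in elements} if np.isscalar(h2_target) \
        else {e: float(h2_target[e]) for e in elements}
    for e, v in h2.items():
        if not 0 < v < 1:
            raise ValueError(f"h2_target for {e} must lie in (0, 1)")
    if rg_within <= 0 or abs(rg_between) > rg_within:
        raise ValueError("need rg_within > 0 and |rg_between| <= rg_within")

    rng = substream(seed, "architecture")
    n_elem = len(elements)
    n_qtl = n_shared + n_antagonistic + n_private * n_elem
    candidates = np.flatnonzero(geno.maf() >= maf_min)
    if n_qtl > candidates.size:
        raise ValueError(
            f"{n_qtl} QTL requested but only {candidates.size} SNPs have MAF >= {maf_min}"
        )
    qtl_idx = rng.choice(candidates, size=n_qtl, replace=False)
    in_g1 = np.array([e in group1 for e in elements])

    beta = np.zeros((n_qtl, n_elem))
    kinds = []
    row = 0
    # group factors with corr c such that between-group corr = rg_between
    c = rg_between / rg_within
    chol = np.linalg.cholesky(np.array([[1.0, c], [c, 1.0]]))
    for _ in range(n_shared):
        u = chol @ rng.standard_normal(2)
        eps = rng.standard_normal(n_elem)
        fac = np.where(in_g1, u[0], u[1])
        beta[row] = np.sqrt(rg_within) * fac + np.sqrt(1.0 - rg_within) * eps
        kinds.append("shared")
        row += 1
    for _ in range(n_antagonistic):
        mag = np.abs(rng.standard_normal(n_elem)) + 0.5
        beta[row] = np.where(in_g1, mag, -mag)
        kinds.append("antagonistic")
        row += 1
    for j in range(n_elem):
        for _ in range(n_private):
            beta[row, j] = rng.standard_normal()
            kinds.append("private")
            row += 1

    # genetic values on mean-imputed dosages (QTL SNPs are usually complete)
    X = geno.dosage[:, qtl_idx].copy()
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean[None, :], X)
    gv = X @ beta
    sd = gv.std(axis=0, ddof=1)
    target_sd = np.array([np.sqrt(h2[e] / (1.0 - h2[e])) for e in elements])
    if (sd == 0).any():
        raise ValueError("an element received zero genetic variance; add QTL")
    scale = target_sd / sd
    beta *= scale[None, :]
    gv *= scale[None, :]

    snp_ids = geno.snps["snp_id"].iloc[qtl_idx].to_numpy()
    return TraitArchitecture(
        elements=elements,
        group1=group1,
        group2=group2,
        qtl_effects=pd.DataFrame(beta, index=snp_ids, columns=elements),
        qtl_flags=pd.DataFrame(
            {"kind": kinds, "antagonistic": [k == "antagonistic" for k in kinds]},
            index=snp_ids,
        ),
        genetic_values=pd.DataFrame(gv, index=geno.lines, columns=elements),
        h2_target=h2,
        rg_within=float(rg_within),
        rg_between=float(rg_between),
    )


@dataclass
class EnvSpec:
    """One field trial: which lines, how many complete blocks, layout."""

    label: str
    lines: list | None = None        # None = all lines in the genotype panel
    n_reps: int = 2
    n_rows: int | None = None        # None = near-square layout per rep
    n_cols: int | None = None
    scaler: float = 1.0              # multiplies genetic values in this env


def default_env_plan(geno: GenotypeMatrix, n_subset: int = 200,
                     seed: int = 0) -> list:
    """Six trials: two on the full panel, four on a diversity subset.

    Mirrors a design with one optimally-sown and one late-sown trial at a
    main site for every line, and optimal/late trials at two further sites
    for a fixed subset."""
    rng = substream(seed, "env-plan")
    subset = [geno.lines[i] for i in
              np.sort(rng.choice(geno.n_lines, size=min(n_subset, geno.n_lines),
                                 replace=False))]
    scalers = {"N_opt": 1.0, "N_late": 0.9, "H_opt": 1.05, "H_late": 0.85,
               "M_opt": 0.95, "M_late": 0.8}
    plan = [EnvSpec("N_opt", None, scaler=scalers["N_opt"]),
            EnvSpec("N_late", None, scaler=scalers["N_late"])]
    for env in ["H_opt", "H_late", "M_opt", "M_late"]:
        plan.append(EnvSpec(env, subset, scaler=scalers[env]))
    return plan


def simulate_trials(
    geno: GenotypeMatrix,
    arch: TraitArchitecture,
    envs: Sequence[EnvSpec],
    spatial_sd: float = 0.3,
    rep_sd: float = 0.2,
    resid_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate plot-level element concentrations for a set of field trials.

    Each trial is a randomised complete block: every line appears once per
    replicate, assigned to plots at random within the rep. Plot value =
    genetic value x env scaler + rep effect + quadratic row/col trend +
    iid residual, independently per element. Returns a long DataFrame with
    columns ``env, row, col, rep, line_id, element, value``.
    """
    rng = substream(seed, "trials")
    gv = arch.genetic_values
    records = []
    for spec in envs:
        lines = list(spec.lines) if spec.lines is not None else list(geno.lines)
        missing = set(lines) - set(gv.index)
        if missing:
            raise ValueError(f"lines absent from genotype panel: {sorted(missing)[:5]}")
        n = len(lines)
        n_rows = spec.n_rows or int(np.ceil(np.sqrt(n)))
        n_cols = spec.n_cols or int(np.ceil(n / n_rows))
        if n_rows * n_cols < n:
            raise ValueError(f"layout {n_rows}x{n_cols} too small for {n} lines")
        scaler = spec.scaler if spec.label not in arch.env_scalers else arch.scaler(spec.label)

        g_env = gv.loc[lines].to_numpy() * scaler  # lines x elements
        for rep in range(1, spec.n_reps + 1):
            order = rng.permutation(n)
            plot_rows = np.arange(n) // n_cols + 1
            plot_cols = np.arange(n) % n_cols + 1 + (rep - 1) * n_cols
            rep_effects = rng.normal(0.0, rep_sd, size=len(arch.elements)) if rep_sd > 0 \
                else np.zeros(len(arch.elements))
            # smooth quadratic trends per element over this rep block
            r = (plot_rows - plot_rows.mean())
            cc = (plot_cols - plot_cols.mean())
            surf = np.zeros((n, len(arch.elements)))
            if spatial_sd > 0:
                coef = rng.standard_normal((4, len(arch.elements)))
                basis = np.column_stack([r, r ** 2, cc, cc ** 2])
                basis = (basis - basis.mean(axis=0)) / np.where(
                    basis.std(axis=0) > 0, basis.std(axis=0), 1.0)
                raw = basis @ coef
                rsd = raw.std(axis=0, ddof=1)
                surf = raw / np.where(rsd > 0, rsd, 1.0) * spatial_sd
            noise = rng.normal(0.0, resid_sd, size=(n, len(arch.elements))) if resid_sd > 0 \
                else np.zeros((n, len(arch.elements)))
            value = g_env[order] + rep_effects[None, :] + surf + noise
            for k, elem in enumerate(arch.elements):
                records.append(pd.DataFrame({
                    "env": spec.label,
                    "row": plot_rows,
                    "col": plot_cols,
                    "rep": rep,
                    "line_id": [lines[i] for i in order],
                    "element": elem,
                    "value": value[:, k],
                }))
    return pd.concat(records, ignore_index=True)[PLOT_COLUMNS]
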