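"""Multi-trait / multi-environment meta-analysis of GWAS summary statistics.

Each univariate analysis (one element in one environment) contributes a
signed t-value t = b / se(b) per SNP. For SNP i with t-vector t_i across
analyses, the meta statistic is

    chi2_i = t_i' V^-1 t_i,

where V is the correlation matrix of the t-values across analyses,
estimated over SNPs. V absorbs the correlation induced by shared lines and
genetically correlated traits; the statistic is chi-square distributed with
df = rank(V) under the global null and is sign-agnostic, so loci with
antagonistic effects across trait groups remain detectable.

Significant SNPs (Bonferroni) are clustered into QTL per chromosome around
lead SNPs using genotypic LD (r2 with the lead > 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix
from .greml import ElementGrouping

__all__ = [
    "TMatrix", "build_t_matrix", "estimate_v", "meta_chi2",
    "bonferroni_threshold", "cluster_qtl", "MetaGWAS", "MetaGWASResults",
    "run_meta_design", "allelic_effect_sd",
]


@dataclass
class TMatrix:
    """Signed t-values per SNP (rows) x univariate analysis (columns)."""

    snps: pd.DataFrame            # snp_id, chrom, pos_bp, pos_cm (+alleles)
    t: pd.DataFrame               # index snp_id, columns analysis labels

    @property
    def analyses(self) -> list:
        return list(self.t.columns)

    def subset(self, analysis_labels) -> "TMatrix":
        return TMatrix(self.snps, self.t[list(analysis_labels)])


def build_t_matrix(assoc_tables: dict) -> TMatrix:
    """Assemble the t-matrix from per-analysis association tables.

    ``assoc_tables`` maps an analysis label (e.g. ``"Zn:N_opt"``) to a
    DataFrame with the association-table contract columns. SNPs are the
    union across analyses; cells missing from an analysis stay NaN.
    Inconsistent alleles for one SNP across analyses are a hard error
    (signs would not be comparable).
    """
    if not assoc_tables:
        raise ValueError("no association tables supplied")
    cols = {}
    meta_frames = []
    for label, df in assoc_tables.items():
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicated SNP {dup!r} in analysis {label!r}")
        with np.errstate(invalid="ignore", divide="ignore"):
            t = df["beta"].to_numpy() / df["se"].to_numpy()
        flagged = df["flag"].astype(str).ne("").to_numpy() if "flag" in df \
            else np.zeros(len(df), bool)
        t = np.where(flagged, 0.0, t)
        cols[label] = pd.Series(t, index=df["snp_id"].to_numpy())
        meta_frames.append(df[["snp_id", "chr", "pos_bp", "pos_cm",
                               "allele_ref", "allele_alt"]])
    allmeta = pd.concat(meta_frames, ignore_index=True)
    uniq = allmeta.drop_duplicates()
    if uniq["snp_id"].duplicated().any():
        bad = uniq.loc[uniq["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"inconsistent alleles or map for SNP {bad!r} across analyses")
    tmat = pd.DataFrame(cols)
    snps = (uniq.set_index("snp_id").loc[tmat.index].reset_index()
            .rename(columns={"chr": "chrom"}))
    return TMatrix(snps=snps, t=tmat)


def estimate_v(tmat: TMatrix, analysis_subset=None,
               trim_quantile: float = 1.0) -> pd.DataFrame:
    """Correlation matrix of t-values among analyses, over SNPs.

    Pairwise-complete Pearson correlation; with ``trim_quantile`` < 1,
    SNPs whose |t| exceeds that per-column quantile are masked first so
    strong signals do not inflate the estimated correlation.
    """
    t = tmat.t if analysis_subset is None else tmat.t[list(analysis_subset)]
    if t.shape[1] < 2:
        raise ValueError("need at least two analyses to estimate V")
    if t.shape[0] < 100:
        import warnings
        warnings.warn(f"estimating V from only {t.shape[0]} SNPs", stacklevel=2)
    work = t.copy()
    if trim_quantile < 1.0:
        for col in work.columns:
            cut = work[col].abs().quantile(trim_quantile)
            work.loc[work[col].abs() > cut, col] = np.nan
    sd = work.std()
    dead = sd[~(sd > 0)].index.tolist()
    if dead:
        raise ValueError(f"zero-variance t column(s): {dead}")
    V = work.corr(min_periods=2)
    if V.isna().any().any():
        raise ValueError("could not estimate all V entries (too much missingness)")
    return V


def meta_chi2(tmat: TMatrix, v: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP meta chi-square, df, and p-value.

    Each SNP uses only the analyses where it has a t-value; V is restricted
    accordingly and inverted by Moore-Penrose pseudo-inverse with
    df = rank of the restriction (eigenvalues below 1e-10 x max count as
    zero). SNPs absent from every analysis are omitted.
    """
    labels = list(v.columns)
    T = tmat.t[labels].to_numpy(dtype=float)
    Vm = v.to_numpy(dtype=float)
    present = ~np.isnan(T)
    chi2 = np.full(T.shape[0], np.nan)
    df_out = np.zeros(T.shape[0], dtype=int)
    patterns = {}
    for i, row in enumerate(present):
        patterns.setdefault(row.tobytes(), []).append(i)
    for key, rows in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        if not mask.any():
            continue
        sub = Vm[np.ix_(mask, mask)]
        w, Q = np.linalg.eigh(sub)
        keep = w > 1e-10 * max(w.max(), 1e-300)
        rank = int(keep.sum())
        Vinv = (Q[:, keep] / w[keep][None, :]) @ Q[:, keep].T
        tm = T[np.ix_(rows, np.flatnonzero(mask))]
        chi2[rows] = np.einsum("ij,jk,ik->i", tm, Vinv, tm)
        df_out[rows] = rank
    ok = df_out > 0
    chi2 = np.clip(chi2, 0.0, None)
    with np.errstate(divide="ignore"):
        p = np.where(ok, stats.chi2.sf(chi2, np.maximum(df_out, 1)), np.nan)
    out = pd.DataFrame({
        "snp_id": tmat.t.index,
        "chi2": chi2,
        "df": df_out,
        "p": p,
        "minus_log10_p": -np.log10(np.clip(p, 1e-300, None)),
        "n_analyses": present.sum(axis=1),
    })
    return out[ok].reset_index(drop=True)


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def cluster_qtl(meta: pd.DataFrame, geno: GenotypeMatrix,
                r2_threshold: float = 0.5,
                significant: pd.Series | None = None) -> pd.DataFrame:
    """Group significant SNPs into QTL around lead SNPs via LD with the lead.

    Per chromosome: the most significant unassigned SNP seeds a cluster and
    absorbs every unassigned significant SNP with r2(lead, snp) >
    ``r2_threshold``; repeat until all are assigned. Returns one row per
    QTL with the lead, members, and bp/cM spans.
    """
    if significant is None:
        if "significant" not in meta:
            raise ValueError("pass `significant` or a meta table with that column")
        significant = meta["significant"]
    sig = meta[significant.to_numpy(dtype=bool)]
    if len(sig) == 0:
        return pd.DataFrame(columns=[
            "qtl_id", "chrom", "lead_snp", "lead_p", "n_members", "members",
            "span_bp_min", "span_bp_max", "span_cm_min", "span_cm_max"])
    info = geno.snps.set_index("snp_id")
    col = {s: j for j, s in enumerate(geno.snps["snp_id"])}
    rows = []
    k = 0
    merged = sig.merge(info[["chrom", "pos_bp", "pos_cm"]], left_on="snp_id",
                       right_index=True, how="left")
    if merged["chrom"].isna().any():
        missing = merged.loc[merged["chrom"].isna(), "snp_id"].iloc[0]
        raise KeyError(f"significant SNP {missing!r} absent from genotype matrix")
    for chrom in sorted(merged["chrom"].unique(), key=str):
        grp = merged[merged["chrom"] == chrom].sort_values("pos_bp")
        unassigned = grp.copy()
        while len(unassigned):
            lead = unassigned.loc[unassigned["p"].idxmin()]
            x = geno.dosage[:, col[lead["snp_id"]]]
            member_mask = []
            for s in unassigned["snp_id"]:
                if s == lead["snp_id"]:
                    member_mask.append(True)
                    continue
                y = geno.dosage[:, col[s]]
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 2 or x[ok].std() == 0 or y[ok].std() == 0:
                    member_mask.append(False)
                    continue
                r = np.corrcoef(x[ok], y[ok])[0, 1]
                member_mask.append(r * r > r2_threshold)
            members = unassigned[np.array(member_mask)]
            k += 1
            rows.append({
                "qtl_id": f"q{k}",
                "chrom": chrom,
                "lead_snp": lead["snp_id"],
                "lead_p": float(lead["p"]),
                "n_members": len(members),
                "members": ",".join(members["snp_id"]),
                "span_bp_min": int(members["pos_bp"].min()),
                "span_bp_max": int(members["pos_bp"].max()),
                "span_cm_min": float(members["pos_cm"].min()),
                "span_cm_max": float(members["pos_cm"].max()),
            })
            unassigned = unassigned[~np.array(member_mask)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model-style wrapper and the three-design runner
# ---------------------------------------------------------------------------

@dataclass
class MetaGWASResults:
    """Meta-analysis over one set of univariate analyses."""

    label: str
    table: pd.DataFrame           # snp_id, chi2, df, p, minus_log10_p, significant
    v: pd.DataFrame
    threshold: float
    analyses: list = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def summary(self) -> str:
        return (
            f"MetaGWAS [{self.label}]: {len(self.analyses)} analyses, "
            f"{len(self.table)} SNPs\n"
            f"  Bonferroni threshold p <= {self.threshold:.6g} "
            f"(-log10 = {-np.log10(self.threshold):.2f})\n"
            f"  significant SNPs: {self.n_significant}"
        )


class MetaGWAS:
    """Meta-analysis model over a t-matrix (statsmodels-style wrapper)."""

    def __init__(self, tmat: TMatrix, label: str = "Meta"):
        self.tmat = tmat
        self.label = label

    def fit(self, analysis_subset=None, alpha: float = 0.05,
            m: int | None = None, trim_quantile: float = 1.0,
            v: pd.DataFrame | None = None) -> MetaGWASResults:
        subset = list(analysis_subset) if analysis_subset is not None \
            else self.tmat.analyses
        if len(subset) == 1:
            # single analysis: chi2 = t^2 against chi-square(1)
            t = self.tmat.t[subset[0]]
            keep = t.notna()
            table = pd.DataFrame({
                "snp_id": t.index[keep],
                "chi2": (t[keep] ** 2).to_numpy(),
                "df": 1,
                "p": stats.chi2.sf((t[keep] ** 2).to_numpy(), 1),
                "n_analyses": 1,
            })
            table["minus_log10_p"] = -np.log10(np.clip(table["p"], 1e-300, None))
            V = pd.DataFrame([[1.0]], index=subset, columns=subset)
        else:
            V = v if v is not None else estimate_v(
                self.tmat, subset, trim_quantile=trim_quantile)
            table = meta_chi2(self.tmat.subset(subset), V)
        m_eff = m if m is not None else len(table)
        thr = bonferroni_threshold(alpha, m_eff)
        table = table.copy()
        table["significant"] = table["p"] <= thr
        return MetaGWASResults(label=self.label, table=table, v=V,
                               threshold=thr, analyses=subset)


def _analysis_labels_for(elements, analyses):
    """Columns whose label 'element:env' starts with one of the elements."""
    chosen = []
    for a in analyses:
        elem = a.split(":", 1)[0]
        if elem in elements:
            chosen.append(a)
    return chosen


def run_meta_design(tmat: TMatrix, grouping: ElementGrouping,
                    alpha: float = 0.05, m: int | None = None,
                    trim_quantile: float = 1.0):
    """Run the three meta-analyses: group 1, group 2, and all elements.

    Analysis labels must follow the ``element:env`` convention. Returns a
    dict of MetaGWASResults keyed ``Meta1, Meta2, Meta`` plus a per-SNP
    comparison table flagging the designs in which each SNP is significant.
    """
    cols1 = _analysis_labels_for(grouping.group1, tmat.analyses)
    cols2 = _analysis_labels_for(grouping.group2, tmat.analyses)
    if not cols1 or not cols2:
        raise ValueError("each group must contribute at least one analysis")
    results = {}
    for label, cols in (("Meta1", cols1), ("Meta2", cols2),
                        ("Meta", cols1 + cols2)):
        results[label] = MetaGWAS(tmat, label=label).fit(
            analysis_subset=cols, alpha=alpha, m=m, trim_quantile=trim_quantile)
    frames = []
    for label, res in results.items():
        frames.append(res.table.set_index("snp_id")["significant"].rename(label))
    comp = pd.concat(frames, axis=1).fillna(False)
    comp = comp[comp.any(axis=1)]
    comp["detected_in"] = comp.apply(
        lambda r: ",".join([c for c in ("Meta1", "Meta2", "Meta") if r[c]]), axis=1)
    return results, comp.reset_index()


def allelic_effect_sd(blues: pd.DataFrame, dosages: np.ndarray,
                      lines: list, min_class: int = 2) -> pd.DataFrame:
    """Allelic contrast in phenotypic-SD units, per environment x element.

    For one SNP: (mean BLUE of alt homozygotes - mean BLUE of ref
    homozygotes) / SD of all BLUEs in that env x element. Heterozygotes are
    excluded; pairs where either homozygote class has fewer than
    ``min_class`` lines are flagged undefined.
    """
    dosages = np.asarray(dosages, dtype=float)
    dmap = pd.Series(dosages, index=lines)
    rows = []
    for (env, element), grp in blues.groupby(["env", "element"], sort=True):
        d = dmap.reindex(grp["line_id"]).to_numpy()
        b = grp["blue"].to_numpy(dtype=float)
        sd = b[~np.isnan(b)].std(ddof=1)
        alt = b[(d == 2) & ~np.isnan(b)]
        ref = b[(d == 0) & ~np.isnan(b)]
        ok = alt.size >= min_class and ref.size >= min_class and sd > 0
        rows.append({
            "env": env, "element": element,
            "n_ref": ref.size, "n_alt": alt.size,
            "effect_sd": (alt.mean() - ref.mean()) / sd if ok else np.nan,
            "defined": bool(ok),
        })
    return pd.DataFrame(rows)
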