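"""Meta chi-square statistic, V estimation, QTL clustering, allelic effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleiometa.datatypes import GenotypeMatrix
from pleiometa.greml import ElementGrouping
from pleiometa.meta import (MetaGWAS, TMatrix, allelic_effect_sd,
                            bonferroni_threshold, build_t_matrix, cluster_qtl,
                            estimate_v, meta_chi2, run_meta_design)


def snp_map(n, chrom="1A", spacing=1000):
    return pd.DataFrame({
        "snp_id": [f"{chrom}_{j}" for j in range(n)], "chrom": chrom,
        "pos_bp": np.arange(1, n + 1) * spacing, "pos_cm": 0.0,
        "allele_ref": "A", "allele_alt": "G"})


def tmatrix_from(tdict, n=None):
    t = pd.DataFrame(tdict)
    n = len(t)
    snps = snp_map(n)
    t.index = snps["snp_id"]
    return TMatrix(snps=snps, t=t)


def assoc_table(snps, beta, se, flag=None):
    df = snps.rename(columns={"chrom": "chr"}).copy()
    df["af"] = 0.3
    df["n"] = 100
    df["beta"] = beta
    df["se"] = se
    df["t"] = df["beta"] / df["se"]
    df["p"] = 1.0
    df["flag"] = flag if flag is not None else ""
    return df


class TestBuildTMatrix:
    def test_t_is_beta_over_se(self):
        snps = snp_map(3)
        tab = assoc_table(snps, beta=[0.5, 1.0, -0.2], se=[0.25, 0.5, 0.1])
        tm = build_t_matrix({"Fe:E1": tab})
        np.testing.assert_allclose(tm.t["Fe:E1"], [2.0, 2.0, -2.0])

    def test_flagged_records_enter_as_zero(self):
        snps = snp_map(2)
        tab = assoc_table(snps, beta=[0.0, 1.0], se=[np.nan, 0.5],
                          flag=["monomorphic", ""])
        tm = build_t_matrix({"Fe:E1": tab})
        assert tm.t["Fe:E1"].iloc[0] == 0.0

    def test_union_with_missing_cells(self):
        s = snp_map(4)
        t1 = assoc_table(s.iloc[:3], beta=[1, 1, 1], se=[1, 1, 1])
        t2 = assoc_table(s.iloc[1:], beta=[2, 2, 2], se=[1, 1, 1])
        tm = build_t_matrix({"a": t1, "b": t2})
        assert tm.t.shape == (4, 2)
        assert np.isnan(tm.t.loc[s["snp_id"][3], "a"])
        assert np.isnan(tm.t.loc[s["snp_id"][0], "b"])

    def test_inconsistent_alleles_hard_error(self):
        s = snp_map(2)
        t1 = assoc_table(s, beta=[1, 1], se=[1, 1])
        s2 = s.copy()
        s2.loc[0, "allele_alt"] = "T"
        t2 = assoc_table(s2, beta=[1, 1], se=[1, 1])
        with pytest.raises(ValueError, match="inconsistent"):
            build_t_matrix({"a": t1, "b": t2})

    def test_full_design_column_count(self):
        s = snp_map(5)
        tables = {f"{el}:{env}": assoc_table(s, beta=np.ones(5), se=np.ones(5))
                  for el in list("ABCDEFGHIJKLM") for env in
                  ["E1", "E2", "E3", "E4", "E5", "E6"]}
        tm = build_t_matrix(tables)
        assert tm.t.shape[1] == 78


class TestEstimateV:
    def test_independent_columns_near_identity(self):
        rng = np.random.default_rng(0)
        tm = tmatrix_from({f"a{k}": rng.standard_normal(10_000)
                           for k in range(4)})
        V = estimate_v(tm)
        off = V.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() <= 0.05

    def test_duplicated_column_unit_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        tm = tmatrix_from({"a": x, "b": x.copy(), "c": rng.standard_normal(500)})
        V = estimate_v(tm)
        assert V.loc["a", "b"] == pytest.approx(1.0)

    def test_snp_order_invariance(self):
        rng = np.random.default_rng(2)
        t = {k: rng.standard_normal(300) for k in "ab"}
        tm1 = tmatrix_from(t)
        perm = rng.permutation(300)
        tm2 = tmatrix_from({k: v[perm] for k, v in t.items()})
        pd.testing.assert_frame_equal(estimate_v(tm1), estimate_v(tm2))

    def test_zero_variance_column_error(self):
        tm = tmatrix_from({"a": np.zeros(200),
                           "b": np.random.default_rng(3).standard_normal(200)})
        with pytest.raises(ValueError, match="zero-variance"):
            estimate_v(tm)


class TestMetaChi2:
    def test_identity_v_reference_point(self):
        tm = tmatrix_from({"a": [2.0, 0.0], "b": [0.0, 0.0], "c": [0.0, 0.0]})
        V = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        out = meta_chi2(tm, V)
        assert out["chi2"][0] == pytest.approx(4.0)
        assert out["df"][0] == 3
        assert out["p"][0] == pytest.approx(stats.chi2.sf(4.0, 3), abs=1e-12)
        assert out["chi2"][1] == 0.0 and out["p"][1] == pytest.approx(1.0)

    def test_identity_v_equals_sum_of_squares(self):
        rng = np.random.default_rng(4)
        t = {k: rng.standard_normal(50) for k in "abcd"}
        tm = tmatrix_from(t)
        V = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        out = meta_chi2(tm, V)
        np.testing.assert_allclose(out["chi2"],
                                   (tm.t.to_numpy() ** 2).sum(axis=1),
                                   atol=1e-10)

    def test_single_analysis_is_squared_normal(self):
        rng = np.random.default_rng(5)
        tm = tmatrix_from({"a": rng.standard_normal(20)})
        res = MetaGWAS(tm).fit(analysis_subset=["a"], m=20)
        t = tm.t["a"].to_numpy()
        np.testing.assert_allclose(res.table["chi2"], t ** 2, atol=1e-12)
        np.testing.assert_allclose(res.table["p"],
                                   2 * stats.norm.sf(np.abs(t)), atol=1e-12)

    def test_missing_entries_use_subset_and_rank_df(self):
        tm = tmatrix_from({"a": [2.0, np.nan], "b": [np.nan, 1.0],
                           "c": [1.0, np.nan]})
        V = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        out = meta_chi2(tm, V)
        assert out["df"].tolist() == [2, 1]
        assert out["chi2"][0] == pytest.approx(5.0)

    def test_rank_deficient_v_uses_pseudoinverse(self):
        tm = tmatrix_from({"a": [2.0], "b": [2.0]})
        V = pd.DataFrame(np.ones((2, 2)), index=list("ab"), columns=list("ab"))
        out = meta_chi2(tm, V)
        # pinv of the all-ones V: single eigen-direction (1,1)/sqrt(2) with
        # eigenvalue 2 -> chi2 = (t.(1,1)/sqrt(2))^2 / 2 = 4
        assert out["df"][0] == 1
        assert out["chi2"][0] == pytest.approx(4.0)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(6)
        t = {k: rng.standard_normal(100) for k in "abc"}
        tm1 = tmatrix_from(t)
        V1 = estimate_v(tm1)
        t2 = dict(t)
        t2["b"] = -t2["b"]
        tm2 = tmatrix_from(t2)
        V2 = estimate_v(tm2)
        o1 = meta_chi2(tm1, V1)
        o2 = meta_chi2(tm2, V2)
        np.testing.assert_allclose(o1["chi2"], o2["chi2"], atol=1e-10)


class TestBonferroni:
    def test_panel_sized_threshold(self):
        thr = bonferroni_threshold(0.05, 41_666)
        assert thr == pytest.approx(1.20002e-06, rel=1e-5)
        assert -np.log10(thr) == pytest.approx(5.92, abs=0.005)

    def test_identity_and_monotonicity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 10) > bonferroni_threshold(0.05, 100)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def ld_geno(r2_12, r2_13, n=400, seed=0):
    """Three significant SNPs with controlled LD to SNP1 plus fillers."""
    rng = np.random.default_rng(seed)
    x1 = rng.choice([0.0, 2.0], n)
    # tune pairwise r2 by flipping a fraction of calls
    def with_target(x, target):
        best, bestv = None, 1
        for fprob in np.linspace(0, 0.5, 101):
            flip = rng.random(n) < fprob
            y = x.copy()
            y[flip] = 2.0 - y[flip]
            r2 = np.corrcoef(x, y)[0, 1] ** 2
            if abs(r2 - target) < bestv:
                best, bestv = y, abs(r2 - target)
        return best
    x2 = with_target(x1, r2_12)
    x3 = with_target(x1, r2_13)
    d = np.column_stack([x1, x2, x3])
    snps = snp_map(3)
    return GenotypeMatrix([f"L{i}" for i in range(n)], snps, d)


class TestClusterQtl:
    def meta_table(self, snps, pvals):
        return pd.DataFrame({"snp_id": snps["snp_id"], "p": pvals,
                             "significant": True})

    def test_lead_absorbs_high_ld_only(self):
        geno = ld_geno(0.9, 0.1, seed=1)
        meta = self.meta_table(geno.snps, [1e-10, 1e-8, 1e-7])
        qtl = cluster_qtl(meta, geno, r2_threshold=0.5)
        assert len(qtl) == 2
        lead_cluster = qtl[qtl["lead_snp"] == geno.snps["snp_id"][0]]
        assert set(lead_cluster["members"].iloc[0].split(",")) == {
            geno.snps["snp_id"][0], geno.snps["snp_id"][1]}

    def test_different_chromosomes_never_merge(self):
        rng = np.random.default_rng(2)
        x = rng.choice([0.0, 2.0], 200)
        s1 = snp_map(1, chrom="1A")
        s2 = snp_map(1, chrom="2B")
        snps = pd.concat([s1, s2], ignore_index=True)
        snps["snp_id"] = ["1A_0", "2B_0"]
        geno = GenotypeMatrix([f"L{i}" for i in range(200)], snps,
                              np.column_stack([x, x]))
        meta = self.meta_table(snps, [1e-9, 1e-9])
        qtl = cluster_qtl(meta, geno)
        assert len(qtl) == 2

    def test_chain_depends_on_lead_choice(self):
        """r2(1,2) and r2(2,3) just above threshold, r2(1,3) far below:
        a middle lead yields one cluster; an end lead yields two."""
        rng = np.random.default_rng(3)
        n = 2000
        x2 = rng.choice([0.0, 2.0], n)
        def flip_frac(x, f, seed):
            r = np.random.default_rng(seed)
            y = x.copy()
            idx = r.random(n) < f
            y[idx] = 2.0 - y[idx]
            return y
        x1 = flip_frac(x2, 0.09, 1)
        x3 = flip_frac(x2, 0.09, 2)
        d = np.column_stack([x1, x2, x3])
        snps = snp_map(3)
        geno = GenotypeMatrix([f"L{i}" for i in range(n)], snps, d)
        r2_12 = np.corrcoef(x1, x2)[0, 1] ** 2
        r2_13 = np.corrcoef(x1, x3)[0, 1] ** 2
        assert r2_12 > 0.5 and r2_13 < 0.5
        mid_lead = self.meta_table(snps, [1e-7, 1e-10, 1e-8])
        assert len(cluster_qtl(mid_lead, geno)) == 1
        end_lead = self.meta_table(snps, [1e-10, 1e-8, 1e-7])
        assert len(cluster_qtl(end_lead, geno)) == 2

    def test_every_significant_snp_in_exactly_one_cluster(self):
        geno = ld_geno(0.7, 0.3, seed=4)
        meta = self.meta_table(geno.snps, [1e-9, 1e-8, 1e-7])
        qtl = cluster_qtl(meta, geno)
        members = sum((row.split(",") for row in qtl["members"]), [])
        assert sorted(members) == sorted(geno.snps["snp_id"])

    def test_empty_input_empty_output(self):
        geno = ld_geno(0.5, 0.5, seed=5)
        meta = pd.DataFrame({"snp_id": [], "p": [], "significant": []})
        assert len(cluster_qtl(meta, geno)) == 0


class TestRunMetaDesign:
    def grouping(self):
        return ElementGrouping(
            avg_rg=pd.DataFrame(), within_env_avg=pd.Series(dtype=float),
            groups={"Ca": 1, "K": 1, "Fe": 2, "Zn": 2}, overrides={})

    def test_group_of_all_elements_identical_to_meta(self):
        rng = np.random.default_rng(7)
        tm = tmatrix_from({f"{el}:E1": rng.standard_normal(300)
                           for el in ["Ca", "K", "Fe", "Zn"]})
        grouping = ElementGrouping(
            avg_rg=pd.DataFrame(), within_env_avg=pd.Series(dtype=float),
            groups={"Ca": 1, "K": 1, "Fe": 1, "Zn": 2}, overrides={})
        res, _ = run_meta_design(tm, grouping)
        sub = MetaGWAS(tm).fit(analysis_subset=[c for c in tm.analyses
                                                if not c.startswith("Zn")])
        np.testing.assert_allclose(
            res["Meta1"].table["chi2"], sub.table["chi2"], atol=1e-12)

    def test_three_results_and_comparison_table(self):
        rng = np.random.default_rng(8)
        tm = tmatrix_from({f"{el}:{env}": rng.standard_normal(400)
                           for el in ["Ca", "K", "Fe", "Zn"]
                           for env in ["E1", "E2"]})
        res, comp = run_meta_design(tm, self.grouping(), alpha=0.5)
        assert set(res) == {"Meta1", "Meta2", "Meta"}
        assert len(res["Meta1"].analyses) == 4
        assert len(res["Meta"].analyses) == 8
        assert "detected_in" in comp.columns

    def test_empty_group_rejected(self):
        tm = tmatrix_from({"Ca:E1": np.random.default_rng(9).standard_normal(100)})
        with pytest.raises(ValueError):
            run_meta_design(tm, self.grouping())


class TestAllelicEffectSd:
    def blues(self, values, lines):
        return pd.DataFrame({"env": "E1", "element": "Fe",
                             "line_id": lines, "blue": values,
                             "se": 0.1})

    def test_one_sd_separation_gives_unit_effect(self):
        rng = np.random.default_rng(10)
        lines = [f"L{i}" for i in range(40)]
        d = np.array([0.0] * 20 + [2.0] * 20)
        vals = rng.standard_normal(40) * 0.01
        vals[20:] += 1.0
        b = self.blues(vals, lines)
        sd = np.std(vals, ddof=1)
        shift = vals[20:].mean() - vals[:20].mean()
        out = allelic_effect_sd(b, d, lines)
        assert out["effect_sd"][0] == pytest.approx(shift / sd)

    def test_identical_means_zero(self):
        lines = [f"L{i}" for i in range(10)]
        d = np.array([0.0, 2.0] * 5)
        vals = np.tile([1.0, 1.0], 5) + np.arange(10) * 0.0
        vals = np.array([1, 1, 2, 2, 3, 3, 4, 4, 5, 5], dtype=float)
        out = allelic_effect_sd(self.blues(vals, lines), d, lines)
        assert out["effect_sd"][0] == pytest.approx(0.0, abs=1e-12)

    def test_allele_swap_flips_sign(self):
        rng = np.random.default_rng(11)
        lines = [f"L{i}" for i in range(30)]
        d = rng.choice([0.0, 2.0], 30)
        vals = rng.standard_normal(30) + d
        b = self.blues(vals, lines)
        e1 = allelic_effect_sd(b, d, lines)["effect_sd"][0]
        e2 = allelic_effect_sd(b, 2.0 - d, lines)["effect_sd"][0]
        assert e2 == pytest.approx(-e1)

    def test_empty_class_flagged(self):
        lines = [f"L{i}" for i in range(6)]
        d = np.zeros(6)
        out = allelic_effect_sd(self.blues(np.arange(6.0), lines), d, lines)
        assert not out["defined"][0]
        assert np.isnan(out["effect_sd"][0])
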