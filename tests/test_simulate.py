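"""Synthetic-data generator: contracts, determinism, and structure."""

import numpy as np
import pytest

from pleiometa.datatypes import GenotypeMatrix
from pleiometa.simulate import (EnvSpec, simulate_architecture,
                                simulate_genotypes, simulate_trials)


class TestSimulateGenotypes:
    def test_no_missing_when_rate_zero(self):
        g = simulate_genotypes(50, [("1A", 100, 10_000_000)], missing_rate=0.0,
                               seed=1)
        assert not np.isnan(g.dosage).any()

    def test_inbred_dosages_are_homozygous(self):
        g = simulate_genotypes(50, [("1A", 100, 10_000_000)],
                               missing_rate=0.1, seed=1)
        obs = g.dosage[~np.isnan(g.dosage)]
        assert set(np.unique(obs)) <= {0.0, 2.0}

    def test_missing_rate_realised(self):
        g = simulate_genotypes(200, [("1A", 300, 10_000_000)],
                               missing_rate=0.05, seed=2)
        assert np.isnan(g.dosage).mean() == pytest.approx(0.05, abs=0.01)

    def test_maf_floor_respected(self):
        g = simulate_genotypes(100, [("1A", 200, 10_000_000)], maf_min=0.1,
                               seed=3)
        assert (g.maf() >= 0.1).all()

    def test_seed_reproducible(self):
        a = simulate_genotypes(40, [("1A", 60, 5_000_000)], missing_rate=0.02,
                               seed=9)
        b = simulate_genotypes(40, [("1A", 60, 5_000_000)], missing_rate=0.02,
                               seed=9)
        np.testing.assert_array_equal(a.dosage, b.dosage)
        assert a.snps.equals(b.snps)

    def test_positions_strictly_increasing(self):
        g = simulate_genotypes(20, [("1A", 150, 3_000_000),
                                    ("2A", 150, 3_000_000)], seed=4)
        for _, grp in g.snps.groupby("chrom"):
            assert (np.diff(grp["pos_bp"]) > 0).all()

    def test_tiny_ld_scale_gives_background_level_adjacent_r2(self):
        """ld_scale -> 0 removes linkage: adjacent-SNP r2 should sit at the
        inter-chromosomal background, not above it (Monte-Carlo over seeds)."""
        from pleiometa.ld import _pairwise_r2
        adj, bg = [], []
        for seed in range(6):
            g = simulate_genotypes(
                150, [("1A", 150, 50_000_000), ("2A", 150, 50_000_000)],
                ld_scale=1.0, seed=seed)
            m1 = (g.snps["chrom"] == "1A").sum()
            ia = np.arange(m1 - 1)
            adj.append(_pairwise_r2(g.dosage, ia, ia + 1).mean())
            rng = np.random.default_rng(seed)
            ja = rng.integers(0, m1, 300)
            jb = rng.integers(m1, g.n_snps, 300)
            bg.append(_pairwise_r2(g.dosage, ja, jb).mean())
        d = np.array(adj) - np.array(bg)
        mc_se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean()) <= max(2.5 * mc_se, 0.2 * np.mean(bg))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(1, [("1A", 10, 1000)])
        with pytest.raises(ValueError):
            simulate_genotypes(10, [("1A", 10, 1000)], ld_scale=0)
        with pytest.raises(ValueError):
            simulate_genotypes(10, [("1A", 10, 1000)], maf_min=0.6)
        with pytest.raises(ValueError):
            simulate_genotypes(10, [("1A", 10, 1000)], missing_rate=1.0)


class TestSimulateArchitecture:
    def test_one_antagonistic_qtl_has_opposite_group_signs(self, inbred_panel):
        arch = simulate_architecture(inbred_panel, n_antagonistic=1, seed=2)
        ant = arch.qtl_flags[arch.qtl_flags["antagonistic"]]
        assert len(ant) == 1
        eff = arch.qtl_effects.loc[ant.index[0]]
        s1 = np.sign(eff[arch.group1])
        s2 = np.sign(eff[arch.group2])
        assert (s1.to_numpy()[0] == s1.to_numpy()).all()
        assert (s2.to_numpy() == -s1.to_numpy()[0]).all()

    def test_full_within_correlation_with_single_shared_qtl_set(self, inbred_panel):
        """rg_within=1 and no private QTL make within-group genetic values
        perfectly correlated (identical up to scale)."""
        arch = simulate_architecture(
            inbred_panel, elements=["Ca", "K", "Fe", "Zn"], group1=["Ca", "K"],
            n_shared=5, n_private=0, n_antagonistic=0,
            rg_within=1.0 - 1e-9, rg_between=0.3, seed=4)
        gv = arch.genetic_values
        assert abs(np.corrcoef(gv["Ca"], gv["K"])[0, 1]) > 0.999
        assert abs(np.corrcoef(gv["Fe"], gv["Zn"])[0, 1]) > 0.999

    def test_between_group_correlation_near_target(self, inbred_panel):
        """Realised between-group genetic correlation tracks the -0.2 target
        over seeds (shared QTL only, as in the construction)."""
        vals = []
        for seed in range(20):
            arch = simulate_architecture(
                inbred_panel, n_shared=20, n_private=0, n_antagonistic=0,
                rg_within=0.45, rg_between=-0.2, seed=seed)
            gv = arch.genetic_values
            c = np.corrcoef(gv.to_numpy(), rowvar=False)
            i1 = [arch.elements.index(e) for e in arch.group1]
            i2 = [arch.elements.index(e) for e in arch.group2]
            vals.append(np.mean([c[i, j] for i in i1 for j in i2]))
        assert np.mean(vals) == pytest.approx(-0.2, abs=0.15)

    def test_h2_scaling_gives_target_genetic_variance(self, inbred_panel):
        arch = simulate_architecture(inbred_panel, h2_target=0.42, seed=6)
        var = arch.genetic_values.var(ddof=1)
        assert np.allclose(var, 0.42 / 0.58, rtol=1e-10)

    def test_too_many_qtl_rejected(self, inbred_panel):
        with pytest.raises(ValueError):
            simulate_architecture(inbred_panel, n_shared=10_000, seed=0)

    def test_qtl_maf_floor(self, inbred_panel):
        arch = simulate_architecture(inbred_panel, maf_min=0.1, seed=1)
        idx = inbred_panel.snps.set_index("snp_id")
        mafs = inbred_panel.maf()[
            [list(inbred_panel.snps["snp_id"]).index(s)
             for s in arch.qtl_effects.index]]
        assert (mafs >= 0.1).all()


class TestSimulateTrials:
    def test_noise_free_limit_equals_genetic_value(self, inbred_panel):
        arch = simulate_architecture(inbred_panel, elements=["Fe", "Zn"],
                                     group1=["Fe"], seed=3)
        plots = simulate_trials(inbred_panel, arch, [EnvSpec("E1")],
                                spatial_sd=0, rep_sd=0, resid_sd=0, seed=5)
        fe = plots[plots["element"] == "Fe"].set_index("line_id")
        truth = arch.genetic_values["Fe"]
        merged = fe.join(truth.rename("gv"))
        np.testing.assert_allclose(merged["value"], merged["gv"], atol=1e-12)

    def test_two_reps_give_two_plots_per_line_and_element(self, inbred_panel):
        arch = simulate_architecture(inbred_panel, elements=["Fe", "Zn"],
                                     group1=["Fe"], seed=3)
        plots = simulate_trials(inbred_panel, arch,
                                [EnvSpec("E1", n_reps=2)], seed=5)
        counts = plots.groupby(["line_id", "element"]).size()
        assert (counts == 2).all()

    def test_each_plot_position_unique_within_env(self, inbred_panel):
        arch = simulate_architecture(inbred_panel, elements=["Fe"],
                                     group1=[], seed=3)
        plots = simulate_trials(inbred_panel, arch, [EnvSpec("E1")], seed=5)
        assert not plots.duplicated(["env", "row", "col", "element"]).any()

    def test_unknown_subset_line_rejected(self, inbred_panel):
        arch = simulate_architecture(inbred_panel, elements=["Fe"],
                                     group1=[], seed=3)
        with pytest.raises(ValueError):
            simulate_trials(inbred_panel, arch,
                            [EnvSpec("E1", lines=["nope"])], seed=5)

    def test_seed_determinism(self, inbred_panel):
        arch = simulate_architecture(inbred_panel, elements=["Fe"],
                                     group1=[], seed=3)
        a = simulate_trials(inbred_panel, arch, [EnvSpec("E1")], seed=8)
        b = simulate_trials(inbred_panel, arch, [EnvSpec("E1")], seed=8)
        assert a.equals(b)
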