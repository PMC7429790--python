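"""Generator structure: pedigree topology, Mendelian transmission,
trait-architecture bookkeeping and panel assignment."""

import numpy as np
import pandas as pd
import pytest

from ssblup.simdata import (ConfigurationError, SimConfig, assign_panels,
                            simulate_dataset, simulate_genotypes,
                            simulate_pedigree, simulate_phenotypes,
                            simulate_qtl)


def small(**kw):
    base = dict(n_founders=30, n_generations=2, females_per_generation=40,
                males_per_generation=6, n_chromosomes=2, snps_per_chromosome=40,
                n_qtl=6, seed=7)
    base.update(kw)
    return SimConfig(**base)


class TestPedigree:
    def test_founders_only(self):
        ped = simulate_pedigree(small(n_founders=10, n_generations=0))
        assert len(ped) == 10
        assert (ped["sire"] == 0).all() and (ped["dam"] == 0).all()

    def test_determinism(self):
        cfg = small()
        a = simulate_pedigree(cfg)
        b = simulate_pedigree(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_parents_come_from_previous_generation(self):
        cfg = small(n_generations=3, females_per_generation=50)
        ped = simulate_pedigree(cfg)
        gen = ped.set_index("animal")["generation"]
        last = ped[ped["generation"] == 3]
        assert len(last) == 50 + cfg.males_per_generation
        assert (gen.reindex(last["sire"]).to_numpy() == 2).all()
        assert (gen.reindex(last["dam"]).to_numpy() == 2).all()

    def test_birth_years_increase_with_generation(self):
        ped = simulate_pedigree(small())
        assert (ped.groupby("generation")["birth_year"].first().diff().dropna()
                == 1).all()

    @pytest.mark.parametrize("field,value", [
        ("n_founders", 0), ("prop_genotyped", 1.2), ("h2", 0.0),
        ("repeatability", 0.2), ("var_hys", 0.7),
    ])
    def test_invalid_config_rejected(self, field, value):
        with pytest.raises(ConfigurationError):
            small(**{field: value})


class TestGeneDropping:
    def test_mendelian_consistency_scan(self, tiny_dataset):
        """Homozygous x homozygous matings transmit deterministically."""
        ped, X = tiny_dataset.pedigree, tiny_dataset.panel.X
        pos = pd.Series(np.arange(len(ped)), index=ped["animal"])
        off = ped[ped["sire"] != 0]
        checked = 0
        for _, row in off.iterrows():
            i, s, d = pos[row["animal"]], pos[row["sire"]], pos[row["dam"]]
            both0 = (X[s] == 0) & (X[d] == 0)
            both2 = (X[s] == 2) & (X[d] == 2)
            assert (X[i][both0] == 0).all()
            assert (X[i][both2] == 2).all()
            # offspring dosage never exceeds what the parents can transmit
            assert (X[i] >= (X[s] // 2 + X[d] // 2) - 2).all()
            checked += int(both0.sum() + both2.sum())
        assert checked > 100  # the scan actually exercised homozygous loci

    def test_offspring_mean_dosage_matches_midparent(self):
        """A large full-sib cohort has mean dosage near the parental mean,
        within binomial sampling error."""
        n_off = 400
        cfg = small(n_founders=2, n_generations=0, n_hist_generations=0,
                    hist_pop_size=10)
        rows = [(1, 0, 0, 2000, "M", 0), (2, 0, 0, 2000, "F", 0)]
        rows += [(3 + k, 1, 2, 2001, "F", 1) for k in range(n_off)]
        ped = pd.DataFrame(rows, columns=["animal", "sire", "dam",
                                          "birth_year", "sex", "generation"])
        panel = simulate_genotypes(ped, cfg)
        X = panel.X.astype(float)
        midparent = (X[0] + X[1]) / 2.0
        diff = np.abs(X[2:].mean(axis=0) - midparent)
        se = np.sqrt(0.5 / n_off)  # max gamete variance 0.25 per parent
        assert diff.mean() < 3 * se
        assert (diff < 4 * se + 1e-12).all()

    def test_genotypes_deterministic(self, tiny_config, tiny_dataset):
        again = simulate_dataset(tiny_config)
        assert np.array_equal(again.panel.X, tiny_dataset.panel.X)
        pd.testing.assert_frame_equal(again.phenotypes,
                                      tiny_dataset.phenotypes)

    def test_founder_frequencies_define_the_population(self):
        """Without burn-in, founder genotypes are the i.i.d. draw itself:
        haplotype frequencies are whatever was realized, exactly."""
        cfg = small(n_founders=200, n_generations=0, n_hist_generations=0)
        panel = simulate_genotypes(simulate_pedigree(cfg), cfg)
        p = panel.X.mean(axis=0) / 2
        # realized founder frequencies stay near the Uniform(0.05, 0.5) draw
        assert p.mean() < 0.5 and (p <= 1.0).all()


class TestTraitArchitecture:
    def test_tbv_is_exact_dot_product(self, tiny_dataset):
        tv = tiny_dataset.true_values
        X = tiny_dataset.panel.X[:, tv.qtl_indices].astype(float)
        assert np.array_equal(X @ tv.effects, tv.tbv.to_numpy())

    @pytest.mark.parametrize("h2,band", [(0.37, 0.03), (0.04, 0.02)])
    def test_realized_heritability(self, h2, band):
        """var(TBV)/var(y - fixed) lands on the target h2 at n >= 5000."""
        cfg = SimConfig(n_founders=400, n_generations=2,
                        females_per_generation=2400, males_per_generation=30,
                        n_chromosomes=2, snps_per_chromosome=50, n_qtl=30,
                        h2=h2, repeatability=max(h2 + 0.08, 0.12),
                        var_hys=0.1, n_parities=2, seed=11)
        data = simulate_dataset(cfg)
        assert len(data.pedigree) >= 5000
        phen = data.phenotypes
        # remove the fixed part by OLS on the factor codes; the residual
        # variance estimates var(tbv + pe + hys + e) = 1 by construction
        resid = phen["y"] - phen.groupby(["age_class", "parity"])["y"].transform("mean")
        ratio = data.true_values.tbv.var(ddof=0) / resid.var(ddof=0)
        assert abs(ratio - h2) < band

    def test_zero_noise_phenotypes_equal_tbv_shift(self):
        """With e, pe and hys variance all zero and one parity, the record
        deviates from the fixed part by exactly the TBV."""
        cfg = small(h2=1.0, repeatability=1.0, var_hys=0.0, n_parities=1)
        ped = simulate_pedigree(cfg)
        panel = simulate_genotypes(ped, cfg)
        tqv = simulate_qtl(panel, cfg)
        phen = simulate_phenotypes(ped, tqv, cfg)
        resid = phen["y"] - phen.groupby(["age_class", "parity"])["y"].transform("mean")
        tbv = tqv.tbv.reindex(phen["animal"]).to_numpy()
        tbv_c = tbv - pd.Series(tbv).groupby(
            [phen["age_class"].to_numpy(), phen["parity"].to_numpy()]
        ).transform("mean").to_numpy()
        assert np.allclose(resid.to_numpy(), tbv_c, atol=1e-10)

    def test_midparent_regression_slope_near_one(self):
        cfg = SimConfig(n_founders=300, n_generations=2,
                        females_per_generation=1500, males_per_generation=30,
                        n_chromosomes=2, snps_per_chromosome=50, n_qtl=30,
                        seed=13)
        data = simulate_dataset(cfg)
        ped, tbv = data.pedigree, data.true_values.tbv
        off = ped[ped["sire"] != 0]
        mid = (tbv.reindex(off["sire"]).to_numpy()
               + tbv.reindex(off["dam"]).to_numpy()) / 2
        child = tbv.reindex(off["animal"]).to_numpy()
        slope = np.cov(mid, child)[0, 1] / np.var(mid)
        assert abs(slope - 1.0) < 0.1


class TestPanelAssignment:
    def test_no_overlap_means_disjoint_union(self, tiny_dataset):
        cfg = SimConfig(**{**tiny_dataset.config.__dict__,
                           "n_dfs": 4, "n_fra": 6, "n_overlap": 0})
        panel = simulate_genotypes(tiny_dataset.pedigree, cfg)
        tqv = simulate_qtl(panel, cfg)
        assign_panels(panel, tqv, cfg)
        dfs, fra = panel.membership["dfs"], panel.membership["fra"]
        assert len(np.union1d(dfs, fra)) == len(dfs) + len(fra) == 10

    def test_configured_overlap_is_exact(self, tiny_dataset):
        cfg = SimConfig(**{**tiny_dataset.config.__dict__,
                           "n_dfs": 6, "n_fra": 9, "n_overlap": 3})
        panel = simulate_genotypes(tiny_dataset.pedigree, cfg)
        tqv = simulate_qtl(panel, cfg)
        assign_panels(panel, tqv, cfg)
        dfs, fra = panel.membership["dfs"], panel.membership["fra"]
        assert len(np.intersect1d(dfs, fra)) == 3
        assert len(np.union1d(dfs, fra)) == 6 + 9 - 3

    def test_base_panel_excludes_qtl_and_addons(self, tiny_dataset):
        m = tiny_dataset.panel.membership
        base = set(m["base"])
        assert not base & set(m["dfs"])
        assert not base & set(m["fra"])
        assert not base & set(tiny_dataset.true_values.qtl_snp_ids)

    def test_oversized_overlap_rejected(self, tiny_dataset):
        cfg = SimConfig(**{**tiny_dataset.config.__dict__,
                           "n_dfs": 4, "n_fra": 6, "n_overlap": 5})
        panel = simulate_genotypes(tiny_dataset.pedigree, cfg)
        tqv = simulate_qtl(panel, cfg)
        with pytest.raises(ConfigurationError):
            assign_panels(panel, tqv, cfg)
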