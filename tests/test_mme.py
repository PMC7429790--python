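"""Mixed-model solutions, variance-component estimation and yield
deviations."""

import numpy as np
import pandas as pd
import pytest

from ssblup import mme, relmat
from ssblup.panels import maf_filter
from ssblup.pipeline import true_variance_components
from ssblup.simdata import SimConfig, simulate_dataset, simulate_pedigree


def founders_frame(n):
    return pd.DataFrame({"animal": np.arange(1, n + 1), "sire": 0, "dam": 0})


@pytest.fixture(scope="module")
def tiny_fit(tiny_dataset_module):
    data, vc = tiny_dataset_module
    fit = mme.fit_pblup(data.pedigree, data.phenotypes, vc)
    return data, vc, fit


@pytest.fixture(scope="module")
def tiny_dataset_module():
    cfg = SimConfig(n_founders=40, n_generations=3, females_per_generation=60,
                    males_per_generation=8, n_chromosomes=3,
                    snps_per_chromosome=60, n_qtl=8, prop_genotyped=0.4,
                    h2=0.37, repeatability=0.5, var_hys=0.1, seed=1)
    return simulate_dataset(cfg), true_variance_components(cfg)


class TestSolver:
    def test_pcg_agrees_with_dense_solve(self, tiny_dataset_module):
        data, vc = tiny_dataset_module
        dense = mme.fit_pblup(data.pedigree, data.phenotypes, vc,
                              method="dense")
        pcg = mme.fit_pblup(data.pedigree, data.phenotypes, vc, method="pcg")
        assert dense.n_equations_ > 500
        assert np.abs(dense.ebv_ - pcg.ebv_).max() < 1e-6
        assert np.abs(dense.fixed_effects_ - pcg.fixed_effects_).max() < 1e-6

    def test_fully_genotyped_ssgblup_degenerates_to_pblup(self):
        cfg = SimConfig(n_founders=30, n_generations=2,
                        females_per_generation=40, males_per_generation=6,
                        n_chromosomes=2, snps_per_chromosome=40, n_qtl=6,
                        prop_genotyped=1.0, seed=4)
        data = simulate_dataset(cfg)
        vc = true_variance_components(cfg)
        ped = data.pedigree
        A, _ = relmat.build_A(ped)
        A_inv = relmat.build_A_inverse(ped)
        gen = np.arange(len(ped))
        A22 = relmat.subset_A22(A, gen)
        hinv = relmat.build_Hinv(A_inv, A22, A22.copy(), gen)
        pblup = mme.fit_pblup(ped, data.phenotypes, vc, A_inv=A_inv)
        ssg = mme.fit_single_step(ped, data.phenotypes, hinv, vc)
        assert np.abs(pblup.ebv_ - ssg.ebv_).max() < 1e-6

    def test_featured_model_with_null_second_component(self, tiny_dataset_module):
        data, vc = tiny_dataset_module
        ped = data.pedigree
        A, _ = relmat.build_A(ped)
        A_inv = relmat.build_A_inverse(ped)
        gen = np.where(ped["genotyped"])[0]
        Xg = data.panel.X[gen].astype(float)
        keep, _ = maf_filter(Xg, np.arange(Xg.shape[1]), 0.0)
        Gm, _ = relmat.build_Gm(Xg[:, keep])
        A22 = relmat.subset_A22(A, gen)
        Ga, _, _ = relmat.adjust_Ga(Gm, A22)
        hinv = relmat.build_Hinv(A_inv, A22, relmat.blend_G(Ga, A22), gen)
        single = mme.fit_single_step(ped, data.phenotypes, hinv, vc)
        vc2 = dict(vc)
        vc2["a_seq"] = 1e-8  # vanishing featured component
        featured = mme.fit_single_step(ped, data.phenotypes, hinv, vc2,
                                       h_inv_seq=hinv)
        assert np.abs(single.ebv_ - featured.ebv_).max() < 1e-4
        # the reported EBV is the per-animal sum of the two components
        assert np.allclose(featured.ebv_,
                           featured.ebv_components_.sum(axis=1))


class TestYieldDeviation:
    def test_record_accounting_identity(self, tiny_fit):
        data, vc, fit = tiny_fit
        phen = data.phenotypes
        # y decomposes exactly into fixed + ebv + pe + hys + residual
        reconstructed = fit.fitted_ + fit.residuals_
        assert np.allclose(reconstructed, phen["y"].to_numpy())
        # and yd = y - everything except the genetic term = ebv + residual
        yd = mme.compute_yd(fit, phen, vc)
        ebv = fit.ebv_.reindex(phen["animal"]).to_numpy()
        per_record = ebv + fit.residuals_
        manual = pd.Series(per_record).groupby(phen["animal"].to_numpy()).mean()
        merged = yd.set_index("animal")["yd"]
        assert np.allclose(manual.sort_index(), merged.sort_index())

    def test_multi_record_yd_is_the_mean(self, tiny_fit):
        data, vc, fit = tiny_fit
        yd = mme.compute_yd(fit, data.phenotypes, vc)
        counts = data.phenotypes.groupby("animal").size()
        assert (yd.set_index("animal")["n_records"].sort_index()
                == counts.sort_index()).all()

    def test_reliability_uses_repeatability_formula(self, tiny_fit):
        data, vc, fit = tiny_fit
        yd = mme.compute_yd(fit, data.phenotypes, vc)
        tot = vc["a"] + vc["pe"] + vc["e"]
        h2, rep = vc["a"] / tot, (vc["a"] + vc["pe"]) / tot
        row = yd.iloc[0]
        expect = row.n_records * h2 / (1 + (row.n_records - 1) * rep)
        assert row.r2_yd == pytest.approx(expect)


class TestRemlEstimation:
    def test_balanced_one_way_matches_anova(self, rng):
        """Founders only, k records each, no pe/hys: REML equals the
        closed-form ANOVA estimators on a balanced one-way layout."""
        n, k = 150, 4
        sa, se = 0.4, 0.6
        a = rng.normal(0, np.sqrt(sa), n)
        y = (np.repeat(a, k) + rng.normal(0, np.sqrt(se), n * k))
        rec = pd.DataFrame({"animal": np.repeat(np.arange(1, n + 1), k),
                            "y": y})
        est = mme.estimate_vc_pblup(founders_frame(n), rec, fixed_effects=(),
                                    use_pe=False, use_hys=False)
        means = rec.groupby("animal")["y"].mean().to_numpy()
        grand = y.mean()
        msb = k * np.sum((means - grand) ** 2) / (n - 1)
        msw = np.sum((y - np.repeat(means, k)) ** 2) / (n * (k - 1))
        assert est["e"] == pytest.approx(msw, rel=1e-3)
        assert est["a"] == pytest.approx((msb - msw) / k, rel=1e-3)

    def test_null_genetic_signal_shrinks_to_boundary(self, rng):
        n, k = 120, 3
        rec = pd.DataFrame({"animal": np.repeat(np.arange(1, n + 1), k),
                            "y": rng.normal(0, 1.0, n * k)})
        est = mme.estimate_vc_pblup(founders_frame(n), rec, fixed_effects=(),
                                    use_pe=False, use_hys=False)
        assert est["a"] < 0.08

    def test_convergence_error_carries_trajectory(self, rng):
        n = 40
        rec = pd.DataFrame({"animal": np.repeat(np.arange(1, n + 1), 2),
                            "y": rng.normal(size=2 * n)})
        with pytest.raises(mme.ConvergenceError) as err:
            mme.estimate_vc_pblup(founders_frame(n), rec, fixed_effects=(),
                                  use_pe=False, use_hys=False, max_iter=1)
        assert len(err.value.history) >= 1


class TestVarianceSplit:
    def test_identical_matrices_split_evenly(self, rng):
        n = 60
        L = rng.standard_normal((n, n)) / np.sqrt(n)
        G = L @ L.T + np.eye(n)
        y = rng.standard_normal(n)
        with pytest.warns(UserWarning, match="non-identifiable"):
            p1, p2, _ = mme.split_variance_fgblup(y, G, G.copy())
        assert p1 == pytest.approx(0.5, abs=0.05)
        assert p1 + p2 == pytest.approx(1.0)

    def test_planted_component_dominates(self, rng):
        n = 120
        Z1 = rng.standard_normal((n, 80)) / np.sqrt(80)
        Z2 = rng.standard_normal((n, 80)) / np.sqrt(80)
        G1, G2 = Z1 @ Z1.T + 0.01 * np.eye(n), Z2 @ Z2.T + 0.01 * np.eye(n)
        g = np.linalg.cholesky(G2 + 1e-8 * np.eye(n)) @ rng.standard_normal(n)
        y = 2.0 * g + rng.standard_normal(n) * 0.5
        p1, p2, est = mme.split_variance_fgblup(y, G1, G2)
        assert p2 > 0.5
        assert est.converged

    def test_null_second_component_recovered(self, rng):
        n = 120
        Z1 = rng.standard_normal((n, 80)) / np.sqrt(80)
        Z2 = rng.standard_normal((n, 80)) / np.sqrt(80)
        G1, G2 = Z1 @ Z1.T + 0.01 * np.eye(n), Z2 @ Z2.T + 0.01 * np.eye(n)
        g = np.linalg.cholesky(G1 + 1e-8 * np.eye(n)) @ rng.standard_normal(n)
        y = 2.0 * g + rng.standard_normal(n) * 0.5
        _, p2, _ = mme.split_variance_fgblup(y, G1, G2)
        assert p2 < 0.3
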