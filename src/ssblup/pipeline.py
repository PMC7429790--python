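"""End-to-end replicate runner: simulate, fit the model family, validate.

One replicate simulates a population, holds out the last generation as the
validation set (reference = all earlier birth years, which by discrete
generations guarantees no validation animal has a sib or daughter in the
reference), derives yield deviations from a full-data PBLUP fit, fits the
requested prediction models on reference phenotypes only, and scores
validation reliability and bias per genotyped / non-genotyped group.

Variance components default to the true simulation values; the study
workflow of estimating them once under PBLUP and fixing them for every
single-step fit is available via ``vc="reml"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import mme, relmat, validate
from .simdata import SimConfig, SimulatedDataset, simulate_dataset
from .weights import BayesN0, compute_weights

__all__ = ["true_variance_components", "run_replicate", "run_study_replicate"]


def true_variance_components(config: SimConfig) -> dict[str, float]:
    """The generative variance components on the unit phenotypic scale."""
    return {"a": config.h2, "pe": config.repeatability - config.h2,
            "hys": config.var_hys,
            "e": 1.0 - config.repeatability - config.var_hys}


def _hinv_for(data: SimulatedDataset, snp_idx: np.ndarray, A: np.ndarray,
              A_inv, gen_idx: np.ndarray, omega: float,
              snp_weights=None):
    Xg = data.panel.X[gen_idx][:, snp_idx].astype(np.float64)
    from .panels import maf_filter
    keep, _ = maf_filter(Xg, np.arange(Xg.shape[1]), threshold=0.0)
    Gm, _ = relmat.build_Gm(Xg[:, keep],
                            None if snp_weights is None else snp_weights[keep])
    A22 = relmat.subset_A22(A, gen_idx)
    Ga, _, _ = relmat.adjust_Ga(Gm, A22)
    G = relmat.blend_G(Ga, A22, omega)
    return relmat.build_Hinv(A_inv, A22, G, gen_idx), Xg, keep


def run_replicate(config: SimConfig, models=("pblup", "ssgblup"),
                  snp_sets=("base", "combined"), bin_size=30,
                  omega: float = relmat.DEFAULT_OMEGA, vc="true",
                  chain=(2000, 400, 8), data: SimulatedDataset | None = None
                  ) -> dict:
    """Run one simulation replicate and return validation metrics.

    ``models`` may contain "pblup", "ssgblup", "sswgblup", "ssfgblup";
    ``snp_sets`` "base" (chip only) and/or "combined" (chip + both
    add-ons).  Returns a nested dict
    ``{model[_snpset]: {"rel_genotyped": ..., "bias_genotyped": ...,
    "rel_non_genotyped": ..., ...}}`` plus the per-animal tables under
    ``"_detail"``.
    """
    if data is None:
        data = simulate_dataset(config)
    ped, panel, phen = data.pedigree, data.panel, data.phenotypes
    if vc == "true":
        vcomp = true_variance_components(config)
    elif vc == "reml":
        est = mme.estimate_vc_pblup(ped, phen)
        vcomp = dict(est.components)
    else:
        vcomp = dict(vc)
    cutoff = ped["generation"].max()
    val_ids = set(ped.loc[ped["generation"] == cutoff, "animal"])
    ref_records = phen.loc[~phen["animal"].isin(val_ids)]
    gen_mask = ped["genotyped"].to_numpy()
    gen_idx = np.where(gen_mask)[0]
    gen_ids = ped["animal"].to_numpy()[gen_idx]

    A_inv = relmat.build_A_inverse(ped)
    A, _ = relmat.build_A(ped)

    # YD from the full-data pedigree fit (reference + validation phenotypes)
    full_fit = mme.fit_pblup(ped, phen, vcomp, A_inv=A_inv)
    yd = mme.compute_yd(full_fit, phen, vcomp)
    yd_val = yd.loc[yd["animal"].isin(val_ids)].reset_index(drop=True)

    set_idx = {}
    if "base" in snp_sets:
        set_idx["base"] = panel.indices_of(panel.membership["base"])
    if "combined" in snp_sets:
        comb = pd.unique(np.concatenate([panel.membership["base"],
                                         panel.membership["dfs"],
                                         panel.membership["fra"]]))
        set_idx["combined"] = panel.indices_of(comb)

    results: dict[str, dict] = {}
    detail: dict[str, pd.Series] = {}

    def record(key, fit):
        reports = validate.evaluate_predictions(fit.ebv_, yd_val, gen_ids,
                                                model=key)
        results[key] = {}
        for r in reports:
            results[key][f"rel_{r.group}"] = r.reliability
            results[key][f"bias_{r.group}"] = r.bias_b
            results[key][f"n_{r.group}"] = r.n_animals
        detail[key] = fit.ebv_.reindex(yd_val["animal"]).reset_index(drop=True)

    if "pblup" in models:
        record("pblup", mme.fit_pblup(ped, ref_records, vcomp, A_inv=A_inv))

    # BayesN0 response: genotyped reference animals with a yield deviation
    yd_ref_gen = yd.loc[yd["animal"].isin(set(gen_ids) - val_ids)]
    gen_pos = pd.Index(panel.animal_ids).get_indexer(yd_ref_gen["animal"])

    for sname, sidx in set_idx.items():
        smap = panel.snp_map.iloc[sidx].reset_index(drop=True)
        if "ssgblup" in models or "ssfgblup" in models:
            hinv, _, _ = _hinv_for(data, sidx, A, A_inv, gen_idx, omega)
            if "ssgblup" in models:
                record(f"ssgblup_{sname}",
                       mme.fit_single_step(ped, ref_records, hinv, vcomp))
        if "sswgblup" in models:
            Xr = panel.X[gen_pos][:, sidx].astype(np.float64)
            from .panels import maf_filter
            keep, _ = maf_filter(Xr, np.arange(Xr.shape[1]), threshold=0.0)
            est = BayesN0(bin_size=bin_size, n_iter=chain[0], burn_in=chain[1],
                          thin=chain[2], random_state=config.seed + 7)
            est.fit(Xr[:, keep], yd_ref_gen["yd"].to_numpy(),
                    reliability=yd_ref_gen["r2_yd"].to_numpy(),
                    snp_map=smap.loc[keep].reset_index(drop=True))
            w_full = np.ones(len(sidx))
            w_full[keep] = compute_weights(est.snp_variance_)
            hinv_w, _, _ = _hinv_for(data, sidx, A, A_inv, gen_idx, omega,
                                     snp_weights=w_full)
            record(f"sswgblup_{sname}",
                   mme.fit_single_step(ped, ref_records, hinv_w, vcomp))
    if "ssfgblup" in models and "combined" in set_idx:
        seq = pd.unique(np.concatenate([panel.membership["dfs"],
                                        panel.membership["fra"]]))
        seq_idx = panel.indices_of(seq)
        base_idx = set_idx.get("base",
                               panel.indices_of(panel.membership["base"]))
        hinv_chip, _, kc = _hinv_for(data, base_idx, A, A_inv, gen_idx, omega)
        hinv_seq, _, ks = _hinv_for(data, seq_idx, A, A_inv, gen_idx, omega)
        # variance split from a two-component genomic fit on genotyped
        # reference animals
        ref_gen_pos = pd.Index(panel.animal_ids).get_indexer(
            yd_ref_gen["animal"])
        A22_ref = relmat.subset_A22(A, pd.Index(ped["animal"]).get_indexer(
            yd_ref_gen["animal"]))

        def _blended(idx):
            Gm, _ = relmat.build_Gm(panel.X[ref_gen_pos][:, idx].astype(float))
            Ga, _, _ = relmat.adjust_Ga(Gm, A22_ref)
            return relmat.blend_G(Ga, A22_ref, omega)

        G1 = _blended(base_idx[kc])
        G2 = _blended(seq_idx[ks])
        p54k, pseq, _ = mme.split_variance_fgblup(
            yd_ref_gen["yd"].to_numpy(), G1, G2)
        vcf = dict(vcomp)
        vcf["a"] = max(vcomp["a"] * p54k, 1e-8)
        vcf["a_seq"] = max(vcomp["a"] * pseq, 1e-8)
        record("ssfgblup_combined",
               mme.fit_single_step(ped, ref_records, hinv_chip, vcf,
                                   h_inv_seq=hinv_seq))
    results["_detail"] = {"yd": yd_val, "ebv": detail,
                          "genotyped_ids": gen_ids}
    return results


def run_study_replicate(config_high: SimConfig, config_low: SimConfig,
                        **kwargs) -> dict:
    """Two traits on one genotyped population, as in a real evaluation.

    The high-heritability (milk-like) and low-heritability (fertility-like)
    traits are simulated on the same pedigree and genotypes with
    independent QTL sets; the add-on panels are assigned from the
    high-h2 trait's QTL, mirroring selected-sequence SNP lists that target
    production traits.  Returns ``{"high": ..., "low": ...}`` of
    :func:`run_replicate` results.
    """
    from dataclasses import replace

    from .simdata import (assign_panels, simulate_genotypes, simulate_pedigree,
                          simulate_phenotypes, simulate_qtl)

    config_low = replace(config_low, seed=config_high.seed)
    ped = simulate_pedigree(config_high)
    panel = simulate_genotypes(ped, config_high)
    tqv_high = simulate_qtl(panel, config_high, stream=41)
    assign_panels(panel, tqv_high, config_high)
    tqv_low = simulate_qtl(panel, config_low, stream=43)
    data_high = SimulatedDataset(config_high, ped, panel, tqv_high,
                                 simulate_phenotypes(ped, tqv_high, config_high))
    data_low = SimulatedDataset(config_low, ped, panel, tqv_low,
                                simulate_phenotypes(ped, tqv_low, config_low, stream=67))
    return {"high": run_replicate(config_high, data=data_high, **kwargs),
            "low": run_replicate(config_low, data=data_low, **kwargs)}
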