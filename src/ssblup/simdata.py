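"""Synthetic pedigree, genotype and phenotype generator for single-step studies.

Emulates the data structure of a dairy-cattle genetic evaluation: a
multi-generation pedigree with genotyped and non-genotyped females, a
medium-density base SNP panel plus two partially overlapping "selected
sequence SNP" add-on panels enriched at QTL, and repeated lactation records
with herd-year-season and permanent-environment random effects.

Genotypes are produced by gene dropping: founder haplotypes are drawn from
per-locus allele frequencies, and offspring gametes are formed by Mendelian
transmission with Haldane (no-interference) recombination at 1 Morgan per
chromosome.

All randomness is driven by ``SimConfig.seed``; identical configs give
bit-identical output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "SimConfig",
    "GenotypePanel",
    "TrueGeneticValues",
    "SimulatedDataset",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_qtl",
    "assign_panels",
    "simulate_phenotypes",
    "simulate_marker_regression",
    "simulate_dataset",
    "write_dataset",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of one simulated population.

    Variance bookkeeping: the phenotypic variance of ``y - fixed`` is
    normalised to 1 and split as sigma2_a = ``h2``, sigma2_pe =
    ``repeatability - h2``, sigma2_hys = ``var_hys`` and sigma2_e =
    ``1 - repeatability - var_hys``.  Records of the same cow share the
    additive and permanent-environment effects, so ``repeatability`` is the
    within-cow correlation net of the contemporary-group effect.
    """

    n_founders: int = 150
    n_generations: int = 3
    females_per_generation: int = 250
    males_per_generation: int = 15
    prop_genotyped: float = 0.6
    n_chromosomes: int = 5
    snps_per_chromosome: int = 200
    n_qtl: int = 100
    qtl_gamma_shape: float = 0.4
    qtl_gamma_scale: float = 1.0
    h2: float = 0.37
    repeatability: float = 0.5
    var_hys: float = 0.1
    n_parities: int = 3
    n_herds: int = 25
    n_seasons: int = 2
    # add-on panel sizes; None derives them from the QTL neighbourhood pool
    n_dfs: int | None = None
    n_fra: int | None = None
    n_overlap: int | None = None
    # historical random-mating burn-in that builds marker-QTL LD before the
    # recorded pedigree (LD extent ~ 1/(4 N c), so a small historical
    # population gives chip-like LD at the few-cM scale)
    n_hist_generations: int = 100
    hist_pop_size: int = 80
    base_year: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "females_per_generation", "males_per_generation",
                     "n_chromosomes", "snps_per_chromosome", "n_qtl", "n_parities",
                     "n_herds", "n_seasons"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_generations < 0:
            raise ConfigurationError("n_generations must be >= 0")
        if not 0.0 <= self.prop_genotyped <= 1.0:
            raise ConfigurationError("prop_genotyped must be in [0, 1]")
        if not 0.0 < self.h2 <= 1.0:
            raise ConfigurationError("h2 must be in (0, 1]")
        if self.repeatability < self.h2:
            raise ConfigurationError("repeatability must be >= h2")
        if self.repeatability > 1.0:
            raise ConfigurationError("repeatability must be <= 1")
        # equality leaves zero residual variance (a legal degenerate case)
        if self.var_hys < 0 or self.repeatability + self.var_hys > 1.0:
            raise ConfigurationError("need repeatability + var_hys <= 1")


@dataclass
class GenotypePanel:
    """0/1/2 dosages plus the SNP map and optional panel membership."""

    animal_ids: np.ndarray            # (n,) int, aligned with rows of X
    X: np.ndarray                     # (n, m) int8 dosage of the A2 allele
    snp_map: pd.DataFrame             # columns: chrom, snp_id, cm, bp (sorted)
    membership: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_map["snp_id"].to_numpy()

    def indices_of(self, snp_ids) -> np.ndarray:
        """Map SNP ids to column indices of ``X`` (map order preserved)."""
        pos = pd.Index(self.snp_map["snp_id"])
        idx = pos.get_indexer(np.asarray(snp_ids))
        if (idx < 0).any():
            missing = np.asarray(snp_ids)[idx < 0][:5]
            raise KeyError(f"SNP ids not in map: {missing}")
        return np.sort(idx)

    def subset_animals(self, animal_ids) -> "GenotypePanel":
        pos = pd.Index(self.animal_ids).get_indexer(animal_ids)
        if (pos < 0).any():
            raise KeyError("animal ids without genotypes requested")
        return GenotypePanel(np.asarray(animal_ids), self.X[pos], self.snp_map,
                             dict(self.membership))


@dataclass
class TrueGeneticValues:
    """Ground truth: QTL placement, allelic effects, and per-animal TBV."""

    qtl_indices: np.ndarray           # column indices into the genotype matrix
    qtl_snp_ids: np.ndarray
    effects: np.ndarray               # trait units per copy of the A2 allele
    tbv: pd.Series                    # indexed by animal id


@dataclass
class SimulatedDataset:
    config: SimConfig
    pedigree: pd.DataFrame
    panel: GenotypePanel
    true_values: TrueGeneticValues
    phenotypes: pd.DataFrame


def simulate_pedigree(config: SimConfig) -> pd.DataFrame:
    """Discrete-generation pedigree with columns
    animal, sire, dam, birth_year, sex, generation, genotyped.

    Founders (generation 0) have unknown parents (coded 0).  Every
    non-founder has a sire and a dam drawn from the previous generation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n_m = min(config.males_per_generation, max(1, config.n_founders - 1))
    records = []
    next_id = 1
    prev_males, prev_females = [], []
    for i in range(config.n_founders):
        sex = "M" if i < n_m else "F"
        records.append((next_id, 0, 0, config.base_year, sex, 0))
        (prev_males if sex == "M" else prev_females).append(next_id)
        next_id += 1
    if not prev_females:  # all-male founder edge case
        prev_females = prev_males
    for g in range(1, config.n_generations + 1):
        males, females = [], []
        n_off = config.females_per_generation + config.males_per_generation
        sires = rng.choice(prev_males, size=n_off)
        dams = rng.choice(prev_females, size=n_off)
        for k in range(n_off):
            sex = "M" if k < config.males_per_generation else "F"
            records.append((next_id, int(sires[k]), int(dams[k]),
                            config.base_year + g, sex, g))
            (males if sex == "M" else females).append(next_id)
            next_id += 1
        prev_males, prev_females = males, females
    ped = pd.DataFrame(records, columns=["animal", "sire", "dam", "birth_year",
                                         "sex", "generation"])
    ped["genotyped"] = rng.random(len(ped)) < config.prop_genotyped
    return ped


def pedigree_to_indices(pedigree: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """0-based sire/dam index arrays (-1 = unknown), validating order."""
    ids = pedigree["animal"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate animal ids in pedigree")
    pos = pd.Series(np.arange(len(ids)), index=ids)
    out = []
    for col in ("sire", "dam"):
        p = pedigree[col].to_numpy()
        idx = np.full(len(ids), -1, dtype=np.int64)
        known = p != 0
        mapped = pos.reindex(p[known])
        if mapped.isna().any():
            raise ValueError(f"{col} ids missing from pedigree")
        idx[known] = mapped.to_numpy(dtype=np.int64)
        out.append(idx)
    sire_idx, dam_idx = out
    own = np.arange(len(ids))
    if (sire_idx >= own).any() or (dam_idx >= own).any():
        raise ValueError("pedigree is not sorted parents-first")
    return sire_idx, dam_idx


@njit(cache=True)
def _gene_drop(hap, sire_idx, dam_idx, chrom_start, chrom_end, pos_cm, seed):
    np.random.seed(seed)
    n = hap.shape[0]
    for i in range(n):
        for slot in range(2):
            parent = sire_idx[i] if slot == 0 else dam_idx[i]
            if parent < 0:
                continue  # founder haplotypes pre-filled
            for c in range(chrom_start.shape[0]):
                lo, hi = chrom_start[c], chrom_end[c]
                length_m = (pos_cm[hi - 1] - pos_cm[lo]) / 100.0
                n_x = np.random.poisson(length_m) if length_m > 0 else 0
                cur = np.random.randint(0, 2)
                if n_x == 0:
                    for j in range(lo, hi):
                        hap[i, slot, j] = hap[parent, cur, j]
                    continue
                xp = np.sort(np.random.uniform(pos_cm[lo], pos_cm[hi - 1], n_x))
                k = 0
                for j in range(lo, hi):
                    while k < n_x and xp[k] <= pos_cm[j]:
                        cur = 1 - cur
                        k += 1
                    hap[i, slot, j] = hap[parent, cur, j]


def simulate_genotypes(pedigree: pd.DataFrame, config: SimConfig) -> GenotypePanel:
    """Gene-drop 0/1/2 genotypes for every animal in the pedigree.

    Allele frequencies at the historical founding are drawn per SNP from
    Uniform(0.05, 0.5); ``n_hist_generations`` of random mating in a
    population of ``hist_pop_size`` then build linkage disequilibrium
    (and drift) before the recorded pedigree founders are sampled, so the
    surviving markers tag nearby QTL as a real chip does.  Dosages count
    copies of the A2 allele.
    """
    sire_idx, dam_idx = pedigree_to_indices(pedigree)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    n = len(pedigree)
    m = config.n_chromosomes * config.snps_per_chromosome
    freqs = rng.uniform(0.05, 0.5, size=m)
    # map: positions uniform on a 100 cM chromosome, sorted within chromosome
    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1),
                       config.snps_per_chromosome)
    cm = np.concatenate([np.sort(rng.uniform(0.0, 100.0, config.snps_per_chromosome))
                         for _ in range(config.n_chromosomes)])
    snp_map = pd.DataFrame({
        "chrom": chroms,
        "snp_id": [f"snp{c}_{j}" for c, j in
                   zip(chroms, np.tile(np.arange(config.snps_per_chromosome),
                                       config.n_chromosomes))],
        "cm": cm,
        "bp": (cm * 1e6).astype(np.int64) + 1,
    })
    # prepend the historical burn-in population: gen 0 drawn from the
    # Uniform frequencies, then random mating for n_hist_generations
    N, T = config.hist_pop_size, config.n_hist_generations
    n_hist = N * (T + 1)
    h_sire = np.full(n_hist + n, -1, dtype=np.int64)
    h_dam = np.full(n_hist + n, -1, dtype=np.int64)
    for t in range(1, T + 1):
        lo_prev, lo = N * (t - 1), N * t
        h_sire[lo:lo + N] = rng.integers(lo_prev, lo_prev + N, size=N)
        h_dam[lo:lo + N] = rng.integers(lo_prev, lo_prev + N, size=N)
    last = np.arange(N * T, n_hist)
    ped_founders = sire_idx < 0
    h_sire[n_hist:][ped_founders] = rng.choice(last, size=ped_founders.sum())
    h_dam[n_hist:][ped_founders] = rng.choice(last, size=ped_founders.sum())
    h_sire[n_hist:][~ped_founders] = sire_idx[~ped_founders] + n_hist
    h_dam[n_hist:][~ped_founders] = dam_idx[~ped_founders] + n_hist

    hap = np.zeros((n_hist + n, 2, m), dtype=np.int8)
    hap[:N] = (rng.random((N, 2, m)) < freqs).astype(np.int8)
    chrom_start = np.arange(config.n_chromosomes) * config.snps_per_chromosome
    chrom_end = chrom_start + config.snps_per_chromosome
    drop_seed = int(np.random.SeedSequence([config.seed, 37]).generate_state(1)[0]
                    % (2 ** 31))
    _gene_drop(hap, h_sire, h_dam, chrom_start, chrom_end, cm, drop_seed)
    X = hap[n_hist:].sum(axis=1, dtype=np.int8)
    return GenotypePanel(pedigree["animal"].to_numpy(), X, snp_map)


def simulate_qtl(panel: GenotypePanel, config: SimConfig,
                 stream: int = 41) -> TrueGeneticValues:
    """Pick QTL among polymorphic loci and draw signed gamma effects.

    Effects are rescaled so that the population variance of the true
    breeding values equals ``h2`` on the unit phenotypic-variance scale;
    each animal's TBV is exactly its QTL dosages dotted with the effects.
    ``stream`` decouples the QTL draw from the rest of the seed so several
    traits can be simulated on one genotype panel.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, stream]))
    p = panel.X.mean(axis=0) / 2.0
    poly = np.where((p > 0.02) & (p < 0.98))[0]
    if len(poly) < config.n_qtl:
        raise ConfigurationError("not enough polymorphic loci for the requested QTL")
    qtl = np.sort(rng.choice(poly, size=config.n_qtl, replace=False))
    eff = rng.gamma(config.qtl_gamma_shape, config.qtl_gamma_scale, config.n_qtl)
    eff *= rng.choice([-1.0, 1.0], size=config.n_qtl)
    raw = panel.X[:, qtl].astype(np.float64) @ eff
    v = raw.var()
    if v <= 0:
        raise ConfigurationError("degenerate QTL genotypes (zero TBV variance)")
    eff *= np.sqrt(config.h2 / v)
    tbv = pd.Series(panel.X[:, qtl].astype(np.float64) @ eff,
                    index=panel.animal_ids, name="tbv")
    return TrueGeneticValues(qtl, panel.snp_ids[qtl], eff, tbv)


def assign_panels(panel: GenotypePanel, true_qtl: TrueGeneticValues,
                  config: SimConfig) -> GenotypePanel:
    """Label SNPs as base / DFS-like / FRA-like panels.

    The base panel is every SNP except the QTL themselves, so the chip
    tags each QTL only through linkage disequilibrium with its flanking
    markers — as a real medium-density chip does.  The add-on panels are
    drawn from the QTL and their immediate flanks with a configured
    overlap, emulating sequence-selected lists of causal loci and tight
    tags; any add-on SNP is removed from the base panel.
    """
    m = panel.X.shape[1]
    chrom = panel.snp_map["chrom"].to_numpy()
    pool_mask = np.zeros(m, dtype=bool)
    pool_mask[true_qtl.qtl_indices] = True
    flank_mask = np.zeros(m, dtype=bool)
    for q in true_qtl.qtl_indices:
        for nb in (q - 1, q + 1):
            if 0 <= nb < m and chrom[nb] == chrom[q] and not pool_mask[nb]:
                flank_mask[nb] = True
    pool = np.where(pool_mask | flank_mask)[0]
    n_pool = len(pool)
    # default sizes keep the roughly 1:1.9 ratio of a small
    # association-selected and a larger bioinformatics-selected list
    n_dfs = (config.n_dfs if config.n_dfs is not None
             else max(2, round(0.6 * config.n_qtl)))
    n_fra = (config.n_fra if config.n_fra is not None
             else max(2, round(1.0 * config.n_qtl)))
    if config.n_overlap is not None:
        n_overlap = config.n_overlap
    else:
        n_overlap = max(round(0.05 * min(n_dfs, n_fra)),
                        n_dfs + n_fra - n_pool)
    if n_overlap > min(n_dfs, n_fra):
        raise ConfigurationError("requested overlap larger than an add-on panel")
    if n_dfs + n_fra - n_overlap > n_pool:
        raise ConfigurationError("QTL neighbourhood pool too small for the add-ons")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 53]))
    # causal loci are picked first; flanking tags only fill out the panels,
    # so the base chip keeps as much of its LD tagging as possible
    perm = np.concatenate([rng.permutation(np.where(pool_mask)[0]),
                           rng.permutation(np.where(flank_mask)[0])])
    shared = perm[:n_overlap]
    dfs_only = perm[n_overlap:n_dfs]
    fra_only = perm[n_dfs:n_dfs + n_fra - n_overlap]
    dfs = np.sort(np.concatenate([shared, dfs_only])).astype(int)
    fra = np.sort(np.concatenate([shared, fra_only])).astype(int)
    excluded = np.zeros(m, dtype=bool)
    excluded[true_qtl.qtl_indices] = True
    excluded[dfs] = True
    excluded[fra] = True
    base = np.where(~excluded)[0]
    ids = panel.snp_ids
    panel.membership = {"base": ids[base], "dfs": ids[dfs], "fra": ids[fra]}
    return panel


def simulate_phenotypes(pedigree: pd.DataFrame, tbv: TrueGeneticValues | pd.Series,
                        config: SimConfig, stream: int = 61) -> pd.DataFrame:
    """Repeated lactation records for every female.

    y = mu + age(fixed) + parity(fixed) + TBV + pe + hys + e, with
    variances on the unit scale described in :class:`SimConfig`.  Returns
    columns animal, parity, age_class, hys, y.
    """
    tbv_s = tbv.tbv if isinstance(tbv, TrueGeneticValues) else tbv
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, stream]))
    var_pe = config.repeatability - config.h2
    var_e = 1.0 - config.repeatability - config.var_hys
    females = pedigree.loc[pedigree["sex"] == "F"]
    n_f = len(females)
    if n_f == 0:
        raise ConfigurationError("no females to phenotype")
    herd = rng.integers(config.n_herds, size=n_f)
    first_age = rng.integers(24, 37, size=n_f)  # months at first calving
    pe = rng.normal(0.0, np.sqrt(var_pe), size=n_f)
    age_levels = {}
    parity_eff = rng.normal(0.0, 0.2, size=config.n_parities)
    rows = []
    for k, (aid, byear) in enumerate(zip(females["animal"].to_numpy(),
                                         females["birth_year"].to_numpy())):
        for par in range(1, config.n_parities + 1):
            # calving intervals vary, so age classes overlap across parities
            age = int(first_age[k]) + 13 * (par - 1) + int(rng.integers(-2, 4))
            age_class = age // 6  # half-year classes
            season = rng.integers(config.n_seasons)
            hys = f"h{herd[k]}_y{byear + 1 + par}_s{season}"
            rows.append((aid, par, age_class, hys, k))
    df = pd.DataFrame(rows, columns=["animal", "parity", "age_class", "hys", "_k"])
    for lvl in df["age_class"].unique():
        age_levels[lvl] = rng.normal(0.0, 0.2)
    hys_levels = {h: rng.normal(0.0, np.sqrt(config.var_hys))
                  for h in df["hys"].unique()}
    e = rng.normal(0.0, np.sqrt(var_e), size=len(df))
    df["y"] = (10.0
               + df["age_class"].map(age_levels).to_numpy()
               + parity_eff[df["parity"].to_numpy() - 1]
               + tbv_s.reindex(df["animal"]).to_numpy()
               + pe[df["_k"].to_numpy()]
               + df["hys"].map(hys_levels).to_numpy()
               + e)
    return df.drop(columns="_k")


def simulate_marker_regression(n_animals: int, n_snps: int,
                               qtl_variance_share: float = 0.3,
                               h2: float = 0.5, n_chromosomes: int = 2,
                               seed: int = 0):
    """Direct genotype-phenotype draw for marker-regression studies.

    Unlinked genotypes with frequencies Uniform(0.1, 0.5); one planted QTL
    carrying ``qtl_variance_share`` of the genetic variance, the remainder
    spread as small normal effects over 10% of the SNPs; phenotypic
    variance 1 with heritability ``h2``.

    Returns ``(X, y, snp_map, qtl_index)``.
    """
    if not 0.0 < qtl_variance_share <= 1.0:
        raise ConfigurationError("qtl_variance_share must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 71]))
    p = rng.uniform(0.1, 0.5, size=n_snps)
    X = rng.binomial(2, p, size=(n_animals, n_snps)).astype(np.float64)
    per_chrom = n_snps // n_chromosomes
    chroms = np.repeat(np.arange(1, n_chromosomes + 1), per_chrom)
    chroms = np.concatenate([chroms, np.full(n_snps - len(chroms),
                                             n_chromosomes)])
    snp_map = pd.DataFrame({"chrom": chroms,
                            "snp_id": [f"m{j}" for j in range(n_snps)],
                            "cm": np.concatenate(
                                [np.arange((chroms == c).sum(), dtype=float)
                                 for c in np.unique(chroms)])})
    qtl = int(rng.integers(n_snps))
    g_qtl = X[:, qtl] - X[:, qtl].mean()
    g_qtl *= np.sqrt(qtl_variance_share * h2) / max(g_qtl.std(), 1e-12)
    n_poly = max(1, n_snps // 10)
    poly_idx = rng.choice(np.setdiff1d(np.arange(n_snps), [qtl]), n_poly,
                          replace=False)
    beta = rng.standard_normal(n_poly)
    g_poly = (X[:, poly_idx] - X[:, poly_idx].mean(axis=0)) @ beta
    g_poly *= np.sqrt((1.0 - qtl_variance_share) * h2) / max(g_poly.std(),
                                                             1e-12)
    e = rng.standard_normal(n_animals) * np.sqrt(1.0 - h2)
    y = g_qtl + g_poly + e
    return X, y, snp_map, qtl


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: pedigree, genotypes, QTL, panels, phenotypes."""
    ped = simulate_pedigree(config)
    panel = simulate_genotypes(ped, config)
    tqv = simulate_qtl(panel, config)
    assign_panels(panel, tqv, config)
    phen = simulate_phenotypes(ped, tqv, config)
    return SimulatedDataset(config, ped, panel, tqv, phen)


def write_dataset(data: SimulatedDataset, out_dir: str) -> None:
    """Write the dataset as plain-text files (CSV/TSV), unknown parent = 0."""
    os.makedirs(out_dir, exist_ok=True)
    data.pedigree.to_csv(os.path.join(out_dir, "pedigree.csv"), index=False)
    data.phenotypes.to_csv(os.path.join(out_dir, "phenotypes.csv"), index=False)
    raw = pd.DataFrame(data.panel.X, columns=data.panel.snp_ids)
    raw.insert(0, "animal", data.panel.animal_ids)
    raw.to_csv(os.path.join(out_dir, "genotypes.raw.tsv"), sep="\t", index=False)
    data.panel.snp_map.to_csv(os.path.join(out_dir, "genotypes.map.tsv"),
                              sep="\t", index=False)
    rows = [(name, sid) for name, ids in data.panel.membership.items()
            for sid in ids]
    pd.DataFrame(rows, columns=["panel", "snp_id"]).to_csv(
        os.path.join(out_dir, "panels.tsv"), sep="\t", index=False)
    tv = pd.DataFrame({"animal": data.true_values.tbv.index,
                       "tbv": data.true_values.tbv.to_numpy()})
    tv.to_csv(os.path.join(out_dir, "true_values.tsv"), sep="\t", index=False)
    pd.DataFrame({"snp_id": data.true_values.qtl_snp_ids,
                  "effect": data.true_values.effects}).to_csv(
        os.path.join(out_dir, "qtl_effects.tsv"), sep="\t", index=False)
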