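"""SNP-set assembly and quality control.

Combines the base chip panel with the selected-sequence add-on panels by
id-level union, applies the minor-allele-frequency filter (strictly greater
than the threshold) and the imputation-accuracy retention rule (both the
imputed/observed dosage correlation and the concordance rate must exceed
0.8), and supports the masking design used to score imputation accuracy.
Imputation itself is out of scope: the module evaluates supplied imputed
matrices against observed ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SnpSet",
    "union_sets",
    "maf_filter",
    "imputation_accuracy",
    "mask_for_assessment",
]

MAF_THRESHOLD = 0.01
ACCURACY_THRESHOLD = 0.8


@dataclass(frozen=True)
class SnpSet:
    """A named, ordered set of unique SNP ids."""

    name: str
    snp_ids: tuple

    def __post_init__(self):
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError(f"duplicate SNP ids in set {self.name!r}")
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))

    def __len__(self) -> int:
        return len(self.snp_ids)


def union_sets(sets, name: str | None = None) -> SnpSet:
    """Order-preserving union of SNP sets (id-level deduplication)."""
    seen = {}
    for s in sets:
        ids = s.snp_ids if isinstance(s, SnpSet) else s
        for sid in ids:
            seen.setdefault(sid, None)
    if name is None:
        name = " + ".join(s.name if isinstance(s, SnpSet) else "set"
                          for s in sets)
    return SnpSet(name, tuple(seen.keys()))


def maf_filter(X: np.ndarray, snp_ids, threshold: float = MAF_THRESHOLD
               ) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep SNPs with minor allele frequency strictly greater than
    ``threshold`` (default 0.01); monomorphic SNPs always fail.

    Returns ``(keep_mask, removal_log)`` where the log has columns
    snp_id, reason, value.
    """
    X = np.asarray(X, dtype=np.float64)
    snp_ids = np.asarray(snp_ids)
    p = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf > threshold
    removed = ~keep
    reasons = np.where(maf[removed] == 0.0, "monomorphic", "low_maf")
    log = pd.DataFrame({"snp_id": snp_ids[removed], "reason": reasons,
                        "value": maf[removed]})
    return keep, log


def imputation_accuracy(imputed: np.ndarray, observed: np.ndarray, snp_ids,
                        masked_idx=None,
                        threshold: float = ACCURACY_THRESHOLD) -> pd.DataFrame:
    """Per-SNP imputation accuracy over the masked animals.

    Correlation is the Pearson correlation between imputed and observed
    dosages (0/1/2); concordance is the fraction of exactly matching
    genotypes.  A SNP is retained only when both strictly exceed
    ``threshold`` (default 0.8); a zero-variance observed SNP has an
    undefined correlation and fails with a reason code.

    Returns columns snp_id, correlation, concordance, retained, reason.
    """
    imputed = np.asarray(imputed, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if imputed.shape != observed.shape:
        raise ValueError("imputed and observed matrices must align")
    if masked_idx is not None:
        imputed = imputed[np.asarray(masked_idx)]
        observed = observed[np.asarray(masked_idx)]
    n, m = observed.shape
    oc = observed - observed.mean(axis=0)
    ic = imputed - imputed.mean(axis=0)
    so = np.sqrt((oc ** 2).sum(axis=0))
    si = np.sqrt((ic ** 2).sum(axis=0))
    denom = so * si
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, (oc * ic).sum(axis=0) / denom, np.nan)
    conc = (imputed == observed).mean(axis=0)
    retained = np.where(np.isnan(corr), False,
                        (corr > threshold) & (conc > threshold))
    reason = np.full(m, "", dtype=object)
    reason[np.isnan(corr)] = "zero_variance_observed"
    reason[(~retained) & (reason == "")] = "low_accuracy"
    return pd.DataFrame({"snp_id": np.asarray(snp_ids),
                         "correlation": corr, "concordance": conc,
                         "retained": retained.astype(bool), "reason": reason})


def mask_for_assessment(X: np.ndarray, fraction: float = 0.10, seed: int = 0,
                        snp_idx=None) -> tuple[np.ndarray, np.ndarray]:
    """Withhold the add-on-panel genotypes of a random animal subset.

    Returns ``(masked_X, masked_animal_idx)`` with NaN at the masked
    entries; ``snp_idx`` restricts masking to the add-on columns (all
    columns when None).  Deterministic given ``seed``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    X = np.asarray(X, dtype=np.float64).copy()
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    k = int(round(fraction * n))
    masked = np.sort(rng.choice(n, size=k, replace=False))
    cols = slice(None) if snp_idx is None else np.asarray(snp_idx)
    if k:
        X[np.ix_(masked, np.arange(X.shape[1])[cols])] = np.nan
    return X, masked
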