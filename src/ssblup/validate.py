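"""Validation of genomic predictions: reliability, bias, bootstrap tests.

Reliability is the squared Pearson correlation between EBV and yield
deviation (YD) divided by the mean reliability of YD in the validation
set; bias is the unweighted OLS slope of YD on EBV (deviation from 1
indicates inflation when < 1, deflation when > 1).  Both are reported for
genotyped and non-genotyped validation animals separately.

Model and SNP-set comparisons use a paired non-parametric bootstrap over
validation animals (default 10,000 resamples) with a two-sided percentile
p-value and Bonferroni adjustment over the number of tests performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "reliability",
    "bias_regression",
    "BootstrapResult",
    "bootstrap_compare",
    "ValidationReport",
    "evaluate_predictions",
]


def reliability(ebv, yd, r2_yd) -> float:
    """corr(EBV, YD)^2 / mean(r2_YD), unweighted."""
    ebv = np.asarray(ebv, dtype=np.float64)
    yd = np.asarray(yd, dtype=np.float64)
    r2 = np.asarray(r2_yd, dtype=np.float64)
    c = np.corrcoef(ebv, yd)[0, 1]
    return float(c * c / r2.mean())


def bias_regression(ebv, yd) -> float:
    """Unweighted OLS slope of YD on EBV."""
    ebv = np.asarray(ebv, dtype=np.float64)
    yd = np.asarray(yd, dtype=np.float64)
    vx = ebv.var()
    if vx == 0:
        raise ValueError("EBV have zero variance; slope undefined")
    return float(np.cov(ebv, yd, bias=True)[0, 1] / vx)


@dataclass
class BootstrapResult:
    """Paired bootstrap comparison of one metric between two pipelines."""

    mean_difference: float
    observed_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    p_adjusted: float
    n_boot: int
    n_tests: int


def _metric_fn(metric):
    if callable(metric):
        return metric
    if metric == "reliability":
        return lambda e, y, r2: reliability(e, y, r2)
    if metric == "bias":
        return lambda e, y, r2: bias_regression(e, y)
    raise ValueError(f"unknown metric {metric!r}")


def bootstrap_compare(ebv_a, ebv_b, yd, r2_yd=None, metric="reliability",
                      n_boot=10000, n_tests=1, seed=0) -> BootstrapResult:
    """Paired bootstrap over validation animals.

    Resamples animals with replacement, recomputes the metric difference
    (pipeline A minus pipeline B) per replicate, and reports a two-sided
    percentile p-value 2 * min(P(diff <= 0), P(diff >= 0)) with continuity
    correction 1 / (n_boot + 1), Bonferroni-adjusted over ``n_tests``.
    Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot < 100 is too unstable; refuse")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    ebv_a = np.asarray(ebv_a, dtype=np.float64)
    ebv_b = np.asarray(ebv_b, dtype=np.float64)
    yd = np.asarray(yd, dtype=np.float64)
    n = yd.shape[0]
    if ebv_a.shape[0] != n or ebv_b.shape[0] != n:
        raise ValueError("prediction vectors must be paired with yd")
    r2 = (np.full(n, 1.0) if r2_yd is None
          else np.asarray(r2_yd, dtype=np.float64))
    fn = _metric_fn(metric)
    observed = fn(ebv_a, yd, r2) - fn(ebv_b, yd, r2)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        diffs[b] = fn(ebv_a[idx], yd[idx], r2[idx]) - fn(ebv_b[idx], yd[idx],
                                                         r2[idx])
    p_low = (np.count_nonzero(diffs <= 0) + 1) / (n_boot + 1)
    p_high = (np.count_nonzero(diffs >= 0) + 1) / (n_boot + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return BootstrapResult(float(diffs.mean()), float(observed), float(lo),
                           float(hi), float(p), min(1.0, p * n_tests),
                           n_boot, n_tests)


@dataclass
class ValidationReport:
    """Reliability and bias for one model x SNP set x animal group."""

    group: str
    n_animals: int
    reliability: float
    bias_b: float
    model: str = ""
    snp_set: str = ""


def evaluate_predictions(ebv: pd.Series, yd_table: pd.DataFrame,
                         genotyped_ids, model: str = "",
                         snp_set: str = "") -> list[ValidationReport]:
    """Reliability and bias per animal group (genotyped / non-genotyped).

    ``yd_table`` has columns animal, yd, r2_yd (as from
    :func:`ssblup.mme.compute_yd`), restricted to the validation animals;
    EBV are matched on animal id.
    """
    genotyped_ids = set(np.asarray(genotyped_ids).tolist())
    merged = yd_table.copy()
    merged["ebv"] = ebv.reindex(merged["animal"]).to_numpy()
    if merged["ebv"].isna().any():
        raise ValueError("EBV missing for some validation animals")
    merged["genotyped"] = merged["animal"].isin(genotyped_ids)
    reports = []
    for flag, name in ((True, "genotyped"), (False, "non_genotyped")):
        sub = merged.loc[merged["genotyped"] == flag]
        if len(sub) < 3:
            continue
        reports.append(ValidationReport(
            group=name, n_animals=len(sub),
            reliability=reliability(sub["ebv"], sub["yd"], sub["r2_yd"]),
            bias_b=bias_regression(sub["ebv"], sub["yd"]),
            model=model, snp_set=snp_set))
    return reports
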