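"""Relationship matrices for the single-step GBLUP family.

Builds the pedigree numerator relationship matrix A (with inbreeding, by
the tabular method), its sparse inverse (Henderson's rules with
Mendelian-sampling variances from parental inbreeding), the genotyped
sub-matrix A22, the VanRaden genomic matrix G_m = M D M' / sum(2 p_j q_j)
(optionally SNP-weighted through D), the scale adjustment G_a = beta G_m +
alpha matching the averages of A22, the blend G = (1 - omega) G_a +
omega A22, and the single-step inverse

    H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]

which equals A^-1 everywhere except the genotyped-by-genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit
from scipy.linalg import cho_factor, cho_solve

from .simdata import pedigree_to_indices

__all__ = [
    "QCError",
    "build_A",
    "inbreeding_coefficients",
    "build_A_inverse",
    "subset_A22",
    "build_Gm",
    "adjust_Ga",
    "blend_G",
    "build_Hinv",
    "HInverse",
]

DEFAULT_OMEGA = 0.2  # fraction of genetic variance assigned to the pedigree


class QCError(ValueError):
    """Genotype quality-control failure (e.g. monomorphic SNPs)."""


@njit(cache=True)
def _tabular_A(sire, dam):
    n = sire.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = a
            A[j, i] = a
    return A


def build_A(pedigree: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Tabular-method numerator relationship matrix.

    Returns ``(A, F)`` with ``diag(A) = 1 + F``.  The pedigree must be
    sorted parents-first (checked); animals are ordered as in the frame.
    """
    sire, dam = pedigree_to_indices(pedigree)
    A = _tabular_A(sire, dam)
    return A, np.diag(A) - 1.0


def inbreeding_coefficients(pedigree: pd.DataFrame) -> np.ndarray:
    """Per-animal inbreeding F (tabular method at desk scale)."""
    return build_A(pedigree)[1]


def build_A_inverse(pedigree: pd.DataFrame) -> sp.csr_matrix:
    """Sparse A^-1 assembled directly from Henderson's rules.

    Mendelian-sampling variances use parental inbreeding:
    d = 0.5 - 0.25 (F_s + F_d) with both parents known,
    0.75 - 0.25 F_p with one, 1 with none.
    """
    sire, dam = pedigree_to_indices(pedigree)
    F = inbreeding_coefficients(pedigree)
    n = len(F)
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            mend = 0.5 - 0.25 * (F[s] + F[d])
            members = [(i, 1.0), (s, -0.5), (d, -0.5)]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            mend = 0.75 - 0.25 * F[p]
            members = [(i, 1.0), (p, -0.5)]
        else:
            mend = 1.0
            members = [(i, 1.0)]
        w = 1.0 / mend
        for a, ca in members:
            for b, cb in members:
                rows.append(a)
                cols.append(b)
                vals.append(ca * cb * w)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def subset_A22(A: np.ndarray, genotyped_idx: np.ndarray) -> np.ndarray:
    """A restricted to the genotyped index set."""
    genotyped_idx = np.asarray(genotyped_idx)
    return A[np.ix_(genotyped_idx, genotyped_idx)]


def build_Gm(X: np.ndarray, weights: np.ndarray | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
    """VanRaden genomic relationship matrix G_m = M D M' / sum(2 p q).

    ``X`` holds 0/1/2 dosages (NaN = missing, mean-imputed to 2 p_j before
    centering).  Allele frequencies are always recomputed from the supplied
    matrix, i.e. from all genotyped animals in the model.  ``weights`` is
    the positive per-SNP diagonal of D (identity when None).

    Returns ``(G_m, p)``.
    """
    X = np.asarray(X, dtype=np.float64)
    p = np.nanmean(X, axis=0) / 2.0
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise QCError("monomorphic SNPs present; apply panels.maf_filter first")
    M = np.where(np.isnan(X), 2.0 * p, X) - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    # one code path for both cases so that unit weights reproduce the
    # unweighted matrix bit for bit
    if weights is None:
        w = np.ones(X.shape[1])
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape[0] != X.shape[1] or np.any(w <= 0):
            raise ValueError("weights must be positive, one per SNP")
    G = ((M * w) @ M.T) / denom
    return G, p


def adjust_Ga(Gm: np.ndarray, A22: np.ndarray
              ) -> tuple[np.ndarray, float, float]:
    """Rescale G_m to the A22 scale: G_a = beta G_m + alpha with

        Avg(diag(G_m)) beta + alpha = Avg(diag(A22))
        Avg(G_m) beta + alpha = Avg(A22)
    """
    dg, mg = float(np.mean(np.diag(Gm))), float(np.mean(Gm))
    da, ma = float(np.mean(np.diag(A22))), float(np.mean(A22))
    if abs(dg - mg) < 1e-12:
        raise np.linalg.LinAlgError(
            "degenerate scale adjustment: Avg(diag(G_m)) == Avg(G_m)")
    beta = (da - ma) / (dg - mg)
    alpha = da - beta * dg
    return beta * Gm + alpha, beta, alpha


def blend_G(Ga: np.ndarray, A22: np.ndarray,
            omega_a: float = DEFAULT_OMEGA) -> np.ndarray:
    """G = (1 - omega_a) G_a + omega_a A22; omega_a is the fraction of the
    genetic variance not captured by SNPs (default 0.2)."""
    if not 0.0 <= omega_a <= 1.0:
        raise ValueError("omega_a must be in [0, 1]")
    return (1.0 - omega_a) * Ga + omega_a * A22


@dataclass
class HInverse:
    """Sparse single-step inverse plus its genotyped index set."""

    H_inv: sp.csr_matrix
    genotyped_index: np.ndarray


def _chol_inverse(M: np.ndarray, what: str) -> np.ndarray:
    try:
        c = cho_factor(M, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"{what} is singular; increase omega_a blending or tighten SNP QC"
        ) from exc
    return cho_solve(c, np.eye(M.shape[0]))


def build_Hinv(A_inv: sp.spmatrix, A22: np.ndarray, G: np.ndarray,
               genotyped_idx: np.ndarray) -> HInverse:
    """Single-step inverse: sparse A^-1 plus the genotyped-block correction
    G^-1 - A22^-1."""
    genotyped_idx = np.asarray(genotyped_idx, dtype=np.int64)
    H = sp.lil_matrix(A_inv.tocsr(), copy=True)
    if genotyped_idx.size:
        if A22.shape[0] != genotyped_idx.size or G.shape != A22.shape:
            raise ValueError("G/A22 shape must match the genotyped index set")
        corr = _chol_inverse(G, "G") - _chol_inverse(A22, "A22")
        H[np.ix_(genotyped_idx, genotyped_idx)] = (
            H[np.ix_(genotyped_idx, genotyped_idx)].toarray() + corr)
    return HInverse(H.tocsr(), genotyped_idx)
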