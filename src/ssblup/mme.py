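"""Henderson mixed-model equations for the four prediction models.

One solver covers PBLUP, ssGBLUP, ssWGBLUP and ssFGBLUP: the repeatability
animal model

    y = X beta + Z_a a + Z_pe pe + Z_hys hys + e

with a ~ N(0, K sigma2_a) where K^-1 is either the pedigree inverse A^-1
(PBLUP) or a single-step inverse H^-1 (the genomic variants), pe and hys
identity-covariance random effects, and e ~ N(0, I sigma2_e).  The featured
model carries two uncorrelated genetic components a_54K + a_seq, each with
its own H^-1 and variance; the reported EBV is their per-animal sum.

Variance components are estimated once under PBLUP (EM-REML with
average-information standard errors) and held fixed for the single-step
fits, mirroring the usual evaluation workflow.  Systems are solved by
diagonally preconditioned conjugate gradients, with a dense direct solve
used (and agreeing) at small scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, lapack
from scipy.sparse.linalg import cg
from sklearn.base import BaseEstimator

from .relmat import HInverse, build_A_inverse
from .weights import reliability_of_yd

__all__ = [
    "GeneticComponent",
    "MixedModelBLUP",
    "VarianceEstimates",
    "estimate_vc_pblup",
    "split_variance_fgblup",
    "compute_yd",
    "fit_pblup",
    "fit_single_step",
]


@dataclass
class GeneticComponent:
    """One additive genetic effect: its covariance inverse and level ids."""

    name: str
    K_inv: sp.spmatrix
    animal_ids: np.ndarray
    variance: float


def _dummies(codes: pd.Series, drop_first: bool) -> tuple[sp.csr_matrix, list]:
    levels, inv = np.unique(codes.to_numpy(), return_inverse=True)
    n = len(codes)
    Z = sp.csr_matrix((np.ones(n), (np.arange(n), inv)),
                      shape=(n, len(levels)))
    if drop_first:
        return Z[:, 1:], list(levels[1:])
    return Z, list(levels)


def _incidence(codes, level_ids) -> sp.csr_matrix:
    pos = pd.Index(level_ids).get_indexer(codes)
    if (pos < 0).any():
        raise ValueError("record levels missing from the covariance index")
    n = len(codes)
    return sp.csr_matrix((np.ones(n), (np.arange(n), pos)),
                         shape=(n, len(level_ids)))


class MixedModelBLUP(BaseEstimator):
    """BLUP solutions of the repeatability animal model.

    Parameters
    ----------
    genetic : list of (name, K_inv, animal_ids) triples or
        :class:`GeneticComponent`; variances come from
        ``variance_components[name]``.
    variance_components : dict with one entry per genetic component plus
        ``"pe"``, ``"hys"`` and ``"e"``.
    fixed_effects : factor column names (dummy-coded, first level zeroed).
    use_pe : include the permanent-environment effect (off for
        heifer-type traits with single records).
    trait, hys_col, animal_col : column names in the record frame.
    method : "auto" (dense below ``dense_limit`` equations, else PCG),
        "dense" or "pcg".
    tol, max_iter : PCG relative-residual tolerance and iteration cap.

    Fitted attributes: ``fixed_effects_``, ``ebv_`` (per-animal sum over
    genetic components), ``ebv_components_``, ``pe_``, ``hys_``,
    ``residuals_``, ``fitted_``, ``n_iter_``.
    """

    def __init__(self, genetic, variance_components,
                 fixed_effects=("age_class", "parity"), use_pe=True,
                 trait="y", hys_col="hys", animal_col="animal",
                 method="auto", dense_limit=2000, tol=1e-10, max_iter=20000):
        self.genetic = genetic
        self.variance_components = variance_components
        self.fixed_effects = fixed_effects
        self.use_pe = use_pe
        self.trait = trait
        self.hys_col = hys_col
        self.animal_col = animal_col
        self.method = method
        self.dense_limit = dense_limit
        self.tol = tol
        self.max_iter = max_iter

    def _components(self) -> list[GeneticComponent]:
        comps = []
        for g in self.genetic:
            if isinstance(g, GeneticComponent):
                comps.append(g)
            else:
                name, K_inv, ids = g
                comps.append(GeneticComponent(
                    name, K_inv, np.asarray(ids),
                    float(self.variance_components[name])))
        return comps

    def fit(self, records: pd.DataFrame, y=None):
        vc = self.variance_components
        comps = self._components()
        for c in comps:
            if c.variance <= 0:
                raise ValueError(f"variance of component {c.name!r} must be > 0")
        yv = records[self.trait].to_numpy(dtype=np.float64)
        n = len(records)
        blocks = [sp.csr_matrix(np.ones((n, 1)))]
        names: list[tuple[str, object]] = [("fixed", "intercept")]
        for col in self.fixed_effects:
            Z, levels = _dummies(records[col], drop_first=True)
            blocks.append(Z)
            names += [("fixed", f"{col}:{lv}") for lv in levels]
        n_fixed = sum(b.shape[1] for b in blocks)
        ranges: dict[str, slice] = {}
        start = n_fixed
        lambdas: list[tuple[slice, sp.spmatrix]] = []
        animal_codes = records[self.animal_col].to_numpy()
        for c in comps:
            Z = _incidence(animal_codes, c.animal_ids)
            blocks.append(Z)
            q = Z.shape[1]
            ranges[c.name] = slice(start, start + q)
            K_inv = (c.K_inv.H_inv if isinstance(c.K_inv, HInverse)
                     else c.K_inv)
            lambdas.append((ranges[c.name], sp.csr_matrix(K_inv) / c.variance))
            start += q
        pe_ids = hys_ids = None
        if self.use_pe:
            Zpe, pe_ids = _dummies(records[self.animal_col], drop_first=False)
            blocks.append(Zpe)
            ranges["pe"] = slice(start, start + Zpe.shape[1])
            lambdas.append((ranges["pe"],
                            sp.identity(Zpe.shape[1]) / float(vc["pe"])))
            start += Zpe.shape[1]
        if self.hys_col is not None:
            Zh, hys_ids = _dummies(records[self.hys_col], drop_first=False)
            blocks.append(Zh)
            ranges["hys"] = slice(start, start + Zh.shape[1])
            lambdas.append((ranges["hys"],
                            sp.identity(Zh.shape[1]) / float(vc["hys"])))
            start += Zh.shape[1]
        W = sp.hstack(blocks, format="csr")
        sigma_e = float(vc["e"])
        C = (W.T @ W) / sigma_e
        C = sp.lil_matrix(C)
        for slc, K in lambdas:
            C[slc, slc] = C[slc, slc] + K
        C = C.tocsr()
        rhs = W.T @ yv / sigma_e
        theta, n_iter = self._solve(C, rhs)
        self.n_equations_ = C.shape[0]
        self.n_iter_ = n_iter
        self.fixed_effects_ = pd.Series(theta[:n_fixed],
                                        index=[nm for _, nm in names])
        comp_sol = {}
        for c in comps:
            comp_sol[c.name] = pd.Series(theta[ranges[c.name]],
                                         index=c.animal_ids)
        self.ebv_components_ = pd.DataFrame(comp_sol)
        self.ebv_ = self.ebv_components_.sum(axis=1)
        self.ebv_.name = "ebv"
        self.pe_ = (pd.Series(theta[ranges["pe"]], index=pe_ids)
                    if self.use_pe else None)
        self.hys_ = (pd.Series(theta[ranges["hys"]], index=hys_ids)
                     if self.hys_col is not None else None)
        self.fitted_ = W @ theta
        self.residuals_ = yv - self.fitted_
        self.theta_ = theta
        self._records_animals = animal_codes
        return self

    def _solve(self, C: sp.csr_matrix, rhs: np.ndarray):
        method = self.method
        if method == "auto":
            method = "dense" if C.shape[0] <= self.dense_limit else "pcg"
        if method == "dense":
            Cd = C.toarray()
            try:
                return np.linalg.solve(Cd, rhs), 0
            except np.linalg.LinAlgError:
                warnings.warn("rank-deficient system; using least squares")
                return np.linalg.lstsq(Cd, rhs, rcond=None)[0], 0
        d = C.diagonal()
        d[d == 0] = 1.0
        M = sp.diags(1.0 / d)
        it = [0]

        def cb(_):
            it[0] += 1

        theta, info = cg(C, rhs, rtol=self.tol, maxiter=self.max_iter, M=M,
                         callback=cb)
        if info != 0:
            raise RuntimeError(f"PCG did not converge (info={info})")
        return theta, it[0]


@dataclass
class VarianceEstimates:
    """REML variance components with average-information standard errors."""

    components: dict[str, float]
    standard_errors: dict[str, float] = field(default_factory=dict)
    n_iter: int = 0
    converged: bool = True
    history: list = field(default_factory=list)

    def __getitem__(self, key):
        return self.components[key]

    @property
    def heritability(self) -> float:
        tot = sum(v for k, v in self.components.items() if k != "hys")
        return self.components["a"] / tot

    @property
    def repeatability(self) -> float:
        tot = sum(v for k, v in self.components.items() if k != "hys")
        return (self.components["a"] + self.components.get("pe", 0.0)) / tot


class ConvergenceError(RuntimeError):
    def __init__(self, msg, history):
        super().__init__(msg)
        self.history = history


def estimate_vc_pblup(pedigree: pd.DataFrame, records: pd.DataFrame,
                      fixed_effects=("age_class", "parity"), use_pe=True,
                      use_hys=True, trait="y", animal_col="animal",
                      hys_col="hys", A_inv: sp.spmatrix | None = None,
                      tol=1e-6, max_iter=500, init=None) -> VarianceEstimates:
    """EM-REML for the PBLUP repeatability model.

    Iterates sigma2_u = (u' K^-1 u + tr(K^-1 C^uu)) / q for each random
    effect and sigma2_e = (y'y - theta' W'y) / (n - rank(X)), where C^uu is
    the corresponding block of the inverse coefficient matrix, until the
    largest relative change drops below ``tol``.  Aitken extrapolation is
    applied every third round to accelerate the EM path.  Standard errors
    come from the average-information matrix at convergence.
    """
    if A_inv is None:
        A_inv = build_A_inverse(pedigree)
    animal_ids = pedigree[animal_col].to_numpy()
    yv = records[trait].to_numpy(dtype=np.float64)
    n = len(records)
    blocks = [sp.csr_matrix(np.ones((n, 1)))]
    for col in fixed_effects:
        Z, _ = _dummies(records[col], drop_first=True)
        blocks.append(Z)
    n_fixed = sum(b.shape[1] for b in blocks)
    Za = _incidence(records[animal_col].to_numpy(), animal_ids)
    blocks.append(Za)
    rand: list[tuple[str, sp.spmatrix, slice]] = []
    start = n_fixed
    qa = Za.shape[1]
    rand.append(("a", sp.csr_matrix(A_inv), slice(start, start + qa)))
    start += qa
    if use_pe:
        Zpe, _ = _dummies(records[animal_col], drop_first=False)
        blocks.append(Zpe)
        rand.append(("pe", sp.identity(Zpe.shape[1], format="csr"),
                     slice(start, start + Zpe.shape[1])))
        start += Zpe.shape[1]
    if use_hys:
        Zh, _ = _dummies(records[hys_col], drop_first=False)
        blocks.append(Zh)
        rand.append(("hys", sp.identity(Zh.shape[1], format="csr"),
                     slice(start, start + Zh.shape[1])))
        start += Zh.shape[1]
    W = sp.hstack(blocks, format="csr")
    WtW_d = (W.T @ W).toarray()
    Wty = W.T @ yv
    yty = float(yv @ yv)
    vy = float(np.var(yv))
    names = [nm for nm, _, _ in rand] + ["e"]
    K_dense = {nm: K.toarray() for nm, K, _ in rand}
    n_eq = WtW_d.shape[0]
    if init is None:
        k = len(rand)
        theta_v = {nm: 0.5 * vy / k for nm in names[:-1]}
        theta_v["e"] = 0.5 * vy
    else:
        theta_v = dict(init)
    floor = 1e-8 * vy

    def _inverse_and_solutions(tv):
        C = WtW_d / tv["e"]
        for nm, _, slc in rand:
            C[slc, slc] += K_dense[nm] / tv[nm]
        cf, info = lapack.dpotrf(C, lower=1, overwrite_a=1)
        if info != 0:
            raise np.linalg.LinAlgError(
                "MME coefficient matrix is not positive definite (check "
                "fixed-effect coding for hidden collinearity)")
        Cinv, info = lapack.dpotri(cf, lower=1, overwrite_c=1)
        Cinv = np.tril(Cinv) + np.tril(Cinv, -1).T
        theta = Cinv @ Wty / tv["e"]
        return Cinv, theta

    def _score_and_ai(tv, Cinv, theta):
        """REML gradient and average-information matrix.

        Uses the MME-inverse trace identities
        tr(P Z_u K_u Z_u') = (q_u - tr(K_u^-1 C^uu)/s_u)/s_u and the BLUP
        identity Z_u' P y = K_u^-1 u / s_u, so no dense K is required
        beyond what the EM step already touches.
        """
        Py = (yv - W @ theta) / tv["e"]
        trs, quads, vs = {}, {}, {}
        for nm, _, slc in rand:
            u = theta[slc]
            trK = float(np.sum(K_dense[nm] * Cinv[slc, slc]))
            q = K_dense[nm].shape[0]
            trs[nm] = (q - trK / tv[nm]) / tv[nm]
            quads[nm] = float(u @ (K_dense[nm] @ u))
            vs[nm] = (W[:, slc] @ u) / tv[nm]
        tr_sum = sum(tv[nm] * trs[nm] for nm in trs)
        trs["e"] = (n - n_fixed - tr_sum) / tv["e"]
        quads["e"] = None
        vs["e"] = Py
        score = np.empty(len(names))
        for i, nm in enumerate(names):
            ypgy = (float(Py @ Py) if nm == "e"
                    else quads[nm] / tv[nm] ** 2)
            score[i] = -0.5 * (trs[nm] - ypgy)
        PG = []
        for nm in names:
            v = vs[nm]
            PG.append((v - W @ (Cinv @ (W.T @ v / tv["e"]))) / tv["e"])
        AI = np.empty((len(names), len(names)))
        for i in range(len(names)):
            for j in range(i, len(names)):
                AI[i, j] = AI[j, i] = 0.5 * float(vs[names[i]] @ PG[j])
        return score, AI

    history = [dict(theta_v)]
    converged = False
    rel = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        try:
            Cinv, theta = _inverse_and_solutions(theta_v)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular MME at round {it}", history) from exc
        new = {}
        for nm, _, slc in rand:
            u = theta[slc]
            quad = float(u @ (K_dense[nm] @ u))
            tr = float(np.sum(K_dense[nm] * Cinv[slc, slc]))
            new[nm] = max((quad + tr) / K_dense[nm].shape[0], floor)
        new["e"] = max((yty - float(theta @ Wty)) / (n - n_fixed), floor)
        em_rel = max(abs(new[nm] - theta_v[nm]) / max(theta_v[nm], floor)
                     for nm in names)
        # Newton step on the average information once EM is in the basin;
        # same fixed point, far fewer rounds to the 1e-6 criterion
        if it >= 3 and em_rel < 0.5:
            score, AI = _score_and_ai(theta_v, Cinv, theta)
            try:
                step = np.linalg.solve(AI, score)
                cand = {nm: float(theta_v[nm] + step[i])
                        for i, nm in enumerate(names)}
                if all(np.isfinite(v) and v > floor for v in cand.values()):
                    new = cand
            except np.linalg.LinAlgError:
                pass
        rel = max(abs(new[nm] - theta_v[nm]) / max(theta_v[nm], floor)
                  for nm in names)
        theta_v = new
        history.append(dict(theta_v))
        if rel < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"EM-REML did not converge in {max_iter} rounds "
            f"(last relative change {rel:.2e})", history)
    Cinv, theta = _inverse_and_solutions(theta_v)
    _, AI = _score_and_ai(theta_v, Cinv, theta)
    try:
        cov = np.linalg.inv(AI)
        ses = {nm: float(np.sqrt(max(cov[i, i], 0.0)))
               for i, nm in enumerate(names)}
    except np.linalg.LinAlgError:
        ses = {}
    return VarianceEstimates(theta_v, ses, it, converged, history)


def split_variance_fgblup(y: np.ndarray, G_54K: np.ndarray, G_seq: np.ndarray,
                          total_va: float | None = None, tol=1e-6,
                          max_iter=500) -> tuple[float, float, VarianceEstimates]:
    """Two-component genomic REML on genotyped animals.

    Fits y = 1 mu + g_54K + g_seq + e with g_c ~ N(0, G_c sigma2_c) and no
    covariance between the components, by EM-REML, and returns the
    proportions of additive variance carried by each component (summing to
    1).  ``total_va`` from the pedigree model, when given, is split by the
    proportions — the study-design approximation for the featured
    single-step fit.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.shape[0]
    mats = {"g54k": np.asarray(G_54K, dtype=np.float64),
            "gseq": np.asarray(G_seq, dtype=np.float64)}
    if np.allclose(mats["g54k"], mats["gseq"]):
        warnings.warn("identical component matrices: split is non-identifiable")
    Kinv = {}
    for nm, G in mats.items():
        ridge = 1e-8 * float(np.mean(np.diag(G)))
        Kinv[nm] = np.linalg.inv(G + ridge * np.eye(n))
    X = np.ones((n, 1))
    vy = float(np.var(y))
    theta_v = {"g54k": vy / 4, "gseq": vy / 4, "e": vy / 2}
    floor = 1e-10 * vy
    n_eq = 1 + 2 * n
    W = np.hstack([X, np.eye(n), np.eye(n)])
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    history = [dict(theta_v)]
    converged = False
    for it in range(1, max_iter + 1):
        C = WtW / theta_v["e"]
        C[1:1 + n, 1:1 + n] += Kinv["g54k"] / theta_v["g54k"]
        C[1 + n:, 1 + n:] += Kinv["gseq"] / theta_v["gseq"]
        Cinv = cho_solve(cho_factor(C, lower=True), np.eye(n_eq))
        theta = Cinv @ Wty / theta_v["e"]
        new = {}
        for nm, sl in (("g54k", slice(1, 1 + n)), ("gseq", slice(1 + n, n_eq))):
            u = theta[sl]
            quad = float(u @ Kinv[nm] @ u)
            tr = float(np.sum(Kinv[nm] * Cinv[sl, sl].T))
            new[nm] = max((quad + tr) / n, floor)
        new["e"] = max((yty - float(theta @ Wty)) / (n - 1), floor)
        rel = max(abs(new[k] - theta_v[k]) / max(theta_v[k], floor)
                  for k in theta_v)
        # geometric extrapolation every third round when the step sizes
        # decay monotonically; plain EM crawls near a variance boundary
        if it % 3 == 0 and len(history) >= 2:
            v0, v1 = history[-2], history[-1]
            acc = {}
            for k in new:
                d0, d1 = v1[k] - v0[k], new[k] - v1[k]
                acc[k] = new[k]
                if d0 != 0.0:
                    r = d1 / d0
                    if 0.0 < r < 1.0:
                        cand = new[k] + d1 * r / (1.0 - r)
                        if np.isfinite(cand) and cand > floor:
                            acc[k] = cand
            new = acc
        theta_v = new
        history.append(dict(theta_v))
        if rel < tol:
            converged = True
            break
    va = theta_v["g54k"] + theta_v["gseq"]
    p54k = theta_v["g54k"] / va
    est = VarianceEstimates(theta_v, {}, it, converged, history)
    return p54k, 1.0 - p54k, est


def compute_yd(fit: MixedModelBLUP, records: pd.DataFrame,
               variance_components=None) -> pd.DataFrame:
    """Yield deviations from a fitted model on all phenotypes.

    Per record, YD = EBV + estimated residual (the phenotype adjusted for
    every effect in the model other than the additive genetic one); the
    per-animal YD is the mean over that animal's records.  Reliabilities
    r2_YD use the repeatability-model formula with h2 and repeatability
    derived from the variance components (contemporary-group variance
    excluded, since YD is adjusted for it).

    Returns columns animal, yd, n_records, r2_yd.
    """
    vc = variance_components or fit.variance_components
    animals = fit._records_animals
    yd_rec = fit.ebv_.reindex(animals).to_numpy() + fit.residuals_
    df = pd.DataFrame({"animal": animals, "yd": yd_rec})
    out = df.groupby("animal", sort=True).agg(yd=("yd", "mean"),
                                              n_records=("yd", "size"))
    va, vpe, ve = float(vc["a"]), float(vc.get("pe", 0.0)), float(vc["e"])
    tot = va + vpe + ve
    h2, rep = va / tot, (va + vpe) / tot
    out["r2_yd"] = reliability_of_yd(out["n_records"].to_numpy(), h2, rep)
    return out.reset_index()


def fit_pblup(pedigree: pd.DataFrame, records: pd.DataFrame,
              variance_components, A_inv=None, **kwargs) -> MixedModelBLUP:
    """PBLUP: the animal model with the pedigree inverse as covariance."""
    if A_inv is None:
        A_inv = build_A_inverse(pedigree)
    model = MixedModelBLUP(
        genetic=[("a", A_inv, pedigree["animal"].to_numpy())],
        variance_components=variance_components, **kwargs)
    return model.fit(records)


def fit_single_step(pedigree: pd.DataFrame, records: pd.DataFrame,
                    h_inv: HInverse | sp.spmatrix, variance_components,
                    h_inv_seq=None, **kwargs) -> MixedModelBLUP:
    """ssGBLUP / ssWGBLUP (one H^-1) or ssFGBLUP (two H^-1 components).

    For the featured model pass ``h_inv_seq`` and variance components
    ``a`` (chip component) and ``a_seq``.
    """
    ids = pedigree["animal"].to_numpy()
    genetic = [("a", h_inv, ids)]
    if h_inv_seq is not None:
        genetic.append(("a_seq", h_inv_seq, ids))
    model = MixedModelBLUP(genetic=genetic,
                           variance_components=variance_components, **kwargs)
    return model.fit(records)
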