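"""Genetic relationship matrices, REML variance components and the
liability-scale transform.

The GRM follows the standard allele-frequency-standardised form: for
individuals j, k and SNPs i with frequency p_i,

    A_jk = (1/m_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i q_i)   (j != k)
    A_jj = 1 + (1/m_j) * sum_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i q_i)

with pairwise-complete SNP counts m_jk under missingness.  Variance
components for y = Xb + sum_r g_r + e, g_r ~ N(0, A_r sigma_r^2), are
estimated by average-information REML with EM fallback steps and
non-negativity constraints; heritability on the observed 0-1 scale is
rescaled to the liability scale via h_l^2 = h_o^2 K(1-K)/z^2 where K is the
disease prevalence and z the standard normal density at the threshold
t = Phi^{-1}(1-K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from autozyg.genotype_io import MISSING, GenotypeDataset
from autozyg.inbreeding import allele_frequencies

__all__ = ["GRM", "compute_grm", "grm_pca", "reml_fit", "liability_transform",
           "VarianceComponents"]


@dataclass
class GRM:
    """Symmetric relatedness matrix with its sample ids and SNP count."""

    sample_ids: list[str]
    matrix: np.ndarray = field(repr=False)
    m: int = 0

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def compute_grm(dataset: GenotypeDataset, variant_subset=None) -> GRM:
    """Allele-frequency-standardised GRM (monomorphic SNPs excluded).

    ``variant_subset`` is an optional boolean mask or integer index over
    variants (e.g. one chromosome).  Missing genotypes contribute zero and
    each pair is normalised by its pairwise-complete SNP count.
    """
    if dataset.n_samples < 2:
        raise ValueError("need at least 2 samples")
    calls = dataset.calls
    if variant_subset is not None:
        calls = calls[:, variant_subset]
    nonmiss = calls != MISSING
    with np.errstate(invalid="ignore"):
        p = np.where(nonmiss.sum(axis=0) > 0,
                     np.where(nonmiss, calls, 0).sum(axis=0)
                     / (2.0 * np.maximum(nonmiss.sum(axis=0), 1)), np.nan)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs monomorphic; GRM undefined")
    calls = calls[:, poly]
    nonmiss = nonmiss[:, poly]
    p = p[poly]
    q = 1.0 - p
    scale = np.sqrt(2.0 * p * q)

    x = np.where(nonmiss, calls, 0).astype(float)
    w = np.where(nonmiss, (x - 2.0 * p) / scale, 0.0)
    pair_m = nonmiss.astype(float) @ nonmiss.astype(float).T
    a = (w @ w.T) / np.maximum(pair_m, 1.0)

    # diagonal: 1 + F3 with the shared frequency estimates
    t3 = (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / (2.0 * p * q)
    m_j = np.maximum(nonmiss.sum(axis=1), 1)
    np.fill_diagonal(a, 1.0 + np.where(nonmiss, t3, 0.0).sum(axis=1) / m_j)
    return GRM(sample_ids=list(dataset.samples["id"]), matrix=a, m=int(poly.sum()))


def grm_pca(grm: GRM, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenvectors/eigenvalues of the GRM.

    Vectors are unit-norm with a deterministic sign (largest-magnitude
    loading positive).  Returns ``(vectors (n, k), values (k,))``.
    """
    a = grm.matrix
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("GRM must be symmetric")
    if k >= a.shape[0]:
        raise ValueError("k must be smaller than the number of samples")
    vals, vecs = np.linalg.eigh(a)
    order = np.argsort(vals)[::-1][:k]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        lead = np.argmax(np.abs(vecs[:, j]))
        if vecs[lead, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs, vals


@dataclass
class VarianceComponents:
    """REML variance components and derived heritabilities."""

    sigma_g2: np.ndarray          # one per GRM
    sigma_e2: float
    h2_obs: float
    se_h2: float
    loglik: float
    converged: bool
    n_iter: int
    h2_liab: float | None = None
    trajectory: list = field(default_factory=list, repr=False)

    @property
    def total_variance(self) -> float:
        return float(np.sum(self.sigma_g2) + self.sigma_e2)


def _reml_loglik(theta, grms, y, X):
    n = y.size
    V = theta[-1] * np.eye(n)
    for t, A in zip(theta[:-1], grms):
        V += t * A
    cho = np.linalg.cholesky(V)
    Vi = np.linalg.inv(V)
    logdet_v = 2.0 * np.sum(np.log(np.diag(cho)))
    XtVi = X.T @ Vi
    XtViX = XtVi @ X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    P = Vi - XtVi.T @ np.linalg.solve(XtViX, XtVi)
    Py = P @ y
    ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
    return ll, P, Py


def reml_fit(y, X, grms, max_iter: int = 100, tol: float = 1e-8,
             constrain: bool = True) -> VarianceComponents:
    """Average-information REML with EM fallback.

    ``grms`` is a single :class:`GRM`/matrix or a list of them.  ``y`` is
    the phenotype on the observed scale (a 0/1 vector is treated as
    quantitative); ``X`` the fixed-effect design (an intercept is added if
    absent).  Components are constrained to a small positive floor when
    ``constrain``; convergence is declared when the log-likelihood change
    falls below ``tol``.  The SE of h2 comes from the inverse AI matrix by
    the delta method.
    """
    if not isinstance(grms, (list, tuple)):
        grms = [grms]
    mats = [g.matrix if isinstance(g, GRM) else np.asarray(g, float) for g in grms]
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.allclose(X[:, 0], 1.0) and not np.any(np.all(X == 1.0, axis=0)):
        X = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is singular")

    k = len(mats)
    vary = float(np.var(y, ddof=1))
    floor = 1e-6 * vary
    theta = np.full(k + 1, vary / (k + 1))
    ll, P, Py = _reml_loglik(theta, mats, y, X)
    trajectory = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        comps = mats + [np.eye(n)]
        PA = [P @ A for A in mats] + [P]
        grad = np.array([
            -0.5 * (np.trace(PA_i) - float(Py @ (A @ Py)))
            for PA_i, A in zip(PA, comps)
        ])
        APy = [A @ Py for A in comps]
        AI = 0.5 * np.array([[float(APy[i] @ (P @ APy[j])) for j in range(k + 1)]
                             for i in range(k + 1)])
        step_kind = "ai" if it > 1 else "em"
        new_theta = None
        if step_kind == "ai":
            try:
                delta = np.linalg.solve(AI, grad)
                new_theta = theta + delta
            except np.linalg.LinAlgError:
                step_kind = "em"
        if step_kind == "em" or new_theta is None or (
                constrain and np.any(new_theta < 0) and step_kind == "ai"
                and np.any(new_theta < -0.1 * vary)):
            new_theta = np.array([
                t + (t * t / n) * (float(Py @ A_Py) - np.trace(PA_i))
                for t, A_Py, PA_i in zip(theta, APy, PA)
            ])
            step_kind = "em"
        if constrain:
            new_theta = np.maximum(new_theta, floor)
        try:
            new_ll, new_P, new_Py = _reml_loglik(new_theta, mats, y, X)
        except np.linalg.LinAlgError:
            new_ll = -np.inf
        if not np.isfinite(new_ll) or (new_ll < ll - 1e-10 and step_kind == "ai"):
            # AI overshoot: fall back to a guaranteed-ascent EM step
            new_theta = np.array([
                t + (t * t / n) * (float(Py @ A_Py) - np.trace(PA_i))
                for t, A_Py, PA_i in zip(theta, APy, PA)
            ])
            if constrain:
                new_theta = np.maximum(new_theta, floor)
            new_ll, new_P, new_Py = _reml_loglik(new_theta, mats, y, X)
        delta_ll = new_ll - ll
        theta, ll, P, Py = new_theta, new_ll, new_P, new_Py
        trajectory.append(ll)
        if abs(delta_ll) < tol:
            converged = True
            break

    # SE of h2 via the delta method on the final AI matrix
    comps = mats + [np.eye(n)]
    APy = [A @ Py for A in comps]
    AI = 0.5 * np.array([[float(APy[i] @ (P @ APy[j])) for j in range(k + 1)]
                         for i in range(k + 1)])
    total = float(theta.sum())
    G = float(theta[:-1].sum())
    grad_h = np.empty(k + 1)
    grad_h[:-1] = (total - G) / total**2
    grad_h[-1] = -G / total**2
    try:
        cov = np.linalg.inv(AI)
        se_h2 = float(np.sqrt(max(grad_h @ cov @ grad_h, 0.0)))
    except np.linalg.LinAlgError:
        se_h2 = float("nan")
    return VarianceComponents(
        sigma_g2=theta[:-1].copy(),
        sigma_e2=float(theta[-1]),
        h2_obs=G / total,
        se_h2=se_h2,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        trajectory=trajectory,
    )


def liability_transform(h2_obs: float, K: float,
                        ascertained_proportion: float | None = None) -> float:
    """Observed-scale to liability-scale heritability.

    ``h_l^2 = h_obs^2-scale * K(1-K)/z^2`` with ``z`` the standard normal
    density at the liability threshold ``t = Phi^{-1}(1-K)``.  When
    ``ascertained_proportion`` (the case fraction P of an ascertained
    case-control sample) is given, the additional factor
    ``K(1-K)/(P(1-P))`` corrects for ascertainment.
    """
    if not 0 < K < 1:
        raise ValueError("prevalence K must lie in (0, 1)")
    if h2_obs < 0:
        raise ValueError("h2_obs must be non-negative")
    t = sps.norm.ppf(1.0 - K)
    z = sps.norm.pdf(t)
    mult = K * (1.0 - K) / (z * z)
    if ascertained_proportion is not None:
        P = ascertained_proportion
        if not 0 < P < 1:
            raise ValueError("ascertained_proportion must lie in (0, 1)")
        mult *= K * (1.0 - K) / (P * (1.0 - P))
    return h2_obs * mult
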