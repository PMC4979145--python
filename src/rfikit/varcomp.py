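"""Relationship matrices and REML variance components.

The animal model is ``y = Xb + Za + e`` with ``a ~ N(0, K*sigma_a2)`` and
``e ~ N(0, I*sigma_e2)``, where K is either a genomic (VanRaden
frequency-weighted) kinship or a pedigree numerator relationship matrix.
Because K appears only through its eigendecomposition, both the
univariate and the bivariate REML likelihoods factor into independent
per-eigenvalue terms after rotating the data by the eigenvectors; the
univariate problem then reduces to a one-dimensional search over the
variance ratio, and the bivariate one to an optimization over two 2x2
covariance blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "KinshipMatrix",
    "VarCompResult",
    "BivarResult",
    "genomic_kinship",
    "pedigree_nrm",
    "reml_univariate",
    "reml_bivariate",
    "blup_ebv",
]

RIDGE = 1e-8  # added to K before eigendecomposition for numerical PSD-ness


@dataclass
class KinshipMatrix:
    """Symmetric relatedness matrix with individual identifiers."""

    ids: list[str]
    phi: np.ndarray

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        if phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
            raise ValueError("phi must be square")
        if phi.shape[0] != len(self.ids):
            raise ValueError("ids and phi dimensions disagree")
        if not np.allclose(phi, phi.T, atol=1e-12):
            raise ValueError("phi must be symmetric")
        self.phi = phi

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.phi, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=[str(c) for c in df.columns], phi=df.to_numpy(dtype=float))


@dataclass
class VarCompResult:
    sigma_a2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float
    converged: bool


@dataclass
class BivarResult:
    g_cov: np.ndarray
    r_cov: np.ndarray
    r_g: float
    se_rg: float
    loglik: float
    converged: bool


def genomic_kinship(G) -> KinshipMatrix:
    """VanRaden frequency-weighted genomic relationship matrix.

    ``Phi_ij = (1/m) * sum_k (g_ik - 2 p_k)(g_jk - 2 p_k) / (2 p_k (1 - p_k))``.
    Missing dosages are mean-imputed per SNP.  Monomorphic SNPs must be
    removed beforehand (QC); their presence raises an error.
    """
    dosage = np.array(G.dosage, dtype=float)
    p = np.nanmean(dosage, axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)) or np.any(~np.isfinite(p)):
        raise ValueError("monomorphic or all-missing SNP present; run QC first")
    # mean-impute missing calls
    nan_mask = np.isnan(dosage)
    if nan_mask.any():
        dosage[nan_mask] = (2.0 * p)[np.where(nan_mask)[1]]
    W = (dosage - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    phi = (W @ W.T) / W.shape[1]
    phi = (phi + phi.T) / 2.0
    return KinshipMatrix(ids=list(G.samples), phi=phi)


def pedigree_nrm(pedigree: pd.DataFrame) -> KinshipMatrix:
    """Additive (numerator) relationship matrix by the tabular method.

    ``pedigree`` columns: id, sire, dam (missing parents as NaN/None/"0").
    The pedigree is topologically sorted internally; a cycle or a parent
    id absent from the id column raises an error.
    """

    def _norm(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) in ("0", "", "nan"):
            return None
        return str(v)

    ids = [str(i) for i in pedigree["id"]]
    sires = [_norm(s) for s in pedigree["sire"]]
    dams = [_norm(d) for d in pedigree["dam"]]
    known = set(ids)
    for parent in sires + dams:
        if parent is not None and parent not in known:
            raise ValueError(f"unknown parent id: {parent}")

    parents = {i: (s, d) for i, s, d in zip(ids, sires, dams)}
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(node: str) -> None:
        if state.get(node) == 2:
            return
        if state.get(node) == 1:
            raise ValueError("pedigree contains a cycle")
        state[node] = 1
        for par in parents[node]:
            if par is not None:
                visit(par)
        state[node] = 2
        order.append(node)

    for i in ids:
        visit(i)

    idx = {v: k for k, v in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, ind in enumerate(order):
        s, d = parents[ind]
        si = idx[s] if s is not None else None
        di = idx[d] if d is not None else None
        for j in range(i):
            a = 0.0
            if si is not None:
                a += 0.5 * A[si, j]
            if di is not None:
                a += 0.5 * A[di, j]
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    # return in the input id order
    perm = [idx[i] for i in ids]
    return KinshipMatrix(ids=ids, phi=A[np.ix_(perm, perm)])


def _eigen(K: KinshipMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    phi = K.phi if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    d, U = np.linalg.eigh(phi + RIDGE * np.eye(phi.shape[0]))
    return np.clip(d, 0.0, None), U


def _reml_neg_loglik_ratio(t: float, yt, Xt, d) -> float:
    """Negative REML log-likelihood profiled over the total scale.

    ``t`` is log(sigma_a2/sigma_e2); with w = 1/(gamma*d + 1) the GLS fit
    of the rotated data yields the profiled residual variance in closed
    form.
    """
    gamma = np.exp(t)
    n, p = Xt.shape
    w = 1.0 / (gamma * d + 1.0)
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yt)
    r = yt - Xt @ beta
    sse = float(np.sum(w * r * r))
    sigma_e2 = sse / (n - p)
    _, logdet_xwx = np.linalg.slogdet(XtWX)
    return 0.5 * (
        (n - p) * np.log(sigma_e2) - np.sum(np.log(w)) + logdet_xwx + (n - p)
    )


def _reml_loglik_full(sigma_a2: float, sigma_e2: float, yt, Xt, d) -> float:
    """Unprofiled REML log-likelihood (used for curvature/SEs)."""
    v = sigma_a2 * d + sigma_e2
    if np.any(v <= 0):
        return -np.inf
    w = 1.0 / v
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yt)
    r = yt - Xt @ beta
    _, logdet_xwx = np.linalg.slogdet(XtWX)
    return -0.5 * (np.sum(np.log(v)) + logdet_xwx + float(np.sum(w * r * r)))


def reml_univariate(
    y: np.ndarray,
    X: np.ndarray | None,
    K: KinshipMatrix | np.ndarray,
    eigen: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarCompResult:
    """Two-component REML via eigendecomposition of the kinship.

    ``X`` defaults to an intercept.  The search is one-dimensional over
    the log variance ratio; the SE of h2 comes from the observed
    information (numeric Hessian of the unprofiled likelihood) and the
    delta method.  Boundary solutions are reported at h2 ~ 0 or ~ 1 with
    ``converged=True``; optimizer failure sets ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 30:
        warnings.warn("REML on fewer than 30 individuals is unreliable", stacklevel=2)
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    d, U = eigen if eigen is not None else _eigen(K)
    yt = U.T @ y
    Xt = U.T @ X

    bounds = (-15.0, 15.0)
    res = optimize.minimize_scalar(
        _reml_neg_loglik_ratio,
        bounds=bounds,
        args=(yt, Xt, d),
        method="bounded",
        options={"xatol": 1e-10},
    )
    t_hat = float(res.x)
    # guard against an interior local flat spot losing to the boundaries
    for t_edge in bounds:
        if _reml_neg_loglik_ratio(t_edge, yt, Xt, d) < res.fun:
            t_hat = t_edge
    gamma = np.exp(t_hat)
    p = Xt.shape[1]
    w = 1.0 / (gamma * d + 1.0)
    Xw = Xt * w[:, None]
    beta = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
    r = yt - Xt @ beta
    sigma_e2 = float(np.sum(w * r * r)) / (n - p)
    sigma_a2 = gamma * sigma_e2
    h2 = sigma_a2 / (sigma_a2 + sigma_e2)
    loglik = _reml_loglik_full(sigma_a2, sigma_e2, yt, Xt, d)

    se_h2 = float("nan")
    try:
        h = 1e-4 * (sigma_a2 + sigma_e2)
        pts = {}
        for i, j in [(0, 0), (0, 1), (1, 1)]:
            def f(da, de):
                return _reml_loglik_full(sigma_a2 + da, sigma_e2 + de, yt, Xt, d)
            if i == j:
                step = (h, 0.0) if i == 0 else (0.0, h)
                pts[(i, j)] = (f(*step) - 2 * loglik + f(-step[0], -step[1])) / h**2
            else:
                pts[(i, j)] = (
                    f(h, h) - f(h, -h) - f(-h, h) + f(-h, -h)
                ) / (4 * h**2)
        H = np.array([[pts[(0, 0)], pts[(0, 1)]], [pts[(0, 1)], pts[(1, 1)]]])
        cov = np.linalg.inv(-H)
        tot = sigma_a2 + sigma_e2
        grad = np.array([sigma_e2 / tot**2, -sigma_a2 / tot**2])
        var_h2 = float(grad @ cov @ grad)
        if var_h2 > 0:
            se_h2 = float(np.sqrt(var_h2))
    except (np.linalg.LinAlgError, FloatingPointError):
        pass

    return VarCompResult(
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        h2=float(h2),
        se_h2=se_h2,
        loglik=float(loglik),
        converged=bool(res.success),
    )


def blup_ebv(
    y: np.ndarray, X: np.ndarray | None, K: KinshipMatrix | np.ndarray, fit: VarCompResult
) -> np.ndarray:
    """BLUP breeding values under fitted variance components.

    ``u_hat = sigma_a2 * Phi * V^{-1} * (y - X beta_GLS)`` with
    ``V = sigma_a2 Phi + sigma_e2 I``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    phi = K.phi if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    V = fit.sigma_a2 * phi + fit.sigma_e2 * np.eye(n)
    Vinv_y = np.linalg.solve(V, y)
    Vinv_X = np.linalg.solve(V, X)
    beta = np.linalg.solve(X.T @ Vinv_X, X.T @ Vinv_y)
    resid = y - X @ beta
    return fit.sigma_a2 * (phi @ np.linalg.solve(V, resid))


def _chol_from_params(p3: np.ndarray) -> np.ndarray:
    L = np.array([[np.exp(p3[0]), 0.0], [p3[1], np.exp(p3[2])]])
    return L @ L.T


def _bivar_neg_loglik(params: np.ndarray, y1t, y2t, Xt, d) -> float:
    G = _chol_from_params(params[:3])
    R = _chol_from_params(params[3:])
    v11 = G[0, 0] * d + R[0, 0]
    v12 = G[0, 1] * d + R[0, 1]
    v22 = G[1, 1] * d + R[1, 1]
    det = v11 * v22 - v12 * v12
    if np.any(det <= 0) or np.any(v11 <= 0) or np.any(v22 <= 0):
        return np.inf
    i11, i12, i22 = v22 / det, -v12 / det, v11 / det

    p = Xt.shape[1]
    # fixed-effect normal equations: 2p x 2p block matrix
    A = np.zeros((2 * p, 2 * p))
    A[:p, :p] = (Xt * i11[:, None]).T @ Xt
    A[:p, p:] = (Xt * i12[:, None]).T @ Xt
    A[p:, :p] = A[:p, p:].T
    A[p:, p:] = (Xt * i22[:, None]).T @ Xt
    b = np.concatenate(
        [Xt.T @ (i11 * y1t + i12 * y2t), Xt.T @ (i12 * y1t + i22 * y2t)]
    )
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf
    r1 = y1t - Xt @ beta[:p]
    r2 = y2t - Xt @ beta[p:]
    quad = float(np.sum(i11 * r1 * r1 + 2 * i12 * r1 * r2 + i22 * r2 * r2))
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    return 0.5 * (float(np.sum(np.log(det))) + logdet_a + quad)


def reml_bivariate(
    y1: np.ndarray,
    y2: np.ndarray,
    X: np.ndarray | None,
    K: KinshipMatrix | np.ndarray,
) -> BivarResult:
    """Bivariate REML exploiting simultaneous diagonalization of K and I.

    After rotating both traits by the eigenvectors of K, the likelihood
    factors into n independent 2x2 blocks ``V_i = G d_i + R``; G and R
    are optimized over log-Cholesky parametrizations (guaranteeing PSD)
    starting from the univariate fits.  ``r_g = g12 / sqrt(g11 g22)``;
    its SE comes from the observed information and the delta method, and
    a near-singular genetic covariance yields a wide SE with a warning.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.shape != y2.shape:
        raise ValueError("both traits must be observed on the same individuals")
    n = y1.size
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    d, U = _eigen(K)
    y1t, y2t, Xt = U.T @ y1, U.T @ y2, U.T @ X

    eig = (d, U)
    uni1 = reml_univariate(y1, X, K, eigen=eig)
    uni2 = reml_univariate(y2, X, K, eigen=eig)

    def _log_chol_start(v1: float, v2: float, cov: float) -> list[float]:
        l11 = np.sqrt(max(v1, 1e-8))
        l21 = cov / l11
        l22 = np.sqrt(max(v2 - l21**2, 1e-8))
        return [np.log(l11), l21, np.log(l22)]

    cov_p = float(np.cov(y1, y2)[0, 1])
    g_cov0 = 0.5 * cov_p * np.sqrt(uni1.h2 * uni2.h2 + 1e-12)
    x0 = np.array(
        _log_chol_start(max(uni1.sigma_a2, 1e-6), max(uni2.sigma_a2, 1e-6), g_cov0)
        + _log_chol_start(max(uni1.sigma_e2, 1e-6), max(uni2.sigma_e2, 1e-6), 0.5 * cov_p)
    )
    res = optimize.minimize(
        _bivar_neg_loglik,
        x0,
        args=(y1t, y2t, Xt, d),
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
    )
    # restart until converged; helps when the optimum sits on the PSD
    # boundary (|r_g| -> 1), which log-Cholesky reaches only asymptotically
    for _ in range(8):
        res2 = optimize.minimize(
            _bivar_neg_loglik,
            res.x,
            args=(y1t, y2t, Xt, d),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
        )
        improved = res.fun - res2.fun
        res = res2
        if improved < 1e-9:
            break
    Gm = _chol_from_params(res.x[:3])
    Rm = _chol_from_params(res.x[3:])
    denom = np.sqrt(Gm[0, 0] * Gm[1, 1])
    r_g = float(Gm[0, 1] / denom) if denom > 0 else float("nan")

    se_rg = float("nan")
    try:
        eps = 1e-4
        k = res.x.size
        H = np.zeros((k, k))
        f0 = res.fun
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = eps
                ej = np.zeros(k); ej[j] = eps
                fpp = _bivar_neg_loglik(res.x + ei + ej, y1t, y2t, Xt, d)
                fpm = _bivar_neg_loglik(res.x + ei - ej, y1t, y2t, Xt, d)
                fmp = _bivar_neg_loglik(res.x - ei + ej, y1t, y2t, Xt, d)
                fmm = _bivar_neg_loglik(res.x - ei - ej, y1t, y2t, Xt, d)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
        cov_par = np.linalg.inv(H)
        grad = np.zeros(k)
        for i in range(k):
            ei = np.zeros(k); ei[i] = eps
            def rg_of(par):
                Gp = _chol_from_params(par[:3])
                dd = np.sqrt(Gp[0, 0] * Gp[1, 1])
                return Gp[0, 1] / dd if dd > 0 else np.nan
            grad[i] = (rg_of(res.x + ei) - rg_of(res.x - ei)) / (2 * eps)
        var_rg = float(grad @ cov_par @ grad)
        if var_rg > 0:
            se_rg = float(np.sqrt(var_rg))
    except (np.linalg.LinAlgError, FloatingPointError):
        pass
    if min(Gm[0, 0], Gm[1, 1]) < 1e-6 * max(np.trace(Gm) + np.trace(Rm), 1e-12):
        warnings.warn("near-singular genetic covariance; r_g is poorly determined", stacklevel=2)
        if not np.isfinite(se_rg):
            se_rg = 1.0

    return BivarResult(
        g_cov=Gm,
        r_cov=Rm,
        r_g=r_g,
        se_rg=se_rg,
        loglik=float(-res.fun),
        converged=bool(res.success),
    )
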