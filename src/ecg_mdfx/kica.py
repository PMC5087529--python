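"""Nonlinear beat features: PCA reduction + kernel ICA projection.

Beats (rows of an n x 250 matrix) are first reduced to 20 principal
components (99.8% cumulative contribution in the intended operating
regime). Kernel independent component analysis (KICA) then searches for
an orthonormal unmixing matrix ``W`` of the whitened scores that
minimizes a kernel canonical-correlation contrast:

    C(W) = -0.5 * log lambda_M

where ``lambda_M`` is the smallest eigenvalue of the generalized
eigenproblem ``K alpha = lambda D alpha`` built from the centered,
ridge-regularized RBF Gram matrices of the estimated sources (pairwise
Gram products off the diagonal, squared regularized Grams on the
diagonal). ``lambda_M`` lies in (0, 1]; it equals 1 exactly when all
kernelized sources are uncorrelated in feature space, so ``C(W) >= 0``
measures residual statistical dependence.

The minimizer is a Jacobi-style coordinate descent: sweeps of Givens
rotations over all source pairs, each pair's angle chosen by a grid
search plus bounded 1-D refinement of the pairwise contrast, with
seeded random restarts. The final base-signal subspace ``S`` maps the
recovered sources back to the 250-sample beat space through the PCA
loadings, and per-beat nonlinear features are the pseudoinverse
projection coefficients ``A = X S^+``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.decomposition import PCA as _SkPCA

logger = logging.getLogger(__name__)

_EPS_LAMBDA = 1e-12  # floor for lambda_M before taking the log


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Retained eigenstructure of the sample covariance of the beats."""

    eigenvalues: np.ndarray          # retained, non-increasing
    eigenvectors: np.ndarray         # (n_components, d), orthonormal rows
    n_components: int
    cumulative_contribution: float   # retained / total variance
    mean_vector: np.ndarray


def pca_fit(
    X, contribution_target: float = 0.998, n_components: int = 20
) -> PCAModel:
    """Eigendecomposition of the sample covariance, keeping ``n_components``.

    The achieved cumulative contribution is recorded and a warning is
    logged when it falls short of ``contribution_target``.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if d < n_components:
        raise ValueError(f"n_components={n_components} exceeds dimension {d}")
    total_var = float(np.var(X, axis=0, ddof=1).sum())
    if total_var == 0.0:
        raise ValueError("degenerate input: all rows identical")
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    if n_components > rank:
        logger.warning("n_components=%d exceeds data rank %d", n_components, rank)
    sk = _SkPCA(n_components=n_components, svd_solver="full")
    sk.fit(X)
    cum = float(sk.explained_variance_ratio_.sum())
    if cum < contribution_target:
        logger.warning(
            "cumulative contribution %.4f below target %.4f", cum, contribution_target
        )
    return PCAModel(
        eigenvalues=sk.explained_variance_.copy(),
        eigenvectors=sk.components_.copy(),
        n_components=n_components,
        cumulative_contribution=cum,
        mean_vector=sk.mean_.copy(),
    )


def pca_transform(X, model: PCAModel) -> np.ndarray:
    """Centered projection onto the retained loadings."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.mean_vector.shape[0]:
        raise ValueError("dimension mismatch with PCA model")
    return (X - model.mean_vector) @ model.eigenvectors.T


# ---------------------------------------------------------------------------
# Kernel machinery
# ---------------------------------------------------------------------------

def rbf_kernel(u, v, kernel_sigma: float) -> float:
    """Gaussian kernel exp(-||u-v||^2 / (2 sigma^2))."""
    if kernel_sigma <= 0:
        raise ValueError("kernel_sigma must be > 0")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("u and v must have equal dimension")
    return float(np.exp(-np.sum((u - v) ** 2) / (2.0 * kernel_sigma**2)))


def centered_gram(component_samples, kernel_sigma: float) -> np.ndarray:
    """Double-centered RBF Gram matrix of a scalar sample sequence."""
    x = np.asarray(component_samples, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    sq = (x[:, None] - x[None, :]) ** 2
    K = np.exp(-sq / (2.0 * kernel_sigma**2))
    row = K.mean(axis=1, keepdims=True)
    col = K.mean(axis=0, keepdims=True)
    return K - row - col + K.mean()


def _component_factor(x, kernel_sigma: float, kap: float, rank_rtol: float = 1e-5):
    """Truncated eigenfactor (U, d) of one regularized centered Gram.

    Returns U (n x m, orthonormal columns) and d_k = lam_k / (lam_k +
    n*kap/2), the spectrum of R = K (K + n*kap/2 I)^{-1} restricted to
    the numerically nonzero eigenspace of K.
    """
    K = centered_gram(x, kernel_sigma)
    n = K.shape[0]
    lam, U = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    keep = lam > rank_rtol * max(lam[-1], _EPS_LAMBDA)
    lam, U = lam[keep], U[:, keep]
    d = lam / (lam + n * kap / 2.0)
    return U, d


def _lambda_min(factors) -> float:
    """Smallest eigenvalue of the reduced dependence matrix.

    With R_i = U_i D_i U_i^T the generalized eigenproblem reduces (after
    the substitution beta_i = (K_i + n*kap/2 I) alpha_i) to the block
    matrix with identity diagonal and off-diagonal blocks R_i R_j; its
    spectrum is {1} on the joint null space plus the spectrum of the
    compressed matrix built from G_i = U_i D_i.
    """
    G = np.hstack([U * d for U, d in factors])
    sizes = [U.shape[1] for U, _ in factors]
    T = G.T @ G
    off = np.cumsum([0] + sizes)
    for i in range(len(sizes)):
        sl = slice(off[i], off[i + 1])
        T[sl, sl] = np.eye(sizes[i])
    lam_min = float(np.linalg.eigvalsh(T)[0])
    return min(lam_min, 1.0)


def kica_contrast(W, Z, kap: float = 0.02, kernel_sigma: float = 1.0) -> float:
    """Kernel dependence contrast C(W) = -0.5 log lambda_M of sources Z W^T."""
    W = np.asarray(W, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    if W.shape != (p, p):
        raise ValueError("W must be p x p")
    if n < p or p < 2:
        raise ValueError("need n >= p >= 2")
    s = Z @ W.T
    factors = [_component_factor(s[:, i], kernel_sigma, kap) for i in range(p)]
    lam_m = max(_lambda_min(factors), _EPS_LAMBDA)
    return -0.5 * float(np.log(lam_m))


# ---------------------------------------------------------------------------
# KICA fit
# ---------------------------------------------------------------------------

@dataclass
class KICAModel:
    """Whitening + unmixing + base-signal subspace of a fitted KICA."""

    mean: np.ndarray            # (d,) training mean of the PCA scores
    whitener: np.ndarray        # (d, p): Z = (X - mean) @ whitener
    W: np.ndarray               # (p, p) orthonormal unmixing matrix
    S: np.ndarray               # (p, d_out) base-signal subspace rows
    kap: float
    kernel_sigma: float
    p: int
    contrast_value: float
    converged: bool = True
    restart_contrasts: list = field(default_factory=list)

    def sources(self, X) -> np.ndarray:
        """Estimated independent components for new PCA-score rows."""
        Z = (np.asarray(X, dtype=float) - self.mean) @ self.whitener
        return Z @ self.W.T


def _pair_contrast(factors, i: int, j: int) -> float:
    return -0.5 * float(np.log(max(_lambda_min([factors[i], factors[j]]),
                                   _EPS_LAMBDA)))


def kica_fit(
    X20,
    p: int | None = None,
    kap: float = 0.02,
    kernel_sigma: float = 1.0,
    seed: int = 0,
    n_restarts: int = 1,
    pca_model: PCAModel | None = None,
    max_sweeps: int = 3,
    contrast_subsample: int = 256,
    angle_grid: int = 9,
    tol: float = 1e-5,
) -> KICAModel:
    """Whiten the scores and minimize the kernel contrast over rotations.

    Parameters
    ----------
    X20 : ndarray (n, d)
        PCA scores (or any data to unmix).
    p : int, optional
        Number of sources; defaults to the data dimension.
    contrast_subsample : int
        Gram matrices are built on a seeded subsample of at most this
        many rows, which bounds the eigenproblem size; rows beyond the
        cap do not change the estimator, only its sample size.
    n_restarts : int
        Orthonormal starting points: identity first, then seeded random
        rotations. The best final contrast wins.
    pca_model : PCAModel, optional
        When given, the base-signal subspace ``S`` is back-projected
        through the PCA loadings into the original beat space.
    """
    X = np.asarray(X20, dtype=float)
    n, d = X.shape
    p = d if p is None else p
    if not 2 <= p <= d:
        raise ValueError("need 2 <= p <= data dimension")
    if n <= p:
        raise ValueError("need more samples than sources")

    rng = np.random.default_rng(seed)
    mean = X.mean(axis=0)
    cov = np.cov(X.T, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:p]
    evals, evecs = evals[order], evecs[:, order]
    if np.any(evals <= 0):
        raise ValueError("covariance not positive on the requested p directions")
    whitener = evecs / np.sqrt(evals)[None, :]
    Z = (X - mean) @ whitener

    sub = rng.permutation(n)[: min(n, contrast_subsample)]
    Zs = Z[sub]

    def factors_for(W):
        s = Zs @ W.T
        return [_component_factor(s[:, k], kernel_sigma, kap) for k in range(p)]

    best_W, best_c, restart_contrasts = None, np.inf, []
    converged = False
    angles = np.linspace(-np.pi / 4, np.pi / 4, angle_grid)
    for r in range(max(1, n_restarts)):
        if r == 0:
            W = np.eye(p)
        else:
            W, _ = np.linalg.qr(rng.normal(size=(p, p)))
        factors = factors_for(W)
        this_converged = False
        for _ in range(max_sweeps):
            sweep_gain = 0.0
            for i in range(p - 1):
                for j in range(i + 1, p):
                    base = _pair_contrast(factors, i, j)

                    def pair_obj(theta, _i=i, _j=j):
                        c, s_ = np.cos(theta), np.sin(theta)
                        si = c * Zs @ W[_i] - s_ * Zs @ W[_j]
                        sj = s_ * Zs @ W[_i] + c * Zs @ W[_j]
                        fi = _component_factor(si, kernel_sigma, kap)
                        fj = _component_factor(sj, kernel_sigma, kap)
                        return _pair_contrast([fi, fj], 0, 1)

                    grid_vals = [pair_obj(t) for t in angles]
                    k0 = int(np.argmin(grid_vals))
                    span = angles[1] - angles[0]
                    res = minimize_scalar(
                        pair_obj,
                        bounds=(angles[k0] - span, angles[k0] + span),
                        method="bounded",
                        options={"xatol": 1e-3, "maxiter": 12},
                    )
                    theta, val = (res.x, res.fun) if res.fun < grid_vals[k0] \
                        else (angles[k0], grid_vals[k0])
                    if val < base - 1e-10 and abs(theta) > 1e-12:
                        c, s_ = np.cos(theta), np.sin(theta)
                        wi = c * W[i] - s_ * W[j]
                        wj = s_ * W[i] + c * W[j]
                        W[i], W[j] = wi, wj
                        factors[i] = _component_factor(
                            Zs @ W[i], kernel_sigma, kap)
                        factors[j] = _component_factor(
                            Zs @ W[j], kernel_sigma, kap)
                        sweep_gain += base - val
            if sweep_gain < tol:
                this_converged = True
                break
        c_final = -0.5 * float(np.log(max(_lambda_min(factors), _EPS_LAMBDA)))
        restart_contrasts.append(c_final)
        if c_final < best_c:
            best_c, best_W, converged = c_final, W.copy(), this_converged
    if not converged:
        logger.warning("KICA optimizer stopped before sweep convergence; "
                       "returning best W found")

    # base-signal subspace: sources a satisfy x_c ~ a @ (W @ pinv(whitener))
    S = best_W @ np.linalg.pinv(whitener)
    if pca_model is not None:
        S = S @ pca_model.eigenvectors
    return KICAModel(
        mean=mean, whitener=whitener, W=best_W, S=S, kap=kap,
        kernel_sigma=kernel_sigma, p=p, contrast_value=best_c,
        converged=converged, restart_contrasts=restart_contrasts,
    )


def project_beats(beats, S) -> np.ndarray:
    """Nonlinear feature coefficients A = X S^+ (Moore-Penrose projection)."""
    X = np.asarray(getattr(beats, "data", beats), dtype=float)
    S = np.asarray(S, dtype=float)
    if X.shape[1] != S.shape[1]:
        raise ValueError(
            f"beat length {X.shape[1]} does not match base-signal length {S.shape[1]}"
        )
    return X @ np.linalg.pinv(S)


def amari_index(M) -> float:
    """Permutation/scale-invariant distance of M from a scaled permutation.

    Zero iff M is a permutation times a diagonal; values below ~0.1
    indicate successful blind source separation of B @ A_true.
    """
    P = np.abs(np.asarray(M, dtype=float))
    p = P.shape[0]
    if P.shape != (p, p):
        raise ValueError("M must be square")
    rows = (P.sum(axis=1) / P.max(axis=1) - 1.0).sum()
    cols = (P.sum(axis=0) / P.max(axis=0) - 1.0).sum()
    return float((rows + cols) / (2.0 * p * (p - 1)))
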