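"""Maximum-likelihood fit of the null polygenic mixed model.

The null model is y = X alpha + h + e with h ~ N(0, sigma_h^2 R) and
e ~ N(0, sigma_e^2 I).  All regional statistics hold Omega = sigma_h^2 R
+ sigma_e^2 I and alpha at their null ML estimates, so the model is
fitted once per phenotype and reused for every region.

The fit eigendecomposes R = U D U' once and profiles the likelihood in
the heritability h2 = sigma_h^2 / (sigma_h^2 + sigma_e^2): for fixed h2
the covariance in the rotated frame is diagonal, alpha and the total
variance have closed-form GLS/ML solutions, and a 1-D bounded Brent
search over h2 finishes the job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .pedigree import RelationshipMatrix

_H2_MAX = 1.0 - 1e-6


@dataclass
class EigenR:
    """Cached eigendecomposition R = U diag(d) U'."""

    d: np.ndarray
    U: np.ndarray

    @classmethod
    def from_matrix(cls, R: np.ndarray) -> "EigenR":
        d, U = np.linalg.eigh(R)
        d = np.clip(d, 0.0, None)  # R is PSD up to roundoff
        return cls(d=d, U=U)


@dataclass
class NullModelFit:
    """ML estimates of the null model and the implied Omega^-1 operator."""

    alpha: np.ndarray
    sigma_h2: float
    sigma_e2: float
    loglik: float
    eigen: EigenR
    n: int
    c: int
    reml: bool = False

    @property
    def heritability(self) -> float:
        return self.sigma_h2 / (self.sigma_h2 + self.sigma_e2)

    @property
    def omega_eigenvalues(self) -> np.ndarray:
        return self.sigma_h2 * self.eigen.d + self.sigma_e2


def fit_null(
    y,
    X,
    R: RelationshipMatrix | np.ndarray | EigenR,
    reml: bool = False,
    h2_grid: int = 8,
) -> NullModelFit:
    """Fit y = X alpha + h + e by ML (or REML with ``reml=True``).

    ``R`` may be a RelationshipMatrix, a raw PSD array, or a cached
    :class:`EigenR` (useful when many phenotypes share one sample).  The
    profile likelihood over h2 can be mildly multimodal on small samples,
    so a coarse grid seeds the bounded Brent refinement.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X and y have different numbers of rows")
    c = X.shape[1]
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype values")
    if n <= c:
        raise ValueError("need n > c")
    if np.linalg.matrix_rank(X) < c:
        raise ValueError("covariate matrix X is rank-deficient")
    if np.var(y) <= 1e-12 * max(1.0, np.mean(y) ** 2):
        raise ValueError("degenerate phenotype")

    if isinstance(R, EigenR):
        eigen = R
    else:
        Rm = R.R if isinstance(R, RelationshipMatrix) else np.asarray(R, float)
        if Rm.shape != (n, n):
            raise ValueError("relationship matrix size does not match y")
        eigen = EigenR.from_matrix(Rm)

    yt = eigen.U.T @ y
    Xt = eigen.U.T @ X
    d = eigen.d

    def profile(h2: float):
        v = h2 * d + (1.0 - h2)
        iv = 1.0 / v
        XtW = Xt * iv[:, None]
        A = XtW.T @ Xt
        b = XtW.T @ yt
        alpha = np.linalg.solve(A, b)
        r = yt - Xt @ alpha
        rss = float(r @ (r * iv))
        dof = n - c if reml else n
        s2 = rss / dof
        ll = -0.5 * (dof * np.log(2 * np.pi * s2) + np.sum(np.log(v)) + dof)
        if reml:
            sign, logdet = np.linalg.slogdet(A / s2)
            ll -= 0.5 * logdet
        return ll, alpha, s2

    def neg(h2: float) -> float:
        return -profile(h2)[0]

    # coarse grid then Brent in the best bracket
    grid = np.linspace(0.0, _H2_MAX, h2_grid + 1)
    vals = [neg(g) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(
        neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    h2_hat = float(res.x)
    # prefer the h2 = 0 boundary when it is as good (flat likelihood, R = I)
    if neg(0.0) <= res.fun + 1e-9:
        h2_hat = 0.0
    ll, alpha, s2 = profile(h2_hat)
    return NullModelFit(
        alpha=alpha,
        sigma_h2=h2_hat * s2,
        sigma_e2=(1.0 - h2_hat) * s2,
        loglik=ll,
        eigen=eigen,
        n=n,
        c=c,
        reml=reml,
    )


def known_variance_fit(
    y, X, eigen: EigenR, sigma_h2: float, sigma_e2: float
) -> NullModelFit:
    """Build a fit with Omega fixed at known variance components
    (alpha still estimated by GLS).  Used when the trait covariance is
    known by construction, e.g. in calibration simulations."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    v = sigma_h2 * eigen.d + sigma_e2
    iv = 1.0 / v
    yt = eigen.U.T @ y
    Xt = eigen.U.T @ X
    A = (Xt * iv[:, None]).T @ Xt
    alpha = np.linalg.solve(A, (Xt * iv[:, None]).T @ yt)
    r = yt - Xt @ alpha
    n = y.size
    ll = -0.5 * (
        n * np.log(2 * np.pi) + np.sum(np.log(v)) + float(r @ (r * iv))
    )
    return NullModelFit(
        alpha=alpha,
        sigma_h2=sigma_h2,
        sigma_e2=sigma_e2,
        loglik=ll,
        eigen=eigen,
        n=n,
        c=X.shape[1],
    )


def whiten(fit: NullModelFit, M) -> np.ndarray:
    """Apply Omega^{-1/2} (via the cached eigendecomposition) to a vector
    or matrix, so that weighted sums like r' Omega^-1 r become ordinary
    sums of squares of whitened residuals."""
    M = np.asarray(M, dtype=float)
    vec = M.ndim == 1
    if M.shape[0] != fit.n:
        raise ValueError("dimension mismatch in whiten")
    w = 1.0 / np.sqrt(fit.omega_eigenvalues)
    rotated = fit.eigen.U.T @ M
    return rotated * (w if vec else w[:, None])
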