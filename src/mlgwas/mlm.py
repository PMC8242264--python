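"""Null-model variance components and the two single-pass genome scans.

The null mixed model is ``y ~ N(X b, sigma_g^2 K + sigma_e^2 I)``.  The
kinship matrix is eigendecomposed once; in the rotated basis the covariance
is diagonal, so the (restricted) likelihood is a cheap 1-D function of the
variance ratio ``lambda = sigma_g^2 / sigma_e^2``, maximized by a log-scale
grid sweep plus golden-section refinement.

Both genome scans hold the null variance components fixed (the P3D device:
population parameters previously determined), so each marker costs O(n):

* :func:`fixed_scan` — generalized least squares effect of each marker as a
  fixed effect, Wald p-value from the normal approximation.
* :func:`random_scan` — each marker enters as a random effect
  ``gamma_k ~ N(0, sigma_k^2)``; the rank-one structure gives the maximizing
  ``sigma_k^2`` in closed form and the likelihood-ratio statistic is tested
  against the boundary mixture ``0.5 chi2_0 + 0.5 chi2_1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .kinship import KinshipMatrix

__all__ = [
    "SpectralBasis",
    "VarianceComponents",
    "ScanResult",
    "spectral_basis",
    "fit_null",
    "reml_loglik_dense",
    "fixed_scan",
    "random_scan",
    "whiten",
]

LAMBDA_LO, LAMBDA_HI = 1e-5, 1e5


@dataclass
class SpectralBasis:
    """Eigendecomposition of K: eigenvalues clamped at 0, sorted descending."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def n(self) -> int:
        return len(self.eigenvalues)


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    lam: float  # sigma_g2 / sigma_e2
    loglik: float
    criterion: str  # "REML" | "ML"
    boundary_flag: bool = False


@dataclass
class ScanResult:
    """Per-marker stage-1 statistics for one trait and one method."""

    effects: np.ndarray
    statistics: np.ndarray
    pvalues: np.ndarray
    method: str
    trait: str = ""

    def __post_init__(self) -> None:
        m = len(self.effects)
        if len(self.statistics) != m or len(self.pvalues) != m:
            raise ValueError("scan arrays must share length")


def spectral_basis(K: KinshipMatrix | np.ndarray) -> SpectralBasis:
    Kv = K.values if isinstance(K, KinshipMatrix) else K
    w, U = np.linalg.eigh(Kv)
    w = np.clip(w, 0.0, None)
    order = np.argsort(w)[::-1]
    return SpectralBasis(w[order], U[:, order])


def _profile_negloglik(log_lam, d, yr, Xr, criterion):
    """-2x profile (restricted) log-likelihood of lambda, up to constants.

    Works in the rotated basis: h_i = lam * d_i + 1 are the covariance
    eigenvalues up to sigma_e^2.
    """
    lam = np.exp(log_lam)
    n, p = Xr.shape
    h = lam * d + 1.0
    wi = 1.0 / h
    XtWX = Xr.T @ (Xr * wi[:, None])
    XtWy = Xr.T @ (yr * wi)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yr - Xr @ beta
    rss_w = float(np.sum(resid * resid * wi))
    logdet_h = float(np.sum(np.log(h)))
    if criterion == "REML":
        df = n - p
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        nll = df * np.log(rss_w / df) + logdet_h + logdet_xwx
    else:
        df = n
        nll = n * np.log(rss_w / n) + logdet_h
    return nll, rss_w / df, beta


def reml_loglik_dense(
    lam: float, y: np.ndarray, X: np.ndarray, K: np.ndarray, criterion: str = "REML"
) -> float:
    """Dense-matrix evaluation of the same profile likelihood (oracle route).

    Returns the log-likelihood up to the same additive constant as the
    rotated-basis evaluation, computed with explicit matrix inverses rather
    than the spectral shortcut.
    """
    n, p = X.shape
    V = lam * K + np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    quad = float(r @ Vi @ r)
    sign, logdet_v = np.linalg.slogdet(V)
    if criterion == "REML":
        df = n - p
        _, logdet_x = np.linalg.slogdet(XtViX)
        return -0.5 * (df * np.log(quad / df) + logdet_v + logdet_x)
    return -0.5 * (n * np.log(quad / n) + logdet_v)


def fit_null(
    y: np.ndarray,
    X: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    criterion: str = "REML",
    basis: SpectralBasis | None = None,
    grid_points: int = 100,
) -> tuple[VarianceComponents, SpectralBasis]:
    """Estimate the null-model variance components by REML (or ML).

    The variance ratio is maximized over ``lambda in [1e-5, 1e5]`` on a
    log-scale grid followed by golden-section refinement; ``sigma_e^2`` has a
    closed profile form given lambda.
    """
    if criterion not in ("REML", "ML"):
        raise ValueError("criterion must be REML or ML")
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need n >= p + 2 (n={n}, p={p})")
    if basis is None:
        basis = spectral_basis(K)
    d = basis.eigenvalues
    U = basis.eigenvectors
    yr = U.T @ y
    Xr = U.T @ X

    grid = np.linspace(np.log(LAMBDA_LO), np.log(LAMBDA_HI), grid_points)
    nlls = np.array([_profile_negloglik(g, d, yr, Xr, criterion)[0] for g in grid])
    flat = nlls.max() - nlls.min() < 1e-8
    boundary = False
    if flat:
        warnings.warn(
            "likelihood is flat in the variance ratio (kinship ~ identity: only "
            "the total variance is identifiable); lambda set to the lower boundary",
            stacklevel=2,
        )
        log_lam_hat = np.log(LAMBDA_LO)
        boundary = True
    else:
        i = int(np.argmin(nlls))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid_points - 1)]
        res = optimize.minimize_scalar(
            lambda g: _profile_negloglik(g, d, yr, Xr, criterion)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        log_lam_hat = float(res.x) if res.fun <= nlls[i] else grid[i]
        if i in (0, grid_points - 1):
            boundary = True
    nll, sigma_e2, _ = _profile_negloglik(log_lam_hat, d, yr, Xr, criterion)
    lam = float(np.exp(log_lam_hat))
    vc = VarianceComponents(
        sigma_g2=lam * sigma_e2,
        sigma_e2=float(sigma_e2),
        lam=lam,
        loglik=-0.5 * nll,
        criterion=criterion,
        boundary_flag=boundary,
    )
    return vc, basis


# ---------------------------------------------------------------------------
# scan machinery


def _whitened_parts(y, X, G, vc, basis):
    """Whiten y, X and the marker matrix, then project X out of the markers.

    Returns (y_resid, Z, s, c) where Z holds whitened X-residualized marker
    columns, s = column squared norms, c = column inner products with the
    whitened phenotype residual.
    """
    h = vc.lam * basis.eigenvalues + 1.0
    iw = 1.0 / np.sqrt(h)
    Ut = basis.eigenvectors.T
    yw = iw * (Ut @ y)
    Xw = iw[:, None] * (Ut @ X)
    Gw = iw[:, None] * (Ut @ G)
    XtX = Xw.T @ Xw
    coefs = np.linalg.solve(XtX, Xw.T @ yw)
    y_res = yw - Xw @ coefs
    B = np.linalg.solve(XtX, Xw.T @ Gw)
    Z = Gw - Xw @ B
    s = np.einsum("ij,ij->j", Z, Z)
    c = Z.T @ y_res
    return y_res, Z, s, c


def fixed_scan(
    y: np.ndarray,
    X: np.ndarray,
    genotype,
    vc: VarianceComponents,
    basis: SpectralBasis,
    trait: str = "",
) -> ScanResult:
    """GLS fixed-effect scan with null variance components held fixed."""
    G = genotype.codes if hasattr(genotype, "codes") else np.asarray(genotype, float)
    _, _, s, c = _whitened_parts(np.asarray(y, float), np.asarray(X, float), G, vc, basis)
    ok = s > 1e-12
    effects = np.zeros(len(s))
    zstat = np.zeros(len(s))
    pvals = np.ones(len(s))
    se = np.sqrt(vc.sigma_e2 / np.maximum(s, 1e-300))
    effects[ok] = c[ok] / s[ok]
    zstat[ok] = effects[ok] / se[ok]
    pvals[ok] = 2.0 * stats.norm.sf(np.abs(zstat[ok]))
    return ScanResult(effects, zstat, pvals, method="fixed_scan", trait=trait)


def random_scan(
    y: np.ndarray,
    X: np.ndarray,
    genotype,
    vc: VarianceComponents,
    basis: SpectralBasis,
    trait: str = "",
) -> ScanResult:
    """Random-effect scan: one variance component per marker, closed form.

    With the null covariance whitened away, each marker contributes a
    rank-one term; writing g = c^2 / (s sigma_e^2), the closed-form maximizer
    gives LR = g - 1 - log(g) for g > 1 and 0 otherwise.  P-values use the
    boundary mixture 0.5 chi2_0 + 0.5 chi2_1.
    """
    G = genotype.codes if hasattr(genotype, "codes") else np.asarray(genotype, float)
    _, _, s, c = _whitened_parts(np.asarray(y, float), np.asarray(X, float), G, vc, basis)
    ok = s > 1e-12
    m = len(s)
    g = np.ones(m)
    g[ok] = (c[ok] ** 2) / (s[ok] * vc.sigma_e2)
    LR = np.where(g > 1.0, g - 1.0 - np.log(np.maximum(g, 1e-300)), 0.0)
    # sigma_k^2-hat and the corresponding BLUP of the marker effect
    tk = np.zeros(m)
    tk[ok] = np.maximum(0.0, (c[ok] ** 2 / s[ok] - vc.sigma_e2) / s[ok])
    effects = np.zeros(m)
    nz = ok & (tk > 0)
    effects[nz] = tk[nz] * c[nz] / (vc.sigma_e2 + tk[nz] * s[nz])
    pvals = np.where(LR > 0, 0.5 * stats.chi2.sf(LR, df=1), 1.0)
    return ScanResult(effects, LR, pvals, method="random_scan", trait=trait)


def whiten(
    y: np.ndarray,
    X: np.ndarray,
    G: np.ndarray,
    vc: VarianceComponents,
    basis: SpectralBasis,
) -> tuple[np.ndarray, np.ndarray]:
    """Return the whitened phenotype residual and whitened marker matrix.

    y_w = D^{-1/2} U' (y - X beta_hat) with D = diag(lam d_i + 1); the same
    transform is applied to the marker columns, which are then residualized
    against the whitened fixed effects.  By Frisch-Waugh the regression of
    y_w on a residualized column equals the marker coefficient of the joint
    model including X, so stage-2 effects stay on the original code scale.
    """
    h = vc.lam * basis.eigenvalues + 1.0
    iw = 1.0 / np.sqrt(h)
    Ut = basis.eigenvectors.T
    yw = iw * (Ut @ np.asarray(y, float))
    Xw = iw[:, None] * (Ut @ np.asarray(X, float))
    XtX = Xw.T @ Xw
    coefs = np.linalg.solve(XtX, Xw.T @ yw)
    y_res = yw - Xw @ coefs
    Gw = iw[:, None] * (Ut @ G)
    Gw = Gw - Xw @ np.linalg.solve(XtX, Xw.T @ Gw)
    return y_res, Gw
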