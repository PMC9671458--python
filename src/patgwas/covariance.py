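"""Covariance model for multi-trait GWAS z-scores.

Under the null hypothesis a variant's vector of z-scores across ``T`` traits
is multivariate normal with mean zero and covariance ``sigma_e`` — the
environmental component.  Its diagonal is exactly 1 (a z-score has unit null
variance by construction) and its off-diagonal entries arise only through
sample overlap between cohorts:

    sigma_e[i, k] = n_shared[i, k] / sqrt(n[i] * n[k]) * rho_e[i, k]

Under the alternative (polygenic) model the genetic effects contribute an
additional component on the z-score scale,

    sigma_g_z[i, k] = sqrt(n[i] * n[k]) * sigma_g[i, k]

where ``sigma_g`` holds the per-variant genetic (co)variances of the raw
effect sizes.  The full alternative covariance is ``sigma_e + sigma_g_z``.

Configuration masks: a binary vector ``c`` of length ``T`` marks which traits
carry a true effect; ``masked_sigma_g`` zeroes every row/column of the
genetic component outside the configuration.  These masked matrices drive the
m-value posterior over the 2**T possible effect configurations.

Genetic and environmental correlation matrices are treated as opaque inputs
(estimated externally, e.g. by LD-score regression); nothing here estimates
them from data.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

__all__ = [
    "CovarianceModel",
    "build_sigma_e",
    "build_sigma_g_z",
    "masked_sigma_g",
    "mvn_logpdf",
    "enumerate_configurations",
    "repair_psd",
]

#: relative eigenvalue tolerance below which a matrix is declared broken
_PSD_RTOL = 1e-8

_LOG_2PI = np.log(2.0 * np.pi)


def repair_psd(sigma: np.ndarray, name: str = "covariance") -> np.ndarray:
    """Clip tiny negative eigenvalues to zero; refuse large ones.

    Externally estimated covariance matrices are noisy and often fail strict
    positive semi-definiteness by floating-point dust.  Eigenvalues in
    ``(-1e-8 * lambda_max, 0)`` are clipped to 0 with a warning; anything more
    negative raises, because silently repairing a substantially indefinite
    matrix would hide an upstream bug.
    """
    sigma = np.asarray(sigma, dtype=float)
    sigma = 0.5 * (sigma + sigma.T)
    w, v = np.linalg.eigh(sigma)
    lam_max = max(w[-1], 0.0)
    floor = -_PSD_RTOL * max(lam_max, 1.0)
    if w[0] < floor:
        raise ValueError(
            f"{name} is not positive semi-definite: smallest eigenvalue "
            f"{w[0]:.3e} (largest {lam_max:.3e})"
        )
    if w[0] < 0.0:
        warnings.warn(
            f"{name}: clipping {int((w < 0).sum())} tiny negative "
            f"eigenvalue(s) (min {w[0]:.3e}) to zero",
            stacklevel=2,
        )
        w = np.clip(w, 0.0, None)
        sigma = (v * w) @ v.T
        sigma = 0.5 * (sigma + sigma.T)
    return sigma


def build_sigma_e(
    rho_e: np.ndarray, n: np.ndarray, n_shared: np.ndarray
) -> np.ndarray:
    """Environmental covariance of z-scores from overlap-weighted correlations.

    Parameters
    ----------
    rho_e : (T, T) symmetric environmental correlations, unit diagonal.
    n : (T,) per-trait sample sizes.
    n_shared : (T, T) counts of individuals shared between each trait pair.

    Returns
    -------
    (T, T) matrix with unit diagonal and off-diagonals
    ``n_shared[i,k] / sqrt(n[i] n[k]) * rho_e[i,k]``.  With zero overlap this
    is the identity regardless of ``rho_e``.
    """
    rho_e = np.asarray(rho_e, dtype=float)
    n = np.asarray(n, dtype=float)
    n_shared = np.asarray(n_shared, dtype=float)
    T = len(n)
    if rho_e.shape != (T, T) or n_shared.shape != (T, T):
        raise ValueError("rho_e and n_shared must be T x T for T sample sizes")
    if not np.allclose(rho_e, rho_e.T):
        raise ValueError("rho_e must be symmetric")
    if np.any(np.abs(rho_e) > 1.0 + 1e-12):
        raise ValueError("rho_e entries must lie in [-1, 1]")
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    off = n_shared / np.sqrt(np.outer(n, n))
    if np.any(off > 1.0 + 1e-12):
        raise ValueError("n_shared[i,k] may not exceed min(n[i], n[k])")
    sigma_e = off * rho_e
    np.fill_diagonal(sigma_e, 1.0)  # z-scores have unit null variance
    sigma_e = 0.5 * (sigma_e + sigma_e.T)
    return repair_psd(sigma_e, name="sigma_e")


def build_sigma_g_z(sigma_g: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Genetic covariance on the z-score scale: sqrt(N_i N_k) * sigma_g[i,k]."""
    sigma_g = np.asarray(sigma_g, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(np.diag(sigma_g) < 0):
        raise ValueError("per-variant genetic variances must be non-negative")
    if not np.allclose(sigma_g, sigma_g.T):
        raise ValueError("sigma_g must be symmetric")
    scale = np.sqrt(np.outer(n, n))
    return scale * sigma_g


def masked_sigma_g(sigma_g_z: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Zero the genetic component outside a configuration.

    Entry ``(i, k)`` survives iff ``c[i] == 1`` and ``c[k] == 1``.  The
    all-ones configuration returns the matrix unchanged; all-zeros returns
    the zero matrix (the global-null configuration).
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (sigma_g_z.shape[0],):
        raise ValueError("configuration length must match number of traits")
    return sigma_g_z * np.outer(c, c)


def enumerate_configurations(T: int) -> np.ndarray:
    """All 2**T binary effect configurations as a (2**T, T) 0/1 array.

    Row ``j`` is the binary expansion of ``j`` with trait 0 as the lowest bit,
    so row 0 is the global null and the last row is the all-ones
    configuration.
    """
    if T < 1:
        raise ValueError("need at least one trait")
    if T > 15:
        raise ValueError("exact configuration enumeration is guarded at T <= 15")
    idx = np.arange(2**T)[:, None]
    return ((idx >> np.arange(T)[None, :]) & 1).astype(np.int8)


def _chol(sigma: np.ndarray, name: str = "covariance") -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        sigma = repair_psd(sigma, name=name)
        try:
            return np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"{name} is not positive definite and could not be repaired"
            ) from err


def mvn_logpdf(S: np.ndarray, sigma: np.ndarray, chol: np.ndarray | None = None):
    """Zero-mean multivariate-normal log-density, vectorised over rows.

    ``S`` may be a single length-T vector or an (M, T) matrix; the return is a
    scalar or a length-M vector accordingly.  ``chol`` may pass a
    pre-computed Cholesky factor of ``sigma`` (the factorisation dominates
    cost when the same covariance is reused across millions of variants).
    """
    S = np.asarray(S, dtype=float)
    one = S.ndim == 1
    Z = S[None, :] if one else S
    T = Z.shape[1]
    L = _chol(sigma) if chol is None else chol
    if L.shape != (T, T):
        raise ValueError(f"dimension mismatch: S has {T} traits, sigma is {L.shape}")
    # solve L x = S^T; quadratic form = |x|^2
    x = solve_triangular(L, Z.T, lower=True, check_finite=False)
    quad = np.einsum("ij,ij->j", x, x)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    out = -0.5 * (T * _LOG_2PI + logdet + quad)
    return float(out[0]) if one else out


@dataclass(frozen=True)
class CovarianceModel:
    """Environmental + genetic covariance decomposition of z-scores.

    Parameters
    ----------
    n : per-trait GWAS sample sizes.
    rho_e : (T, T) environmental correlations between traits.
    sigma_g : (T, T) per-variant genetic covariances of raw effect sizes
        (typically heritability / number of variants on the diagonal).
    n_shared : (T, T) pairwise sample-overlap counts; defaults to zero overlap
        (diagonal is always the per-trait n).
    trait_names : optional labels, used to validate input ordering.
    """

    n: np.ndarray
    rho_e: np.ndarray
    sigma_g: np.ndarray
    n_shared: np.ndarray | None = None
    trait_names: tuple[str, ...] | None = None
    sigma_e: np.ndarray = field(init=False, repr=False)
    sigma_g_z: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        n = np.atleast_1d(np.asarray(self.n, dtype=float))
        T = n.shape[0]
        rho_e = np.asarray(self.rho_e, dtype=float)
        sigma_g = np.asarray(self.sigma_g, dtype=float)
        if self.n_shared is None:
            n_shared = np.diag(n)
        else:
            n_shared = np.asarray(self.n_shared, dtype=float).copy()
            np.fill_diagonal(n_shared, n)
        if self.trait_names is not None and len(self.trait_names) != T:
            raise ValueError("trait_names length must match number of traits")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "rho_e", rho_e)
        object.__setattr__(self, "sigma_g", sigma_g)
        object.__setattr__(self, "n_shared", n_shared)
        object.__setattr__(self, "sigma_e", build_sigma_e(rho_e, n, n_shared))
        object.__setattr__(self, "sigma_g_z", build_sigma_g_z(sigma_g, n))
        # the alternative covariance must be usable
        repair_psd(self.sigma_e + self.sigma_g_z, name="sigma_e + sigma_g_z")

    @property
    def T(self) -> int:
        return int(self.n.shape[0])

    @property
    def sigma_alt(self) -> np.ndarray:
        """Covariance under the all-traits alternative: sigma_e + sigma_g_z."""
        return self.sigma_e + self.sigma_g_z

    def masked(self, c: np.ndarray, scale: float = 1.0) -> np.ndarray:
        """sigma_e + scale * sigma_g_z(c) for one effect configuration."""
        return self.sigma_e + scale * masked_sigma_g(self.sigma_g_z, c)

    def sigma_e_fingerprint(self) -> str:
        """Stable hash of the null covariance, used to pin calibrations."""
        h = hashlib.sha256()
        h.update(np.round(self.sigma_e, 12).tobytes())
        return h.hexdigest()[:16]

    def permuted(self, order) -> "CovarianceModel":
        """Same model with traits re-ordered (for equivariance checks)."""
        order = np.asarray(order)
        names = (
            tuple(np.asarray(self.trait_names)[order])
            if self.trait_names is not None
            else None
        )
        return CovarianceModel(
            n=self.n[order],
            rho_e=self.rho_e[np.ix_(order, order)],
            sigma_g=self.sigma_g[np.ix_(order, order)],
            n_shared=self.n_shared[np.ix_(order, order)],
            trait_names=names,
        )
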