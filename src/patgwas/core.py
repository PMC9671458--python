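"""Pleiotropic omnibus likelihood-ratio test on multi-trait z-scores.

For a variant's z-score vector S across T traits the test compares two
zero-mean multivariate normals:

    null:        S ~ N(0, sigma_e)
    alternative: S ~ N(0, sigma_e + sigma_g_z)

The statistic is the log likelihood ratio
``log N(S; 0, sigma_e + sigma_g_z) - log N(S; 0, sigma_e)``, kept in log
space because the raw ratio overflows at genome-wide-significant z-scores.
Significance is decided against a critical value kappa calibrated by
(importance-sampled) null simulation; a variant is significant iff its
statistic is strictly greater than kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationTable, critical_value, pvalue_of
from .covariance import CovarianceModel, _chol

__all__ = ["PatResult", "pat_statistic", "run_pat"]


@dataclass(frozen=True)
class PatResult:
    variant_key: str
    stat: float
    pvalue: float
    significant: bool
    below_floor: bool = False


def pat_statistic(S: np.ndarray, model: CovarianceModel):
    """Log likelihood-ratio statistic, vectorised over rows of ``S``.

    ``S`` is a length-T vector or an (M, T) matrix.  With ``sigma_g_z = 0``
    the statistic is identically zero; at ``S = 0`` it equals
    ``0.5 * (log det sigma_e - log det(sigma_e + sigma_g_z))`` which is
    negative whenever the genetic component is non-trivial.
    """
    S = np.asarray(S, dtype=float)
    one = S.ndim == 1
    Z = S[None, :] if one else S
    if Z.shape[1] != model.T:
        raise ValueError(
            f"dimension mismatch: S has {Z.shape[1]} traits, model has {model.T}"
        )
    from scipy.linalg import solve_triangular

    out = np.zeros(Z.shape[0])
    for sign, sigma in ((+1.0, model.sigma_alt), (-1.0, model.sigma_e)):
        L = _chol(sigma, name="model covariance")
        x = solve_triangular(L, Z.T, lower=True, check_finite=False)
        quad = np.einsum("ij,ij->j", x, x)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out += sign * (-0.5) * (logdet + quad)
    return float(out[0]) if one else out


def run_pat(
    data,
    model: CovarianceModel,
    calibration: CalibrationTable,
    alpha: float = 5e-8,
) -> pd.DataFrame:
    """Test every variant and decide significance at level ``alpha``.

    ``data`` is a :class:`~patgwas.sumstats.MultiTraitSumStats` (or any object
    with ``z_matrix`` and ``variants`` attributes, or a bare (M, T) array).
    Returns a DataFrame with columns ``variant``, ``stat``, ``pvalue``,
    ``significant`` and ``below_floor`` (p-value reported at the calibration
    floor rather than zero).
    """
    if calibration.statistic != "pat":
        raise ValueError("calibration table was built for a different statistic")
    if calibration.sigma_e_fingerprint != model.sigma_e_fingerprint():
        raise ValueError(
            "calibration was built under a different null covariance "
            "(sigma_e fingerprint mismatch)"
        )
    if hasattr(data, "z_matrix"):
        Z = np.asarray(data.z_matrix, dtype=float)
        variants = list(getattr(data, "variants"))
    else:
        Z = np.asarray(data, dtype=float)
        variants = [f"variant_{i}" for i in range(Z.shape[0])]
    stats = pat_statistic(Z, model)
    kappa = critical_value(alpha, calibration)
    pvals = pvalue_of(stats, calibration)
    below = stats > calibration.stats[0]
    return pd.DataFrame(
        {
            "variant": variants,
            "stat": stats,
            "pvalue": pvals,
            "significant": stats > kappa,  # strict >: a tie with kappa is not significant
            "below_floor": below,
        }
    )
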