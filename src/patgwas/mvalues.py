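"""Per-trait interpretation of omnibus hits via configuration posteriors.

An omnibus test returns one p-value per variant for the whole trait set; the
m-value framework turns a significant hit into per-trait statements.  Each of
the 2**T binary configurations c marks which traits carry a true effect and
induces the covariance ``sigma_e + scale * sigma_g_z(c)``.  With a uniform
prior over configurations, the m-value of trait i is

    m_i = sum_{c : c_i = 1} N(S; 0, sigma_e + scale * sigma_g_z(c))
          / sum_{all c}     N(S; 0, sigma_e + scale * sigma_g_z(c))

computed with log-sum-exp over cached Cholesky factors.  A trait is called
"associated" when m_i > 0.9 (strict); otherwise the interpretation stays
ambiguous.  The global-null configuration c = 0 is retained in the
denominator.

Rescaling by M/Q: under the fully polygenic model the per-variant genetic
variance is heritability / M, so ``sigma_g_z + sigma_e ~ sigma_e`` and the
configurations are indistinguishable.  Significant variants, however, are
drawn from the causal minority; their expected effect corresponds to Q causal
variants rather than M.  ``estimate_q`` picks one significant variant per
100 kb window (to approximate independence) and grid-searches Q in [1, M] for
the value maximising the joint likelihood of those lead variants under
``(M/Q) * sigma_g_z + sigma_e``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .covariance import (
    CovarianceModel,
    _chol,
    enumerate_configurations,
    masked_sigma_g,
    mvn_logpdf,
)

__all__ = [
    "MValueReport",
    "CausalScaling",
    "compute_mvalues",
    "assign",
    "estimate_q",
    "pm_plot_data",
    "config_logliks",
]

ASSIGN_THRESHOLD = 0.9
Q_WINDOW_BP = 100_000


@dataclass(frozen=True)
class CausalScaling:
    """Result of the causal-count grid search."""

    M: int
    Q: int
    k: int  # number of clumped lead variants in the likelihood
    grid: pd.DataFrame  # columns: Q, loglik
    seed: int

    @property
    def scale(self) -> float:
        """Multiplier M/Q applied to the genetic covariance."""
        return self.M / self.Q


@dataclass(frozen=True)
class MValueReport:
    trait_names: tuple[str, ...]
    variants: np.ndarray
    m: np.ndarray  # (M, T) in [0, 1]
    assignment: np.ndarray  # (M, T) of {"associated", "ambiguous"}
    q_used: int | None
    scale: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"variant": self.variants})
        for j, t in enumerate(self.trait_names):
            df[f"m_{t}"] = self.m[:, j]
        for j, t in enumerate(self.trait_names):
            df[f"assignment_{t}"] = self.assignment[:, j]
        df["Q"] = self.q_used if self.q_used is not None else pd.NA
        df["scale"] = self.scale
        return df


def config_logliks(
    Z: np.ndarray, model: CovarianceModel, scale: float = 1.0
) -> np.ndarray:
    """Log-density of every row of Z under every configuration.

    Returns a (2**T, M) array; row j corresponds to configuration j of
    :func:`~patgwas.covariance.enumerate_configurations`.  Cholesky factors
    are computed once per configuration.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    T = model.T
    configs = enumerate_configurations(T)
    out = np.empty((configs.shape[0], Z.shape[0]))
    for j, c in enumerate(configs):
        sigma = model.sigma_e + scale * masked_sigma_g(model.sigma_g_z, c)
        try:
            L = _chol(sigma, name=f"sigma_e + scale*sigma_g(c) for c={tuple(c)}")
        except ValueError as err:
            raise ValueError(
                f"covariance for configuration {tuple(int(x) for x in c)} "
                "is not positive definite"
            ) from err
        out[j] = mvn_logpdf(Z, sigma, chol=L)
    return out


def compute_mvalues(
    S: np.ndarray, model: CovarianceModel, scale: float = 1.0
) -> np.ndarray:
    """m-values for one z-vector (length T) or a matrix of them (M, T).

    Uniform prior over the 2**T configurations; numerator restricted to
    configurations with an effect in the trait; log-sum-exp throughout.
    """
    S = np.asarray(S, dtype=float)
    one = S.ndim == 1
    ll = config_logliks(S, model, scale=scale)  # (2**T, M)
    configs = enumerate_configurations(model.T).astype(bool)  # (2**T, T)
    denom = logsumexp(ll, axis=0)  # (M,)
    m = np.empty((ll.shape[1], model.T))
    for i in range(model.T):
        num = logsumexp(ll[configs[:, i]], axis=0)
        m[:, i] = np.exp(num - denom)
    m = np.clip(m, 0.0, 1.0)
    return m[0] if one else m


def assign(m: np.ndarray, threshold: float = ASSIGN_THRESHOLD) -> np.ndarray:
    """Label each trait "associated" iff m > threshold (strict), else "ambiguous"."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    m = np.asarray(m, dtype=float)
    return np.where(m > threshold, "associated", "ambiguous")


def estimate_q(
    hits,
    model: CovarianceModel,
    M: int,
    window_bp: int = Q_WINDOW_BP,
    seed: int = 0,
    grid_size: int = 512,
) -> CausalScaling:
    """Estimate the causal variant count Q from omnibus-significant variants.

    ``hits`` needs ``z_matrix``, ``chrom`` and ``pos`` attributes (a
    MultiTraitSumStats restricted to significant variants).  One variant is
    drawn uniformly per non-empty 100 kb window (fixed genome bins, 0-based
    half-open after converting the 1-based positions), giving k approximately
    independent leads.  Q maximises ``sum_i log N(S_i; 0, (M/Q) sigma_g_z +
    sigma_e)`` over a geometric integer grid on [1, M] with one linear
    refinement pass around the optimum; ties break toward the smallest
    (most polygenic) Q.
    """
    Z = np.atleast_2d(np.asarray(hits.z_matrix, dtype=float))
    chrom = np.asarray(hits.chrom)
    pos = np.asarray(hits.pos, dtype=np.int64)
    if Z.shape[0] == 0:
        raise ValueError("no significant variants to estimate Q from")
    if chrom.shape[0] != Z.shape[0] or pos.shape[0] != Z.shape[0]:
        raise ValueError("positions are required for window clumping")
    if M < Z.shape[0]:
        raise ValueError("M must be at least the number of variants tested")

    rng = np.random.default_rng(seed)
    bins = (pos - 1) // window_bp  # 1-based -> 0-based half-open bins
    keys = pd.Series([f"{c}:{b}" for c, b in zip(chrom, bins)])
    lead_idx = []
    for _, grp in keys.groupby(keys, sort=True):
        lead_idx.append(int(rng.choice(grp.index.to_numpy())))
    lead = Z[np.sort(lead_idx)]
    k = lead.shape[0]

    def loglik(q_values: np.ndarray) -> np.ndarray:
        out = np.empty(len(q_values))
        for j, q in enumerate(q_values):
            sigma = (M / q) * model.sigma_g_z + model.sigma_e
            out[j] = mvn_logpdf(lead, sigma).sum()
        return out

    grid = np.unique(
        np.round(np.geomspace(1, M, num=min(grid_size, M))).astype(np.int64)
    )
    ll = loglik(grid)
    best = int(np.argmax(ll))  # argmax returns the first (smallest Q) on ties
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if hi - lo > 1:
        fine = np.unique(
            np.round(np.linspace(lo, hi, num=min(grid_size, hi - lo + 1))).astype(
                np.int64
            )
        )
        ll_fine = loglik(fine)
        grid = np.concatenate([grid, fine])
        ll = np.concatenate([ll, ll_fine])
    order = np.argsort(grid, kind="stable")
    grid, ll = grid[order], ll[order]
    grid, uniq_idx = np.unique(grid, return_index=True)
    ll = ll[uniq_idx]
    q_best = int(grid[int(np.argmax(ll))])
    return CausalScaling(
        M=int(M),
        Q=q_best,
        k=k,
        grid=pd.DataFrame({"Q": grid, "loglik": ll}),
        seed=int(seed),
    )


def interpret_hits(
    hits,
    model: CovarianceModel,
    M: int | None = None,
    scale: float | None = None,
    threshold: float = ASSIGN_THRESHOLD,
    window_bp: int = Q_WINDOW_BP,
    seed: int = 0,
) -> MValueReport:
    """Full interpretation pass: estimate Q (unless a scale is given), then
    compute m-values and assignments for every hit."""
    if scale is None:
        if M is None:
            raise ValueError("either an explicit scale or M (for Q estimation)")
        cs = estimate_q(hits, model, M=M, window_bp=window_bp, seed=seed)
        scale, q_used = cs.scale, cs.Q
    else:
        q_used = None
    m = compute_mvalues(np.atleast_2d(hits.z_matrix), model, scale=scale)
    return MValueReport(
        trait_names=tuple(getattr(hits, "trait_names", range(model.T))),
        variants=np.asarray(getattr(hits, "variants", np.arange(m.shape[0]))),
        m=m,
        assignment=assign(m, threshold=threshold),
        q_used=q_used,
        scale=float(scale),
    )


def pm_plot_data(
    pvalues: np.ndarray,
    m: np.ndarray,
    gw_alpha: float = 5e-8,
    threshold: float = ASSIGN_THRESHOLD,
) -> pd.DataFrame:
    """P-M plot table: per-trait single-GWAS p against m-value, with regions.

    Region A: single-trait significant but ambiguous m (anomalous — such
    points should not occur); B: significant and assigned; C: neither;
    D: assigned without single-trait significance (the novel interpretations).
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    mm = np.asarray(m, dtype=float).ravel()
    if p.shape != mm.shape:
        raise ValueError("pvalues and m must align")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    sig = p < gw_alpha
    hi = mm > threshold
    region = np.where(
        sig & ~hi, "A", np.where(sig & hi, "B", np.where(~sig & ~hi, "C", "D"))
    )
    return pd.DataFrame(
        {
            "neg_log10_p": -np.log10(p),
            "m": mm,
            "region": region,
            "anomaly": region == "A",
        }
    )
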