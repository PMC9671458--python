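"""Post-discovery replication analytics for novel GWAS associations.

Given lead variants discovered in one cohort and summary statistics from an
independent replication cohort:

* ``clump`` reduces correlated nearby hits to one lead per 1 Mb region,
  greedily keeping the best-scoring variant (largest m-value, or smallest
  p-value) and suppressing everything within +/- 500 kb of it on the same
  chromosome.
* ``one_sided_replication_test`` tests each lead in the direction of the
  discovery effect: z = sign(beta_disc) * beta_rep / se_rep, p = 1 - Phi(z),
  compared against a Bonferroni-adjusted level.
* ``concordance_binomial`` asks whether the fraction of effect sizes sharing
  the discovery direction exceeds the 50% expected under the null, via an
  exact one-sided binomial test computed with log-gamma sums (the interesting
  p-values are far beyond normal-approximation validity).
* ``replication_power`` approximates each lead's one-sided replication power
  from the discovery effect, the replication MAF and sample size, assuming
  standardised phenotype and genotype; ``power_decile_table`` bins leads by
  power and compares expected with observed replications.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

__all__ = [
    "clump",
    "one_sided_replication_test",
    "concordance_binomial",
    "replication_power",
    "power_decile_table",
]


def clump(
    variants: pd.DataFrame,
    window_bp: int = 1_000_000,
    score: str = "m",
    ascending: bool | None = None,
) -> pd.DataFrame:
    """Greedy 1 Mb clumping to independent lead variants.

    ``variants`` needs ``chrom``, ``pos`` and the ``score`` column.  By
    default larger scores win (m-value rule); pass ``score="p",
    ascending=True`` for the smallest-p rule.  Repeatedly take the
    best-scoring remaining variant and drop every other variant within
    +/- window/2 of it (half-open) on the same chromosome.  Ties break toward
    the smaller genomic coordinate.  Output preserves selection order.
    """
    if ascending is None:
        ascending = score == "p"
    df = variants.reset_index(drop=True)
    if not np.isfinite(df[score].to_numpy(dtype=float)).all():
        raise ValueError("clumping scores must be finite")
    order = df.sort_values(
        [score, "chrom", "pos"], ascending=[ascending, True, True], kind="stable"
    ).index.to_numpy()
    half = window_bp // 2
    taken = np.zeros(len(df), dtype=bool)
    suppressed = np.zeros(len(df), dtype=bool)
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy(dtype=np.int64)
    leads = []
    for i in order:
        if suppressed[i]:
            continue
        taken[i] = True
        leads.append(i)
        near = (chrom == chrom[i]) & (pos >= pos[i] - half) & (pos < pos[i] + half)
        suppressed |= near
    return df.loc[leads].reset_index(drop=True)


def one_sided_replication_test(
    beta_disc, beta_rep, se_rep, alpha_adjusted: float
):
    """One-sided z-test in the discovery effect direction.

    Returns ``(p_one_sided, replicated)``; vectorised.  A replicated variant
    necessarily has its effect in the same direction as discovery.
    """
    beta_disc = np.asarray(beta_disc, dtype=float)
    beta_rep = np.asarray(beta_rep, dtype=float)
    se_rep = np.asarray(se_rep, dtype=float)
    if np.any(se_rep <= 0):
        raise ValueError("replication standard errors must be positive")
    if np.any(beta_disc == 0):
        raise ValueError("discovery effect of zero has no direction to test")
    z = np.sign(beta_disc) * beta_rep / se_rep
    p = norm.sf(z)
    return p, p < alpha_adjusted


def concordance_binomial(n_same: int, n_total: int) -> float:
    """Exact one-sided binomial p-value for direction concordance vs 0.5.

    ``P(X >= n_same)`` for X ~ Binomial(n_total, 1/2), summed in log space
    with log-gamma coefficients so values like 1e-184 are exact to machine
    precision.
    """
    if n_total < 1 or not 0 <= n_same <= n_total:
        raise ValueError("need 0 <= n_same <= n_total with n_total >= 1")
    k = np.arange(n_same, n_total + 1)
    log_terms = (
        gammaln(n_total + 1)
        - gammaln(k + 1)
        - gammaln(n_total - k + 1)
        - n_total * np.log(2.0)
    )
    return float(np.exp(logsumexp(log_terms)))


def replication_power(beta_disc, maf, n_rep, alpha_adjusted: float):
    """Approximate power of the one-sided replication test.

    Assumes a standardised phenotype and genotype, so the replication z-score
    is ~ N(lambda, 1) with non-centrality
    ``lambda = |beta_disc| * sqrt(2 * maf * (1 - maf) * n_rep)`` (the MAF
    enters through the genotype variance 2p(1-p)).  Power is
    ``1 - Phi(Phi^-1(1 - alpha) - lambda)``; with a zero discovery effect this
    reduces to the test's size.  Labelled approximate: reference-panel MAFs
    and meta-analysis sample sizes both bias it.
    """
    beta_disc = np.asarray(beta_disc, dtype=float)
    maf = np.asarray(maf, dtype=float)
    n_rep = np.asarray(n_rep, dtype=float)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    if np.any(n_rep < 1):
        raise ValueError("replication sample size must be >= 1")
    lam = np.abs(beta_disc) * np.sqrt(2.0 * maf * (1.0 - maf) * n_rep)
    out = norm.sf(norm.isf(alpha_adjusted) - lam)
    return float(out) if out.ndim == 0 else out


def power_decile_table(
    power: np.ndarray, replicated: np.ndarray, same_direction: np.ndarray
) -> pd.DataFrame:
    """Bin leads into power deciles [0,10%) ... [90,100%] and summarise.

    Per decile: average power, leads tested, expected replications (sum of
    power), observed replications, direction-concordant count, and the exact
    binomial concordance p-value for that decile.
    """
    power = np.asarray(power, dtype=float)
    replicated = np.asarray(replicated, dtype=bool)
    same_direction = np.asarray(same_direction, dtype=bool)
    bins = np.minimum((power * 10).astype(int), 9)
    rows = []
    for d in range(10):
        mask = bins == d
        n = int(mask.sum())
        row = {
            "decile": f"{10 * d}-{10 * (d + 1)}%",
            "n_variants": n,
            "average_power": float(power[mask].mean()) if n else np.nan,
            "expected_replications": float(power[mask].sum()),
            "observed_replications": int(replicated[mask].sum()),
            "same_direction": int(same_direction[mask].sum()),
        }
        row["concordance_p"] = (
            concordance_binomial(row["same_direction"], n) if n else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
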