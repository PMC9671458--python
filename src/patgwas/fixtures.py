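"""On-disk synthetic multi-trait GWAS fixtures for end-to-end exercises.

``make_fixture`` writes per-trait summary-statistics files with deliberately
planted defects — allele swaps relative to the first trait, strand-ambiguous
pairs, low-MAF and low-INFO rows — together with the matching covariance
matrices and a truth table of effect configurations, so the whole pipeline
(QC, harmonisation, calibration, testing, interpretation) can run with no
external data.  Everything is seeded and byte-reproducible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .covariance import CovarianceModel, masked_sigma_g
from .matrices import write_matrix

__all__ = ["make_fixture"]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def make_fixture(
    out_dir,
    T: int = 4,
    n_variants: int = 1000,
    seed: int = 0,
    n_per_trait: int = 50_000,
    causal_frac: float = 0.10,
    causal: int = 200,
    swap_frac: float = 0.05,
    bad_frac: float = 0.05,
) -> dict:
    """Write a seeded synthetic fixture; returns a manifest of paths/counts.

    10% of variants are causal (in a random non-null configuration each),
    drawn from the corresponding covariance; ``swap_frac`` of rows in each
    non-first trait have ref/alt swapped with negated z (harmonisation must
    undo this), and ``bad_frac`` of extra rows fail QC (strand-ambiguous or
    low MAF/INFO).
    """
    if not 2 <= T <= 6:
        raise ValueError("fixture supports 2 to 6 traits")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    trait_names = [f"trait{i + 1}" for i in range(T)]
    # mildly correlated synthetic panel
    rho_e = np.full((T, T), 0.2)
    np.fill_diagonal(rho_e, 1.0)
    h2 = np.linspace(0.2, 0.4, T)
    rho_g = np.full((T, T), 0.4)
    np.fill_diagonal(rho_g, 1.0)
    sigma_h2 = rho_g * np.sqrt(np.outer(h2, h2))
    n_vec = np.full(T, n_per_trait)
    n_shared = np.full((T, T), n_per_trait)
    model = CovarianceModel(
        n=n_vec, rho_e=rho_e, sigma_g=sigma_h2 / causal, n_shared=n_shared
    )

    # variant scaffold
    chrom = rng.integers(1, 5, size=n_variants)
    pos = rng.integers(1, 50_000_000, size=n_variants)
    order = np.lexsort((pos, chrom))
    chrom, pos = chrom[order], pos[order]
    ref = rng.choice(_BASES, size=n_variants)
    alt = np.array(
        [rng.choice([b for b in _BASES if b not in (r, _COMPLEMENT[r])]) for r in ref]
    )
    vid = np.array([f"rs{1000 + i}" for i in range(n_variants)])
    maf = rng.uniform(0.05, 0.5, size=n_variants)
    info = rng.uniform(0.85, 1.0, size=n_variants)

    # truth: 10% causal, random non-null configuration each
    n_causal = int(round(causal_frac * n_variants))
    causal_idx = rng.choice(n_variants, size=n_causal, replace=False)
    config_codes = np.zeros(n_variants, dtype=int)
    config_codes[causal_idx] = rng.integers(1, 2**T, size=n_causal)

    Z = rng.standard_normal((n_variants, T)) @ np.linalg.cholesky(model.sigma_e).T
    for code in np.unique(config_codes[causal_idx]):
        c = (code >> np.arange(T)) & 1
        sigma = model.sigma_e + masked_sigma_g(model.sigma_g_z, c.astype(float))
        mask = config_codes == code
        Z[mask] = rng.standard_normal((int(mask.sum()), T)) @ np.linalg.cholesky(
            sigma
        ).T

    planted = {"swaps": {}, "bad_rows": {}}
    paths = {}
    for j, t in enumerate(trait_names):
        df = pd.DataFrame(
            {
                "id": vid,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "z": Z[:, j],
                "n": n_per_trait,
                "maf": maf,
                "info": info,
            }
        )
        if j > 0:
            n_swap = int(round(swap_frac * n_variants))
            swap = rng.choice(n_variants, size=n_swap, replace=False)
            df.loc[swap, ["ref", "alt"]] = df.loc[swap, ["alt", "ref"]].to_numpy()
            df.loc[swap, "z"] = -df.loc[swap, "z"]
            planted["swaps"][t] = int(n_swap)
        # planted QC failures appended as extra rows
        n_bad = int(round(bad_frac * n_variants))
        bad = pd.DataFrame(
            {
                "id": [f"bad{t}_{i}" for i in range(n_bad)],
                "chrom": rng.integers(1, 5, size=n_bad),
                "pos": rng.integers(1, 50_000_000, size=n_bad),
                "ref": "A",
                "alt": "T",  # strand-ambiguous
                "z": rng.standard_normal(n_bad),
                "n": n_per_trait,
                "maf": rng.uniform(0.001, 0.009, size=n_bad),  # fails MAF too
                "info": rng.uniform(0.5, 0.7, size=n_bad),  # and INFO
            }
        )
        planted["bad_rows"][t] = int(n_bad)
        full = pd.concat([df, bad], ignore_index=True)
        p = out / f"sumstats_{t}.tsv"
        full.to_csv(p, sep="\t", index=False)
        paths[t] = str(p)

    write_matrix(rho_e, trait_names, out / "rho_e.csv")
    write_matrix(sigma_h2 / causal, trait_names, out / "sigma_g.csv")
    write_matrix(n_shared, trait_names, out / "overlap.csv")
    truth = pd.DataFrame({"id": vid, "chrom": chrom, "pos": pos})
    for j, t in enumerate(trait_names):
        truth[f"causal_{t}"] = (config_codes >> j) & 1
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    return {
        "trait_names": trait_names,
        "sumstats": paths,
        "rho_e": str(out / "rho_e.csv"),
        "sigma_g": str(out / "sigma_g.csv"),
        "overlap": str(out / "overlap.csv"),
        "truth": str(out / "truth.tsv"),
        "n_per_trait": n_per_trait,
        "n_causal": n_causal,
        "planted": planted,
    }
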