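"""Reading, QC-filtering and harmonising GWAS summary-statistics tables.

Input files are headered, tab- or whitespace-delimited text (optionally
gzipped), one per trait, with columns mapped to the canonical names via a
``column_map``.  Required: variant id, chromosome, position, ref/alt alleles,
a sample size, and either a z-score or beta + se (z is computed as beta/se
when absent).  Coordinates are 1-based, the usual sumstats convention; window
arithmetic elsewhere converts to 0-based half-open bins internally.

QC follows standard practice for summary-statistics harmonisation: keep
biallelic SNPs with non-ambiguous strand (drop A/T and C/G pairs), minor
allele frequency above 1% and imputation INFO above 0.80.  Harmonisation
inner-joins variants across traits on chromosome:position:allele-pair and
flips the sign of z (and beta) wherever a trait reports the alleles in the
opposite orientation to the first trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MultiTraitSumStats",
    "read_sumstats",
    "qc_filter",
    "harmonize",
    "write_harmonized",
    "REQUIRED_COLUMNS",
    "STRAND_AMBIGUOUS_PAIRS",
]

REQUIRED_COLUMNS = ("id", "chrom", "pos", "ref", "alt", "n")
#: allele pairs unresolvable under strand flips
STRAND_AMBIGUOUS_PAIRS = frozenset(
    {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
)
_BASES = frozenset("ACGT")

#: canonical internal column order
_CANON = ["id", "chrom", "pos", "ref", "alt", "z", "beta", "se", "n", "maf", "info"]


@dataclass(frozen=True)
class MultiTraitSumStats:
    """Harmonised z-scores for M variants across T traits.

    ``z_matrix`` is (M, T) with one column per trait in ``trait_names``
    order; every variant is present for all traits with consistent allele
    orientation.  ``n_per_trait`` carries one sample size per trait (the
    median of per-variant sizes when those vary).
    """

    trait_names: tuple[str, ...]
    variants: np.ndarray  # variant ids
    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    ref: np.ndarray
    alt: np.ndarray
    z_matrix: np.ndarray
    n_per_trait: np.ndarray

    def __post_init__(self):
        M, T = self.z_matrix.shape
        if len(self.trait_names) != T or len(self.n_per_trait) != T:
            raise ValueError("trait dimension mismatch")
        for arr in (self.variants, self.chrom, self.pos, self.ref, self.alt):
            if len(arr) != M:
                raise ValueError("variant dimension mismatch")

    @property
    def n_variants(self) -> int:
        return self.z_matrix.shape[0]

    @property
    def n_traits(self) -> int:
        return self.z_matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "variant_id": self.variants,
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
            }
        )
        for j, t in enumerate(self.trait_names):
            df[f"z_{t}"] = self.z_matrix[:, j]
        for j, t in enumerate(self.trait_names):
            df[f"n_{t}"] = self.n_per_trait[j]
        return df


def _variant_key(df: pd.DataFrame) -> pd.Series:
    """Join key robust to allele orientation: chr:pos:sorted-allele-pair."""
    lo = np.minimum(df["ref"].to_numpy(), df["alt"].to_numpy())
    hi = np.maximum(df["ref"].to_numpy(), df["alt"].to_numpy())
    return (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(str)
        + ":"
        + pd.Series(lo, index=df.index)
        + ":"
        + pd.Series(hi, index=df.index)
    )


def read_sumstats(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read one trait's summary statistics into canonical columns.

    ``column_map`` maps canonical names (``id, chrom, pos, ref, alt, z, beta,
    se, n, maf, info``) to the file's header names; canonical names present in
    the header are picked up without mapping.  Rows with unparseable required
    fields, ref == alt, or non-positive se are dropped with a logged count.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep=r"\s+")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    rename = {}
    for canon in _CANON:
        src = column_map.get(canon, canon)
        if src in df.columns:
            rename[src] = canon
    df = df.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; "
            "provide a column_map entry for each"
        )
    if "z" not in df.columns and not {"beta", "se"} <= set(df.columns):
        raise ValueError(f"{path}: need either a z column or both beta and se")

    n0 = len(df)
    for col in ("pos", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("z", "beta", "se", "maf", "info"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("ref", "alt"):
        df[col] = df[col].astype(str).str.upper()
    df["chrom"] = df["chrom"].astype(str)

    if "z" not in df.columns:
        df["z"] = df["beta"] / df["se"]
    else:
        need = df["z"].isna() & df.get("beta", pd.Series(dtype=float)).notna()
        if need.any():
            df.loc[need, "z"] = df.loc[need, "beta"] / df.loc[need, "se"]

    ok = (
        df["id"].notna()
        & df["pos"].notna()
        & (df["pos"] > 0)
        & df["n"].notna()
        & (df["n"] > 0)
        & df["z"].notna()
        & np.isfinite(df["z"])
        & (df["ref"] != df["alt"])
    )
    if "se" in df.columns:
        ok &= df["se"].isna() | (df["se"] > 0)
    dropped = n0 - int(ok.sum())
    if dropped:
        logger.info("%s: dropped %d unparseable/invalid rows", path, dropped)
    df = df.loc[ok].copy()
    if df.empty:
        raise ValueError(f"{path}: no valid rows after parsing")
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    keep = [c for c in _CANON if c in df.columns]
    return df[keep].reset_index(drop=True)


def qc_filter(
    records: pd.DataFrame,
    maf_min: float | None = 0.01,
    info_min: float | None = 0.80,
    drop_strand_ambiguous: bool = True,
    missing_fails: bool = True,
) -> pd.DataFrame:
    """Standard variant QC: biallelic SNPs, MAF > 1%, INFO > 0.80, no A/T-C/G.

    A filter is skipped entirely when its threshold is None.  When a filter is
    enabled and the column is absent or NaN, the variant fails closed by
    default (``missing_fails=False`` lets such variants through instead).
    """
    for thr, name in ((maf_min, "maf_min"), (info_min, "info_min")):
        if thr is not None and not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    df = records
    keep = pd.Series(True, index=df.index)
    # biallelic single-nucleotide alleles only
    keep &= df["ref"].isin(_BASES) & df["alt"].isin(_BASES)
    if drop_strand_ambiguous:
        pairs = list(zip(df["ref"], df["alt"]))
        keep &= ~pd.Series(
            [p in STRAND_AMBIGUOUS_PAIRS for p in pairs], index=df.index
        )
    for col, thr in (("maf", maf_min), ("info", info_min)):
        if thr is None:
            continue
        if col in df.columns:
            present = df[col].notna()
            passed = present & (df[col] > thr)
            if not missing_fails:
                passed |= ~present
            keep &= passed
        elif missing_fails:
            keep &= False
    out = df.loc[keep].reset_index(drop=True)
    logger.info("qc_filter: %d of %d variants retained", len(out), len(df))
    return out


def harmonize(
    tables: list[pd.DataFrame], trait_names: list[str] | None = None
) -> MultiTraitSumStats:
    """Inner-join T trait tables on variant key and align allele orientation.

    The first trait defines the reference orientation.  A trait whose ref/alt
    are swapped relative to it has its z (and beta) negated; a variant whose
    allele pair matches neither orientation in some trait is dropped and
    counted.  Output rows are sorted by (chrom, pos).
    """
    T = len(tables)
    if T < 2:
        raise ValueError("harmonisation needs at least two traits")
    if trait_names is None:
        trait_names = [f"trait{i + 1}" for i in range(T)]
    if len(trait_names) != T:
        raise ValueError("one trait name per table required")

    frames = []
    for i, df in enumerate(tables):
        f = df.copy()
        f["_key"] = _variant_key(f)
        f = f.drop_duplicates("_key").set_index("_key")
        frames.append(f)

    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    if len(common) == 0:
        raise ValueError("no variants shared by all traits after joining")

    base = frames[0].loc[common]
    z_cols = [base["z"].to_numpy(dtype=float)]
    n_per_trait = [int(np.median(base["n"]))]
    mismatched = np.zeros(len(common), dtype=bool)
    for f in frames[1:]:
        sub = f.loc[common]
        same = (sub["ref"].to_numpy() == base["ref"].to_numpy()) & (
            sub["alt"].to_numpy() == base["alt"].to_numpy()
        )
        swapped = (sub["ref"].to_numpy() == base["alt"].to_numpy()) & (
            sub["alt"].to_numpy() == base["ref"].to_numpy()
        )
        z = sub["z"].to_numpy(dtype=float).copy()
        z[swapped] = -z[swapped]
        mismatched |= ~(same | swapped)
        z_cols.append(z)
        n_per_trait.append(int(np.median(sub["n"])))

    if mismatched.any():
        logger.info(
            "harmonize: dropped %d variants with inconsistent allele pairs",
            int(mismatched.sum()),
        )
    keep = ~mismatched
    order = np.lexsort(
        (base["pos"].to_numpy()[keep], base["chrom"].to_numpy()[keep])
    )

    def _take(arr):
        return np.asarray(arr)[keep][order]

    return MultiTraitSumStats(
        trait_names=tuple(trait_names),
        variants=_take(base["id"].to_numpy()),
        chrom=_take(base["chrom"].to_numpy()),
        pos=_take(base["pos"].to_numpy(dtype=np.int64)),
        ref=_take(base["ref"].to_numpy()),
        alt=_take(base["alt"].to_numpy()),
        z_matrix=np.column_stack([z[keep][order] for z in z_cols]),
        n_per_trait=np.asarray(n_per_trait, dtype=np.int64),
    )


def write_harmonized(data: MultiTraitSumStats, path) -> None:
    """Write the harmonised table as tab-delimited text with a header."""
    data.to_frame().to_csv(path, sep="\t", index=False)
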