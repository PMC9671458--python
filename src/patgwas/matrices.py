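"""Reading and writing trait-by-trait covariance matrices as labelled CSV.

Matrices (environmental correlations, genetic covariances, overlap counts)
are square numeric tables with trait names as both header row and index
column; the trait order is validated by name against the summary-statistics
order before use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_matrix", "write_matrix", "align_matrix"]


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: covariance matrix must be square")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column trait names disagree")
    return df.astype(float)


def write_matrix(mat: np.ndarray, trait_names, path) -> None:
    pd.DataFrame(mat, index=list(trait_names), columns=list(trait_names)).to_csv(
        path
    )


def align_matrix(df: pd.DataFrame, trait_names) -> np.ndarray:
    """Reorder a labelled matrix to the given trait order, by name."""
    missing = [t for t in trait_names if t not in df.index]
    if missing:
        raise ValueError(f"matrix is missing trait(s) {missing}")
    return df.loc[list(trait_names), list(trait_names)].to_numpy()
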