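"""Screen phenotype tables and robust Z-score normalization.

A screen table holds one row per siRNA pool with a quantitative phenotype:
either a raw measurement (``response``, e.g. cell viability) or a
precomputed score (``z``), plus optional gene and batch labels.  Raw values
are converted to robust Z scores batch by batch:

    Z_i = (X_i - median(X)) / MAD,   MAD = median_j |X_j - median(X)|

The MAD here is the *raw* median absolute deviation, without the 1.4826
normal-consistency factor; pass ``scale="normal"`` to apply it when Z scores
on the standard-normal scale are wanted (with unit-variance Gaussian noise
this makes Z units coincide with raw units).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegenerateMAD, EmptyTable, MissingColumn

logger = logging.getLogger(__name__)

#: 1 / Phi^{-1}(3/4): multiplying the raw MAD by this makes it a consistent
#: estimator of the standard deviation under normality.
NORMAL_CONSISTENCY = 1.4826022185056018

CANONICAL_COLUMNS = ("pool_id", "gene_id", "response", "z", "batch")


def read_screen_csv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a screen table; ``column_map`` renames file columns to canonical
    names (pool_id, gene_id, response, z, batch).

    Rows whose phenotype fails to parse are dropped with a logged count
    (also stored in ``df.attrs["n_dropped"]``).
    """
    df = pd.read_csv(path, dtype={0: str})
    if column_map:
        df = df.rename(columns=column_map)
    if "pool_id" not in df.columns:
        raise MissingColumn(f"{path}: no pool_id column (column_map={column_map})")
    if "response" not in df.columns and "z" not in df.columns:
        raise MissingColumn(f"{path}: need a response or z column")
    df["pool_id"] = df["pool_id"].astype(str)
    if df["pool_id"].duplicated().any():
        dupes = df.loc[df["pool_id"].duplicated(), "pool_id"].head().tolist()
        raise EmptyTable(f"{path}: duplicate pool_ids, e.g. {dupes}")

    n_before = len(df)
    for col in ("response", "z"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    phenotype_cols = [c for c in ("response", "z") if c in df.columns]
    keep = df[phenotype_cols].notna().any(axis=1)
    df = df.loc[keep].reset_index(drop=True)
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.warning("%s: dropped %d rows with unparseable phenotype", path, n_dropped)
    if df.empty:
        raise EmptyTable(f"{path}: no rows with a usable phenotype")
    df.attrs["n_dropped"] = n_dropped
    return df


def robust_z(values, scale: str = "raw") -> np.ndarray:
    """Robust Z scores of a 1-d array: (x - median) / MAD.

    Raises :class:`DegenerateMAD` when the MAD is zero (constant input) —
    such a batch must be excluded, not silently scored.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise EmptyTable("robust_z needs a 1-d array of >= 2 values")
    if not np.all(np.isfinite(x)):
        raise DegenerateMAD("non-finite values in input")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise DegenerateMAD("median absolute deviation is zero")
    if scale == "normal":
        mad *= NORMAL_CONSISTENCY
    elif scale != "raw":
        raise ValueError(f"scale must be 'raw' or 'normal', got {scale!r}")
    return (x - med) / mad


def robust_z_by_batch(
    table: pd.DataFrame, scale: str = "raw", response_col: str = "response"
) -> pd.DataFrame:
    """Populate the ``z`` column by applying :func:`robust_z` within batches.

    Without a ``batch`` column the whole table is one implicit batch.
    Batches with zero MAD are flagged (z left NaN, batch names in
    ``df.attrs["degenerate_batches"]``) while the remaining batches are
    scored; an all-degenerate table raises.
    """
    if response_col not in table.columns:
        raise MissingColumn(f"no {response_col!r} column to normalize")
    out = table.copy()
    out["z"] = np.nan
    groups = (
        out.groupby("batch", sort=False).indices.items()
        if "batch" in out.columns
        else [(None, np.arange(len(out)))]
    )
    degenerate: list = []
    for name, idx in groups:
        try:
            out.iloc[np.asarray(idx), out.columns.get_loc("z")] = robust_z(
                out[response_col].to_numpy()[idx], scale=scale
            )
        except DegenerateMAD:
            degenerate.append(name)
            logger.warning("batch %r has zero MAD; left unscored", name)
    if out["z"].isna().all():
        raise DegenerateMAD("every batch is degenerate")
    out.attrs["degenerate_batches"] = degenerate
    return out


def write_screen_csv(df: pd.DataFrame, path) -> None:
    """Write a screen table with fixed float precision (reproducible runs)."""
    df.to_csv(path, index=False, float_format="%.9g")
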