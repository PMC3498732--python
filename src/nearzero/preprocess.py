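"""Expression-matrix normalization and filtering.

The expression matrix is a genes x samples pandas DataFrame of
non-negative hybridization intensities (index: gene ids, columns: sample
ids).  Sample metadata is a DataFrame with columns ``sample_id``,
``growth_rate`` (h-1), ``mode`` ("chemostat" or "retentostat"),
``replicate`` and optional ``time_d`` (retentostat day).

Processing order follows the array-analysis narrative: global scaling of
every array to a common target mean, flooring of low intensities,
removal of genes that never rise above a minimal maximum, restriction to
open reading frames, and finally replicate collapsing plus per-gene
mean-normalization for profile comparisons.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScalingError",
    "validate_matrix",
    "validate_metadata",
    "global_scale",
    "floor_and_filter",
    "select_orfs",
    "collapse_replicates",
    "mean_normalize_profiles",
    "housekeeping_cv",
]


class ScalingError(ValueError):
    """A sample cannot be scaled (non-positive mean)."""


def validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    if matrix.columns.has_duplicates:
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes[:5]}")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression intensities must be >= 0")


def validate_metadata(matrix: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Check metadata covers every sample; return it indexed by sample_id."""
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    missing = [s for s in matrix.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    if (meta.loc[list(matrix.columns), "growth_rate"] <= 0).any():
        raise ValueError("growth_rate must be > 0 for every sample")
    return meta


def global_scale(matrix: pd.DataFrame, target: float = 300.0) -> pd.DataFrame:
    """Scale each array so its mean intensity over all features equals ``target``.

    Every sample's values are multiplied by ``target / mean(sample)``.
    Idempotent: re-scaling an already-scaled matrix is the identity.
    """
    means = matrix.mean(axis=0)
    bad = means[means <= 0]
    if not bad.empty:
        raise ScalingError(f"sample(s) with non-positive mean cannot be scaled: {list(bad.index)}")
    return matrix * (target / means)


def floor_and_filter(
    matrix: pd.DataFrame,
    floor: float = 12.0,
    min_max: float = 20.0,
) -> tuple[pd.DataFrame, list]:
    """Floor low intensities and drop never-expressed genes.

    Values below ``floor`` are set to ``floor``; genes whose maximum across
    all samples is below ``min_max`` are discarded.  Returns the filtered
    matrix and the list of removed gene ids.
    """
    floored = matrix.clip(lower=floor)
    keep = matrix.max(axis=1) >= min_max
    removed = list(matrix.index[~keep])
    result = floored.loc[keep]
    if result.empty:
        import warnings

        warnings.warn("floor_and_filter removed every gene", stacklevel=2)
    return result, removed


def select_orfs(matrix: pd.DataFrame, orf_list: Iterable) -> pd.DataFrame:
    """Restrict the matrix to the given open-reading-frame ids, order preserved."""
    orfs = set(orf_list)
    if not orfs:
        raise ValueError("orf_list is empty")
    keep = matrix.index.isin(orfs)
    if not keep.any():
        raise ValueError("no overlap between matrix genes and the ORF list")
    return matrix.loc[keep]


def _condition_table(meta: pd.DataFrame, samples: Sequence) -> pd.DataFrame:
    sub = meta.loc[list(samples)].copy()
    if "time_d" not in sub.columns:
        sub["time_d"] = np.nan
    sub["time_d"] = pd.to_numeric(sub["time_d"], errors="coerce")
    key = sub.groupby(["mode", "growth_rate", "time_d"], dropna=False, sort=False)
    conds = (
        key.size()
        .reset_index(name="n_replicates")
        .sort_values(["growth_rate", "mode"], kind="stable")
        .reset_index(drop=True)
    )
    conds["label"] = [
        f"{row['mode']}:mu={row['growth_rate']:g}" for _, row in conds.iterrows()
    ]
    return conds


def collapse_replicates(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average replicate arrays per (mode, growth_rate, time_d) condition.

    Returns the genes x conditions matrix (columns ordered by increasing
    growth rate) and the condition table (label, mode, growth_rate,
    time_d, n_replicates).
    """
    meta = validate_metadata(matrix, metadata)
    conds = _condition_table(meta, matrix.columns)
    cols = {}
    for _, row in conds.iterrows():
        mask = (meta.loc[list(matrix.columns), "mode"] == row["mode"]) & (
            meta.loc[list(matrix.columns), "growth_rate"] == row["growth_rate"]
        )
        if not np.isnan(row["time_d"]):
            mask &= pd.to_numeric(
                meta.loc[list(matrix.columns), "time_d"], errors="coerce"
            ) == row["time_d"]
        else:
            mask &= pd.to_numeric(
                meta.loc[list(matrix.columns), "time_d"], errors="coerce"
            ).isna()
        cols[row["label"]] = matrix.loc[:, mask.to_numpy()].mean(axis=1)
    collapsed = pd.DataFrame(cols, index=matrix.index)
    return collapsed, conds


def mean_normalize_profiles(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    collapse: bool = True,
) -> pd.DataFrame:
    """Divide each gene's profile by its across-condition mean.

    If metadata is supplied and ``collapse`` is true, replicates are first
    averaged per condition.  The output rows have mean 1, making profiles
    comparable in shape regardless of absolute expression level; the
    result is invariant to positive per-gene scaling of the input.
    """
    prof = matrix
    if metadata is not None and collapse:
        prof, _ = collapse_replicates(matrix, metadata)
    means = prof.mean(axis=1)
    zero = means[means == 0]
    if not zero.empty:
        raise ValueError(f"gene(s) with zero mean cannot be mean-normalized: {list(zero.index)[:5]}")
    return prof.div(means, axis=0)


def housekeeping_cv(matrix: pd.DataFrame, gene_ids: Sequence) -> pd.Series:
    """Coefficient of variation (sample sd / mean) across all arrays per gene.

    Used to verify that putative housekeeping genes stay constant; values
    below ~0.20 indicate the global-scaling normalization is safe.
    """
    missing = [g for g in gene_ids if g not in matrix.index]
    if missing:
        raise KeyError(f"gene(s) not in matrix: {missing}")
    sub = matrix.loc[list(gene_ids)]
    return sub.std(axis=1, ddof=1) / sub.mean(axis=1)
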