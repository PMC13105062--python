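"""Replicate intensity normalization.

Raw per-feature fluorescence from replicate arrays is brought onto a common
scale in three steps: a global per-replicate rescaling, quantile
normalization so all replicates share one intensity distribution, and a
per-probe median collapse to a single final normalized intensity.

The default global step divides each replicate by its own median, so the
final normalized intensity is a fold-over-median-probe quantity: the whole
pipeline is then exactly invariant to arbitrary per-replicate scale factors
(scanner gain, exposure), and a fixed direct-binding threshold on the final
scale is meaningful across experiments. ``target="mean_of_medians"``
instead rescales every replicate median to the mean of the raw replicate
medians, which preserves the raw fluorescence magnitude.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "global_normalize",
    "quantile_normalize",
    "median_collapse",
    "normalize_pipeline",
]


def _validate(matrix: pd.DataFrame, min_reps: int = 1) -> None:
    if matrix.shape[1] < min_reps:
        raise ValueError(f"need at least {min_reps} replicate column(s)")
    if not matrix.index.is_unique:
        raise ValueError("probe ids must be unique")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing values present; drop incomplete rows first")
    if (values < 0).any():
        raise ValueError("negative intensities are not allowed")


def drop_incomplete(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Remove rows with any missing replicate; returns (kept, dropped ids)."""
    mask = matrix.notna().all(axis=1)
    return matrix.loc[mask], matrix.index[~mask]


def global_normalize(
    matrix: pd.DataFrame,
    target: str = "unit_median",
) -> tuple[pd.DataFrame, pd.Series]:
    """Rescale each replicate by a single multiplicative factor.

    target='unit_median' divides each replicate by its median (final scale is
    fold-over-median); 'mean_of_medians' rescales every replicate median to
    the mean of the raw replicate medians; 'total_sum' equalizes column sums
    to the mean raw column sum. Within-replicate rank order is unchanged.

    Returns the rescaled matrix and the per-replicate factors applied.
    """
    _validate(matrix, min_reps=2)
    medians = matrix.median(axis=0)
    for rep, med in medians.items():
        if med <= 0:
            raise ValueError(f"replicate {rep!r} has non-positive median {med}")
    if target == "unit_median":
        factors = 1.0 / medians
    elif target == "mean_of_medians":
        factors = medians.mean() / medians
    elif target == "total_sum":
        sums = matrix.sum(axis=0)
        factors = sums.mean() / sums
    else:
        raise ValueError(f"unknown target {target!r}")
    return matrix * factors, factors


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force all replicates onto the mean empirical distribution.

    The reference vector is the across-replicate mean of the sorted columns;
    each value is replaced by the reference value at its within-column rank.
    Tied raw values receive the mean of the reference values their ranks
    span, so ties stay tied.
    """
    _validate(matrix, min_reps=2)
    values = matrix.to_numpy(dtype=float)
    n, k = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(k):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(n)
        mapped[order] = reference
        # average reference values over runs of tied raw values
        tied = pd.Series(mapped).groupby(col, sort=False).transform("mean")
        out[:, j] = tied.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_collapse(matrix: pd.DataFrame) -> pd.Series:
    """Per-probe median across replicates (mean-of-middle for even counts)."""
    _validate(matrix, min_reps=1)
    collapsed = matrix.median(axis=1)
    collapsed.name = "intensity"
    return collapsed


def normalize_pipeline(
    raw: pd.DataFrame,
    target: str = "unit_median",
) -> tuple[pd.Series, dict]:
    """Global scaling -> quantile normalization -> median collapse.

    Returns the final per-probe normalized intensity and a log dict with the
    per-replicate global factors and the number of dropped incomplete rows.
    """
    kept, dropped = drop_incomplete(raw)
    scaled, factors = global_normalize(kept, target=target)
    quantiled = quantile_normalize(scaled)
    final = median_collapse(quantiled)
    log = {
        "global_factors": factors.to_dict(),
        "dropped_rows": list(map(str, dropped)),
        "target": target,
    }
    return final, log
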