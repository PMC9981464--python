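"""Trait transforms and prevalence filtering.

``rankz`` is the rank-based inverse-normal transform applied to every
abundance trait before mapping; ``prevalence_filter`` implements the
"at least ``min_value`` in ``min_fraction`` of samples" detection filter
used for metagene and transcript matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateTraitError

__all__ = ["rankz", "rankz_frame", "prevalence_filter", "FilterReport"]


def rankz(values) -> np.ndarray:
    """Rank-based inverse-normal transform.

    Maps values to normal quantiles ``Phi^-1((rank - 0.5) / n)`` using
    average ranks for ties, computed over the finite entries; NaNs
    propagate. Invariant under monotone transforms of the input.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 3:
        raise DegenerateTraitError(f"need >=3 finite values to rank-normalize, got {n}")
    finite = x[mask]
    if np.all(finite == finite[0]):
        raise DegenerateTraitError("all finite values are equal; trait is degenerate")
    ranks = stats.rankdata(finite, method="average")
    out[mask] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def rankz_frame(traits: pd.DataFrame, on_degenerate: str = "drop") -> pd.DataFrame:
    """Apply :func:`rankz` column-wise.

    ``on_degenerate='drop'`` silently drops constant/too-short columns;
    ``'raise'`` propagates the error.
    """
    cols = {}
    for name in traits.columns:
        try:
            cols[name] = rankz(traits[name].to_numpy())
        except DegenerateTraitError:
            if on_degenerate == "raise":
                raise
    return pd.DataFrame(cols, index=traits.index)


@dataclass
class FilterReport:
    n_kept: int
    n_dropped: int
    dropped: list[str]


def prevalence_filter(
    traits: pd.DataFrame, min_value: float, min_fraction: float
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep traits detected at >= ``min_value`` in >= ``min_fraction`` of samples.

    Both comparisons are inclusive, so a trait exactly at the boundary is
    kept. NaN entries count as not detected.
    """
    if traits.shape[0] == 0 or traits.shape[1] == 0:
        raise DataError("prevalence filter on an empty trait matrix")
    if not 0 < min_fraction <= 1:
        raise DataError(f"min_fraction must be in (0,1], got {min_fraction}")
    values = traits.to_numpy(dtype=float)
    frac = np.mean(np.nan_to_num(values, nan=-np.inf) >= min_value, axis=0)
    keep = frac >= min_fraction
    kept = traits.loc[:, keep]
    dropped = [c for c, k in zip(traits.columns, keep) if not k]
    return kept, FilterReport(n_kept=int(keep.sum()), n_dropped=len(dropped), dropped=dropped)
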