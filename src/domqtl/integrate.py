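"""Cross-dataset synthesis: co-mapping, allele-effect correlation,
hotspots, enrichment, trait-trait correlation and differential screening.

These are the bookkeeping statistics that tie the per-dataset QTL results
together: matching peaks across trait classes within a genomic window,
correlating 8-founder allele-effect vectors (with an exact permutation
null, since n=8 is fully enumerable), binning peaks into hotspot windows,
Fisher-exact category enrichment with Benjamini-Hochberg FDR, Spearman
correlation tables and Welch's-t differential screens.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .scan import AlleleEffects, Peak

__all__ = [
    "CoMapPair",
    "Hotspot",
    "match_comapping",
    "effect_correlation",
    "detect_hotspots",
    "enrich_categories",
    "correlate_matrices",
    "differential_features",
    "bh_adjust",
]


@dataclass
class CoMapPair:
    trait_a: str
    trait_b: str
    chrom: str
    pos_a: float
    pos_b: float
    distance: float
    rho: float | None = None
    p: float | None = None
    method: str = ""


@dataclass
class Hotspot:
    chrom: str
    lo_mbp: float
    hi_mbp: float
    n_traits: int
    traits: list[str] = field(default_factory=list)
    lod_floor: float = 6.0


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, idempotent)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def match_comapping(
    peaksA: list[Peak], peaksB: list[Peak], window_mbp: float = 4.0
) -> list[CoMapPair]:
    """All same-chromosome peak pairs within ``window_mbp`` of each other.

    Symmetric in A and B up to the orientation of the pair.
    """
    pairs = []
    for a, b in itertools.product(peaksA, peaksB):
        if a.chrom != b.chrom:
            continue
        d = abs(a.pos_mbp - b.pos_mbp)
        if d <= window_mbp:
            pairs.append(
                CoMapPair(
                    trait_a=a.trait, trait_b=b.trait, chrom=a.chrom,
                    pos_a=a.pos_mbp, pos_b=b.pos_mbp, distance=d,
                )
            )
    return pairs


_PERM_CACHE: dict[int, np.ndarray] = {}


def _exact_spearman_null(n: int) -> np.ndarray:
    """All n! permutations of 1..n as an array (cached; n <= 8)."""
    if n not in _PERM_CACHE:
        _PERM_CACHE[n] = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
    return _PERM_CACHE[n]


def effect_correlation(
    a: AlleleEffects | np.ndarray, b: AlleleEffects | np.ndarray, method: str = "spearman"
) -> tuple[float, float]:
    """Correlation of two 8-founder allele-effect vectors.

    For Spearman the p-value is exact: the observed rank correlation is
    compared against all 8! = 40,320 orderings (two-sided). Pearson uses
    the usual t approximation.
    """
    va = a.effects if isinstance(a, AlleleEffects) else np.asarray(a, dtype=float)
    vb = b.effects if isinstance(b, AlleleEffects) else np.asarray(b, dtype=float)
    if va.shape != vb.shape or va.ndim != 1:
        raise ConfigError("allele-effect vectors must be 1-D and of equal length")
    if np.std(va) == 0 or np.std(vb) == 0:
        raise DataError("zero-variance allele-effect vector: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(va, vb)
        return float(r), float(p)
    if method != "spearman":
        raise ConfigError(f"unknown method {method!r}")
    ra = stats.rankdata(va)
    rb = stats.rankdata(vb)
    rho = float(np.corrcoef(ra, rb)[0, 1])
    n = len(va)
    if n > 8:
        return rho, float(stats.spearmanr(va, vb)[1])
    perms = _exact_spearman_null(n)
    ra_c = ra - ra.mean()
    denom = np.sqrt((ra_c @ ra_c) * np.sum((perms - perms.mean(axis=1, keepdims=True)) ** 2, axis=1))
    # null rhos: correlation of the fixed rank vector with every ordering of rb
    null = (perms - perms.mean(axis=1, keepdims=True)) @ ra_c / denom
    # under exchangeability, permuting rb's ranks is equivalent; ties in the
    # observed vectors only affect the observed rho, not the null
    p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    return rho, p


def detect_hotspots(
    peaks: list[Peak] | pd.DataFrame,
    bin_mbp: float = 1.0,
    min_traits: int = 5,
    lod_floor: float = 6.0,
) -> list[Hotspot]:
    """Genomic windows where unusually many traits map.

    Peaks with LOD >= ``lod_floor`` are assigned to fixed ``bin_mbp`` bins
    per chromosome; bins holding >= ``min_traits`` peaks seed hotspots and
    adjacent qualifying bins merge, reporting the distinct trait count.
    """
    if isinstance(peaks, list):
        rows = [
            {"trait": p.trait, "chrom": p.chrom, "pos_mbp": p.pos_mbp, "lod": p.lod}
            for p in peaks
        ]
        peaks = pd.DataFrame(rows, columns=["trait", "chrom", "pos_mbp", "lod"])
    hot: list[Hotspot] = []
    use = peaks[peaks["lod"] >= lod_floor]
    for chrom, sub in use.groupby("chrom", sort=True):
        bins = np.floor(sub["pos_mbp"].to_numpy() / bin_mbp).astype(int)
        counts = pd.Series(bins).value_counts()
        qualifying = sorted(b for b, c in counts.items() if c >= min_traits)
        if not qualifying:
            continue
        runs: list[list[int]] = [[qualifying[0]]]
        for b in qualifying[1:]:
            if b == runs[-1][-1] + 1:
                runs[-1].append(b)
            else:
                runs.append([b])
        for run in runs:
            lo, hi = run[0] * bin_mbp, (run[-1] + 1) * bin_mbp
            in_run = sub[(bins >= run[0]) & (bins <= run[-1])]
            traits = sorted(set(in_run["trait"]))
            hot.append(
                Hotspot(chrom=str(chrom), lo_mbp=lo, hi_mbp=hi,
                        n_traits=len(traits), traits=traits, lod_floor=lod_floor)
            )
    return hot


def enrich_categories(
    hit_set: set | list,
    annotation: dict | pd.DataFrame,
    background: set | list,
) -> pd.DataFrame:
    """Two-sided Fisher exact enrichment of categories among the hit set.

    ``annotation`` maps trait id -> iterable of categories (many-to-many),
    or a DataFrame with columns (trait_id, category). The 2x2 table for a
    category counts hits/non-hits inside/outside it over the background;
    p-values are BH-adjusted across the categories tested.
    """
    background = set(background)
    if not background:
        raise DataError("empty background set")
    hits = set(hit_set)
    if not hits <= background:
        raise DataError("hit set must be a subset of the background")
    if isinstance(annotation, pd.DataFrame):
        ann: dict[str, set] = {}
        for t, c in annotation.itertuples(index=False):
            ann.setdefault(t, set()).add(c)
    else:
        ann = {t: set(cs) for t, cs in annotation.items()}
    categories = sorted({c for t in background for c in ann.get(t, ())})
    rows = []
    for cat in categories:
        in_cat = {t for t in background if cat in ann.get(t, ())}
        a = len(hits & in_cat)
        b = len(hits - in_cat)
        c = len(in_cat - hits)
        d = len(background) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"category": cat, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p": p})
    table = pd.DataFrame(rows, columns=["category", "a", "b", "c", "d", "odds_ratio", "p"])
    if not table.empty:
        table["q"] = bh_adjust(table["p"])
        table = table.sort_values("p", ignore_index=True)
    return table


def correlate_matrices(
    traitsA: pd.DataFrame, traitsB: pd.DataFrame, method: str = "spearman"
) -> pd.DataFrame:
    """All A x B trait correlations with BH FDR across the full table.

    Individuals are aligned on the index; each pair uses its
    pairwise-complete observations. Constant columns yield a flagged row
    with undefined rho.
    """
    common = traitsA.index.intersection(traitsB.index)
    if len(common) < 3:
        raise DataError("fewer than 3 shared individuals between the two matrices")
    A = traitsA.loc[common]
    B = traitsB.loc[common]
    rows = []
    for ca in A.columns:
        xa = A[ca].to_numpy(dtype=float)
        for cb in B.columns:
            xb = B[cb].to_numpy(dtype=float)
            mask = np.isfinite(xa) & np.isfinite(xb)
            n = int(mask.sum())
            if n < 3 or np.std(xa[mask]) == 0 or np.std(xb[mask]) == 0:
                rows.append({"a": ca, "b": cb, "n": n, "rho": np.nan, "p": np.nan,
                             "undefined": True})
                continue
            if method == "spearman":
                rho, p = stats.spearmanr(xa[mask], xb[mask])
            elif method == "pearson":
                rho, p = stats.pearsonr(xa[mask], xb[mask])
            else:
                raise ConfigError(f"unknown method {method!r}")
            rows.append({"a": ca, "b": cb, "n": n, "rho": float(rho), "p": float(p),
                         "undefined": False})
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"])
    return table


def differential_features(
    groupA: pd.DataFrame,
    groupB: pd.DataFrame,
    fc_min: float = 10.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group screen: Welch's t per feature, BH FDR, fold-change gate.

    Fold change is mean(A)/mean(B) on a pseudocounted scale (pseudocount =
    half the smallest positive value observed anywhere in either matrix).
    ``kept`` requires fold_change > fc_min and q < alpha. Features with
    zero variance in both groups and equal means get p = 1 by convention.
    """
    features = [c for c in groupA.columns if c in groupB.columns]
    if not features:
        raise DataError("the two groups share no features")
    both = np.concatenate([groupA[features].to_numpy().ravel(), groupB[features].to_numpy().ravel()])
    positive = both[np.isfinite(both) & (both > 0)]
    pseudo = positive.min() / 2.0 if positive.size else 0.5
    rows = []
    for f in features:
        xa = groupA[f].to_numpy(dtype=float)
        xb = groupB[f].to_numpy(dtype=float)
        xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        if len(xa) < 2 or len(xb) < 2:
            raise DataError(f"feature {f!r} needs >=2 samples per group")
        fc = (xa.mean() + pseudo) / (xb.mean() + pseudo)
        degenerate = xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0
        if degenerate and xa.mean() == xb.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append({"feature": f, "fold_change": float(fc), "t": float(t),
                     "p": float(p), "degenerate": bool(degenerate)})
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"])
    table["kept"] = (table["fold_change"] > fc_min) & (table["q"] < alpha)
    return table
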