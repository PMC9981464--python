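"""Covariate-inclusion mediation scans.

For an outcome trait with a QTL, each candidate mediator is added as an
additive covariate to the QTL model and the LOD at the original peak
marker is recomputed on the subset of individuals where both traits are
observed (the original LOD is recomputed on the same subset, so the drop
is never an artifact of a sample-set change). The drop
``lod_adj - lod_orig`` is standardized against the drop distribution of a
declared null candidate set, and candidates at ``z <= -6`` (default) are
flagged as potential mediators. Because conditioning is symmetric, a
flagged mediator does not by itself establish the direction of the causal
effect; the bidirectional scan reports both directions without asserting
either.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .kinship import KinshipSet
from .lmm import fit_null, wls_rss
from .scan import Peak, _as_array, _covar_matrix
from .simulate import GenoProbs
from .transform import rankz

__all__ = [
    "MediationConfig",
    "MediationScan",
    "adjusted_lod",
    "mediation_scan",
    "group_mediation",
    "bidirectional_scan",
]

RECORD_COLUMNS = ["candidate", "n", "lod_orig", "lod_adj", "drop", "z", "flagged"]


@dataclass
class MediationConfig:
    z_threshold: float = -6.0
    min_overlap: int = 50
    null_set: object = "all"  # "all" or list of candidate ids
    robust: bool = False      # median/MAD null statistics instead of mean/sd
    min_group_size: int = 5
    suggestive_lod: float = 6.0
    sqrt_n_group: bool = False
    transform_candidates: bool = True
    h2_grid: int = 21


@dataclass
class MediationScan:
    """All mediation records for one (outcome, locus)."""

    outcome: str
    locus: dict
    records: pd.DataFrame  # RECORD_COLUMNS, sorted by z ascending
    null_mean: float
    null_sd: float
    skipped: list = field(default_factory=list)
    config: MediationConfig = field(default_factory=MediationConfig)

    @property
    def flagged(self) -> pd.DataFrame:
        return self.records[self.records["flagged"]]


def _eigen_subset(kin: KinshipSet | None, kinship_mode: str, chrom: str, mask: np.ndarray):
    if kin is None or kinship_mode == "none":
        return None
    K = kin.matrix_for(chrom, kinship_mode)
    if not mask.all():
        K = K[np.ix_(mask, mask)]
    lam, U = np.linalg.eigh(K)
    return np.maximum(lam, 0.0), U


def _lod_at_marker(yv, Xc, Z, eig, n_grid: int = 101) -> float:
    """LOD of the 8-founder marker model vs covariates-only null, with the
    null h2 re-fitted for this covariate set."""
    n = yv.shape[0]
    X0 = np.concatenate([np.ones((n, 1)), Xc], axis=1)
    nf = fit_null(yv, X0, eig, n_grid=n_grid)
    sw = 1.0 / np.sqrt(nf.weights)
    if nf.eigenvectors is not None:
        U = nf.eigenvectors
        yw = (U.T @ yv) * sw
        Xcw = (U.T @ Xc) * sw[:, None] if Xc.shape[1] else np.empty((n, 0))
        Zw = (U.T @ Z) * sw[:, None]
    else:
        yw = yv * sw
        Xcw = Xc * sw[:, None]
        Zw = Z * sw[:, None]
    rss1 = wls_rss(np.concatenate([Xcw, Zw], axis=1), yw)
    lod = (n / 2.0) * np.log10(max(nf.rss0, 1e-300) / max(rss1, 1e-300))
    return max(lod, 0.0)


def adjusted_lod(
    y_outcome,
    X,
    mediator,
    probs: GenoProbs,
    kin: KinshipSet | None,
    chrom: str,
    marker_idx: int,
    kinship_mode: str = "loco",
    min_overlap: int = 50,
    transform_mediator: bool = True,
    rescan: bool = False,
) -> dict | None:
    """LOD of the outcome at its peak marker with the mediator as covariate.

    Returns ``{'n', 'lod_orig', 'lod_adj', 'drop'}`` computed on the
    overlap subset, or ``None`` (record skipped) when the overlap is below
    ``min_overlap``. With ``rescan=True`` the adjusted LOD is the maximum
    over the whole chromosome instead of the single peak marker.
    """
    yv = _as_array(y_outcome, probs.individuals)
    med = _as_array(mediator, probs.individuals)
    Xc, _ = _covar_matrix(X, probs.individuals)
    mask = np.isfinite(yv) & np.isfinite(med)
    n = int(mask.sum())
    if n < min_overlap:
        return None
    yv, med, Xc = yv[mask], med[mask], Xc[mask]
    if transform_mediator:
        med = rankz(med)
    eig = _eigen_subset(kin, kinship_mode, chrom, mask)
    Z = probs.arrays[chrom][mask, :, marker_idx]
    lod_orig = _lod_at_marker(yv, Xc, Z, eig)
    Xm = np.concatenate([Xc, med[:, None]], axis=1)
    if rescan:
        lods = [
            _lod_at_marker(yv, Xm, probs.arrays[chrom][mask, :, j], eig)
            for j in range(probs.arrays[chrom].shape[2])
        ]
        lod_adj = float(np.max(lods))
    else:
        lod_adj = _lod_at_marker(yv, Xm, Z, eig)
    return {"n": n, "lod_orig": lod_orig, "lod_adj": lod_adj, "drop": lod_adj - lod_orig}


def mediation_scan(
    y_outcome,
    X,
    peak: Peak,
    candidates: pd.DataFrame,
    probs: GenoProbs,
    kin: KinshipSet | None = None,
    kinship_mode: str = "loco",
    config: MediationConfig | None = None,
) -> MediationScan:
    """Scan every candidate mediator against one outcome QTL.

    Drops are computed candidate by candidate (the result is independent
    of candidate order); the null mean/sd come from ``config.null_set``
    ("all" = every scanned candidate) and each record's
    ``z = (drop - mean_null) / sd_null`` is flagged at
    ``z <= config.z_threshold``. Records are sorted by z ascending.
    """
    config = config or MediationConfig()
    if peak.lod < config.suggestive_lod:
        raise ConfigError(
            f"outcome peak LOD {peak.lod:.2f} is below the suggestive threshold "
            f"{config.suggestive_lod}"
        )
    yv = _as_array(y_outcome, probs.individuals)
    Xc, _ = _covar_matrix(X, probs.individuals)
    chrom, marker_idx = peak.chrom, peak.marker_idx

    # group candidates by overlap pattern so the eigendecomposition and
    # the recomputed original LOD are shared
    cand_values = {c: _as_array(candidates[c], probs.individuals) for c in candidates.columns}
    base_mask = np.isfinite(yv)
    groups: dict[bytes, list[str]] = {}
    masks: dict[bytes, np.ndarray] = {}
    skipped: list[tuple[str, str]] = []
    for c, v in cand_values.items():
        mask = base_mask & np.isfinite(v)
        n = int(mask.sum())
        if n < config.min_overlap:
            skipped.append((c, f"overlap {n} below minimum {config.min_overlap}"))
            continue
        key = mask.tobytes()
        groups.setdefault(key, []).append(c)
        masks[key] = mask

    rows = []
    for key, cands in groups.items():
        mask = masks[key]
        n = int(mask.sum())
        ys, Xs = yv[mask], Xc[mask]
        eig = _eigen_subset(kin, kinship_mode, chrom, mask)
        Z = probs.arrays[chrom][mask, :, marker_idx]
        lod_orig = _lod_at_marker(ys, Xs, Z, eig, n_grid=config.h2_grid)
        for c in cands:
            med = cand_values[c][mask]
            if config.transform_candidates:
                try:
                    med = rankz(med)
                except DataError:
                    skipped.append((c, "degenerate candidate on overlap subset"))
                    continue
            Xm = np.concatenate([Xs, med[:, None]], axis=1)
            lod_adj = _lod_at_marker(ys, Xm, Z, eig, n_grid=config.h2_grid)
            rows.append(
                {
                    "candidate": c,
                    "n": n,
                    "lod_orig": lod_orig,
                    "lod_adj": lod_adj,
                    "drop": lod_adj - lod_orig,
                }
            )
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS[:5])
    if records.empty:
        raise DataError("no candidates survived the overlap filter")

    if config.null_set == "all":
        null_drops = records["drop"].to_numpy()
    else:
        null_drops = records.loc[records["candidate"].isin(list(config.null_set)), "drop"].to_numpy()
        if null_drops.size == 0:
            raise ConfigError("declared null set shares no candidates with the scan")
    if config.robust:
        null_mean = float(np.median(null_drops))
        null_sd = float(1.4826 * np.median(np.abs(null_drops - null_mean)))
    else:
        null_mean = float(np.mean(null_drops))
        null_sd = float(np.std(null_drops, ddof=1)) if null_drops.size > 1 else 0.0
    if null_sd == 0:
        raise DataError("degenerate null: zero spread of drops in the null candidate set")
    records["z"] = (records["drop"] - null_mean) / null_sd
    records["flagged"] = records["z"] <= config.z_threshold
    records = records.sort_values("z", ignore_index=True)
    return MediationScan(
        outcome=peak.trait,
        locus={"chrom": chrom, "pos_mbp": peak.pos_mbp, "marker_idx": marker_idx},
        records=records,
        null_mean=null_mean,
        null_sd=null_sd,
        skipped=skipped,
        config=config,
    )


def group_mediation(
    scan: MediationScan, group_map: dict | pd.Series, config: MediationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate mediation drops per candidate group (e.g. per taxon).

    The group z is the group's mean drop standardized by the scan's null
    statistics; by default without sqrt(n) inflation (conservative),
    switchable via ``config.sqrt_n_group``. Candidates without a mapping
    fall into ``"ungrouped"``. Returns (included groups sorted by z,
    excluded-groups report).
    """
    config = config or scan.config
    if isinstance(group_map, pd.Series):
        group_map = group_map.to_dict()
    rec = scan.records.copy()
    rec["group"] = [group_map.get(c, "ungrouped") for c in rec["candidate"]]
    rows = []
    for group, sub in rec.groupby("group"):
        n = len(sub)
        mean_drop = float(sub["drop"].mean())
        z = (mean_drop - scan.null_mean) / scan.null_sd
        if config.sqrt_n_group:
            z *= np.sqrt(n)
        rows.append({"group": group, "n_candidates": n, "mean_drop": mean_drop, "z": z})
    table = pd.DataFrame(rows)
    included = table[table["n_candidates"] >= config.min_group_size].sort_values(
        "z", ignore_index=True
    )
    excluded = table[table["n_candidates"] < config.min_group_size].reset_index(drop=True)
    return included, excluded


def bidirectional_scan(
    traitsA: pd.DataFrame,
    traitsB: pd.DataFrame,
    peaksA: list[Peak],
    peaksB: list[Peak],
    X,
    probs: GenoProbs,
    kin: KinshipSet | None = None,
    kinship_mode: str = "loco",
    config: MediationConfig | None = None,
    window_mbp: float = 4.0,
) -> dict:
    """Run the mediation scan in both directions over co-located peaks.

    For each A-peak co-locating (same chromosome, positions within
    ``window_mbp``) with a B-peak, B traits are scanned as candidate
    mediators of the A outcome, and vice versa; a trait never mediates
    itself. The direction of any causal effect cannot be inferred from
    conditioning alone, and the combined report says so.
    """
    config = config or MediationConfig()

    def _co_located(peak: Peak, others: list[Peak]) -> bool:
        return any(
            p.chrom == peak.chrom and abs(p.pos_mbp - peak.pos_mbp) <= window_mbp for p in others
        )

    def _run(peaks, outcomes, cands):
        scans = []
        other_peaks = peaksB if outcomes is traitsA else peaksA
        for peak in peaks:
            if peak.trait not in outcomes.columns or not _co_located(peak, other_peaks):
                continue
            use = cands.drop(columns=[peak.trait], errors="ignore")
            if use.shape[1] == 0:
                continue
            scans.append(
                mediation_scan(
                    outcomes[peak.trait], X, peak, use, probs, kin, kinship_mode, config
                )
            )
        return scans

    a_to_b = _run(peaksA, traitsA, traitsB)
    b_to_a = _run(peaksB, traitsB, traitsA)
    notice = (
        "no co-located peaks between the two trait sets"
        if not a_to_b and not b_to_a
        else "the direction of the causal effect between the paired traits "
        "cannot be directly inferred from conditioning"
    )
    return {"a_to_b": a_to_b, "b_to_a": b_to_a, "notice": notice}
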