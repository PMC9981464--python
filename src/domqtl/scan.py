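"""Haplotype-dosage genome scans, permutation thresholds, peaks, support
intervals, BLUP founder-allele effects and SNP association.

The scan statistic is the LOD score, the log10 likelihood ratio between
the marker model (covariates plus eight founder-dosage columns, which
replace the intercept since they sum to one) and the covariates-only
null, both fitted by weighted least squares at the null heritability of
the scanned chromosome's LOCO kinship. Genome-wide significance is
calibrated by permuting trait values against everything else and taking
order statistics of the per-permutation maximum LOD. QTL support
intervals are 95% Bayesian credible intervals over the chromosome's
posterior ``p_m \\propto 10^{LOD_m}``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from ._constants import FOUNDER_STRAINS, N_FOUNDERS
from .errors import ConfigError, DataError
from .kinship import KinshipSet
from .lmm import NullFit, fit_null, wls_rss
from .simulate import GenoProbs

__all__ = [
    "ScanResult",
    "Peak",
    "PermThresholds",
    "AlleleEffects",
    "SnpDef",
    "scan_genome",
    "find_peaks",
    "bayes_interval",
    "permutation_thresholds",
    "blup_effects",
    "scan_snps",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


@dataclass
class ScanResult:
    """Per-marker LOD curve for one trait."""

    trait: str
    table: pd.DataFrame  # columns: chrom, marker, pos_mbp, lod
    h2: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def lod(self, chrom: str | None = None) -> np.ndarray:
        if chrom is None:
            return self.table["lod"].to_numpy()
        return self.table.loc[self.table["chrom"] == chrom, "lod"].to_numpy()

    def positions(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "pos_mbp"].to_numpy()

    @property
    def max_lod(self) -> float:
        return float(self.table["lod"].max())


@dataclass
class Peak:
    """A called QTL: marker of maximum LOD plus its support interval."""

    trait: str
    chrom: str
    pos_mbp: float
    lod: float
    ci_lo: float
    ci_hi: float
    marker: str = ""
    marker_idx: int = 0


@dataclass
class PermThresholds:
    """Genome-wide LOD thresholds from a permutation null."""

    n_perm: int
    thresholds: dict[float, float]
    max_lods: np.ndarray

    def threshold(self, alpha: float) -> float:
        return self.thresholds[alpha]


@dataclass
class AlleleEffects:
    """BLUPs of the eight founder-haplotype effects at a locus."""

    effects: np.ndarray
    locus: dict = field(default_factory=dict)
    founders: tuple = FOUNDER_STRAINS
    shrunk_to_null: bool = False
    lambda_: float = 0.0
    h2: float = 0.0


@dataclass
class SnpDef:
    """A biallelic SNP given by its strain distribution pattern (SDP)."""

    id: str
    chrom: str
    pos_mbp: float
    sdp: np.ndarray  # 8-vector of 0/1

    def __post_init__(self) -> None:
        self.sdp = np.asarray(self.sdp, dtype=float)
        if self.sdp.shape != (N_FOUNDERS,):
            raise ConfigError(f"SDP must have length 8, got {self.sdp.shape}")

    @property
    def informative(self) -> bool:
        s = self.sdp.sum()
        return 0 < s < N_FOUNDERS


# ---------------------------------------------------------------------------
# helpers


def _as_array(y, individuals: list[str]) -> np.ndarray:
    if isinstance(y, pd.Series):
        return y.reindex(individuals).to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != len(individuals):
        raise DataError(f"trait has {y.shape[0]} values for {len(individuals)} individuals")
    return y


def _covar_matrix(X, individuals: list[str]) -> tuple[np.ndarray, list[str]]:
    if X is None:
        return np.empty((len(individuals), 0)), []
    if isinstance(X, pd.DataFrame):
        arr = X.reindex(individuals).to_numpy(dtype=float)
        names = list(X.columns)
    else:
        arr = np.asarray(X, dtype=float)
        names = [f"covar_{j}" for j in range(arr.shape[1])]
    if arr.shape[0] != len(individuals):
        raise DataError("covariate table does not align with individuals")
    if not np.all(np.isfinite(arr)):
        raise DataError("covariate rows must be complete (no missing values)")
    return arr, names


def _chrom_machinery(
    kin: KinshipSet | None,
    kinship_mode: str,
    chrom: str,
    mask: np.ndarray,
    cache: dict | None,
):
    """(eigenvalues, U) for the requested chromosome/mode, subset to mask."""
    if kin is None or kinship_mode == "none":
        return None
    full = bool(mask.all())
    if full:
        return kin.eigen_for(chrom, kinship_mode)
    K = kin.matrix_for(chrom, kinship_mode)
    Ksub = K[np.ix_(mask, mask)]
    lam, U = np.linalg.eigh(Ksub)
    return np.maximum(lam, 0.0), U


def _rotated_probs(
    probs: GenoProbs, chrom: str, U: np.ndarray | None, mask: np.ndarray, cache: dict | None, mode_key: str
) -> np.ndarray:
    """Founder-dosage array rotated into the kinship eigenbasis, (n, 8, m)."""
    full = bool(mask.all())
    key = ("rotprobs", mode_key, chrom)
    if full and cache is not None and key in cache:
        return cache[key]
    arr = probs.arrays[chrom][mask]
    if U is not None:
        n = arr.shape[0]
        arr = (U.T @ arr.reshape(n, -1)).reshape(arr.shape)
    if full and cache is not None:
        cache[key] = arr
    return arr


def _lod_curve(
    yr: np.ndarray,
    Xr0: np.ndarray,
    RP: np.ndarray,
    weights: np.ndarray,
    rss0: float,
) -> np.ndarray:
    """Per-marker LODs from rotated data at fixed weights.

    ``Xr0`` is the rotated null design including the intercept column
    first; the marker model swaps the intercept for the 8 founder columns.
    """
    n = yr.shape[0]
    sw = 1.0 / np.sqrt(weights)
    yw = yr * sw
    X0w = Xr0 * sw[:, None]
    Xcov_w = X0w[:, 1:]  # covariates without intercept
    m = RP.shape[2]
    lods = np.empty(m)
    for j in range(m):
        Xw = np.concatenate([Xcov_w, RP[:, :, j] * sw[:, None]], axis=1)
        rss1 = wls_rss(Xw, yw)
        lods[j] = (n / 2.0) * np.log10(max(rss0, 1e-300) / max(rss1, 1e-300))
    return np.maximum(lods, 0.0)


def _scan_arrays(
    y: np.ndarray,
    Xc: np.ndarray,
    probs: GenoProbs,
    kin: KinshipSet | None,
    kinship_mode: str,
    cache: dict | None,
    fixed_h2: dict[str, float] | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """LOD curves per chromosome (internal; inputs already masked/aligned)."""
    n = y.shape[0]
    X0 = np.concatenate([np.ones((n, 1)), Xc], axis=1)
    mask = np.ones(n, dtype=bool)
    lods: dict[str, np.ndarray] = {}
    h2s: dict[str, float] = {}
    for chrom in probs.chromosomes:
        eig = _chrom_machinery(kin, kinship_mode, chrom, mask, cache)
        if fixed_h2 is not None and chrom in fixed_h2 and eig is not None:
            lam, U = eig
            h2 = fixed_h2[chrom]
            w = h2 * lam + (1 - h2)
            yr, Xr0 = U.T @ y, U.T @ X0
            sw = 1.0 / np.sqrt(w)
            rss0 = wls_rss(Xr0 * sw[:, None], yr * sw)
        else:
            nf = fit_null(y, X0, eig)
            h2 = nf.h2
            w = nf.weights
            rss0 = nf.rss0
            if eig is None:
                yr, Xr0 = y, X0
            else:
                _, U = eig
                yr, Xr0 = U.T @ y, U.T @ X0
        U_rot = None if eig is None else eig[1]
        RP = _rotated_probs(probs, chrom, U_rot, mask, cache, kinship_mode)
        lods[chrom] = _lod_curve(yr, Xr0, RP, w, rss0)
        h2s[chrom] = h2
    return lods, h2s


# ---------------------------------------------------------------------------
# public operations


def scan_genome(
    y,
    X,
    probs: GenoProbs,
    kin: KinshipSet | None = None,
    kinship_mode: str = "loco",
    trait: str = "trait",
    cache: dict | None = None,
) -> ScanResult:
    """Genome scan of one trait against founder-haplotype dosages.

    ``y`` may be a Series (aligned by individual id) or an array in
    ``probs`` order; individuals with missing ``y`` are dropped for this
    trait. ``X`` holds additive covariates without an intercept. The null
    heritability is estimated once per (trait, LOCO chromosome) and held
    fixed across that chromosome's markers. Collinear founder columns at
    a marker are absorbed by the minimum-norm least-squares solution and
    never fail the scan.
    """
    yv = _as_array(y, probs.individuals)
    Xc, names = _covar_matrix(X, probs.individuals)
    mask = np.isfinite(yv)
    if mask.sum() < Xc.shape[1] + N_FOUNDERS + 2:
        raise DataError(f"too few non-missing values ({int(mask.sum())}) to scan trait {trait!r}")
    if not mask.all():
        # per-trait subset: kinship rows/cols are subset and re-decomposed
        sub = _subset_probs(probs, mask)
        kin_sub = _subset_kinship(kin, mask)
        return _finalize_scan(
            trait, sub, *_scan_arrays(yv[mask], Xc[mask], sub, kin_sub, kinship_mode, None),
            kinship_mode, int(mask.sum()),
        )
    lods, h2s = _scan_arrays(yv, Xc, probs, kin, kinship_mode, cache)
    return _finalize_scan(trait, probs, lods, h2s, kinship_mode, int(mask.sum()))


def _subset_probs(probs: GenoProbs, mask: np.ndarray) -> GenoProbs:
    return GenoProbs(
        individuals=[i for i, m in zip(probs.individuals, mask) if m],
        arrays={c: a[mask] for c, a in probs.arrays.items()},
        markers=probs.markers,
    )


def _subset_kinship(kin: KinshipSet | None, mask: np.ndarray) -> KinshipSet | None:
    if kin is None:
        return None
    ix = np.ix_(mask, mask)
    return KinshipSet(
        overall=kin.overall[ix],
        loco=None if kin.loco is None else {c: K[ix] for c, K in kin.loco.items()},
    )


def _finalize_scan(trait, probs, lods, h2s, kinship_mode, n_used) -> ScanResult:
    frames = []
    for chrom in probs.chromosomes:
        tab = probs.markers[chrom]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "marker": tab["marker"].to_numpy(),
                    "pos_mbp": tab["pos_mbp"].to_numpy(),
                    "lod": lods[chrom],
                }
            )
        )
    return ScanResult(
        trait=trait,
        table=pd.concat(frames, ignore_index=True),
        h2=h2s,
        meta={"kinship_mode": kinship_mode, "n_used": n_used},
    )


def bayes_interval(
    scan: ScanResult, chrom: str, coverage: float = 0.95
) -> tuple[float, float]:
    """Bayesian QTL support interval on one chromosome.

    Posterior mass at marker m is proportional to ``10^LOD_m``; the
    interval spans the central ``coverage`` mass, expanded if necessary to
    contain the peak marker.
    """
    sub = scan.table[scan.table["chrom"] == chrom]
    if sub.empty:
        raise DataError(f"chromosome {chrom!r} not present in scan")
    lod = sub["lod"].to_numpy()
    pos = sub["pos_mbp"].to_numpy()
    if len(pos) == 1:
        return float(pos[0]), float(pos[0])
    p = np.power(10.0, lod - lod.max())
    p /= p.sum()
    c = np.cumsum(p)
    lo_idx = int(np.searchsorted(c, (1 - coverage) / 2.0, side="left"))
    hi_idx = int(np.searchsorted(c, 1 - (1 - coverage) / 2.0, side="left"))
    hi_idx = min(hi_idx, len(pos) - 1)
    # expand only if no maximum-LOD marker already lies inside the interval
    # (with tied maxima the first/lowest-position one stands in for the peak)
    max_idx = np.flatnonzero(lod == lod.max())
    if not np.any((max_idx >= lo_idx) & (max_idx <= hi_idx)):
        peak = int(max_idx[0])
        lo_idx = min(lo_idx, peak)
        hi_idx = max(hi_idx, peak)
    return float(pos[lo_idx]), float(pos[hi_idx])


def find_peaks(scan: ScanResult, threshold: float, coverage: float = 0.95) -> list[Peak]:
    """One peak per chromosome: the marker of maximum LOD if it clears
    ``threshold`` (ties broken to the lower position)."""
    if threshold < 0:
        raise ConfigError(f"threshold must be >= 0, got {threshold}")
    peaks: list[Peak] = []
    for chrom in scan.table["chrom"].unique():
        sub = scan.table[scan.table["chrom"] == chrom].reset_index(drop=True)
        k = int(sub["lod"].to_numpy().argmax())
        lod = float(sub.loc[k, "lod"])
        if lod < threshold:
            continue
        lo, hi = bayes_interval(scan, chrom, coverage)
        peaks.append(
            Peak(
                trait=scan.trait,
                chrom=str(chrom),
                pos_mbp=float(sub.loc[k, "pos_mbp"]),
                lod=lod,
                ci_lo=lo,
                ci_hi=hi,
                marker=str(sub.loc[k, "marker"]),
                marker_idx=k,
            )
        )
    return peaks


def permutation_thresholds(
    y,
    X,
    probs: GenoProbs,
    kin: KinshipSet | None,
    n_perm: int,
    alphas=(0.05, 0.2),
    seed: int = 0,
    kinship_mode: str = "loco",
    refit_h2: bool = True,
    cache: dict | None = None,
) -> PermThresholds:
    """Genome-wide LOD thresholds by phenotype permutation.

    Trait values are shuffled against genotypes and covariates; each
    permutation records the genome-wide maximum LOD, and the threshold at
    level alpha is the ``floor(alpha * n_perm) + 1``-th largest maximum.
    By default the null heritability is re-estimated within each
    permutation; ``refit_h2=False`` reuses the unpermuted fit.
    """
    if n_perm < 100:
        raise ConfigError(f"need n_perm >= 100 for usable quantiles, got {n_perm}")
    for a in alphas:
        if a * n_perm < 1:
            raise ConfigError(f"alpha={a} with n_perm={n_perm} gives no exceedances to count")
    yv = _as_array(y, probs.individuals)
    Xc, _ = _covar_matrix(X, probs.individuals)
    if not np.all(np.isfinite(yv)):
        raise DataError("permutation thresholds require a complete trait vector")
    if cache is None:
        cache = {}
    rng = np.random.default_rng(seed)
    fixed = None
    if not refit_h2:
        _, fixed = _scan_arrays(yv, Xc, probs, kin, kinship_mode, cache)
    max_lods = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(yv))
        lods, _ = _scan_arrays(yv[perm], Xc, probs, kin, kinship_mode, cache, fixed_h2=fixed)
        max_lods[b] = max(float(v.max()) for v in lods.values())
    order = np.sort(max_lods)[::-1]
    thresholds = {float(a): float(order[int(np.floor(a * n_perm))]) for a in alphas}
    return PermThresholds(n_perm=n_perm, thresholds=thresholds, max_lods=max_lods)


# ---------------------------------------------------------------------------
# BLUP founder effects


def _blup_neg_loglik(log_lam: float, yw, Xw, Zw) -> float:
    lam = 10.0**log_lam
    n = yw.shape[0]
    A = Zw.T @ Zw
    M = np.eye(N_FOUNDERS) + lam * A
    Minv = np.linalg.inv(M)

    def vinv(v):
        return v - lam * (Zw @ (Minv @ (Zw.T @ v)))

    XtVX = Xw.T @ vinv(Xw)
    XtVy = Xw.T @ vinv(yw)
    c = np.linalg.lstsq(XtVX, XtVy, rcond=None)[0]
    r = yw - Xw @ c
    q = float(r @ vinv(r))
    if q <= 0:
        return np.inf
    sign, logdetV = np.linalg.slogdet(M)
    if sign <= 0:
        return np.inf
    s2 = q / n
    return 0.5 * (n * np.log(2 * np.pi * s2) + logdetV + n)


def _blup_solve(lam: float, yw, Xw, Zw) -> tuple[np.ndarray, np.ndarray]:
    A = Zw.T @ Zw
    M = np.eye(N_FOUNDERS) + lam * A
    Minv = np.linalg.inv(M)

    def vinv(v):
        return v - lam * (Zw @ (Minv @ (Zw.T @ v)))

    XtVX = Xw.T @ vinv(Xw)
    XtVy = Xw.T @ vinv(yw)
    c = np.linalg.lstsq(XtVX, XtVy, rcond=None)[0]
    u = lam * (Zw.T @ vinv(yw - Xw @ c))
    return u, c


def blup_effects(
    y,
    X,
    probs: GenoProbs,
    chrom: str,
    marker_idx: int,
    kin: KinshipSet | None = None,
    kinship_mode: str = "loco",
    locus: dict | None = None,
) -> AlleleEffects:
    """Founder allele effects at a marker as best linear unbiased predictors.

    The model adds a random founder effect ``u ~ N(0, sigma_u^2 I_8)`` with
    design Z = founder dosages on top of the null mixed model; the
    variance ratio ``lambda = sigma_u^2 / sigma_e^2`` is estimated by
    maximum likelihood on whitened data and ``E[u | y]`` is returned
    (ridge-shrunk GLS, shrinking toward zero relative to the fixed-effect
    estimates). If the optimum is at ``sigma_u^2 = 0`` a zero vector is
    returned with ``shrunk_to_null=True``.
    """
    yv = _as_array(y, probs.individuals)
    Xc, _ = _covar_matrix(X, probs.individuals)
    mask = np.isfinite(yv)
    yv, Xc = yv[mask], Xc[mask]
    Z = probs.arrays[chrom][mask, :, marker_idx]
    n = yv.shape[0]
    X0 = np.concatenate([np.ones((n, 1)), Xc], axis=1)
    eig = _chrom_machinery(kin, kinship_mode, chrom, mask[mask], None) if mask.all() else None
    if kin is not None and kinship_mode != "none" and not mask.all():
        K = kin.matrix_for(chrom, kinship_mode)[np.ix_(mask, mask)]
        lam_e, U = np.linalg.eigh(K)
        eig = (np.maximum(lam_e, 0.0), U)
    nf = fit_null(yv, X0, eig)
    sw = 1.0 / np.sqrt(nf.weights)
    if nf.eigenvectors is not None:
        U = nf.eigenvectors
        yw = (U.T @ yv) * sw
        Xw = (U.T @ X0) * sw[:, None]
        Zw = (U.T @ Z) * sw[:, None]
    else:
        yw, Xw, Zw = yv * sw, X0 * sw[:, None], Z * sw[:, None]

    grid = np.linspace(-6, 6, 25)
    vals = [_blup_neg_loglik(t, yw, Xw, Zw) for t in grid]
    k = int(np.argmin(vals))
    res = optimize.minimize_scalar(
        _blup_neg_loglik,
        bounds=(grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]),
        args=(yw, Xw, Zw),
        method="bounded",
        options={"xatol": 1e-4},
    )
    log_lam = float(res.x) if res.fun <= vals[k] else float(grid[k])
    lam = 10.0**log_lam
    if log_lam <= grid[0] + 1e-9:
        return AlleleEffects(
            effects=np.zeros(N_FOUNDERS),
            locus=locus or {"chrom": chrom, "marker_idx": marker_idx},
            shrunk_to_null=True,
            lambda_=0.0,
            h2=nf.h2,
        )
    u, _ = _blup_solve(lam, yw, Xw, Zw)
    return AlleleEffects(
        effects=u,
        locus=locus or {"chrom": chrom, "marker_idx": marker_idx},
        shrunk_to_null=False,
        lambda_=lam,
        h2=nf.h2,
    )


# ---------------------------------------------------------------------------
# SNP association


def scan_snps(
    y,
    X,
    probs: GenoProbs,
    snps: list[SnpDef],
    kin: KinshipSet | None = None,
    kinship_mode: str = "loco",
    trait: str = "trait",
) -> pd.DataFrame:
    """1-df LMM association of SDP-collapsed SNP dosages.

    The SNP dosage of individual i is ``sum_f sdp_f p_if`` at the marker
    nearest the SNP; the LOD compares [intercept, covariates, dosage]
    against the covariates-only null at the chromosome's null h2.
    Non-informative SDPs (all 0 or all 1) are skipped with a warning.
    """
    yv = _as_array(y, probs.individuals)
    Xc, _ = _covar_matrix(X, probs.individuals)
    mask = np.isfinite(yv)
    yv, Xc = yv[mask], Xc[mask]
    n = yv.shape[0]
    X0 = np.concatenate([np.ones((n, 1)), Xc], axis=1)
    rows = []
    null_cache: dict[str, tuple[NullFit, np.ndarray | None]] = {}
    for snp in snps:
        if not snp.informative:
            warnings.warn(f"SNP {snp.id}: non-informative SDP (all 0 or all 1); skipped")
            continue
        chrom = snp.chrom
        if chrom not in null_cache:
            if kin is not None and kinship_mode != "none":
                K = kin.matrix_for(chrom, kinship_mode)
                if not mask.all():
                    K = K[np.ix_(mask, mask)]
                lam_e, U = np.linalg.eigh(K)
                eig = (np.maximum(lam_e, 0.0), U)
            else:
                eig = None
            null_cache[chrom] = (fit_null(yv, X0, eig), None if eig is None else eig[1])
        nf, U = null_cache[chrom]
        pos = probs.markers[chrom]["pos_mbp"].to_numpy()
        j = int(np.argmin(np.abs(pos - snp.pos_mbp)))
        d = probs.arrays[chrom][mask, :, j] @ snp.sdp
        sw = 1.0 / np.sqrt(nf.weights)
        if U is not None:
            yw = (U.T @ yv) * sw
            X0w = (U.T @ X0) * sw[:, None]
            dw = (U.T @ d) * sw
        else:
            yw, X0w, dw = yv * sw, X0 * sw[:, None], d * sw
        rss1 = wls_rss(np.concatenate([X0w, dw[:, None]], axis=1), yw)
        lod = (n / 2.0) * np.log10(max(nf.rss0, 1e-300) / max(rss1, 1e-300))
        rows.append(
            {"snp": snp.id, "chrom": chrom, "pos_mbp": snp.pos_mbp, "lod": max(lod, 0.0), "trait": trait}
        )
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos_mbp", "lod", "trait"])
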