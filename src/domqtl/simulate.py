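"""Synthetic Diversity Outbred cohorts.

Generates founder-haplotype mosaics, haplotype-dosage probabilities,
covariate tables and trait matrices with planted additive 8-founder QTL,
a polygenic background of stated heritability, and Gaussian or
zero-inflated log-normal (abundance-like) noise. Mediation triplets — a
microbial trait M with a QTL and a lipid trait L either caused by M or
sharing the locus independently — provide ground truth for the mediation
scan.

The mosaic process is a continuous-time Markov ancestry model: breakpoints
arrive as a Poisson process at rate ``n_generations`` per Morgan along each
chromosome, and the founder after each breakpoint is drawn uniformly from
the eight founders (self-transitions are merged away). This yields
DO-like haplotype block lengths without modelling the actual outbreeding
pedigree. Haplotype-reconstruction uncertainty is emulated by blending the
true founder indicator with a uniform ``softness`` mass over the other
seven founders.

Every generator is bit-reproducible given its seed. Truth records
describing planted effects are returned (and serialized by the pipeline)
so recovery tests never re-derive ground truth from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._constants import FOUNDER_LETTERS, N_FOUNDERS
from .errors import ConfigError
from .genmap import GeneticMap

__all__ = [
    "FounderMosaic",
    "GenoProbs",
    "QTLSpec",
    "SimTraitSpec",
    "MediationSpec",
    "simulate_do_mosaics",
    "mosaics_to_probs",
    "simulate_covariates",
    "simulate_traits",
    "simulate_mediation_triplet",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class FounderMosaic:
    """Founder-ancestry mosaics for a cohort.

    ``segments[i][chrom]`` is a list of ``(start_mbp, end_mbp, founder_idx)``
    tuples tiling ``[0, chr_length]`` without gaps or overlaps.
    """

    individuals: list[str]
    segments: list[dict[str, list[tuple[float, float, int]]]]

    def founder_at(self, ind: int, chrom: str, pos_mbp: float) -> int:
        for start, end, f in self.segments[ind][chrom]:
            if start <= pos_mbp <= end:
                return f
        raise AssertionError(
            f"position {pos_mbp} on chromosome {chrom} not covered by any segment "
            "(mosaic invariant violated)"
        )

    def founder_letter_at(self, ind: int, chrom: str, pos_mbp: float) -> str:
        return FOUNDER_LETTERS[self.founder_at(ind, chrom, pos_mbp)]


@dataclass
class GenoProbs:
    """Per-chromosome haplotype-dosage probability arrays.

    ``arrays[chrom]`` has shape (n_individuals, 8, n_markers), founder axis
    in the fixed A..H order; each (individual, marker) slice sums to 1.
    ``markers[chrom]`` aligns the marker axis (columns ``marker``, ``pos_mbp``).
    """

    individuals: list[str]
    arrays: dict[str, np.ndarray]
    markers: dict[str, pd.DataFrame]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.arrays)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return sum(a.shape[2] for a in self.arrays.values())

    def validate(self, atol: float = 1e-9) -> None:
        for chrom, arr in self.arrays.items():
            if arr.ndim != 3 or arr.shape[0] != len(self.individuals) or arr.shape[1] != N_FOUNDERS:
                raise ConfigError(f"probability array for chromosome {chrom!r} has shape {arr.shape}")
            if arr.shape[2] != len(self.markers[chrom]):
                raise ConfigError(f"marker index misaligned on chromosome {chrom!r}")
            if arr.min() < -atol or arr.max() > 1 + atol:
                raise ConfigError(f"probabilities outside [0,1] on chromosome {chrom!r}")
            sums = arr.sum(axis=1)
            if np.abs(sums - 1.0).max() > atol:
                raise ConfigError(f"founder probabilities do not sum to 1 on chromosome {chrom!r}")

    def dosages_at(self, chrom: str, marker_idx: int) -> np.ndarray:
        """(n_individuals, 8) founder dosages at one marker."""
        return self.arrays[chrom][:, :, marker_idx]


@dataclass
class QTLSpec:
    """One planted additive QTL: locus, centred 8-founder effect vector and
    the fraction of trait variance it explains."""

    chrom: str
    pos_mbp: float
    beta: np.ndarray  # length 8; centred before scaling
    var_frac: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (N_FOUNDERS,):
            raise ConfigError(f"founder effect vector must have length 8, got {self.beta.shape}")
        if not 0 <= self.var_frac < 1:
            raise ConfigError(f"qtl variance fraction must be in [0,1), got {self.var_frac}")


@dataclass
class SimTraitSpec:
    """Recipe for one simulated trait.

    ``h2_polygenic`` is the variance fraction of the kinship-structured
    polygenic term; QTL fractions and ``h2_polygenic`` must sum below 1,
    the remainder being i.i.d. noise. ``noise_model='lognormal'`` maps the
    latent Gaussian trait through ``exp`` and zeroes a ``zero_inflation``
    fraction of samples, emulating compositional abundance data.
    """

    name: str
    qtls: list[QTLSpec] = field(default_factory=list)
    h2_polygenic: float = 0.0
    covar_effects: dict[str, float] = field(default_factory=dict)
    noise_model: Literal["gaussian", "lognormal"] = "gaussian"
    zero_inflation: float = 0.0
    #: explicit noise standard deviation; None derives it from the variance
    #: budget (1 - sum of QTL fractions - h2). noise_sd=0 with no effects
    #: yields a constant trait, flagged degenerate in the truth record.
    noise_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(q.var_frac for q in self.qtls) + self.h2_polygenic
        if total >= 1:
            raise ConfigError(
                f"trait {self.name!r}: QTL variance fractions + h2_polygenic = {total:.3f} >= 1"
            )
        if not 0 <= self.h2_polygenic < 1:
            raise ConfigError(f"h2_polygenic must be in [0,1), got {self.h2_polygenic}")
        if not 0 <= self.zero_inflation < 1:
            raise ConfigError(f"zero_inflation must be in [0,1), got {self.zero_inflation}")


@dataclass
class MediationSpec:
    """A microbe/lipid mediation triplet at one locus.

    ``mode='mediated'``: the lipid is ``alpha * M`` plus residual noise, so
    its locus association flows entirely through the microbe trait M.
    ``mode='independent'``: the lipid has its own QTL at the same marker
    with founder effects drawn independently of M's, and ``alpha`` must be 0.
    """

    chrom: str
    pos_mbp: float
    microbe: SimTraitSpec
    alpha: float
    lipid_residual_sd: float
    mode: Literal["mediated", "independent"]
    lipid_qtl_var_frac: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode == "mediated" and self.alpha == 0:
            raise ConfigError("mediated mode requires alpha != 0")
        if self.mode == "independent" and self.alpha != 0:
            raise ConfigError("independent mode requires alpha == 0")


# ---------------------------------------------------------------------------
# generators


def simulate_do_mosaics(
    gmap: GeneticMap, n_mice: int, n_generations: int, seed: int = 0
) -> FounderMosaic:
    """Draw founder-haplotype mosaics for ``n_mice`` individuals.

    Breakpoints arrive at rate ``n_generations`` per Morgan; the founder
    after each breakpoint is drawn uniformly from the seven *other*
    founders, so every breakpoint is visible and the expected breakpoint
    count per chromosome equals ``n_generations`` times the chromosome
    length in Morgans. ``n_generations=0`` gives single-founder
    chromosomes.
    """
    if n_mice < 1:
        raise ConfigError(f"n_mice must be >= 1, got {n_mice}")
    if n_generations < 0:
        raise ConfigError(f"n_generations must be >= 0, got {n_generations}")
    rng = np.random.default_rng(seed)
    mbp_per_morgan = 100.0 / gmap.cm_per_mbp
    individuals = [f"DO{i + 1:04d}" for i in range(n_mice)]
    segments: list[dict[str, list[tuple[float, float, int]]]] = []
    for _ in range(n_mice):
        per_chr: dict[str, list[tuple[float, float, int]]] = {}
        for chrom in gmap.chromosomes:
            length = gmap.lengths[chrom]
            segs: list[tuple[float, float, int]] = []
            seg_start = 0.0
            cur = 0.0
            founder = int(rng.integers(N_FOUNDERS))
            while True:
                if n_generations == 0:
                    nxt = length
                else:
                    gap_morgan = rng.exponential(1.0 / n_generations)
                    nxt = cur + gap_morgan * mbp_per_morgan
                if nxt >= length:
                    segs.append((seg_start, length, founder))
                    break
                # uniform draw over the 7 other founders keeps occupancy
                # exchangeable while making every breakpoint visible
                step = int(rng.integers(1, N_FOUNDERS))
                segs.append((seg_start, nxt, founder))
                founder = (founder + step) % N_FOUNDERS
                seg_start = cur = nxt
            per_chr[chrom] = segs
        segments.append(per_chr)
    return FounderMosaic(individuals=individuals, segments=segments)


def mosaics_to_probs(
    mosaic: FounderMosaic, gmap: GeneticMap, softness: float = 0.0
) -> GenoProbs:
    """Convert mosaics to haplotype-dosage probabilities at map markers.

    The true founder receives ``1 - softness``; the remaining mass is
    spread uniformly over the other seven founders.
    """
    if not 0 <= softness < 0.5:
        raise ConfigError(f"softness must be in [0, 0.5), got {softness}")
    n = len(mosaic.individuals)
    off = softness / (N_FOUNDERS - 1)
    arrays: dict[str, np.ndarray] = {}
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        m = len(pos)
        arr = np.full((n, N_FOUNDERS, m), off)
        for i in range(n):
            segs = mosaic.segments[i][chrom]
            ends = np.array([s[1] for s in segs])
            founders = np.array([s[2] for s in segs])
            idx = np.searchsorted(ends, pos, side="left")
            idx = np.minimum(idx, len(segs) - 1)
            arr[i, founders[idx], np.arange(m)] = 1.0 - softness
        arrays[chrom] = arr
    return GenoProbs(
        individuals=list(mosaic.individuals),
        arrays=arrays,
        markers={c: gmap.markers[c][["marker", "pos_mbp"]].copy() for c in gmap.chromosomes},
    )


def simulate_covariates(n_mice: int, n_waves: int = 5, seed: int = 0) -> pd.DataFrame:
    """Covariate table with sex, days on diet and cohort-wave dummies.

    Sex is balanced to within one mouse of 50/50 and encoded 0/1; days on
    diet is an integer count; waves are encoded as dummy columns
    ``wave_2 .. wave_<n_waves>`` against wave 1.
    """
    if n_mice < 1 or n_waves < 1:
        raise ConfigError(f"need n_mice >= 1 and n_waves >= 1 (got {n_mice}, {n_waves})")
    rng = np.random.default_rng(seed)
    sex = np.zeros(n_mice, dtype=int)
    sex[: n_mice // 2] = 1
    rng.shuffle(sex)
    days = rng.integers(60, 130, size=n_mice)
    wave = 1 + (rng.permutation(n_mice) % n_waves)
    table = pd.DataFrame(
        {"sex": sex, "days_on_diet": days},
        index=[f"DO{i + 1:04d}" for i in range(n_mice)],
    )
    for w in range(2, n_waves + 1):
        table[f"wave_{w}"] = (wave == w).astype(int)
    table.index.name = "id"
    return table


def _scaled_component(x: np.ndarray, target_var: float) -> np.ndarray:
    """Centre and rescale ``x`` to an exact empirical variance."""
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return x * np.sqrt(target_var) / sd


def simulate_traits(
    probs: GenoProbs,
    gmap: GeneticMap,
    covars: pd.DataFrame | None,
    specs: list[SimTraitSpec],
    kinship: np.ndarray | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate traits with planted QTL, polygenic background and noise.

    The latent trait is a sum of components each standardized to its exact
    target variance fraction (QTL terms ``P_marker @ beta``, a polygenic
    draw with covariance proportional to the genome-wide kinship, i.i.d.
    noise), plus covariate effects. Returns the trait matrix (individuals
    x traits) and one truth record per trait with the snapped marker,
    scaled effects and realized variance fractions.

    ``kinship`` (overall genome kinship) is computed on the fly when any
    spec has ``h2_polygenic > 0`` and none is given.
    """
    n = probs.n_individuals
    need_kinship = any(s.h2_polygenic > 0 for s in specs)
    if need_kinship and kinship is None:
        from .kinship import calc_kinship

        kinship = calc_kinship(probs, mode="overall").overall
    chol = None
    if need_kinship:
        assert kinship is not None
        chol = np.linalg.cholesky(kinship + 1e-8 * np.eye(n))

    values: dict[str, np.ndarray] = {}
    truth: list[dict] = []
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        y = np.zeros(n)
        qtl_truth = []
        for q in spec.qtls:
            idx = gmap.nearest_marker(q.chrom, q.pos_mbp)
            beta_c = q.beta - q.beta.mean()
            g = probs.dosages_at(q.chrom, idx) @ beta_c
            g = _scaled_component(g, q.var_frac)
            y += g
            qtl_truth.append(
                {
                    "chrom": q.chrom,
                    "pos_mbp": float(gmap.positions(q.chrom)[idx]),
                    "marker_idx": idx,
                    "marker": str(gmap.markers[q.chrom]["marker"].iloc[idx]),
                    "beta": beta_c.tolist(),
                    "var_frac": q.var_frac,
                }
            )
        if spec.h2_polygenic > 0:
            u = chol @ rng.standard_normal(n)
            y += _scaled_component(u, spec.h2_polygenic)
        if spec.noise_sd is not None:
            if spec.noise_sd > 0:
                y += spec.noise_sd * rng.standard_normal(n)
        else:
            noise_var = 1.0 - sum(q.var_frac for q in spec.qtls) - spec.h2_polygenic
            if noise_var > 0:
                y += _scaled_component(rng.standard_normal(n), noise_var)
        latent_var = float(np.var(y))
        degenerate = latent_var < 1e-12
        if spec.covar_effects:
            if covars is None:
                raise ConfigError(f"trait {spec.name!r} has covariate effects but no covariates given")
            for col, coef in spec.covar_effects.items():
                if col not in covars.columns:
                    raise ConfigError(f"unknown covariate {col!r} for trait {spec.name!r}")
                y = y + coef * covars[col].to_numpy(dtype=float)
        if spec.noise_model == "lognormal":
            y = np.exp(y)
            if spec.zero_inflation > 0:
                y[rng.random(n) < spec.zero_inflation] = 0.0
        values[spec.name] = y
        truth.append(
            {
                "trait": spec.name,
                "qtls": qtl_truth,
                "h2_polygenic": spec.h2_polygenic,
                "noise_model": spec.noise_model,
                "zero_inflation": spec.zero_inflation,
                "degenerate": bool(degenerate),
                "realized_var_fracs": {
                    t["marker"]: t["var_frac"] for t in qtl_truth
                },
            }
        )
    traits = pd.DataFrame(values, index=probs.individuals)
    traits.index.name = "id"
    return traits, truth


def simulate_mediation_triplet(
    probs: GenoProbs, gmap: GeneticMap, spec: MediationSpec
) -> tuple[pd.Series, pd.Series, dict]:
    """Simulate a (microbe M, lipid L) pair sharing a locus.

    In mediated mode ``L = alpha * M + eps``; in independent mode L gets
    its own QTL at the same marker with effects drawn independently of M's.
    """
    if spec.chrom not in gmap.lengths:
        raise ConfigError(f"mediation locus chromosome {spec.chrom!r} not on map")
    microbe_df, truth_m = simulate_traits(probs, gmap, None, [spec.microbe])
    m = microbe_df.iloc[:, 0]
    rng = np.random.default_rng(spec.seed + 1)
    n = probs.n_individuals
    if spec.mode == "mediated":
        lipid = spec.alpha * m.to_numpy() + spec.lipid_residual_sd * rng.standard_normal(n)
        truth_l: dict = {"mode": "mediated", "alpha": spec.alpha}
    else:
        var_frac = (
            spec.lipid_qtl_var_frac
            if spec.lipid_qtl_var_frac is not None
            else (spec.microbe.qtls[0].var_frac if spec.microbe.qtls else 0.2)
        )
        beta = rng.standard_normal(N_FOUNDERS)
        idx = gmap.nearest_marker(spec.chrom, spec.pos_mbp)
        g = probs.dosages_at(spec.chrom, idx) @ (beta - beta.mean())
        g = _scaled_component(g, var_frac)
        noise = _scaled_component(rng.standard_normal(n), 1.0 - var_frac)
        lipid = g + noise
        if spec.lipid_residual_sd > 0:
            lipid = lipid + spec.lipid_residual_sd * rng.standard_normal(n)
        truth_l = {"mode": "independent", "alpha": 0.0, "lipid_beta": (beta - beta.mean()).tolist()}
    lipid_s = pd.Series(lipid, index=probs.individuals, name="lipid")
    truth = {
        "locus": {"chrom": spec.chrom, "pos_mbp": spec.pos_mbp,
                  "marker_idx": gmap.nearest_marker(spec.chrom, spec.pos_mbp)},
        "microbe": truth_m[0],
        "lipid": truth_l,
    }
    return m.rename("microbe"), lipid_s, truth
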