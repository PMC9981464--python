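"""Genetic relationship (kinship) matrices from haplotype dosages.

The similarity between individuals i and j is the average over markers of
the founder-probability inner product, ``K[i,j] = (1/M) sum_m sum_f
p_imf p_jmf``, rescaled so the mean diagonal equals 1. The
leave-one-chromosome-out (LOCO) variant excludes the scanned chromosome's
markers, which controls population structure without absorbing the tested
locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .simulate import GenoProbs

__all__ = ["KinshipSet", "calc_kinship", "calc_kinship_loco"]


def _rescale(K: np.ndarray) -> np.ndarray:
    mean_diag = np.mean(np.diag(K))
    if mean_diag <= 0:
        return K
    return K / mean_diag


@dataclass
class KinshipSet:
    """Overall and (optionally) per-chromosome LOCO kinship matrices.

    Eigendecompositions are cached lazily per chromosome key (``None`` for
    the overall matrix) because every trait scanned against the same
    genotypes reuses them.
    """

    overall: np.ndarray
    loco: dict[str, np.ndarray] | None = None
    _eig_cache: dict = field(default_factory=dict, repr=False)

    def matrix_for(self, chrom: str | None, mode: str = "loco") -> np.ndarray | None:
        if mode == "none":
            return None
        if mode == "overall" or self.loco is None:
            return self.overall
        if mode == "loco":
            if chrom is None:
                return self.overall
            return self.loco[chrom]
        raise ConfigError(f"unknown kinship mode {mode!r}")

    def eigen_for(self, chrom: str | None, mode: str = "loco"):
        """Cached ``(eigenvalues, eigenvectors)`` of the requested matrix."""
        key = (mode, chrom if mode == "loco" else None)
        if key not in self._eig_cache:
            K = self.matrix_for(chrom, mode)
            if K is None:
                self._eig_cache[key] = None
            else:
                lam, U = np.linalg.eigh(K)
                self._eig_cache[key] = (np.maximum(lam, 0.0), U)
        return self._eig_cache[key]


def calc_kinship(probs: GenoProbs, mode: str = "loco") -> KinshipSet:
    """Compute kinship matrices from genotype probabilities.

    ``mode='loco'`` (requires >=2 chromosomes) returns per-chromosome
    leave-out matrices alongside the overall matrix; ``mode='overall'``
    returns only the all-chromosome matrix.
    """
    chroms = probs.chromosomes
    if not chroms:
        raise ConfigError("no chromosomes in genotype probabilities")
    if mode == "loco" and len(chroms) < 2:
        raise ConfigError(
            "LOCO kinship needs >=2 chromosomes; use mode='overall' for a single chromosome"
        )
    n = probs.n_individuals
    cross: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for chrom in chroms:
        arr = probs.arrays[chrom]  # (n, 8, m)
        flat = arr.reshape(n, -1)
        cross[chrom] = flat @ flat.T
        counts[chrom] = arr.shape[2]
    total = sum(cross.values())
    m_total = sum(counts.values())
    overall = _rescale(total / m_total)
    loco = None
    if mode == "loco":
        loco = {}
        for chrom in chroms:
            m_rest = m_total - counts[chrom]
            loco[chrom] = _rescale((total - cross[chrom]) / m_rest)
    return KinshipSet(overall=overall, loco=loco)


def calc_kinship_loco(probs: GenoProbs) -> KinshipSet:
    """LOCO kinship (convenience wrapper around :func:`calc_kinship`)."""
    return calc_kinship(probs, mode="loco")
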