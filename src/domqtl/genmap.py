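"""Genetic maps for simulated genomes.

A :class:`GeneticMap` carries an ordered set of chromosomes, each with a
physical length in Mbp and a strictly increasing list of marker positions.
Genetic positions (cM) are derived from physical positions via a constant
map density (default 0.5 cM/Mbp, the mouse genome-average scale), so
1 Morgan corresponds to ``100 / density`` Mbp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._constants import DEFAULT_CM_PER_MBP
from .errors import ConfigError


@dataclass
class GeneticMap:
    """Chromosome lengths and ordered marker positions.

    Attributes
    ----------
    lengths : dict
        Chromosome name -> length in Mbp (all > 0).
    markers : dict
        Chromosome name -> DataFrame with columns ``marker`` (str id),
        ``pos_mbp`` and ``pos_cm``, sorted by position.
    cm_per_mbp : float
        Map density used to convert Mbp to cM.
    """

    lengths: dict[str, float]
    markers: dict[str, pd.DataFrame]
    cm_per_mbp: float = DEFAULT_CM_PER_MBP

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ConfigError(f"chromosome {chrom!r} has non-positive length {length}")
            tab = self.markers[chrom]
            pos = tab["pos_mbp"].to_numpy()
            if len(pos) < 2:
                raise ConfigError(f"chromosome {chrom!r} has fewer than 2 markers")
            if not np.all(np.diff(pos) > 0):
                raise ConfigError(f"marker positions on chromosome {chrom!r} are not strictly increasing")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def n_markers(self) -> int:
        return sum(len(t) for t in self.markers.values())

    def positions(self, chrom: str) -> np.ndarray:
        return self.markers[chrom]["pos_mbp"].to_numpy()

    def chr_length_morgans(self, chrom: str) -> float:
        return self.lengths[chrom] * self.cm_per_mbp / 100.0

    def nearest_marker(self, chrom: str, pos_mbp: float) -> int:
        """Index (0-based, within chromosome) of the marker closest to ``pos_mbp``."""
        if chrom not in self.lengths:
            raise ConfigError(f"chromosome {chrom!r} not on map")
        return int(np.argmin(np.abs(self.positions(chrom) - pos_mbp)))


def make_genetic_map(
    n_chr: int,
    markers_per_chr: int,
    chr_length_mbp: float = 100.0,
    seed: int = 0,
    cm_per_mbp: float = DEFAULT_CM_PER_MBP,
) -> GeneticMap:
    """Build a synthetic map with near-evenly spaced, jittered markers.

    Markers are placed at the centres of ``markers_per_chr`` equal bins and
    jittered by less than half the bin width, so positions are strictly
    increasing and lie in (0, chr_length_mbp]. Deterministic given ``seed``.
    """
    if n_chr < 1 or markers_per_chr < 2 or chr_length_mbp <= 0:
        raise ConfigError(
            "need n_chr >= 1, markers_per_chr >= 2 and chr_length_mbp > 0 "
            f"(got {n_chr}, {markers_per_chr}, {chr_length_mbp})"
        )
    rng = np.random.default_rng(seed)
    spacing = chr_length_mbp / markers_per_chr
    lengths: dict[str, float] = {}
    markers: dict[str, pd.DataFrame] = {}
    for c in range(1, n_chr + 1):
        chrom = str(c)
        base = (np.arange(markers_per_chr) + 0.5) * spacing
        jitter = rng.uniform(-0.45, 0.45, size=markers_per_chr) * spacing
        pos = base + jitter
        lengths[chrom] = float(chr_length_mbp)
        markers[chrom] = pd.DataFrame(
            {
                "marker": [f"c{chrom}_m{i + 1}" for i in range(markers_per_chr)],
                "pos_mbp": pos,
                "pos_cm": pos * cm_per_mbp,
            }
        )
    return GeneticMap(lengths=lengths, markers=markers, cm_per_mbp=cm_per_mbp)
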