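"""Ornithine-lipid composition, formula and exact-mass bookkeeping.

An ornithine lipid (OL) is a phosphorus-free bacterial membrane lipid in
which a 3-hydroxy fatty acid is amide-linked to the ornithine headgroup
and a second fatty acid is esterified to the 3-hydroxy group. A sum
composition such as ``OL 30:0`` gives total acyl carbons and double bonds;
a split notation ``OL 15:0_15:0`` assigns them to the two chains.

The elemental formula is assembled by condensation bookkeeping::

    ornithine C5H12N2O2
  + 3-hydroxy fatty acid  CnH(2n-2d)O3
  + fatty acid            CmH(2m-2d')O2
  - 2 H2O                 (one per amide/ester linkage)

with n+m the total carbons and d+d' the total double bonds. The
monoisotopic mass is the sum of monoisotopic atomic masses; two
protonation conventions are exposed because mass lists in the literature
mix them: ``M+H_atom`` adds the mass of a neutral hydrogen atom, while
``M+H_proton`` adds a bare proton (H minus one electron), about 0.55 mDa
lighter. ``M+H_atom`` is the package default for matching printed
"[M]+ calculated" values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ConfigError, DomqtlError, UnsupportedLipidClassError

__all__ = [
    "LipidComposition",
    "ol_formula",
    "monoisotopic_mass",
    "formula_to_string",
    "parse_formula",
]

# monoisotopic atomic masses (Da), CODATA/AME-derived values
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
}
ELECTRON_MASS = 0.000548579909
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

ADDUCTS = ("M", "M+H_atom", "M+H_proton", "M-H")

_COMP_RE = re.compile(r"^(?P<cls>[A-Za-z]+)\s+(?P<chains>\d+:\d+(?:_\d+:\d+)*)$")
_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class LipidComposition:
    """A lipid sum composition, optionally with an explicit acyl split."""

    lipid_class: str
    carbons: int
    double_bonds: int
    acyl_split: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.carbons <= 0:
            raise ConfigError(f"total acyl carbons must be > 0, got {self.carbons}")
        if self.double_bonds < 0:
            raise ConfigError(f"double bonds must be >= 0, got {self.double_bonds}")
        if self.acyl_split is not None:
            if sum(c for c, _ in self.acyl_split) != self.carbons:
                raise ConfigError(
                    f"split carbons {self.acyl_split} do not sum to total {self.carbons}"
                )
            if sum(d for _, d in self.acyl_split) != self.double_bonds:
                raise ConfigError(
                    f"split double bonds {self.acyl_split} do not sum to total {self.double_bonds}"
                )

    @classmethod
    def parse(cls, text: str) -> "LipidComposition":
        """Parse ``"OL 30:0"`` or split notation ``"OL 15:0_15:0"``."""
        m = _COMP_RE.match(text.strip())
        if m is None:
            raise ConfigError(f"cannot parse lipid composition {text!r}")
        chains = [tuple(int(x) for x in ch.split(":")) for ch in m.group("chains").split("_")]
        carbons = sum(c for c, _ in chains)
        dbs = sum(d for _, d in chains)
        split = tuple((c, d) for c, d in chains) if len(chains) > 1 else None
        return cls(m.group("cls"), carbons, dbs, split)

    def __str__(self) -> str:
        if self.acyl_split:
            chains = "_".join(f"{c}:{d}" for c, d in self.acyl_split)
            return f"{self.lipid_class} {chains}"
        return f"{self.lipid_class} {self.carbons}:{self.double_bonds}"


def _add(formula: dict[str, int], other: dict[str, int], scale: int = 1) -> None:
    for el, k in other.items():
        formula[el] = formula.get(el, 0) + scale * k


def ol_formula(comp: LipidComposition | str) -> dict[str, int]:
    """Elemental formula of a di-acyl ornithine lipid from its composition.

    Accepts a :class:`LipidComposition` (class tag must be ``OL``) or a
    string like ``"OL 30:0"``. The split of carbons/double bonds between
    the two chains does not affect the formula (constant-sum bookkeeping),
    so an unsplit sum composition is enough.
    """
    if isinstance(comp, str):
        comp = LipidComposition.parse(comp)
    if comp.lipid_class.upper() != "OL":
        raise UnsupportedLipidClassError(
            f"formula bookkeeping implemented for ornithine lipids only, got {comp.lipid_class!r}"
        )
    n, d = comp.carbons, comp.double_bonds
    if comp.acyl_split is not None:
        for c_i, _ in comp.acyl_split:
            if c_i < 3:
                raise ConfigError(f"acyl chain with {c_i} carbons is not a fatty acid")
    formula: dict[str, int] = {}
    _add(formula, {"C": 5, "H": 12, "N": 2, "O": 2})          # ornithine
    _add(formula, {"C": n, "H": 2 * n - 2 * d, "O": 5})        # two acyls (O3 + O2)
    _add(formula, {"H": 2, "O": 1}, scale=-2)                  # two condensations
    if any(v < 0 for v in formula.values()):
        raise ConfigError(f"composition {comp} yields a negative atom count")
    return formula


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style formula string like ``"C35H68N2O5"``."""
    formula: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos:
            raise DomqtlError(f"cannot parse formula {text!r}")
        pos = m.end()
        if m.group(0) == "":
            continue
        el = m.group(1)
        formula[el] = formula.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(text) or not formula:
        raise DomqtlError(f"cannot parse formula {text!r}")
    return formula


def formula_to_string(formula: dict[str, int]) -> str:
    """Hill notation: C, H, then other elements alphabetically."""
    parts = []
    for el in ["C", "H"] + sorted(e for e in formula if e not in ("C", "H")):
        k = formula.get(el, 0)
        if k:
            parts.append(el + (str(k) if k != 1 else ""))
    return "".join(parts)


def monoisotopic_mass(formula: dict[str, int] | str, adduct: str = "M") -> float:
    """Monoisotopic mass (Da) of a formula under an adduct convention.

    ``adduct`` is one of ``M`` (neutral), ``M+H_atom`` (+1.007825, a
    hydrogen atom), ``M+H_proton`` (+1.007276, a proton; the physically
    correct [M+H]+ ion mass) or ``M-H`` (deprotonated anion).
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if adduct not in ADDUCTS:
        raise ConfigError(f"unknown adduct {adduct!r}; choose from {ADDUCTS}")
    mass = 0.0
    for el, k in formula.items():
        if el not in MONOISOTOPIC_MASS:
            raise DomqtlError(f"element {el!r} not in the monoisotopic mass table (C,H,N,O)")
        mass += MONOISOTOPIC_MASS[el] * k
    if adduct == "M+H_atom":
        mass += MONOISOTOPIC_MASS["H"]
    elif adduct == "M+H_proton":
        mass += PROTON_MASS
    elif adduct == "M-H":
        mass -= PROTON_MASS
    return mass
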