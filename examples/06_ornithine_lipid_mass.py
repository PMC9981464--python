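"""Ornithine-lipid sum compositions, elemental formulas and exact masses.

OL 30:0 (equivalently the di-C15:0 split OL 15:0_15:0) is the headline
species: ornithine amide-linked to 3-hydroxy-C15:0, esterified with
C15:0. The protonated exact mass under the hydrogen-atom convention
matches the calculated [M]+ value quoted for the synthetic standard.
"""

from domqtl.lipids import (
    LipidComposition, formula_to_string, monoisotopic_mass, ol_formula,
)

for comp in ["OL 15:0_15:0", "OL 30:0", "OL 31:0", "OL 32:0"]:
    formula = ol_formula(comp)
    m = monoisotopic_mass(formula)
    mh = monoisotopic_mass(formula, adduct="M+H_atom")
    print(f"{comp:>12}: {formula_to_string(formula):>11}  "
          f"M = {m:.4f} Da  [M+H] = {mh:.4f} Da")

f = ol_formula("OL 30:0")
print(f"\nH-atom vs proton convention for OL 30:0: "
      f"{monoisotopic_mass(f, 'M+H_atom'):.4f} vs "
      f"{monoisotopic_mass(f, 'M+H_proton'):.4f} Da "
      "(one electron mass apart; the H-atom value matches printed "
      "'calculated' masses)")
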