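"""Monoisotopic peptide and fragment-ion mass arithmetic.

Residue masses are derived from Biopython's monoisotopic free-amino-acid
weights minus one water. Cysteine is treated as carbamidomethylated
(+57.02146 Da fixed modification), matching iodoacetamide alkylation
during sample preparation.
"""

from __future__ import annotations

from Bio.Data.IUPACData import monoisotopic_protein_weights

PROTON = 1.00728
WATER = 18.01056
CARBAMIDOMETHYL = 57.02146

#: Monoisotopic residue masses (free amino acid minus water).
RESIDUE_MASS: dict[str, float] = {
    aa: w - 18.010565 for aa, w in monoisotopic_protein_weights.items()
}


def peptide_neutral_mass(peptide: str, *, fixed_cam: bool = True) -> float:
    """Neutral monoisotopic mass of a peptide (residues + one water)."""
    mass = WATER
    for aa in peptide:
        mass += RESIDUE_MASS[aa]
        if fixed_cam and aa == "C":
            mass += CARBAMIDOMETHYL
    return mass


def _residue(aa: str, fixed_cam: bool) -> float:
    m = RESIDUE_MASS[aa]
    if fixed_cam and aa == "C":
        m += CARBAMIDOMETHYL
    return m


def b_ions(peptide: str, *, fixed_cam: bool = True) -> list[float]:
    """Singly charged b-ion m/z values b1..b(n-1)."""
    out, acc = [], PROTON
    for aa in peptide[:-1]:
        acc += _residue(aa, fixed_cam)
        out.append(acc)
    return out

def y_ions(peptide: str, *, fixed_cam: bool = True) -> list[float]:
    """Singly charged y-ion m/z values y1..y(n-1)."""
    out, acc = [], PROTON + WATER
    for aa in reversed(peptide[1:]):
        acc += _residue(aa, fixed_cam)
        out.append(acc)
    return out


def fragment_ladder(peptide: str, *, fixed_cam: bool = True) -> list[float]:
    """All singly charged b- and y-ion m/z values for a peptide."""
    return b_ions(peptide, fixed_cam=fixed_cam) + y_ions(peptide, fixed_cam=fixed_cam)
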