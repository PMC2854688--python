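"""Crystal-form bookkeeping: cell volume, Matthews coefficient, solvent content.

The Matthews coefficient V_m is the crystal volume per Dalton of
macromolecule (Å³/Da); assuming a protein partial specific volume of
0.74 cm³/g it converts to the solvent fraction as

    solvent = 1 - 1.23 / V_m.

Protein crystals usually fall between V_m 1.7 (very tight packing, ~28%
solvent) and 3.5; the MLLE/PAM2 co-crystals sit at the tight end of that
range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
from Bio.SeqUtils import molecular_weight

__all__ = [
    "PROTEIN_DENSITY_CONSTANT",
    "CrystalForm",
    "MatthewsResult",
    "cell_volume",
    "matthews",
    "sequence_mw",
    "space_group_multiplicity",
]

#: Divisor converting V_m to protein volume fraction (Å³/Da), equivalent
#: to a partial specific volume of 0.74 cm³/g.
PROTEIN_DENSITY_CONSTANT = 1.23


def space_group_multiplicity(symbol: str) -> int:
    """Number of asymmetric units per cell for a space-group symbol.

    Accepts both compact ("P21212") and spaced ("P 21 21 2") symbols.
    """
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise ValueError(f"unknown space group symbol {symbol!r}")
    return len(list(sg.operations()))


@dataclass(frozen=True)
class CrystalForm:
    """Unit cell, space group and asymmetric-unit content mass.

    ``z`` defaults to the space-group multiplicity (one complex per
    asymmetric unit); override for multiple copies.
    """

    space_group: str
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    complex_mw: float | None = None
    z: int | None = None

    def __post_init__(self) -> None:
        for name, edge in (("a", self.a), ("b", self.b), ("c", self.c)):
            if not (math.isfinite(edge) and edge > 0):
                raise ValueError(f"cell edge {name} must be positive, got {edge!r}")
        if self.complex_mw is not None and self.complex_mw <= 0:
            raise ValueError("complex molecular weight must be positive")
        # sanity on the orthorhombic groups this package is used with
        sg = gemmi.find_spacegroup_by_name(self.space_group)
        if sg is not None and sg.crystal_system_str() == "orthorhombic":
            if not all(abs(ang - 90.0) < 1e-9 for ang in (self.alpha, self.beta, self.gamma)):
                raise ValueError("orthorhombic cells require 90 degree angles")

    @property
    def multiplicity(self) -> int:
        if self.z is not None:
            return self.z
        return space_group_multiplicity(self.space_group)


def cell_volume(form: CrystalForm) -> float:
    """Unit-cell volume in Å³ (general triclinic closed form).

    Reduces to a·b·c for orthorhombic cells.
    """
    cell = gemmi.UnitCell(form.a, form.b, form.c, form.alpha, form.beta, form.gamma)
    return cell.volume


@dataclass(frozen=True)
class MatthewsResult:
    """Matthews coefficient and derived solvent fraction."""

    vm: float
    solvent_fraction: float

    @property
    def solvent_percent(self) -> float:
        return 100.0 * self.solvent_fraction


def matthews(form: CrystalForm) -> MatthewsResult:
    """Matthews coefficient V_m = V_cell / (z × MW) and solvent fraction.

    Physical protein crystals require V_m > 1.23 Å³/Da (zero solvent);
    smaller values mean the assumed content mass cannot fit the cell.
    """
    if form.complex_mw is None or form.complex_mw <= 0:
        raise ValueError("matthews() requires a positive complex molecular weight")
    vm = cell_volume(form) / (form.multiplicity * form.complex_mw)
    return MatthewsResult(vm=vm, solvent_fraction=1.0 - PROTEIN_DENSITY_CONSTANT / vm)


def sequence_mw(sequence: str, termini: str = "water") -> float:
    """Average molecular weight (Da) of a peptide sequence.

    Residue masses summed with loss of one water per peptide bond;
    ``termini='water'`` (default) adds one water back for the free
    N/C termini, ``termini='residue'`` reports the bare residue-mass sum
    (useful for summing chain segments).
    """
    if not sequence:
        raise ValueError("empty sequence has no molecular weight")
    try:
        mw = molecular_weight(sequence, seq_type="protein")
    except ValueError as exc:
        raise ValueError(f"cannot compute mass: {exc}") from exc
    if termini == "water":
        return mw
    if termini == "residue":
        return mw - 18.0153
    raise ValueError(f"unknown termini policy {termini!r}")
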