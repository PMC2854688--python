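"""Synthetic data generators: every analysis stage runs offline.

Provides

* the eRF3 PAM2-region sequence 67–90 reconstructed from the residue
  identities that interface analysis pins down (unknown positions carry
  the wildcard ``X``),
* random protein sequences with planted PAM2 motifs (including
  overlapping pairs at the eRF3 offset of nine residues) plus a truth
  table,
* schematic two-chain coordinate models of the MLLE/PAM2-N and
  MLLE/PAM2-C complexes realising the enumerated hydrogen bonds,
  hydrophobic contacts, β-turn and (for PAM2-C) an ordered water bridge,
* noisy 1:1 saturation-binding titrations.

All generators are pure functions of their arguments; a fixed seed gives
byte-identical output.  The toy structures are geometric cartoons: only
the atoms needed for the declared interactions plus backbone are placed,
at idealised bond lengths, with no attempt at a physical fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import TitrationDataset
from .motif import AMINO_ACIDS, WILDCARD, build_default_consensus, scan
from .structure import Atom, Chain, Residue, Structure

__all__ = [
    "NumberedSequence",
    "PlantedMotifSet",
    "reconstruct_erf3",
    "plant_motifs",
    "build_toy_complex",
    "generate_titration",
    "PLANTED_HBONDS",
    "PLANTED_WATER_BRIDGES",
    "PLANTED_CONTACT_PAIRS",
    "PLANTED_BETA_TURNS",
]

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


@dataclass(frozen=True)
class NumberedSequence:
    """A sequence carrying its author residue numbering."""

    id: str
    sequence: str
    first_residue_number: int

    def residue(self, number: int) -> str:
        return self.sequence[number - self.first_residue_number]


#: eRF3 residue identities fixed by the complex structures (author
#: numbering).  The remaining positions of the 67–90 fragment are
#: unknown at this level of description and stay wildcards.
ERF3_NAMED_RESIDUES = {
    69: "L", 70: "N", 71: "V", 72: "N", 73: "A",
    76: "F", 77: "V", 78: "P", 79: "N", 80: "V", 81: "H", 82: "A",
    84: "E", 85: "F", 87: "P",
}

ERF3_FIRST, ERF3_LAST = 67, 90


def reconstruct_erf3() -> NumberedSequence:
    """The 24-residue eRF3 fragment 67–90 with wildcards at unknowns.

    Both PAM2 registers (starts 67 and 76) have all five consensus
    anchors at named, non-wildcard residues.
    """
    seq = "".join(
        ERF3_NAMED_RESIDUES.get(i, WILDCARD) for i in range(ERF3_FIRST, ERF3_LAST + 1)
    )
    return NumberedSequence(id="eRF3_67-90", sequence=seq, first_residue_number=ERF3_FIRST)


# ---------------------------------------------------------------------------
# planted-motif sequence sets


@dataclass(frozen=True)
class PlantedMotifSet:
    """FASTA-ready records plus the ground-truth motif table."""

    records: tuple[tuple[str, str], ...]
    truth: pd.DataFrame

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for name, seq in self.records:
                fh.write(f">{name}\n{seq}\n")


_ALPHABET = sorted(AMINO_ACIDS)


def _planted_window(rng: np.random.Generator, overlap: bool) -> str:
    """A random window satisfying all anchors (21-mer for overlap pairs)."""
    consensus = build_default_consensus()
    if not overlap:
        window = [rng.choice(_ALPHABET) for _ in range(12)]
        for pos in consensus.constrained_positions:
            window[pos - 1] = rng.choice(sorted(consensus.rule(pos).required_set))
        return "".join(window)
    window = [rng.choice(_ALPHABET) for _ in range(21)]
    for pos in consensus.constrained_positions:
        window[pos - 1] = rng.choice(sorted(consensus.rule(pos).required_set))
        window[pos + 8] = rng.choice(sorted(consensus.rule(pos).required_set))
    # shared constraints of the eRF3-like geometry: position 12 of the
    # first copy is position 3 of the second (proline satisfies both),
    # position 10 of the first is the shared phenylalanine.
    window[11] = "P"
    window[9] = "F"
    return "".join(window)


def plant_motifs(
    n_sequences: int,
    length: int,
    n_planted: int,
    overlap: bool = False,
    seed: int = 0,
) -> PlantedMotifSet:
    """Random sequences with exactly ``n_planted`` PAM2 motifs each.

    ``overlap`` plants pairs at offset 9 sharing a phenylalanine (each
    pair counts as one planted unit but yields two scanner matches).
    Background is uniform over the 20 residues; whole sequences whose
    scan does not reproduce the intended truth exactly (accidental
    anchor completions) are rejection-sampled.
    """
    width = 21 if overlap else 12
    if length < 12:
        raise ValueError("sequences must be at least 12 residues long")
    if n_planted * (width + 1) > length + 1:
        raise ValueError(
            f"cannot pack {n_planted} windows of width {width} into length {length}"
        )
    rng = np.random.default_rng(seed)
    records = []
    rows = []
    for idx in range(n_sequences):
        name = f"synth_{idx:03d}"
        for _attempt in range(1000):
            seq = [str(rng.choice(_ALPHABET)) for _ in range(length)]
            starts: list[int] = []
            ok = True
            for _ in range(n_planted):
                for _try in range(200):
                    s = int(rng.integers(0, length - width + 1))
                    if all(s + width + 1 <= t or t + width + 1 <= s for t in starts):
                        starts.append(s)
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            starts.sort()
            expected = []
            for s in starts:
                seq[s : s + width] = _planted_window(rng, overlap)
                expected.append(s + 1)
                if overlap:
                    expected.append(s + 10)
            sequence = "".join(seq)
            found = [m.start for m in scan(sequence, sequence_id=name)]
            if found == sorted(expected):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("rejection sampling failed to produce a clean sequence")
        records.append((name, sequence))
        for s in starts:
            rows.append(
                {
                    "sequence_id": name,
                    "start": s + 1,
                    "overlap_partner_start": s + 10 if overlap else pd.NA,
                }
            )
            if overlap:
                rows.append(
                    {
                        "sequence_id": name,
                        "start": s + 10,
                        "overlap_partner_start": s + 1,
                    }
                )
    truth = pd.DataFrame(rows, columns=["sequence_id", "start", "overlap_partner_start"])
    return PlantedMotifSet(records=tuple(records), truth=truth)


# ---------------------------------------------------------------------------
# toy MLLE/PAM2 complexes
#
# Layout: the peptide runs along +x with Cα spacing 3.8 Å, interrupted by
# a four-residue turn block that rises in +y and closes the
# carbonyl(i)→amide(i+3) hydrogen bond.  Peptide side chains point -y
# (except the turn tip valine, +y, and the turn asparagine, +z); MLLE
# residues are satellites whose interacting atoms sit 2.9 Å (hydrogen
# bonds) or ~3.2–4.1 Å (hydrophobic contacts) from their peptide
# partners, with backbones parked away from the interface.

PEPTIDE_CHAIN = "P"
MLLE_CHAIN = "A"
WATER_CHAIN = "W"

_CA_SPACING = 3.8
_TURN_OFFSETS = [(0.0, 0.0, 0.0), (2.2, 2.6, 0.0), (4.3, 2.6, 0.0), (6.5, 0.0, 0.0)]


def _ca_positions(first: int, last: int, turn_start: int) -> dict[int, np.ndarray]:
    origin_x = (turn_start - first) * _CA_SPACING
    cas = {}
    for r in range(first, last + 1):
        if r < turn_start:
            cas[r] = np.array([origin_x - (turn_start - r) * _CA_SPACING, 0.0, 0.0])
        elif r <= turn_start + 3:
            off = _TURN_OFFSETS[r - turn_start]
            cas[r] = np.array([origin_x + off[0], off[1], off[2]])
        else:
            cas[r] = np.array(
                [origin_x + 6.5 + (r - turn_start - 3) * _CA_SPACING, 0.0, 0.0]
            )
    return cas


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class _Builder:
    def __init__(self) -> None:
        self.residues: dict[tuple[str, int], tuple[str, dict[str, np.ndarray]]] = {}

    def add(self, chain: str, number: int, name: str, atoms: dict[str, np.ndarray]) -> None:
        key = (chain, number)
        if key in self.residues:
            old_name, old_atoms = self.residues[key]
            assert old_name == name
            old_atoms.update(atoms)
        else:
            self.residues[key] = (name, dict(atoms))

    def atom(self, chain: str, number: int, atom: str) -> np.ndarray:
        return self.residues[(chain, number)][1][atom]

    def build(self, name: str) -> Structure:
        chains: dict[str, list[Residue]] = {}
        for (chain, number), (resname, atoms) in sorted(self.residues.items()):
            element = {"N": "N", "O": "O", "S": "S"}
            residue = Residue(
                number=number,
                name=resname,
                atoms=tuple(
                    Atom(
                        name=aname,
                        element=element.get(aname[0], "C"),
                        pos=tuple(np.round(pos, 3)),
                    )
                    for aname, pos in atoms.items()
                ),
            )
            chains.setdefault(chain, []).append(residue)
        order = [c for c in (MLLE_CHAIN, PEPTIDE_CHAIN, WATER_CHAIN) if c in chains]
        return Structure(
            chains=tuple(Chain(name=c, residues=tuple(chains[c])) for c in order),
            name=name,
        )


def _peptide_backbone(
    builder: _Builder,
    names: dict[int, str],
    cas: dict[int, np.ndarray],
    turn_start: int,
) -> None:
    numbers = sorted(cas)
    for r in numbers:
        ca = cas[r]
        n = ca + np.array([-1.2, 0.25, 0.0])
        c = ca + np.array([1.2, 0.25, 0.0])
        if r == turn_start:
            # carbonyl oriented to close the turn hydrogen bond at 2.9 Å
            n_i3 = cas[r + 3] + np.array([-1.2, 0.25, 0.0])
            o = n_i3 + 2.9 * _unit(c - n_i3)
        else:
            o = c + np.array([0.2, 1.2, 0.0])
        builder.add(
            PEPTIDE_CHAIN, r, THREE_LETTER[names.get(r, "X")],
            {"N": n, "CA": ca, "C": c, "O": o},
        )


def _phe_ring(ca: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "CB": ca + np.array([0.0, -1.3, 0.5]),
        "CG": ca + np.array([0.0, -2.7, 0.6]),
        "CD1": ca + np.array([0.7, -3.6, 0.6]),
        "CD2": ca + np.array([-0.7, -3.6, 0.6]),
        "CE1": ca + np.array([0.7, -5.0, 0.6]),
        "CE2": ca + np.array([-0.7, -5.0, 0.6]),
        "CZ": ca + np.array([0.0, -5.8, 0.6]),
    }


def _asn_turn_sidechain(builder: _Builder, resnum: int, cas: dict[int, np.ndarray]) -> None:
    """Turn asparagine: OD1 caps the i+2 amide; side chain points +z."""
    ca = cas[resnum]
    n_i2 = cas[resnum + 2] + np.array([-1.2, 0.25, 0.0])
    od1 = n_i2 + 2.9 * _unit([-0.30, -0.55, 0.78])
    cb = ca + np.array([0.3, 0.6, 1.3])
    cg = od1 - 1.3 * _unit(od1 - cb)
    nd2 = cg + np.array([-0.5, -0.9, 0.8])
    builder.add(PEPTIDE_CHAIN, resnum, "ASN", {"CB": cb, "CG": cg, "OD1": od1, "ND2": nd2})


def _tip_val_sidechain(builder: _Builder, resnum: int, cas: dict[int, np.ndarray]) -> None:
    ca = cas[resnum]
    builder.add(
        PEPTIDE_CHAIN, resnum, "VAL",
        {
            "CB": ca + np.array([0.0, 1.3, 0.5]),
            "CG1": ca + np.array([0.8, 2.5, 0.55]),
            "CG2": ca + np.array([-0.8, 2.5, 0.55]),
        },
    )


def _pro_sidechain(ca: np.ndarray) -> dict[str, np.ndarray]:
    return {"CB": ca + np.array([0.0, -1.3, 0.5]), "CG": ca + np.array([-0.3, -2.6, 0.55])}


def _mlle_backbone(builder: _Builder, number: int, name: str, anchor: np.ndarray) -> None:
    """Parked backbone for a satellite residue, pointing away from the
    interface (below for -y satellites, above for +y ones)."""
    ca = np.asarray(anchor, dtype=float)
    builder.add(
        MLLE_CHAIN, number, name,
        {
            "N": ca + np.array([-1.2, 0.25, 0.0]),
            "CA": ca,
            "C": ca + np.array([1.2, 0.25, 0.0]),
            "O": ca + np.array([1.4, 1.45, 0.0]) if anchor[1] > 0
            else ca + np.array([1.4, -0.95, 0.0]),
        },
    )


def _common_cterminal_satellites(builder: _Builder, b: _Builder | None = None) -> None:
    """MLLE residues around the C-terminal anchor block (identical for the
    two variants because the Phe(position 10)/Pro(position 12) geometry
    repeats at the same absolute coordinates)."""
    # Gly579: carbonyl accepts the anchor phenylalanine amide (residue at
    # x = 29.3 has N at (28.1, 0.25, 0)); amide donates to the water
    # bridge in the PAM2-C variant.  The backbone drops in -z to stay
    # clear of the peptide main chain and the Glu84 side chain.
    n_phe = np.array([28.1, 0.25, 0.0])
    o579 = n_phe + 2.9 * _unit([-0.42, -0.20, -0.89])
    c579 = o579 + np.array([-0.2, -0.5, -1.15])
    ca579 = c579 + np.array([-1.0, -0.3, -0.7])
    builder.add(
        MLLE_CHAIN, 579, "GLY",
        {"N": ca579 + np.array([-1.2, 0.25, 0.0]), "CA": ca579, "C": c579, "O": o579},
    )
    # shallow pocket around the anchor phenylalanine ring (centred x=29.3)
    builder.add(MLLE_CHAIN, 582, "THR", {"CG2": np.array([26.2, -7.2, 1.2])})
    _mlle_backbone(builder, 582, "THR", np.array([24.5, -9.5, 0.6]))
    builder.add(MLLE_CHAIN, 586, "LEU", {"CD1": np.array([27.6, -5.2, 3.6])})
    _mlle_backbone(builder, 586, "LEU", np.array([27.0, -9.0, 5.0]))
    # Phe567 ring runs in the trough between the anchor phenylalanine and
    # the position-12 proline (x=36.9)
    builder.add(
        MLLE_CHAIN, 567, "PHE",
        {
            "CB": np.array([32.0, -7.8, 0.6]),
            "CG": np.array([33.2, -8.2, 0.6]),
            "CD1": np.array([34.4, -7.8, 0.6]),
            "CE1": np.array([35.5, -7.2, 0.6]),
            "CZ": np.array([36.3, -6.2, 0.6]),
        },
    )
    _mlle_backbone(builder, 567, "PHE", np.array([33.0, -11.5, 0.6]))
    # Gln560/Glu564 side-chain acceptors for the amides at motif
    # positions 11 and 13 (x = 31.9 and 39.5); they approach from -z to
    # stay clear of the anchor phenylalanine ring and the Phe567 trough.
    oe1_560 = np.array([31.9, 0.25, 0.0]) + 2.9 * _unit([-0.3, -0.35, -0.89])
    builder.add(MLLE_CHAIN, 560, "GLN", {"CD": oe1_560 + np.array([0.0, -0.5, -1.2]), "OE1": oe1_560})
    _mlle_backbone(builder, 560, "GLN", np.array([30.5, -11.0, -2.0]))
    oe1_564 = np.array([39.5, 0.25, 0.0]) + 2.9 * _unit([-0.3, -0.35, -0.89])
    builder.add(MLLE_CHAIN, 564, "GLU", {"CD": oe1_564 + np.array([0.0, -0.5, -1.2]), "OE1": oe1_564})
    _mlle_backbone(builder, 564, "GLU", np.array([38.5, -11.0, -2.0]))


def _build_pam2n() -> Structure:
    builder = _Builder()
    names = dict(ERF3_NAMED_RESIDUES)
    cas = _ca_positions(67, 81, turn_start=70)
    _peptide_backbone(builder, names, cas, turn_start=70)
    # peptide side chains
    ca69 = cas[69]
    builder.add(
        PEPTIDE_CHAIN, 69, "LEU",
        {
            "CB": ca69 + np.array([0.0, -1.3, 0.5]),
            "CG": ca69 + np.array([0.0, -2.7, 0.7]),
            "CD1": ca69 + np.array([0.9, -3.7, 0.7]),
            "CD2": ca69 + np.array([-0.9, -3.7, 0.7]),
        },
    )
    _asn_turn_sidechain(builder, 70, cas)
    _tip_val_sidechain(builder, 71, cas)
    builder.add(PEPTIDE_CHAIN, 73, "ALA", {"CB": cas[73] + np.array([0.0, -1.3, 0.5])})
    builder.add(PEPTIDE_CHAIN, 76, "PHE", _phe_ring(cas[76]))
    builder.add(PEPTIDE_CHAIN, 77, "VAL", {"CB": cas[77] + np.array([0.0, -1.3, 0.5])})
    builder.add(PEPTIDE_CHAIN, 78, "PRO", _pro_sidechain(cas[78]))
    builder.add(PEPTIDE_CHAIN, 79, "ASN", {"CB": cas[79] + np.array([0.0, -1.3, 0.5])})
    builder.add(PEPTIDE_CHAIN, 80, "VAL", {"CB": cas[80] + np.array([0.0, -1.3, 0.5])})
    builder.add(PEPTIDE_CHAIN, 81, "HIS", {"CB": cas[81] + np.array([0.0, -1.3, 0.5])})

    # --- MLLE satellites -------------------------------------------------
    # Lys580 ammonium bridges the two turn carbonyls (Val71, Ala73); the
    # carbonyls are tilted +z so the shared site clears the Asn72 carbonyl.
    o71 = builder.atom(PEPTIDE_CHAIN, 71, "C") + np.array([0.2, 0.3, 1.15])
    builder.add(PEPTIDE_CHAIN, 71, "VAL", {"O": o71})
    o73 = builder.atom(PEPTIDE_CHAIN, 73, "C") + np.array([0.2, 0.3, 1.15])
    builder.add(PEPTIDE_CHAIN, 73, "ALA", {"O": o73})
    axis = _unit(o73 - o71)
    mid = (o71 + o73) / 2.0
    u = _unit(np.cross([0.0, 0.0, 1.0], axis))
    w = np.array([0.0, 0.0, 1.0])
    half = np.linalg.norm(o73 - o71) / 2.0
    h = float(np.sqrt(2.9**2 - half**2))
    # position on the equidistant circle chosen to clear the Asn72
    # carbonyl and backbone amides; CE points back towards Asn70 OD1 so
    # the 3.3 Å NZ···OD1 approach fails the antecedent-angle test.
    theta = math.radians(110.0)
    nz = mid + h * (math.cos(theta) * u + math.sin(theta) * w)
    ce = nz + 1.5 * _unit([-0.40, -0.80, 0.45])
    builder.add(MLLE_CHAIN, 580, "LYS", {"CE": ce, "NZ": nz})
    _mlle_backbone(builder, 580, "LYS", np.array([15.5, -8.5, 3.5]))
    # α2/α3 pocket around Leu69
    builder.add(
        MLLE_CHAIN, 584, "MET",
        {
            "CB": np.array([15.3, -3.5, 0.5]),
            "CG": np.array([14.0, -4.2, 0.57]),
            "SD": np.array([12.8, -4.9, 0.63]),
            "CE": np.array([11.5, -5.5, 0.7]),
        },
    )
    _mlle_backbone(builder, 584, "MET", np.array([16.5, -8.0, 0.5]))
    builder.add(MLLE_CHAIN, 585, "LEU", {"CD1": np.array([9.8, -6.3, -0.8])})
    _mlle_backbone(builder, 585, "LEU", np.array([10.5, -10.0, -2.0]))
    builder.add(MLLE_CHAIN, 588, "ILE", {"CD1": np.array([6.0, -5.9, -1.3])})
    _mlle_backbone(builder, 588, "ILE", np.array([5.0, -9.5, -2.5]))
    builder.add(
        MLLE_CHAIN, 606, "LYS",
        {
            "CB": np.array([7.2, -9.3, 2.7]),
            "CG": np.array([7.6, -7.9, 2.6]),
            "CD": np.array([8.0, -6.5, 2.5]),
        },
    )
    _mlle_backbone(builder, 606, "LYS", np.array([7.0, -12.0, 2.8]))
    builder.add(MLLE_CHAIN, 609, "GLU", {"CB": np.array([7.0, -7.0, -0.3])})
    _mlle_backbone(builder, 609, "GLU", np.array([2.5, -9.0, 0.0]))
    builder.add(MLLE_CHAIN, 610, "ALA", {"CB": np.array([5.5, -6.8, 0.7])})
    _mlle_backbone(builder, 610, "ALA", np.array([1.0, -7.0, 2.0]))
    # small pocket above the turn tip (Val71)
    builder.add(MLLE_CHAIN, 613, "VAL", {"CG1": np.array([15.6, 8.2, 1.0])})
    _mlle_backbone(builder, 613, "VAL", np.array([17.5, 11.0, 1.0]))
    builder.add(MLLE_CHAIN, 617, "HIS", {"CB": np.array([11.6, 8.0, 0.3])})
    _mlle_backbone(builder, 617, "HIS", np.array([9.5, 11.0, 0.3]))
    _common_cterminal_satellites(builder)
    return builder.build("toy MLLE/PAM2-N complex (synthetic)")


def _build_pam2c() -> Structure:
    builder = _Builder()
    names = dict(ERF3_NAMED_RESIDUES)
    cas = _ca_positions(76, 90, turn_start=79)
    _peptide_backbone(builder, names, cas, turn_start=79)
    builder.add(PEPTIDE_CHAIN, 76, "PHE", _phe_ring(cas[76]))
    builder.add(PEPTIDE_CHAIN, 77, "VAL", {"CB": cas[77] + np.array([0.0, -1.3, 0.5])})
    builder.add(PEPTIDE_CHAIN, 78, "PRO", _pro_sidechain(cas[78]))
    _asn_turn_sidechain(builder, 79, cas)
    _tip_val_sidechain(builder, 80, cas)
    builder.add(PEPTIDE_CHAIN, 81, "HIS", {"CB": cas[81] + np.array([0.0, 1.3, 0.5])})
    builder.add(PEPTIDE_CHAIN, 82, "ALA", {"CB": cas[82] + np.array([0.0, -1.3, 0.5])})
    # Glu84 carboxylate dives -z towards the ordered water, clearing the
    # Gly579 backbone and the Thr582/Leu586 pocket atoms
    ca84 = cas[84]
    builder.add(
        PEPTIDE_CHAIN, 84, "GLU",
        {
            "CB": ca84 + np.array([0.0, -1.3, 0.5]),
            "CG": ca84 + np.array([0.0, -2.4, -0.3]),
            "CD": ca84 + np.array([0.0, -3.4, -1.2]),
            "OE1": ca84 + np.array([-0.4, -4.2, -2.1]),
            "OE2": ca84 + np.array([0.9, -3.8, -1.9]),
        },
    )
    builder.add(PEPTIDE_CHAIN, 85, "PHE", _phe_ring(cas[85]))
    builder.add(PEPTIDE_CHAIN, 87, "PRO", _pro_sidechain(cas[87]))

    # --- MLLE satellites -------------------------------------------------
    # α2/α3 pocket now holds Phe76 (and Pro78)
    builder.add(MLLE_CHAIN, 585, "LEU", {"CD1": np.array([3.3, -6.9, -1.0])})
    _mlle_backbone(builder, 585, "LEU", np.array([4.0, -10.5, -2.0]))
    builder.add(MLLE_CHAIN, 610, "ALA", {"CB": np.array([1.8, -8.6, 0.6])})
    _mlle_backbone(builder, 610, "ALA", np.array([-1.5, -10.5, 0.6]))
    builder.add(
        MLLE_CHAIN, 606, "LYS",
        {
            "CB": np.array([-3.6, -10.1, 1.6]),
            "CG": np.array([-3.2, -8.7, 1.55]),
            "CD": np.array([-2.8, -7.3, 1.5]),
        },
    )
    _mlle_backbone(builder, 606, "LYS", np.array([-4.0, -13.0, 1.7]))
    builder.add(MLLE_CHAIN, 588, "ILE", {"CD1": np.array([9.0, -5.3, -0.8])})
    _mlle_backbone(builder, 588, "ILE", np.array([10.0, -9.0, -2.0]))
    builder.add(MLLE_CHAIN, 617, "VAL", {"CG1": np.array([7.6, -6.2, 0.2])})
    _mlle_backbone(builder, 617, "VAL", np.array([7.0, -10.0, 0.2]))
    # Met584 packs on the invariant Ala82 (signature methionine)
    builder.add(
        MLLE_CHAIN, 584, "MET",
        {
            "CG": np.array([12.0, -4.8, 0.5]),
            "SD": np.array([13.4, -4.1, 0.5]),
            "CE": np.array([15.0, -3.5, 0.5]),
        },
    )
    _mlle_backbone(builder, 584, "MET", np.array([12.0, -8.5, 0.5]))
    # Val613 above the turn tip (Val80), shifted +x to clear His81 CB
    builder.add(MLLE_CHAIN, 613, "VAL", {"CG1": np.array([16.2, 8.6, 1.0])})
    _mlle_backbone(builder, 613, "VAL", np.array([18.0, 11.2, 1.0]))
    # Glu587 salt bridge to the turn asparagine (Asn79 ND2)
    nd2 = builder.atom(PEPTIDE_CHAIN, 79, "ND2")
    cg = builder.atom(PEPTIDE_CHAIN, 79, "CG")
    oe1_587 = nd2 + 2.9 * _unit(nd2 - cg)
    builder.add(MLLE_CHAIN, 587, "GLU", {"CD": oe1_587 + np.array([0.0, -0.5, 1.2]), "OE1": oe1_587})
    _mlle_backbone(builder, 587, "GLU", np.array([9.0, -2.0, 8.0]))
    _common_cterminal_satellites(builder)
    # Lys580 backbone: its amide joins the water bridge
    n580 = np.array([21.5, -5.6, -4.8])
    ca580 = n580 + 1.5 * _unit([-1.0, -0.8, -0.5])
    builder.add(
        MLLE_CHAIN, 580, "LYS",
        {"N": n580, "CA": ca580, "C": ca580 + np.array([0.0, -1.3, -0.4]),
         "O": ca580 + np.array([0.2, -2.5, -0.8])},
    )
    # ordered water bridging Glu84 OE1 to the Gly579/Lys580 amides
    builder.add(WATER_CHAIN, 1, "HOH", {"O": np.array([23.2, -3.5, -4.0])})
    return builder.build("toy MLLE/PAM2-C complex (synthetic)")


def build_toy_complex(variant: str) -> Structure:
    """Schematic coordinate model of an MLLE/PAM2 complex.

    ``variant`` is ``"PAM2-N"`` (eRF3 67–81 bound, turn at 70–73) or
    ``"PAM2-C"`` (eRF3 76–90 bound, turn at 79–82, with the ordered
    water bridging Glu84 to the Gly579/Lys580 amides).  Every planted
    interaction (see ``PLANTED_HBONDS``/``PLANTED_CONTACT_PAIRS``) is
    realised at hydrogen-bond distance 2.9 ± 0.1 Å or hydrophobic
    distance ≤ 4.2 Å, and no unplanned intermolecular interaction passes
    the detection criteria.  Geometry is schematic — ideal local bond
    lengths, no physical fold — and side-chain atoms not needed for the
    declared interactions are omitted.
    """
    if variant == "PAM2-N":
        return _build_pam2n()
    if variant == "PAM2-C":
        return _build_pam2c()
    raise ValueError(f"unknown variant {variant!r}; expected 'PAM2-N' or 'PAM2-C'")


#: Intermolecular hydrogen bonds planted in each toy complex, as
#: ((chain, residue, atom) donor, (chain, residue, atom) acceptor).
PLANTED_HBONDS = {
    "PAM2-N": (
        (("A", 580, "NZ"), ("P", 71, "O")),
        (("A", 580, "NZ"), ("P", 73, "O")),
        (("P", 76, "N"), ("A", 579, "O")),
        (("P", 77, "N"), ("A", 560, "OE1")),
        (("P", 79, "N"), ("A", 564, "OE1")),
    ),
    "PAM2-C": (
        (("P", 85, "N"), ("A", 579, "O")),
        (("P", 86, "N"), ("A", 560, "OE1")),
        (("P", 88, "N"), ("A", 564, "OE1")),
        (("P", 79, "ND2"), ("A", 587, "OE1")),
    ),
}

#: Water bridges planted in each variant: (water, partner, partner).
PLANTED_WATER_BRIDGES = {
    "PAM2-N": (),
    "PAM2-C": ((("W", 1, "O"), ("P", 84, "OE1"), ("A", 579, "N"), ("A", 580, "N")),),
}

#: Intermolecular hydrophobic contacts at residue-pair level,
#: (peptide residue, MLLE residue).
PLANTED_CONTACT_PAIRS = {
    "PAM2-N": (
        (69, 584), (69, 585), (69, 588), (69, 606), (69, 609), (69, 610),
        (71, 613), (71, 617),
        (73, 584),
        (76, 582), (76, 586), (76, 567),
        (78, 567),
    ),
    "PAM2-C": (
        (76, 585), (76, 606), (76, 610),
        (78, 588), (78, 617),
        (80, 613),
        (82, 584),
        (85, 582), (85, 586), (85, 567),
        (87, 567),
    ),
}

#: β-turn spans (start residue i of the i..i+3 span).
PLANTED_BETA_TURNS = {"PAM2-N": (70,), "PAM2-C": (79,)}


# ---------------------------------------------------------------------------
# titrations


def generate_titration(
    kd: float,
    concentrations=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationDataset:
    """Noisy 1:1 saturation-binding titration.

    Response is ``m/(kd+m)`` plus additive Gaussian noise (sd
    ``noise_sd`` on the fraction-bound scale), truncated to
    [-0.05, 1.05].  Default design: 12 points log-spaced over
    0.1×–10× the dissociation constant.
    """
    if not kd > 0:
        raise ValueError("kd must be positive")
    if concentrations is None:
        concentrations = np.geomspace(0.1 * kd, 10.0 * kd, 12)
    conc = np.asarray(concentrations, dtype=float)
    response = conc / (kd + conc)
    if noise_sd:
        rng = np.random.default_rng(seed)
        response = np.clip(response + rng.normal(0.0, noise_sd, conc.size), -0.05, 1.05)
    return TitrationDataset(
        titrant_concentrations=tuple(float(c) for c in conc),
        response=tuple(float(r) for r in response),
        noise_sd=noise_sd,
        seed=seed,
    )
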