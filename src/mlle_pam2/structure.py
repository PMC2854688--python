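"""Interface analysis of MLLE–peptide complexes.

Detects intermolecular hydrogen bonds (direct and water-mediated),
hydrophobic contacts and β-turns in atomic models, classifies which MLLE
pocket each peptide residue occupies, and assigns the bound peptide's
PAM2 register from its anchor contacts.

The geometric criteria are chosen for crystal structures without explicit
hydrogens: a hydrogen bond is a donor–acceptor heavy-atom pair within
3.5 Å whose donor-antecedent–donor–acceptor angle is at least 90° (when
the antecedent atom is present); with hydrogens, a D–H–A angle of at
least 120° is additionally required.  A hydrophobic contact is a pair of
apolar heavy atoms (carbon or sulfur not bonded to oxygen/nitrogen)
within 4.5 Å.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "AtomRef",
    "HBond",
    "WaterBridge",
    "Contact",
    "BetaTurn",
    "PocketDefinition",
    "PocketAssignment",
    "RegisterAssignment",
    "HBondConfig",
    "ContactConfig",
    "DEFAULT_POCKETS",
    "read_structure",
    "write_structure",
    "detect_hbonds",
    "detect_water_bridges",
    "detect_hydrophobic_contacts",
    "aggregate_residue_contacts",
    "detect_beta_turns",
    "classify_pocket_occupancy",
    "assign_register",
    "chain_sequence",
]

WATER_NAMES = {"HOH", "WAT", "H2O"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# ---------------------------------------------------------------------------
# atom chemistry tables

#: Side-chain hydrogen-bond donor atoms per residue type.
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}

#: Side-chain acceptor atoms per residue type.
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}

#: Antecedent (covalently bonded heavy atom) used for the angle criterion.
DONOR_ANTECEDENT = {
    "N": "CA",
    "NZ": "CE",
    "ND2": "CG",
    "NE2": "CD",   # Gln; His NE2 handled via fallback below
    "NE1": "CE2",
    "NE": "CD",
    "NH1": "CZ",
    "NH2": "CZ",
    "OG": "CB",
    "OG1": "CB",
    "OH": "CZ",
    "ND1": "CG",
}

#: Apolar heavy atoms (C/S not bonded to O or N) per residue type.  The
#: aliphatic stem of lysine (CB–CD) counts as apolar; atoms bonded to
#: polar atoms (e.g. Lys CE, Ser CB) do not.
APOLAR_ATOMS = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CG", "SD", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "PRO": {"CB", "CG"},
    "LYS": {"CB", "CG", "CD"},
    "ARG": {"CB", "CG"},
    "GLU": {"CB", "CG"},
    "GLN": {"CB", "CG"},
    "ASP": {"CB"},
    "ASN": {"CB"},
    "THR": {"CG2"},
    "CYS": {"CB", "SG"},
    "HIS": {"CB"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
}

# ---------------------------------------------------------------------------
# data model


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    pos: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(x) for x in self.pos):
            raise ValueError(f"atom {self.name} has non-finite coordinates")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)


@dataclass(frozen=True)
class Residue:
    number: int
    name: str
    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate atom names in residue {self.name}{self.number}")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass(frozen=True)
class Chain:
    name: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError(f"residue numbers in chain {self.name} must strictly increase")

    def residue(self, number: int) -> Residue | None:
        for r in self.residues:
            if r.number == number:
                return r
        return None


@dataclass(frozen=True)
class Structure:
    """Light atomic model: chains → residues → atoms, coordinates in Å."""

    chains: tuple[Chain, ...]
    name: str = "model"

    def __post_init__(self) -> None:
        names = [c.name for c in self.chains]
        if len(set(names)) != len(names):
            raise ValueError("chain names must be unique")

    def chain(self, name: str) -> Chain:
        for c in self.chains:
            if c.name == name:
                return c
        raise KeyError(f"no chain {name!r}")

    def atom_count(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Apply a global rigid-body transform (used in invariance tests)."""
        rot = np.asarray(rotation, float)
        trans = np.asarray(translation, float)
        new_chains = []
        for c in self.chains:
            new_res = []
            for r in c.residues:
                new_atoms = tuple(
                    replace(a, pos=tuple(rot @ a.xyz + trans)) for a in r.atoms
                )
                new_res.append(replace(r, atoms=new_atoms))
            new_chains.append(replace(c, residues=tuple(new_res)))
        return replace(self, chains=tuple(new_chains))


@dataclass(frozen=True)
class AtomRef:
    """Fully qualified reference to one atom."""

    chain: str
    residue_number: int
    residue_name: str
    atom_name: str

    def __str__(self) -> str:
        return f"{self.chain}/{self.residue_name}{self.residue_number}/{self.atom_name}"


@dataclass(frozen=True)
class HBond:
    donor: AtomRef
    acceptor: AtomRef
    distance: float
    dha_angle: float | None = None


@dataclass(frozen=True)
class WaterBridge:
    """Two hydrogen bonds sharing an ordered water molecule."""

    water: AtomRef
    partner_a: AtomRef
    partner_b: AtomRef
    distance_a: float
    distance_b: float


@dataclass(frozen=True)
class Contact:
    atom_a: AtomRef
    atom_b: AtomRef
    distance: float


@dataclass(frozen=True)
class BetaTurn:
    """An i..i+3 chain reversal closed by a carbonyl(i)→amide(i+3) bond.

    ``central`` carries the customary three-residue naming (i, i+1, i+2)
    alongside the full span.
    """

    chain: str
    start: int
    end: int
    central: tuple[int, int, int]
    hbond_distance: float
    ca_distance: float


@dataclass(frozen=True)
class PocketDefinition:
    name: str
    mlle_residues: frozenset[int]


#: MLLE peptide-binding pockets (author numbering of human PABPC1).
#: Membership is the union of the residue lists reported for each pocket
#: across descriptions; the α2/α3 pocket receives the hydrophobe at motif
#: position 3 (or position 1 in the eRF3 PAM2-C register), the shallow
#: α3/α5 pocket the invariant phenylalanine at position 10.
DEFAULT_POCKETS = (
    PocketDefinition("α2/α3", frozenset({584, 585, 588, 606, 609, 610})),
    PocketDefinition("α3/α5", frozenset({563, 564, 567, 582, 586})),
)


@dataclass(frozen=True)
class PocketAssignment:
    pockets: tuple[str, ...]
    tied: bool

    @property
    def pocket(self) -> str:
        return self.pockets[0]


@dataclass(frozen=True)
class RegisterAssignment:
    """Peptide residues mapped onto PAM2 positions from contact evidence."""

    mapping: dict[int, int]
    start: int
    anchor_evidence: dict[int, tuple[str, ...]]
    offset_consistent: bool


@dataclass(frozen=True)
class HBondConfig:
    max_distance: float = 3.5
    min_antecedent_angle: float = 90.0
    min_dha_angle: float = 120.0
    intermolecular_only: bool = True


@dataclass(frozen=True)
class ContactConfig:
    max_distance: float = 4.5
    intermolecular_only: bool = True


# ---------------------------------------------------------------------------
# I/O


def read_structure(path: str) -> Structure:
    """Read a PDB-format file into a :class:`Structure`.

    Alternate locations are collapsed to the highest-occupancy conformer
    (logged).  Malformed or empty files raise ``ValueError``.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0 or st[0].count_atom_sites() == 0:
        raise ValueError(f"no atoms found in {path}")
    model = st[0]
    chains = []
    for gchain in model:
        residues = []
        for gres in gchain:
            atoms: dict[str, gemmi.Atom] = {}
            for gatom in gres:
                prev = atoms.get(gatom.name)
                if prev is not None:
                    logger.info(
                        "alternate location for %s %s%d %s: keeping highest occupancy",
                        gchain.name, gres.name, gres.seqid.num, gatom.name,
                    )
                    if gatom.occ <= prev.occ:
                        continue
                atoms[gatom.name] = gatom
            residues.append(
                Residue(
                    number=gres.seqid.num,
                    name=gres.name.strip(),
                    atoms=tuple(
                        Atom(
                            name=a.name,
                            element=a.element.name,
                            pos=(a.pos.x, a.pos.y, a.pos.z),
                            occupancy=a.occ,
                            b_factor=a.b_iso,
                        )
                        for a in atoms.values()
                    ),
                )
            )
        chains.append(Chain(name=gchain.name, residues=tuple(residues)))
    return Structure(chains=tuple(chains), name=st.name or "model")


def write_structure(structure: Structure, path: str) -> None:
    """Write a :class:`Structure` as a PDB-format file (via gemmi)."""
    st = gemmi.Structure()
    st.name = structure.name
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.name)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, " ")
            gres.het_flag = "H" if res.is_water else "A"
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.pos)
                gatom.occ = atom.occupancy
                gatom.b_iso = atom.b_factor
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def chain_sequence(structure: Structure, chain_name: str) -> tuple[str, int]:
    """One-letter sequence of a chain and its first residue number.

    Gaps in numbering are filled with the wildcard so the sequence stays
    aligned with author numbering.
    """
    chain = structure.chain(chain_name)
    residues = [r for r in chain.residues if not r.is_water]
    if not residues:
        raise ValueError(f"chain {chain_name} has no polymer residues")
    first = residues[0].number
    seq = ["X"] * (residues[-1].number - first + 1)
    for r in residues:
        seq[r.number - first] = r.one_letter
    return "".join(seq), first


# ---------------------------------------------------------------------------
# detection helpers


def _iter_atoms(structure: Structure):
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                yield chain, res, atom


def _ref(chain: Chain, res: Residue, atom: Atom) -> AtomRef:
    return AtomRef(chain.name, res.number, res.name, atom.name)


def _is_donor(res: Residue, atom: Atom) -> bool:
    if res.is_water:
        return atom.name == "O"
    if atom.name == "N" and res.name != "PRO":
        return True
    return atom.name in SIDECHAIN_DONORS.get(res.name, ())


def _is_acceptor(res: Residue, atom: Atom) -> bool:
    if res.is_water:
        return atom.name == "O"
    if atom.name in ("O", "OXT"):
        return True
    return atom.name in SIDECHAIN_ACCEPTORS.get(res.name, ())


def _antecedent(res: Residue, atom: Atom) -> Atom | None:
    name = DONOR_ANTECEDENT.get(atom.name)
    if res.name == "HIS" and atom.name == "NE2":
        name = "CD2"
    if name is None:
        return None
    return res.atom(name)


def _angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - vertex, b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def _excluded_pair(chain_a: Chain, res_a: Residue, chain_b: Chain, res_b: Residue,
                   intermolecular_only: bool) -> bool:
    if chain_a.name == chain_b.name:
        if intermolecular_only:
            return True
        # same or covalently adjacent residues never count
        if abs(res_a.number - res_b.number) <= 1:
            return True
    return False


def _geometry_ok(donor_entry, acceptor_entry, config: HBondConfig) -> bool:
    chain_d, res_d, atom_d = donor_entry
    _, _, atom_a = acceptor_entry
    ante = _antecedent(res_d, atom_d)
    if ante is not None:
        if _angle(ante.xyz, atom_d.xyz, atom_a.xyz) < config.min_antecedent_angle:
            return False
    hydrogen = res_d.atom("H") if atom_d.name == "N" else None
    if hydrogen is not None:
        if _angle(atom_d.xyz, hydrogen.xyz, atom_a.xyz) < config.min_dha_angle:
            return False
    return True


def detect_hbonds(
    structure: Structure, config: HBondConfig | None = None
) -> list[HBond]:
    """All donor–acceptor pairs satisfying the hydrogen-bond criteria.

    Sorted by distance.  With ``intermolecular_only`` (default) only
    pairs across different chains are reported; waters participate on
    both sides (use :func:`detect_water_bridges` for bridge records).
    """
    if config is None:
        config = HBondConfig()
    donors = [
        (c, r, a) for c, r, a in _iter_atoms(structure) if _is_donor(r, a)
    ]
    acceptors = [
        (c, r, a) for c, r, a in _iter_atoms(structure) if _is_acceptor(r, a)
    ]
    if not donors or not acceptors:
        return []
    tree = cKDTree(np.array([a.xyz for _, _, a in acceptors]))
    bonds = []
    for donor_entry in donors:
        chain_d, res_d, atom_d = donor_entry
        for j in tree.query_ball_point(atom_d.xyz, config.max_distance):
            chain_a, res_a, atom_a = acceptors[j]
            if res_d is res_a:
                continue
            if _excluded_pair(chain_d, res_d, chain_a, res_a, config.intermolecular_only):
                continue
            dist = float(np.linalg.norm(atom_d.xyz - atom_a.xyz))
            if dist > config.max_distance:
                continue
            if not _geometry_ok(donor_entry, (chain_a, res_a, atom_a), config):
                continue
            hydrogen = res_d.atom("H") if atom_d.name == "N" else None
            dha = (
                _angle(atom_d.xyz, hydrogen.xyz, atom_a.xyz)
                if hydrogen is not None
                else None
            )
            bonds.append(
                HBond(_ref(chain_d, res_d, atom_d), _ref(chain_a, res_a, atom_a), dist, dha)
            )
    bonds.sort(key=lambda b: (b.distance, str(b.donor), str(b.acceptor)))
    return bonds


def detect_water_bridges(
    structure: Structure, config: HBondConfig | None = None
) -> list[WaterBridge]:
    """Pairs of hydrogen bonds sharing an ordered water.

    Both water hydrogen bonds must satisfy the distance cutoff; the two
    bridged partners must come from different (non-water) chains.
    """
    if config is None:
        config = HBondConfig()
    water_cfg = replace(config, intermolecular_only=False)
    partners: dict[AtomRef, list[tuple[AtomRef, float]]] = {}
    for bond in detect_hbonds(structure, water_cfg):
        for water_side, other in ((bond.donor, bond.acceptor), (bond.acceptor, bond.donor)):
            if water_side.residue_name in WATER_NAMES and other.residue_name not in WATER_NAMES:
                partners.setdefault(water_side, []).append((other, bond.distance))
    bridges = []
    for water, linked in partners.items():
        seen = {}
        for ref, dist in linked:
            if ref not in seen or dist < seen[ref]:
                seen[ref] = dist
        refs = sorted(seen, key=str)
        for i, ref_a in enumerate(refs):
            for ref_b in refs[i + 1 :]:
                if ref_a.chain == ref_b.chain:
                    continue
                bridges.append(
                    WaterBridge(water, ref_a, ref_b, seen[ref_a], seen[ref_b])
                )
    bridges.sort(key=lambda b: (str(b.water), str(b.partner_a), str(b.partner_b)))
    return bridges


def detect_hydrophobic_contacts(
    structure: Structure, config: ContactConfig | None = None
) -> list[Contact]:
    """Apolar heavy-atom pairs within the hydrophobic cutoff, by distance."""
    if config is None:
        config = ContactConfig()
    apolar = [
        (c, r, a)
        for c, r, a in _iter_atoms(structure)
        if a.name in APOLAR_ATOMS.get(r.name, ())
    ]
    if len(apolar) < 2:
        return []
    tree = cKDTree(np.array([a.xyz for _, _, a in apolar]))
    contacts = []
    for i, j in tree.query_pairs(config.max_distance):
        chain_i, res_i, atom_i = apolar[i]
        chain_j, res_j, atom_j = apolar[j]
        if _excluded_pair(chain_i, res_i, chain_j, res_j, config.intermolecular_only):
            continue
        dist = float(np.linalg.norm(atom_i.xyz - atom_j.xyz))
        if dist > config.max_distance:
            continue
        ref_i, ref_j = _ref(chain_i, res_i, atom_i), _ref(chain_j, res_j, atom_j)
        if (ref_j.chain, ref_j.residue_number, ref_j.atom_name) < (
            ref_i.chain, ref_i.residue_number, ref_i.atom_name
        ):
            ref_i, ref_j = ref_j, ref_i
        contacts.append(Contact(ref_i, ref_j, dist))
    contacts.sort(key=lambda c: (c.distance, str(c.atom_a), str(c.atom_b)))
    return contacts


def aggregate_residue_contacts(contacts: list[Contact]) -> pd.DataFrame:
    """Residue-pair table with the minimum atom-atom distance per pair."""
    rows = {}
    for c in contacts:
        key = (
            c.atom_a.chain, c.atom_a.residue_number, c.atom_a.residue_name,
            c.atom_b.chain, c.atom_b.residue_number, c.atom_b.residue_name,
        )
        if key not in rows or c.distance < rows[key]:
            rows[key] = c.distance
    table = pd.DataFrame(
        [(*key, dist) for key, dist in sorted(rows.items())],
        columns=[
            "chain_a", "residue_a", "name_a",
            "chain_b", "residue_b", "name_b", "min_distance",
        ],
    )
    return table


def detect_beta_turns(
    structure: Structure, chain_name: str, config: HBondConfig | None = None
) -> list[BetaTurn]:
    """β-turns: i..i+3 spans with a carbonyl(i)→amide(i+3) hydrogen bond
    and Cα(i)–Cα(i+3) distance ≤ 7 Å.

    Reported with the full span and the customary central triple
    (i, i+1, i+2).  Prolines at i+3 are skipped (no amide hydrogen).
    """
    if config is None:
        config = HBondConfig()
    chain = structure.chain(chain_name)
    by_number = {r.number: r for r in chain.residues if not r.is_water}
    turns = []
    for i in sorted(by_number):
        span = [by_number.get(i + k) for k in range(4)]
        if any(r is None for r in span):
            continue
        res_i, _, _, res_i3 = span
        if res_i3.name == "PRO":
            continue
        o_i, n_i3 = res_i.atom("O"), res_i3.atom("N")
        ca_i, ca_i3 = res_i.atom("CA"), res_i3.atom("CA")
        if None in (o_i, n_i3, ca_i, ca_i3):
            continue
        hb_dist = float(np.linalg.norm(o_i.xyz - n_i3.xyz))
        ca_dist = float(np.linalg.norm(ca_i.xyz - ca_i3.xyz))
        if hb_dist > config.max_distance or ca_dist > 7.0:
            continue
        ante = res_i3.atom("CA")
        if ante is not None and _angle(ante.xyz, n_i3.xyz, o_i.xyz) < config.min_antecedent_angle:
            continue
        turns.append(
            BetaTurn(
                chain=chain_name,
                start=i,
                end=i + 3,
                central=(i, i + 1, i + 2),
                hbond_distance=hb_dist,
                ca_distance=ca_dist,
            )
        )
    return turns


# ---------------------------------------------------------------------------
# pocket classification and register assignment


def classify_pocket_occupancy(
    contacts: list[Contact],
    pockets: tuple[PocketDefinition, ...] = DEFAULT_POCKETS,
    *,
    peptide_chain: str,
) -> dict[int, PocketAssignment]:
    """Assign each contacting peptide residue to an MLLE pocket.

    A peptide residue is assigned the pocket containing the majority of
    the MLLE residues it contacts; exact ties report all tied pockets,
    flagged.  Residues whose contacts touch no pocket are omitted.
    """
    names = [p.name for p in pockets]
    if len(set(names)) != len(names):
        raise ValueError("pocket names must be unique")
    for i, p in enumerate(pockets):
        for q in pockets[i + 1 :]:
            if p.mlle_residues & q.mlle_residues:
                raise ValueError(f"pockets {p.name} and {q.name} overlap")
    votes: dict[int, Counter] = {}
    for c in contacts:
        if c.atom_a.chain == peptide_chain and c.atom_b.chain != peptide_chain:
            pep, mlle = c.atom_a, c.atom_b
        elif c.atom_b.chain == peptide_chain and c.atom_a.chain != peptide_chain:
            pep, mlle = c.atom_b, c.atom_a
        else:
            continue
        for pocket in pockets:
            if mlle.residue_number in pocket.mlle_residues:
                votes.setdefault(pep.residue_number, Counter())[pocket.name] += 1
    result = {}
    for resnum, counter in sorted(votes.items()):
        top = counter.most_common()
        best = top[0][1]
        winners = tuple(sorted(name for name, n in top if n == best))
        result[resnum] = PocketAssignment(pockets=winners, tied=len(winners) > 1)
    return result


def _has_gly_carbonyl_anchor(hbonds: list[HBond], peptide_chain: str, resnum: int) -> bool:
    for b in hbonds:
        if (
            b.donor.chain == peptide_chain
            and b.donor.residue_number == resnum
            and b.donor.atom_name == "N"
            and b.acceptor.chain != peptide_chain
            and b.acceptor.atom_name == "O"
            and b.acceptor.residue_name == "GLY"
        ):
            return True
    return False


def assign_register(
    structure: Structure,
    contacts: list[Contact],
    hbonds: list[HBond],
    pockets: tuple[PocketDefinition, ...] = DEFAULT_POCKETS,
    *,
    peptide_chain: str,
) -> RegisterAssignment:
    """Map the bound peptide's residues onto PAM2 positions.

    Anchor logic: position 10 is the peptide phenylalanine sitting in the
    shallow α3/α5 pocket whose backbone amide hydrogen-bonds a conserved
    MLLE glycine carbonyl (Gly579 in PABPC1 numbering); position 1 of the
    motif is then nine residues upstream.  Anchor positions 1, 3, 7 and
    12 are included in the mapping when the corresponding residue shows
    intermolecular contact evidence.  The offset between the position-10
    phenylalanine and the α2/α3-pocket hydrophobe (position 3) is
    cross-checked (must be 7).
    """
    chain = structure.chain(peptide_chain)
    occupancy = classify_pocket_occupancy(contacts, pockets, peptide_chain=peptide_chain)
    candidates = [
        r.number
        for r in chain.residues
        if r.name == "PHE"
        and occupancy.get(r.number) is not None
        and "α3/α5" in occupancy[r.number].pockets
        and _has_gly_carbonyl_anchor(hbonds, peptide_chain, r.number)
    ]
    if not candidates:
        raise ValueError(
            "no position-10 candidate: no peptide phenylalanine occupies the "
            "α3/α5 pocket with a glycine-carbonyl amide hydrogen bond"
        )
    phe10 = max(candidates)  # with both registers present, the C-terminal Phe anchors
    start = phe10 - 9
    evidence: dict[int, list[str]] = {}
    for c in contacts:
        for ref in (c.atom_a, c.atom_b):
            if ref.chain == peptide_chain:
                evidence.setdefault(ref.residue_number, []).append(f"contact:{c.atom_a}~{c.atom_b}")
    for b in hbonds:
        for ref in (b.donor, b.acceptor):
            if ref.chain == peptide_chain:
                evidence.setdefault(ref.residue_number, []).append(f"hbond:{b.donor}->{b.acceptor}")
    mapping = {phe10: 10}
    for pos in (1, 3, 7, 12):
        resnum = start + pos - 1
        if chain.residue(resnum) is not None and resnum in evidence:
            mapping[resnum] = pos
    pos3_res = start + 2
    offset_consistent = (
        pos3_res in occupancy
        and "α2/α3" in occupancy[pos3_res].pockets
        and phe10 - pos3_res == 7
    )
    return RegisterAssignment(
        mapping=dict(sorted(mapping.items())),
        start=start,
        anchor_evidence={k: tuple(v) for k, v in sorted(evidence.items()) if k in mapping},
        offset_consistent=offset_consistent,
    )
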