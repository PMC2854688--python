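"""Independent brute-force oracles used by the test suite.

Everything here is deliberately implemented from the definitions alone —
naive O(n²) loops and bisection — without importing the package's
detection or solver internals, so agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np

# --- motif scanning --------------------------------------------------------

ORACLE_ANCHORS = {3: set("LPF"), 5: set("PVT"), 7: {"A"}, 10: {"F"}, 12: {"P"}}


def oracle_scan_starts(sequence: str, strict: bool = False) -> list[int]:
    """1-based starts of all 12-windows satisfying the five anchors."""
    starts = []
    for i in range(len(sequence) - 11):
        window = sequence[i : i + 12]
        ok = True
        for pos, allowed in ORACLE_ANCHORS.items():
            ch = window[pos - 1]
            if ch == "X":
                if strict:
                    ok = False
            elif ch not in allowed:
                ok = False
        if ok:
            starts.append(i + 1)
    return starts


# --- competition equilibrium ----------------------------------------------


def oracle_bound_per_ligand(m_free: float, kds, exclusive: bool) -> float:
    if exclusive:
        s = sum(m_free / kd for kd in kds)
        return s / (1.0 + s)
    return sum(m_free / (kd + m_free) for kd in kds)


def oracle_free_mlle(total_mlle: float, ligands) -> float:
    """Bisection on MLLE conservation; ``ligands`` is a list of
    (total, kds, exclusive) triples."""

    def residual(m):
        bound = sum(
            total * oracle_bound_per_ligand(m, kds, excl)
            for total, kds, excl in ligands
        )
        return m + bound - total_mlle

    lo, hi = 0.0, total_mlle
    if total_mlle == 0:
        return 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# --- structure chemistry (independent copies of the criteria) ---------------

ORACLE_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
}
ORACLE_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}
ORACLE_ANTECEDENT = {
    "N": "CA", "NZ": "CE", "ND2": "CG", "NE2": "CD", "NE1": "CE2",
    "NE": "CD", "NH1": "CZ", "NH2": "CZ", "OG": "CB", "OG1": "CB",
    "OH": "CZ", "ND1": "CG",
}
ORACLE_APOLAR = {
    "ALA": {"CB"}, "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"}, "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CG", "SD", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "PRO": {"CB", "CG"}, "LYS": {"CB", "CG", "CD"}, "ARG": {"CB", "CG"},
    "GLU": {"CB", "CG"}, "GLN": {"CB", "CG"}, "ASP": {"CB"}, "ASN": {"CB"},
    "THR": {"CG2"}, "CYS": {"CB", "SG"}, "HIS": {"CB"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
}
WATERS = {"HOH", "WAT", "H2O"}


def _flat_atoms(structure):
    out = []
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                out.append((chain.name, res, atom))
    return out


def _is_donor(res, atom) -> bool:
    if res.name in WATERS:
        return atom.name == "O"
    if atom.name == "N" and res.name != "PRO":
        return True
    return atom.name in ORACLE_SIDECHAIN_DONORS.get(res.name, ())


def _is_acceptor(res, atom) -> bool:
    if res.name in WATERS:
        return atom.name == "O"
    if atom.name in ("O", "OXT"):
        return True
    return atom.name in ORACLE_SIDECHAIN_ACCEPTORS.get(res.name, ())


def _angle(a, vertex, b) -> float:
    v1 = np.asarray(a) - np.asarray(vertex)
    v2 = np.asarray(b) - np.asarray(vertex)
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def oracle_hbonds(structure, intermolecular_only=True, max_distance=3.5,
                  min_angle=90.0):
    """All-pairs hydrogen-bond detection, as (donor key, acceptor key,
    distance) with keys (chain, resnum, atom name)."""
    atoms = _flat_atoms(structure)
    bonds = set()
    for cd, rd, ad in atoms:
        if not _is_donor(rd, ad):
            continue
        for ca_, ra, aa in atoms:
            if rd is ra or not _is_acceptor(ra, aa):
                continue
            if cd == ca_:
                if intermolecular_only or abs(rd.number - ra.number) <= 1:
                    continue
            d = float(np.linalg.norm(np.asarray(ad.pos) - np.asarray(aa.pos)))
            if d > max_distance:
                continue
            ante_name = ORACLE_ANTECEDENT.get(ad.name)
            if rd.name == "HIS" and ad.name == "NE2":
                ante_name = "CD2"
            ante = rd.atom(ante_name) if ante_name else None
            if ante is not None and _angle(ante.pos, ad.pos, aa.pos) < min_angle:
                continue
            bonds.add(((cd, rd.number, ad.name), (ca_, ra.number, aa.name), round(d, 6)))
    return bonds


def oracle_contacts(structure, intermolecular_only=True, max_distance=4.5):
    """All-pairs apolar contacts as unordered key pairs with distance."""
    atoms = [
        (c, r, a) for c, r, a in _flat_atoms(structure)
        if a.name in ORACLE_APOLAR.get(r.name, ())
    ]
    contacts = set()
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            ci, ri, ai = atoms[i]
            cj, rj, aj = atoms[j]
            if ci == cj:
                if intermolecular_only or abs(ri.number - rj.number) <= 1:
                    continue
            d = float(np.linalg.norm(np.asarray(ai.pos) - np.asarray(aj.pos)))
            if d > max_distance:
                continue
            key_i = (ci, ri.number, ai.name)
            key_j = (cj, rj.number, aj.name)
            pair = (key_i, key_j) if key_i <= key_j else (key_j, key_i)
            contacts.add((*pair, round(d, 6)))
    return contacts
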