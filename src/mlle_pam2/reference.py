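"""Reference constructs and crystal forms for the MLLE/PAM2 co-crystals.

The packaged FASTA carries the crystallisation constructs: the PABPC1
MLLE domain (residues 544–626, expressed as a GST fusion that leaves a
five-residue ``GPLGS`` scar after PreScission cleavage) and the two eRF3
peptides, PAM2-N (67–81) and PAM2-C (76–90).  Both complexes crystallise
in space group P2₁2₁2 with one complex per asymmetric unit.
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources

from .crystal import CrystalForm, sequence_mw
from .synthetic import NumberedSequence

__all__ = [
    "CRYSTAL_FORMS",
    "PEPTIDE_BY_VARIANT",
    "MLLE_CONSTRUCT_ID",
    "SCAR_ID",
    "load_construct_sequences",
    "complex_mass",
    "crystal_form",
]

MLLE_CONSTRUCT_ID = "MLLE_544-626"
SCAR_ID = "GST_scar"

#: Unit cells of the two co-crystal forms (Å, orthorhombic P2₁2₁2, z=4).
CRYSTAL_FORMS: dict[str, CrystalForm] = {
    "PAM2-N": CrystalForm("P21212", a=37.43, b=63.63, c=32.23),
    "PAM2-C": CrystalForm("P21212", a=45.22, b=50.80, c=32.12),
}

PEPTIDE_BY_VARIANT = {"PAM2-N": "eRF3_67-81", "PAM2-C": "eRF3_76-90"}


def load_construct_sequences() -> dict[str, NumberedSequence]:
    """Parse the packaged construct FASTA into numbered sequences.

    Headers carry a ``first=<n>`` token giving the author residue number
    of the first character.
    """
    text = (
        resources.files("mlle_pam2").joinpath("data/constructs.fasta").read_text()
    )
    out: dict[str, NumberedSequence] = {}
    name, first, chunks = None, 1, []
    def flush():
        if name is not None:
            out[name] = NumberedSequence(
                id=name, sequence="".join(chunks), first_residue_number=first
            )
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            fields = line[1:].split()
            name = fields[0]
            first = 1
            for tok in fields[1:]:
                if tok.startswith("first="):
                    first = int(tok.split("=", 1)[1])
            chunks = []
        else:
            chunks.append(line)
    flush()
    if not out:
        raise ValueError("packaged construct FASTA is empty")
    return out


def complex_mass(variant: str, include_scar: bool = True) -> float:
    """Mass (Da) of one MLLE–peptide complex in the asymmetric unit.

    The MLLE chain is the 544–626 construct, by default with the
    ``GPLGS`` cleavage scar fused at its N terminus; the peptide chain is
    the variant's eRF3 fragment.  Each chain contributes one terminal
    water.
    """
    seqs = load_construct_sequences()
    if variant not in PEPTIDE_BY_VARIANT:
        raise ValueError(f"unknown variant {variant!r}")
    mlle = seqs[MLLE_CONSTRUCT_ID].sequence
    if include_scar:
        mlle = seqs[SCAR_ID].sequence + mlle
    peptide = seqs[PEPTIDE_BY_VARIANT[variant]].sequence
    return sequence_mw(mlle) + sequence_mw(peptide)


def crystal_form(variant: str, include_scar: bool = True) -> CrystalForm:
    """The variant's crystal form with the complex mass filled in."""
    base = CRYSTAL_FORMS[variant]
    return replace(base, complex_mw=complex_mass(variant, include_scar=include_scar))
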