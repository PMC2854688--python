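"""PAM2 consensus definition and motif scanning.

The PAM2 (PABP-interacting motif 2) is a 12-residue short linear motif
through which partner proteins (Paip1/2, eRF3, PAN3, Tob, Ataxin-2) bind
the MLLE domain of PABPC1.  High-resolution complex structures support a
refined consensus ``--Φ-(P/V)-A--F-P``: five anchor positions carry real
side-chain constraints while the remainder of the motif is free.  eRF3 is
the unusual family member: it carries two PAM2 copies offset by exactly
nine residues, so the phenylalanine that is anchor position 10 of the
N-terminal copy is simultaneously position 1 of the C-terminal copy.

This module encodes the consensus, scans numbered protein sequences for
matches (including overlapping pairs), and scores hits by how many anchor
and preference positions they satisfy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "WILDCARD",
    "PositionRule",
    "Pam2Consensus",
    "Pam2Match",
    "OverlapPair",
    "build_default_consensus",
    "scan",
    "find_overlap_pairs",
    "score_match",
    "rank_matches",
]

#: Unknown-residue character (FASTA convention); satisfies any anchor
#: unless strict mode is requested.
WILDCARD = "X"

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Length of the motif proper.  A 13th position is recorded when present
#: because its backbone amide still contacts MLLE, but it never
#: constrains matching.
MOTIF_LENGTH = 12

#: Offset between the two eRF3 PAM2 copies: position 10 of the first copy
#: coincides with position 1 of the second.
OVERLAP_OFFSET = 9

#: Anchor positions of the refined consensus (the "five conserved
#: recognition elements").
ANCHOR_POSITIONS = (3, 5, 7, 10, 12)

#: Preference positions: annotations that affect ranking only.
PREFERENCE_POSITIONS = (4, 9)


@dataclass(frozen=True)
class PositionRule:
    """Constraint attached to one motif position.

    ``required_set`` empty means the position is unconstrained.
    ``preferred_set`` is an annotation used only for scoring.
    """

    index: int
    required_set: frozenset[str] = frozenset()
    preferred_set: frozenset[str] = frozenset()
    note: str = ""

    def allows(self, residue: str, strict: bool = False) -> bool:
        if not self.required_set:
            return True
        if residue == WILDCARD:
            return not strict
        return residue in self.required_set


@dataclass(frozen=True)
class Pam2Consensus:
    """Ordered 12-position PAM2 motif definition."""

    positions: tuple[PositionRule, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != MOTIF_LENGTH:
            raise ValueError("PAM2 consensus must have exactly 12 positions")
        indices = [rule.index for rule in self.positions]
        if indices != list(range(1, MOTIF_LENGTH + 1)):
            raise ValueError("position indices must be 1..12 in order")

    def rule(self, index: int) -> PositionRule:
        return self.positions[index - 1]

    @property
    def constrained_positions(self) -> tuple[int, ...]:
        return tuple(r.index for r in self.positions if r.required_set)


@dataclass(frozen=True)
class Pam2Match:
    """A motif hit anchored in the sequence's own residue numbering.

    ``start`` is the residue number of motif position 1, so the anchor
    phenylalanine at position 10 sits at residue ``start + 9``.
    ``residue_at`` maps motif positions 1..12 (and 13 when the window has
    a following residue) to one-letter residues.
    """

    sequence_id: str
    start: int
    residue_at: dict[int, str] = field(compare=False)
    satisfied_preferences: frozenset[int] = frozenset()

    @property
    def end(self) -> int:
        return self.start + MOTIF_LENGTH - 1

    @property
    def phe10_residue_number(self) -> int:
        return self.start + OVERLAP_OFFSET

    def motif_string(self) -> str:
        return "".join(self.residue_at[p] for p in range(1, MOTIF_LENGTH + 1))


@dataclass(frozen=True)
class OverlapPair:
    """Two PAM2 hits offset by nine residues sharing one phenylalanine.

    The shared residue occupies position 10 of ``first`` and position 1
    of ``second``; in eRF3 this is Phe76.
    """

    first: Pam2Match
    second: Pam2Match
    shared_residue_index: int

    def __post_init__(self) -> None:
        if self.second.start - self.first.start != OVERLAP_OFFSET:
            raise ValueError("overlap pair must be offset by exactly 9")
        if self.shared_residue_index != self.second.start:
            raise ValueError("shared residue must be position 1 of the second match")


def build_default_consensus() -> Pam2Consensus:
    """Return the refined PAM2 consensus ``--Φ-(P/V)-A--F-P``.

    Anchors: position 3 hydrophobic Φ ∈ {L, P, F} (usually leucine),
    position 5 ∈ {P, V, T}, position 7 invariant alanine, position 10
    invariant phenylalanine (the single most important binding residue),
    position 12 usually proline.  Positions 4 (N/S) and 9 (E) are
    preferences only: they annotate scoring and never reject a match.
    """
    rules = {
        1: PositionRule(1, note="polar/charged; binds MLLE only in the eRF3 PAM2-C register"),
        2: PositionRule(2, note="polar/charged, not recognised"),
        3: PositionRule(3, frozenset("LPF"), note="Φ hydrophobic, usually leucine"),
        4: PositionRule(4, frozenset(), frozenset("NS"),
                        note="polar; side chain contacts Glu587 and stabilises the β-turn"),
        5: PositionRule(5, frozenset("PVT"), note="fits a small hydrophobic cavity in helix α5"),
        6: PositionRule(6, note="solvent exposed"),
        7: PositionRule(7, frozenset("A"), note="invariant alanine; packs on the signature methionine"),
        8: PositionRule(8, note="solvent exposed"),
        9: PositionRule(9, frozenset(), frozenset("E"),
                        note="glutamate preferred; water-mediated bonds to Gly579/Lys580 amides"),
        10: PositionRule(10, frozenset("F"), note="invariant phenylalanine, key binding determinant"),
        11: PositionRule(11, note="not conserved"),
        12: PositionRule(12, frozenset("P"), note="usually proline, extra MLLE contact"),
    }
    return Pam2Consensus(tuple(rules[i] for i in range(1, MOTIF_LENGTH + 1)))


def _validate_sequence(sequence: str) -> None:
    bad = sorted(set(sequence) - AMINO_ACIDS - {WILDCARD})
    if bad:
        raise ValueError(
            f"sequence contains non-amino-acid characters {bad!r}; "
            f"only the 20 standard one-letter codes and the wildcard "
            f"'{WILDCARD}' are accepted"
        )


def scan(
    sequence: str,
    consensus: Pam2Consensus | None = None,
    *,
    sequence_id: str = "seq",
    first_residue_number: int = 1,
    strict: bool = False,
) -> list[Pam2Match]:
    """Scan a numbered sequence for PAM2 motifs.

    Every length-12 window whose five anchor positions all satisfy their
    required sets is reported, in ascending start order; matches may
    overlap.  ``first_residue_number`` sets the residue number of the
    first character so that author numbering (e.g. eRF3 fragment 67–90)
    is preserved.  In ``strict`` mode the wildcard no longer satisfies
    anchors.

    A sequence shorter than 12 residues yields an empty list.
    """
    if consensus is None:
        consensus = build_default_consensus()
    _validate_sequence(sequence)
    matches: list[Pam2Match] = []
    n = len(sequence)
    for offset in range(n - MOTIF_LENGTH + 1):
        window = sequence[offset : offset + MOTIF_LENGTH]
        if not all(
            consensus.rule(p).allows(window[p - 1], strict=strict)
            for p in consensus.constrained_positions
        ):
            continue
        residue_at = {p: window[p - 1] for p in range(1, MOTIF_LENGTH + 1)}
        if offset + MOTIF_LENGTH < n:
            residue_at[13] = sequence[offset + MOTIF_LENGTH]
        prefs = frozenset(
            p
            for p in PREFERENCE_POSITIONS
            if residue_at[p] in consensus.rule(p).preferred_set
        )
        matches.append(
            Pam2Match(
                sequence_id=sequence_id,
                start=first_residue_number + offset,
                residue_at=residue_at,
                satisfied_preferences=prefs,
            )
        )
    return matches


def find_overlap_pairs(matches: list[Pam2Match]) -> list[OverlapPair]:
    """Return all pairs of hits offset by exactly 9 sharing an F.

    The shared residue (position 10 of the first hit, position 1 of the
    second) must be phenylalanine — a wildcard there is not accepted,
    since the overlap's defining feature is the shared phenylalanine.
    """
    by_start = {m.start: m for m in matches}
    pairs = []
    for m in sorted(matches, key=lambda m: m.start):
        partner = by_start.get(m.start + OVERLAP_OFFSET)
        if partner is None:
            continue
        if m.residue_at[10] == "F" and partner.residue_at[1] == "F":
            pairs.append(OverlapPair(m, partner, shared_residue_index=partner.start))
    return pairs


def score_match(match: Pam2Match, consensus: Pam2Consensus | None = None) -> float:
    """Score a hit in [0, 1].

    Anchors matched without a wildcard plus satisfied preferences at
    positions 4 and 9, out of seven.  Anchor positions are pass/fail at
    scan time; the score only ranks hits.
    """
    if consensus is None:
        consensus = build_default_consensus()
    anchors = sum(
        1
        for p in consensus.constrained_positions
        if match.residue_at[p] in consensus.rule(p).required_set
    )
    return (anchors + len(match.satisfied_preferences)) / (
        len(consensus.constrained_positions) + len(PREFERENCE_POSITIONS)
    )


def rank_matches(
    matches: list[Pam2Match], consensus: Pam2Consensus | None = None
) -> list[Pam2Match]:
    """Sort by descending score, ties broken by ascending start."""
    if consensus is None:
        consensus = build_default_consensus()
    return sorted(matches, key=lambda m: (-score_match(m, consensus), m.start))
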