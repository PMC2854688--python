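"""Motif scanner tests: oracle agreement, numbering, scoring, overlaps."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mlle_pam2 import motif
from mlle_pam2.motif import (
    ANCHOR_POSITIONS,
    MOTIF_LENGTH,
    OVERLAP_OFFSET,
    OverlapPair,
    build_default_consensus,
    find_overlap_pairs,
    rank_matches,
    scan,
    score_match,
)
from oracles import oracle_scan_starts

# alphabet enriched in anchor residues so random sequences produce matches
ENRICHED = list("ACDEFGHIKLMNPQRSTVWY") + list("LPFAVTX" * 3)


def test_consensus_shape():
    consensus = build_default_consensus()
    assert len(consensus.positions) == MOTIF_LENGTH == 12
    assert consensus.constrained_positions == ANCHOR_POSITIONS == (3, 5, 7, 10, 12)
    assert consensus.rule(3).required_set == frozenset("LPF")
    assert consensus.rule(5).required_set == frozenset("PVT")
    assert consensus.rule(7).required_set == frozenset("A")
    assert consensus.rule(10).required_set == frozenset("F")
    assert consensus.rule(12).required_set == frozenset("P")
    assert consensus.rule(4).preferred_set == frozenset("NS")
    assert consensus.rule(9).preferred_set == frozenset("E")


def _random_consensus_window(rng) -> str:
    """A 12-mer satisfying all anchors over random background."""
    consensus = motif.build_default_consensus()
    window = [str(c) for c in rng.choice(ENRICHED, size=12)]
    for pos in consensus.constrained_positions:
        window[pos - 1] = str(rng.choice(sorted(consensus.rule(pos).required_set)))
    return "".join(window)


def test_scanner_matches_brute_force_oracle():
    rng = np.random.default_rng(101)
    n_with_matches = 0
    for _ in range(1200):
        length = int(rng.integers(0, 80))
        seq = "".join(rng.choice(ENRICHED, size=length))
        # splice in a consensus window half the time so the comparison
        # exercises genuine hits, not just empty agreement
        if length >= 12 and rng.random() < 0.5:
            at = int(rng.integers(0, length - 11))
            seq = seq[:at] + _random_consensus_window(rng) + seq[at + 12 :]
        for strict in (False, True):
            got = [m.start for m in scan(seq, strict=strict)]
            assert got == oracle_scan_starts(seq, strict=strict), (seq, strict)
        if got:
            n_with_matches += 1
    assert n_with_matches > 50  # the comparison actually exercised hits


def test_shift_equivariance_of_numbering():
    rng = np.random.default_rng(7)
    for _ in range(50):
        seq = "".join(rng.choice(ENRICHED, size=40))
        base = [m.start for m in scan(seq)]
        shifted = [m.start for m in scan(seq, first_residue_number=67)]
        assert shifted == [s + 66 for s in base]


def test_short_sequence_yields_empty():
    assert scan("") == []
    assert scan("ALAFP") == []
    assert scan("A" * 11) == []


def test_invalid_characters_rejected():
    with pytest.raises(ValueError, match="non-amino-acid"):
        scan("AALAPAAAFAP1")
    with pytest.raises(ValueError, match="non-amino-acid"):
        scan("aalapxaaafap")  # lowercase is not accepted


def test_wildcard_policy():
    window = "XXLXVXXXXFXP"  # anchor position 7 is a wildcard
    assert [m.start for m in scan(window)] == [1]
    assert scan(window, strict=True) == []
    # the wildcard anchor never counts towards the score (4 real anchors)
    (m,) = scan(window)
    assert score_match(m) == pytest.approx(4 / 7)


def test_position_13_recorded_but_not_constraining():
    core = "AALAPAAAAFAP"
    assert scan(core)[0].residue_at.get(13) is None
    (m,) = scan(core + "W")
    assert m.residue_at[13] == "W"
    # any residue at 13 still matches
    for ch in "WGPX":
        assert len(scan(core + ch)) == 1


def test_overlap_pair_detection_requires_shared_phe():
    # two registers offset by 9 sharing the F at position 10/1
    seq = "AALAPAAAAFAPAVAAAAFAP"
    matches = scan(seq)
    assert [m.start for m in matches] == [1, 10]
    pairs = find_overlap_pairs(matches)
    assert len(pairs) == 1
    assert pairs[0].shared_residue_index == 10
    assert pairs[0].first.phe10_residue_number == pairs[0].second.start


def test_overlap_pair_rejects_wildcard_phe():
    seq = "AALAPAAAAXAPAVAAAAFAP"  # shared position is a wildcard
    matches = scan(seq)
    assert [m.start for m in matches] == [1, 10]
    assert find_overlap_pairs(matches) == []


def test_overlap_pair_validation():
    m1, m2 = scan("AALAPAAAAFAPAVAAAAFAP")
    with pytest.raises(ValueError, match="offset"):
        OverlapPair(m1, m1, shared_residue_index=1)
    with pytest.raises(ValueError, match="shared residue"):
        OverlapPair(m1, m2, shared_residue_index=1)


def test_scoring_and_ranking():
    # perfect seven-of-seven: anchors + N at 4 + E at 9
    perfect = "AALNPAAAEFAP"
    (m,) = scan(perfect)
    assert score_match(m) == 1.0
    weaker = "AALAPAAAAFAP"  # anchors only
    (w,) = scan(weaker)
    assert score_match(w) == pytest.approx(5 / 7)
    ranked = rank_matches([w, m])
    assert ranked[0].motif_string() == perfect


@given(
    st.integers(0, 30),
    st.text(alphabet="ACDEGHIKMQRSWY", min_size=0, max_size=30),
    st.text(alphabet="ACDEGHIKMQRSWY", min_size=0, max_size=30),
)
def test_planted_window_always_found(pad, left, right):
    """A consensus-satisfying window is found wherever it is planted,
    inside any background free of anchor residues."""
    window = "AALNPAAAEFAP"
    seq = left + window + right
    starts = [m.start for m in scan(seq)]
    assert len(left) + 1 in starts
    assert starts == oracle_scan_starts(seq)
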