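"""Sequence-pair validation and the two encoding schemes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from offgru.encoding import (BASE_ORDER, GAP, PAIR_ORDER, GuidePair,
                             PairValidationError, decode_16ch,
                             encode_pair_7ch, encode_pair_16ch,
                             format_matrix, validate_pair)

GUIDE = "GACGCATAAAGATGAGACGCTGG"  # 20-nt protospacer + TGG PAM


def pair_with_target(target: str, guide: str = GUIDE) -> GuidePair:
    return GuidePair(guide, target)


def onehot(base: str) -> np.ndarray:
    v = np.zeros(4, dtype=int)
    v[BASE_ORDER.index(base)] = 1
    return v


# ---------------------------------------------------------------------------
# 7-channel scheme
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("base,expected", [
    ("A", (1, 0, 0, 0)), ("T", (0, 1, 0, 0)),
    ("G", (0, 0, 1, 0)), ("C", (0, 0, 0, 1)),
])
def test_matched_base_channels(base, expected):
    """A matched base pair XX sets exactly the single one-hot bit of X."""
    guide = base * 20 + "TGG"
    mat = encode_pair_7ch(GuidePair(guide, guide))
    assert tuple(mat[0, :4]) == expected


def test_perfect_match_pad_and_bits():
    """23-nt perfect match: 23 single-bit base columns, one all-zero pad
    between protospacer and PAM, channels 5-7 zero everywhere."""
    mat = encode_pair_7ch(GuidePair(GUIDE, GUIDE))
    assert mat.shape == (24, 7)
    base_bits = mat[:, :4].sum(axis=1)
    assert base_bits[20] == 0  # pad sits between protospacer and PAM
    assert (np.delete(base_bits, 20) == 1).all()
    assert (mat[:, 4:] == 0).all()


def test_or_composite_bit_counts_match_enumeration():
    """Across all 16 ordered base combinations the OR composite has one
    base bit for the 4 matches and two for the 12 mismatches, equal to an
    independent one-hot OR enumeration."""
    for g in BASE_ORDER:
        for d in BASE_ORDER:
            guide = g + "A" * 19 + "TGG"
            target = d + "A" * 19 + "TGG"
            mat = encode_pair_7ch(GuidePair(guide, target))
            expected = np.logical_or(onehot(g), onehot(d)).astype(int)
            assert (mat[0, :4] == expected).all()
            assert mat[0, :4].sum() == (1 if g == d else 2)


def test_mismatch_direction_bits():
    """Direction bits: channel 6 when the guide base's channel index
    precedes the DNA base's, channel 7 for the converse, neither on match."""
    for g in BASE_ORDER:
        for d in BASE_ORDER:
            mat = encode_pair_7ch(GuidePair(g + "A" * 19 + "TGG",
                                            d + "A" * 19 + "TGG"))
            if g == d:
                assert (mat[0, 5:7] == 0).all()
            elif BASE_ORDER.index(g) < BASE_ORDER.index(d):
                assert tuple(mat[0, 5:7]) == (1, 0)
            else:
                assert tuple(mat[0, 5:7]) == (0, 1)


def test_bulge_channels(fixture_pairs):
    """RNA/DNA bulges set the indel flag at exactly one position and the
    matching direction bit; 24-nt pairs are not padded."""
    rna = next(p for p in fixture_pairs if GAP in p.target_seq)
    dna = next(p for p in fixture_pairs if GAP in p.guide_seq)
    m_rna = encode_pair_7ch(rna)
    m_dna = encode_pair_7ch(dna)
    assert m_rna[:, 4].sum() == 1 and m_dna[:, 4].sum() == 1
    (i_rna,) = np.flatnonzero(m_rna[:, 4])
    (i_dna,) = np.flatnonzero(m_dna[:, 4])
    assert rna.target_seq[i_rna] == GAP
    assert dna.guide_seq[i_dna] == GAP
    assert m_rna[i_rna, 5] == 1 and m_rna[i_rna, 6] == 0
    assert m_dna[i_dna, 6] == 1 and m_dna[i_dna, 5] == 0


# ---------------------------------------------------------------------------
# 16-channel scheme
# ---------------------------------------------------------------------------

def test_16ch_worked_vectors():
    """AA is the first channel and CG the last of the fixed order."""
    aa = encode_pair_16ch(GuidePair("A" * 20 + "TGG", "A" * 20 + "TGG"))
    assert (aa[0] == np.eye(16)[0]).all()

    cg = encode_pair_16ch(GuidePair("C" + "A" * 19 + "TGG",
                                    "G" + "A" * 19 + "TGG"))
    assert PAIR_ORDER[15] == "CG"
    assert (cg[0] == np.eye(16)[15]).all()


def test_16ch_round_trip_all_pairs():
    """Encoding then decoding recovers the exact base pair at every
    position for all 16 ordered combinations."""
    for g in BASE_ORDER:
        for d in BASE_ORDER:
            pair = GuidePair(g + "A" * 19 + "TGG", d + "A" * 19 + "TGG")
            guide, target = decode_16ch(encode_pair_16ch(pair))
            assert guide[0] == g and target[0] == d
            # pad decodes to '-', everything else round-trips exactly
            assert guide.replace("-", "") == pair.guide_seq
            assert target.replace("-", "") == pair.target_seq


def test_16ch_columns_one_hot(small_dataset):
    pairs, _ = small_dataset
    for p in pairs[:50]:
        m = encode_pair_16ch(p)
        sums = m.sum(axis=1)
        assert set(sums.tolist()) <= {0, 1}
        assert sums[20] == 0  # pad position


def test_projection_16_to_7(small_dataset):
    """For mismatch-only pairs the 7-channel encoding is reconstructible
    from the 16-channel one."""
    pairs, _ = small_dataset
    for p in pairs[:40]:
        guide, target = decode_16ch(encode_pair_16ch(p))
        rebuilt = GuidePair(guide.replace("-", ""), target.replace("-", ""),
                            p.label, p.guide_id)
        assert (encode_pair_7ch(rebuilt) == encode_pair_7ch(p)).all()


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def independent_check(guide: str, target: str) -> int:
    """Character-by-character re-check of the alignment invariants,
    written independently of validate_pair."""
    count = 0
    if len(guide) != len(target):
        return 1
    for a, b in zip(guide, target):
        if a not in "ACGT_":
            count += 1
        if b not in "ACGT_":
            count += 1
        if a == "_" and b == "_":
            count += 1
    gaps = guide.count("_") + target.count("_")
    if len(guide) == 23 and gaps != 0:
        count += 1
    elif len(guide) == 24 and gaps != 1:
        count += 1
    elif len(guide) not in (23, 24):
        count += 1
    tail = [c for c in target if c != "_"][-2:]
    if tail != ["G", "G"]:
        count += 1
    return count


def test_validate_pair_trivial_cases():
    assert validate_pair(GuidePair(GUIDE, GUIDE)) == []
    double_gap = GuidePair(GUIDE[:5] + "_" + GUIDE[6:] + "A",
                           GUIDE[:5] + "_" + GUIDE[6:] + "A")
    bad = validate_pair(double_gap)
    assert any("both strands" in v for v in bad)


def test_validate_matches_independent_checker():
    """Violation counts on randomly corrupted pairs agree with an
    independent character-level checker."""
    rng = np.random.default_rng(5)
    alphabet = list("ACGT_X")
    for _ in range(200):
        n = int(rng.choice([22, 23, 24]))
        guide = "".join(rng.choice(alphabet, n))
        target = "".join(rng.choice(alphabet, n))
        pair = GuidePair(guide, target)
        ours = validate_pair(pair)
        theirs = independent_check(guide, target)
        assert (len(ours) == 0) == (theirs == 0), (guide, target, ours)


def test_encode_raises_with_position(fixture_pairs):
    bad = GuidePair(GUIDE, GUIDE[:-1] + "A")  # target PAM broken
    with pytest.raises(PairValidationError, match="PAM"):
        encode_pair_7ch(bad)
    with pytest.raises(PairValidationError):
        encode_pair_16ch(GuidePair(GUIDE + "A", GUIDE))


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

@st.composite
def valid_pairs(draw):
    bases = "ACGT"
    guide = "".join(draw(st.lists(st.sampled_from(bases), min_size=20,
                                  max_size=20)))
    pam = draw(st.sampled_from(bases)) + "GG"
    guide += pam
    target = list(guide)
    n_mm = draw(st.integers(0, 6))
    positions = draw(st.permutations(range(20)))[:n_mm]
    for p in positions:
        target[p] = draw(st.sampled_from([b for b in bases if b != guide[p]]))
    return GuidePair(guide, "".join(target))


@settings(max_examples=60, derandomize=True)
@given(valid_pairs())
def test_7ch_invariants_on_random_pairs(pair):
    """Binary (24,7) output with per-position bit-count rules, and
    deterministic."""
    mat = encode_pair_7ch(pair)
    assert mat.shape == (24, 7)
    assert set(np.unique(mat).tolist()) <= {0, 1}
    for i, (g, d) in enumerate(zip(pair.guide_seq[:20], pair.target_seq[:20])):
        expected_bits = 1 if g == d else 2
        assert mat[i, :4].sum() == expected_bits
    assert (mat == encode_pair_7ch(pair)).all()
    m16 = encode_pair_16ch(pair)
    nonpad = np.delete(np.arange(24), 20)
    assert (m16[nonpad].sum(axis=1) == 1).all()


def test_format_matrix_dump():
    text = format_matrix(encode_pair_7ch(GuidePair(GUIDE, GUIDE)))
    assert "PAM1" in text and "indel" in text
    assert len(text.splitlines()) == 25
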