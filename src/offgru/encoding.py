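"""Encoding of aligned sgRNA-DNA sequence pairs.

An off-target record is an aligned pair of a guide sequence (20-nt
protospacer followed by a 3-nt NGG PAM) and a genomic target sequence.
Mismatches are positions where the two bases differ; a single 1-bp bulge
(RNA bulge = unpaired guide base, DNA bulge = unpaired target base) is
written as ``_`` on the strand that lacks the base.  Aligned pairs are 23 nt
long without a bulge and 24 nt with one.

Two numeric encodings are provided:

* a 24x7 binary matrix (``encode_pair_7ch``): channels 1-4 hold the OR of
  the one-hot codes of the two bases (order A, T, G, C), channel 5 flags a
  bulge, channels 6-7 record mismatch/bulge direction.  23-nt pairs are
  padded to 24 by inserting one all-zero position between the protospacer
  and the PAM.
* a 24x16 one-hot matrix (``encode_pair_16ch``) over ordered (guide base,
  DNA base) combinations.  Unlike the OR composite this keeps the exact
  identity of each mismatch, which is what makes base-pair level
  attribution possible; bulge positions have no base pair and encode as
  all-zero columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Base-channel order of the 7-channel scheme (fixed by the worked
#: examples AA->1000, TT->0100, GG->0010, CC->0001).
BASE_ORDER = "ATGC"
BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

#: Channel order of the 16-channel base-pair scheme: guide base blocks
#: A, T, G, C; within each block the DNA base runs A, T, C, G uniformly
#: (AA is the first channel and CG the last, per the worked examples).
PAIR_ORDER = tuple(g + d for g in "ATGC" for d in "ATCG")
PAIR_INDEX = {p: i for i, p in enumerate(PAIR_ORDER)}

ALPHABET = set("ACGT_")
ENCODED_LENGTH = 24
GUIDE_LENGTH = 23  # 20-nt protospacer + 3-nt PAM, before any bulge

GAP = "_"


class PairValidationError(ValueError):
    """Raised when a sequence pair violates the alignment invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid sgRNA-DNA pair: " + "; ".join(self.violations))


@dataclass(frozen=True)
class GuidePair:
    """One aligned sgRNA-DNA record.

    Parameters
    ----------
    guide_seq
        Guide sequence over ``{A,C,G,T,_}``: 20-nt protospacer + NGG PAM,
        with ``_`` marking the gap opposite a DNA bulge.
    target_seq
        Aligned target DNA sequence of equal length, ``_`` marking the gap
        opposite an RNA bulge.
    label
        1 for a validated off-target site, 0 otherwise.
    guide_id
        Identifier grouping records that share an sgRNA (used by
        leave-one-sgRNA-out splits).
    """

    guide_seq: str
    target_seq: str
    label: int = 0
    guide_id: str = ""

    @property
    def has_indel(self) -> bool:
        return GAP in self.guide_seq or GAP in self.target_seq

    def validate(self) -> list[str]:
        return validate_pair(self)


def validate_pair(pair: GuidePair) -> list[str]:
    """Check all alignment invariants; return a list of violations.

    Total function: never raises.  An empty list means the pair is valid.
    Each violation names the invariant and, where meaningful, the 0-based
    offending position.
    """
    g, t = pair.guide_seq, pair.target_seq
    violations: list[str] = []

    if len(g) != len(t):
        violations.append(
            f"length mismatch: guide has {len(g)} characters, target has {len(t)}"
        )
        return violations  # positional checks are meaningless past this point

    for i, (a, b) in enumerate(zip(g, t)):
        if a not in ALPHABET:
            violations.append(f"illegal character {a!r} in guide at position {i}")
        if b not in ALPHABET:
            violations.append(f"illegal character {b!r} in target at position {i}")
        if a == GAP and b == GAP:
            violations.append(f"gap on both strands at position {i}")

    n_gaps = g.count(GAP) + t.count(GAP)
    if len(g) == GUIDE_LENGTH:
        if n_gaps > 0:
            violations.append("23-nt pair must not contain a bulge gap")
    elif len(g) == GUIDE_LENGTH + 1:
        if n_gaps != 1:
            violations.append(
                f"24-nt pair must contain exactly one bulge gap, found {n_gaps}"
            )
    else:
        violations.append(
            f"aligned length must be 23 or 24, got {len(g)}"
        )

    if pair.label not in (0, 1):
        violations.append(f"label must be 0 or 1, got {pair.label!r}")

    # NGG PAM: the two 3'-most non-gap target bases must be GG.
    tail = [b for b in t if b != GAP][-2:]
    if len(tail) < 2 or tail != ["G", "G"]:
        violations.append(
            "target PAM must end in GG at the two 3'-most non-gap positions"
        )
    return violations


def _checked(pair: GuidePair) -> GuidePair:
    violations = validate_pair(pair)
    if violations:
        raise PairValidationError(violations)
    return pair


def _padded_columns(pair: GuidePair) -> list[tuple[str, str]]:
    """Aligned (guide, target) character columns, padded to 24.

    23-nt (mismatch-only) pairs get one all-zero pad column, written
    ``("-", "-")``, inserted between the protospacer and the PAM.
    """
    cols = list(zip(pair.guide_seq, pair.target_seq))
    if len(cols) == GUIDE_LENGTH:
        cols.insert(GUIDE_LENGTH - 3, ("-", "-"))
    return cols


def encode_pair_7ch(pair: GuidePair) -> np.ndarray:
    """Encode a pair as the 24x7 OR-composite binary matrix.

    Channels (0-based columns):

    0-3  OR of the one-hot base codes (order A, T, G, C): one bit set at a
         match, two at a mismatch, the unpaired base's bit at a bulge, none
         at the pad position.
    4    bulge flag: 1 iff either strand has ``_`` here.
    5    set for a mismatch whose guide base precedes the DNA base in the
         A,T,G,C channel order, and for RNA bulges (unpaired guide base).
    6    the converse mismatch direction, and DNA bulges.

    Raises :class:`PairValidationError` on an invalid pair.
    """
    _checked(pair)
    mat = np.zeros((ENCODED_LENGTH, 7), dtype=np.int8)
    for i, (a, b) in enumerate(_padded_columns(pair)):
        if (a, b) == ("-", "-"):
            continue  # pad column: all channels stay 0
        if a == GAP:  # DNA bulge: unpaired target base
            mat[i, BASE_INDEX[b]] = 1
            mat[i, 4] = 1
            mat[i, 6] = 1
        elif b == GAP:  # RNA bulge: unpaired guide base
            mat[i, BASE_INDEX[a]] = 1
            mat[i, 4] = 1
            mat[i, 5] = 1
        else:
            mat[i, BASE_INDEX[a]] = 1
            mat[i, BASE_INDEX[b]] = 1
            if a != b:
                if BASE_INDEX[a] < BASE_INDEX[b]:
                    mat[i, 5] = 1
                else:
                    mat[i, 6] = 1
    return mat


def encode_pair_16ch(pair: GuidePair) -> np.ndarray:
    """Encode a pair as the 24x16 base-pair one-hot matrix.

    Each non-pad, non-bulge position is one-hot over the 16 ordered
    (guide, DNA) base combinations in :data:`PAIR_ORDER`.  Pad and bulge
    positions are all-zero columns, so this scheme carries base-pair
    information only; downstream consumers that need bulges should use the
    7-channel scheme.
    """
    _checked(pair)
    mat = np.zeros((ENCODED_LENGTH, 16), dtype=np.int8)
    for i, (a, b) in enumerate(_padded_columns(pair)):
        if GAP in (a, b) or (a, b) == ("-", "-"):
            continue
        mat[i, PAIR_INDEX[a + b]] = 1
    return mat


def decode_16ch(matrix: np.ndarray) -> tuple[str, str]:
    """Invert :func:`encode_pair_16ch` (pad/bulge columns decode to ``-``)."""
    matrix = np.asarray(matrix)
    if matrix.shape != (ENCODED_LENGTH, 16):
        raise ValueError(f"expected a (24, 16) matrix, got {matrix.shape}")
    guide, target = [], []
    for row in matrix:
        hot = np.flatnonzero(row)
        if hot.size == 0:
            guide.append("-")
            target.append("-")
        elif hot.size == 1:
            pair = PAIR_ORDER[hot[0]]
            guide.append(pair[0])
            target.append(pair[1])
        else:
            raise ValueError("16-channel columns must be one-hot or all-zero")
    return "".join(guide), "".join(target)


def encode_batch(pairs: list[GuidePair], scheme: str = "7ch") -> np.ndarray:
    """Stack per-pair encodings into an (n, 24, channels) float32 tensor."""
    if scheme == "7ch":
        enc = encode_pair_7ch
    elif scheme == "16ch":
        enc = encode_pair_16ch
    else:
        raise ValueError(f"unknown scheme {scheme!r}; use '7ch' or '16ch'")
    if not pairs:
        width = 7 if scheme == "7ch" else 16
        return np.zeros((0, ENCODED_LENGTH, width), dtype=np.float32)
    return np.stack([enc(p) for p in pairs]).astype(np.float32)


def position_labels(has_indel: bool = False) -> list[str]:
    """Row labels for a 24-row encoding.

    For mismatch-only pairs, protospacer positions are numbered 1-20 from
    the PAM-distal end, followed by the pad row and the three PAM bases.
    Pairs with a bulge fill all 24 rows, so rows are labelled by aligned
    index instead.
    """
    if has_indel:
        return [f"aln{i + 1}" for i in range(ENCODED_LENGTH)]
    return [str(i + 1) for i in range(20)] + ["pad", "PAM1", "PAM2", "PAM3"]


def format_matrix(matrix: np.ndarray, header: tuple[str, ...] | None = None) -> str:
    """Plain-text dump of an encoded matrix (debugging / docs)."""
    matrix = np.asarray(matrix)
    if header is None:
        header = (
            ("A", "T", "G", "C", "indel", "dir<", "dir>")
            if matrix.shape[1] == 7
            else PAIR_ORDER
        )
    lines = ["pos  " + " ".join(f"{h:>5s}" for h in header)]
    labels = position_labels(False) if matrix.shape[0] == ENCODED_LENGTH else None
    for i, row in enumerate(matrix):
        tag = labels[i] if labels else str(i + 1)
        lines.append(f"{tag:>4s} " + " ".join(f"{int(v):>5d}" for v in row))
    return "\n".join(lines)
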