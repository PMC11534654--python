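"""Compositional encoders for coding sequences.

A coding sequence (CDS) is decomposed into five fixed-length trait vectors:

========== ====== =====================================================
trait      length meaning
========== ====== =====================================================
``dnt``        48 16 dinucleotides x 3 codon-phase classes
``dcr``      1536 256 ordered dinucleotide pairs x 6 positional classes
``codon``      64 codon usage over all 64 codons
``codonpair`` 3721 61 x 61 ordered pairs of consecutive sense codons
``aa``         20 amino-acid usage of the translated frame-0 product
========== ====== =====================================================

Index schemes (pinned conventions)
----------------------------------
Nucleotides are ordered **T, C, A, G** everywhere; a dinucleotide ``xy``
has index ``4*i(x) + i(y)`` and a codon ``xyz`` has index
``16*i(x) + 4*i(y) + i(z)`` under that order.

*dnt* — vector index ``class*16 + dinucleotide`` with classes ordered
``(1,2)`` (codon positions 1-2), ``(2,3)`` (positions 2-3) and ``(3,1)``
(position 3 paired with position 1 of the *next* codon; the final codon
contributes no such pair).  Each 16-entry class block is normalised to
sum 1 over its own total.

*dcr* — vector index ``class*256 + first_dinuc*16 + second_dinuc``.
The 6 classes are the grid (start phase of the first dinucleotide
``i in {1,2,3}``) x (start offset of the second dinucleotide relative
to the first, ``+1`` overlapping or ``+2`` adjacent), ordered
``(1,+1),(1,+2),(2,+1),(2,+2),(3,+1),(3,+2)``.  Each 256-entry class
block is normalised to sum 1.  ``dcr_to_tensor`` reshapes this vector
to ``(6, 16, 16)`` = (class, first dinucleotide, second dinucleotide).

*codon* — ``freq(c) = count(c) * 64 * 3 / L`` with ``L`` the full
sequence length; counts are over complete frame-0 codons (a trailing
partial codon is ignored but still contributes to ``L``).

*codonpair* — 61 sense codons (stops excluded) in T,C,A,G codon order;
pairs are the overlapping walk over consecutive in-frame codons, pairs
containing a stop are skipped; ``freq = count * 3721 * 3 / L``.

*aa* — the 20 standard amino acids in one-letter alphabetical order
(``ACDEFGHIKLMNPQRSTVWY``); stops are untallied;
``freq = count * 20 * 3 / L``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

NUCLEOTIDE_ORDER = "TCAG"
_NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDE_ORDER)}

DINUCLEOTIDES = [a + b for a in NUCLEOTIDE_ORDER for b in NUCLEOTIDE_ORDER]
CODONS = [a + b + c for a in NUCLEOTIDE_ORDER for b in NUCLEOTIDE_ORDER
          for c in NUCLEOTIDE_ORDER]
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]
_SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

DNT_CLASSES = ["(1,2)", "(2,3)", "(3,1)"]
DCR_CLASSES = ["(1,+1)", "(1,+2)", "(2,+1)", "(2,+2)", "(3,+1)", "(3,+2)"]

TRAIT_DIMENSIONS = {"dnt": 48, "dcr": 1536, "codon": 64,
                    "codonpair": 3721, "aa": 20}


class SequenceError(ValueError):
    """Raised for sequences outside the {A,C,G,T} alphabet or too short."""


@dataclass
class CompositionVector:
    """One fixed-length trait vector for a single sequence.

    ``index_scheme`` names the feature behind every vector component, in
    order, so downstream tables stay self-describing.
    """

    trait: str
    values: np.ndarray
    index_scheme: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        expected = TRAIT_DIMENSIONS[self.trait]
        if len(self.values) != expected:
            raise ValueError(
                f"{self.trait} vector must have length {expected}, "
                f"got {len(self.values)}")


def encode_bases(sequence: str) -> np.ndarray:
    """Map an A/C/G/T string to integer codes under T,C,A,G order."""
    seq = sequence.upper()
    try:
        return np.fromiter((_NT_INDEX[c] for c in seq), dtype=np.int64,
                           count=len(seq))
    except KeyError as exc:
        raise SequenceError(f"non-ACGT character {exc.args[0]!r}") from None


def feature_names(trait: str) -> list[str]:
    """The documented index scheme: component ``i`` of a trait vector."""
    if trait == "dnt":
        return [f"dnt{cls}:{d}" for cls in DNT_CLASSES for d in DINUCLEOTIDES]
    if trait == "dcr":
        return [f"dcr{cls}:{d1}.{d2}" for cls in DCR_CLASSES
                for d1 in DINUCLEOTIDES for d2 in DINUCLEOTIDES]
    if trait == "codon":
        return [f"codon:{c}" for c in CODONS]
    if trait == "codonpair":
        return [f"codonpair:{c1}.{c2}" for c1 in SENSE_CODONS
                for c2 in SENSE_CODONS]
    if trait == "aa":
        return [f"aa:{a}" for a in AMINO_ACIDS]
    raise ValueError(f"unknown trait {trait!r}")


def _normalize_block(counts: np.ndarray, label: str) -> np.ndarray:
    total = counts.sum()
    if total == 0:
        logger.warning("empty positional class %s: block left all-zero", label)
        return np.zeros_like(counts, dtype=float)
    return counts / total


def count_dnt(sequence: str) -> CompositionVector:
    """Positional dinucleotide composition: 16 dinucleotides x 3 classes.

    Classes pair codon positions (1,2), (2,3) and (3, next codon's 1);
    each class block is normalised to sum 1 by its own total.
    """
    codes = encode_bases(sequence)
    L = len(codes)
    if L < 6:
        raise SequenceError("sequence shorter than 6 nt")
    pair_codes = 4 * codes[:-1] + codes[1:]          # dinuc starting at p
    start_phase = np.arange(L - 1) % 3               # 0-based codon phase
    blocks = []
    for phase in range(3):
        counts = np.bincount(pair_codes[start_phase == phase], minlength=16)
        blocks.append(_normalize_block(counts, f"dnt{DNT_CLASSES[phase]}"))
    return CompositionVector("dnt", np.concatenate(blocks),
                             feature_names("dnt"))


def count_dcr(sequence: str) -> CompositionVector:
    """Dinucleotide composition representation: 256 ordered dinucleotide
    pairs x 6 positional classes (start phase x overlap offset).

    For a first dinucleotide starting at phase ``i``, the paired second
    dinucleotide starts either 1 base later (overlapping) or 2 bases
    later (adjacent).  Each of the 6 class blocks is normalised to sum 1
    over its 256 pair types.
    """
    codes = encode_bases(sequence)
    L = len(codes)
    if L < 6:
        raise SequenceError("sequence shorter than 6 nt")
    dinuc = 4 * codes[:-1] + codes[1:]               # index p -> dinuc at p
    phases = np.arange(L - 1) % 3
    blocks = []
    for phase in range(3):
        for offset in (1, 2):
            # first dinuc at p, second at p+offset; both need p+offset+1 < L
            valid = np.flatnonzero(phases == phase)
            valid = valid[valid + offset + 1 < L]
            pair = 16 * dinuc[valid] + dinuc[valid + offset]
            counts = np.bincount(pair, minlength=256)
            cls = DCR_CLASSES[2 * phase + (offset - 1)]
            blocks.append(_normalize_block(counts, f"dcr{cls}"))
    return CompositionVector("dcr", np.concatenate(blocks),
                             feature_names("dcr"))


def _codon_codes(codes: np.ndarray) -> np.ndarray:
    n = len(codes) // 3
    trimmed = codes[:3 * n]
    return (16 * trimmed[0::3] + 4 * trimmed[1::3] + trimmed[2::3])


def count_codon(sequence: str) -> CompositionVector:
    """Codon usage over all 64 codons, scaled by 64*3/L."""
    codes = encode_bases(sequence)
    L = len(codes)
    if L < 3:
        raise SequenceError("sequence shorter than 3 nt")
    counts = np.bincount(_codon_codes(codes), minlength=64)
    return CompositionVector("codon", counts * 64 * 3 / L,
                             feature_names("codon"))


def count_codonpair(sequence: str) -> CompositionVector:
    """Usage of consecutive in-frame sense-codon pairs (61 x 61),
    scaled by 3721*3/L; pairs containing a stop codon are skipped."""
    codes = encode_bases(sequence)
    L = len(codes)
    if L < 6:
        raise SequenceError("sequence shorter than 6 nt")
    codons = _codon_codes(codes)
    stop_codes = np.array([CODONS.index(c) for c in sorted(STOP_CODONS)])
    sense_of = np.full(64, -1, dtype=np.int64)
    for i, c in enumerate(SENSE_CODONS):
        sense_of[CODONS.index(c)] = i
    first, second = codons[:-1], codons[1:]
    keep = ~(np.isin(first, stop_codes) | np.isin(second, stop_codes))
    pair = 61 * sense_of[first[keep]] + sense_of[second[keep]]
    counts = np.bincount(pair, minlength=3721)
    return CompositionVector("codonpair", counts * 3721 * 3 / L,
                             feature_names("codonpair"))


def count_aa(sequence: str) -> CompositionVector:
    """Amino-acid usage of the frame-0 translation (stops untallied),
    scaled by 20*3/L."""
    seq = sequence.upper()
    encode_bases(seq)  # alphabet validation
    L = len(seq)
    if L < 3:
        raise SequenceError("sequence shorter than 3 nt")
    protein = str(Seq(seq[:3 * (L // 3)]).translate())
    counts = np.zeros(20)
    for aa in protein:
        if aa != "*":
            counts[_AA_INDEX[aa]] += 1
    return CompositionVector("aa", counts * 20 * 3 / L, feature_names("aa"))


_ENCODERS = {"dnt": count_dnt, "dcr": count_dcr, "codon": count_codon,
             "codonpair": count_codonpair, "aa": count_aa}


def encode(sequence: str, trait: str) -> CompositionVector:
    """Dispatch to one of the five trait encoders by name."""
    try:
        return _ENCODERS[trait](sequence)
    except KeyError:
        raise ValueError(f"unknown trait {trait!r}; "
                         f"expected one of {sorted(_ENCODERS)}") from None


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant vector maps to all zeros."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty vector")
    lo, hi = values.min(), values.max()
    if hi == lo:
        logger.warning("constant vector in min-max normalization; "
                       "returning zeros")
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def dcr_to_tensor(vector: CompositionVector | np.ndarray) -> np.ndarray:
    """Reshape a 1536-vector to the (6, 16, 16) layout
    (class, first dinucleotide, second dinucleotide); exact bijection."""
    values = vector.values if isinstance(vector, CompositionVector) else \
        np.asarray(vector)
    if values.shape != (1536,):
        raise ValueError(f"expected a 1536-vector, got shape {values.shape}")
    return values.reshape(6, 16, 16)


def tensor_to_dcr(tensor: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dcr_to_tensor`."""
    tensor = np.asarray(tensor)
    if tensor.shape != (6, 16, 16):
        raise ValueError(f"expected shape (6, 16, 16), got {tensor.shape}")
    return tensor.reshape(1536)
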