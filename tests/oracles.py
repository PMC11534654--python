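"""Independent brute-force oracles used by the test suite.

Everything here is written as plain enumeration over string windows and
dictionaries, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

ORDER = "TCAG"

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
STOPS = {"TAA", "TAG", "TGA"}
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def _dinuc_index(d: str) -> int:
    return 4 * ORDER.index(d[0]) + ORDER.index(d[1])


def brute_dnt(seq: str) -> list[float]:
    """48-vector: tally every dinucleotide window by the codon phase of
    its first base, then normalise each phase block."""
    blocks = []
    for phase in range(3):
        counts = [0] * 16
        for p in range(len(seq) - 1):
            if p % 3 == phase:
                counts[_dinuc_index(seq[p:p + 2])] += 1
        total = sum(counts)
        blocks.extend([c / total if total else 0.0 for c in counts])
    return blocks


def brute_dcr(seq: str) -> list[float]:
    """1536-vector: enumerate every base index, derive (phase, offset)
    class, tally ordered dinucleotide pairs, normalise per class."""
    blocks = []
    for phase in range(3):
        for offset in (1, 2):
            counts = [0] * 256
            for p in range(len(seq)):
                if p % 3 != phase:
                    continue
                q = p + offset
                if q + 2 > len(seq):
                    continue
                first, second = seq[p:p + 2], seq[q:q + 2]
                if len(first) < 2:
                    continue
                counts[16 * _dinuc_index(first) + _dinuc_index(second)] += 1
            total = sum(counts)
            blocks.extend([c / total if total else 0.0 for c in counts])
    return blocks


def brute_codon(seq: str) -> list[float]:
    codons = [a + b + c for a in ORDER for b in ORDER for c in ORDER]
    counts = {c: 0 for c in codons}
    for k in range(len(seq) // 3):
        counts[seq[3 * k:3 * k + 3]] += 1
    return [counts[c] * 64 * 3 / len(seq) for c in codons]


def brute_codonpair(seq: str) -> list[float]:
    codons = [a + b + c for a in ORDER for b in ORDER for c in ORDER]
    sense = [c for c in codons if c not in STOPS]
    counts = {(c1, c2): 0 for c1 in sense for c2 in sense}
    frame = [seq[3 * k:3 * k + 3] for k in range(len(seq) // 3)]
    for c1, c2 in zip(frame, frame[1:]):
        if c1 not in STOPS and c2 not in STOPS:
            counts[(c1, c2)] += 1
    return [counts[(c1, c2)] * 3721 * 3 / len(seq)
            for c1 in sense for c2 in sense]


def brute_aa(seq: str) -> list[float]:
    counts = {a: 0 for a in AA_ORDER}
    for k in range(len(seq) // 3):
        aa = GENETIC_CODE[seq[3 * k:3 * k + 3]]
        if aa != "*":
            counts[aa] += 1
    return [counts[a] * 20 * 3 / len(seq) for a in AA_ORDER]


def brute_false_stop(seq: str) -> bool:
    """Regex-free scan: any stop codon among the in-frame codons before
    the final complete one."""
    n = len(seq) // 3
    return any(seq[3 * k:3 * k + 3] in STOPS for k in range(n - 1))


def pair_count_auc(scores_pos, scores_neg) -> float:
    """Mann-Whitney pair-counting AUC with ties worth 1/2."""
    wins = 0.0
    for sp in scores_pos:
        for sn in scores_neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(scores_pos) * len(scores_neg))


def pearson_r(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx * vy) ** 0.5
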