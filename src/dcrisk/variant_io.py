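"""Reading reference CDS and ClinVar-style variant tables, and
reconstructing each variant's full coding sequence from its HGVS ``c.``
expression.

Supported HGVS coding-variant grammar (1-based, inclusive spans)::

    c.<p><R>><A>           single-nucleotide variant
    c.<p>del               single-base deletion
    c.<p1>_<p2>del         multi-base deletion
    c.<p>_<p+1>ins<SEQ>    insertion between two adjacent bases
    c.<p>dup               single-base duplication
    c.<p1>_<p2>dup         span duplication (copy inserted after the span)
    c.<p>delins<SEQ>       single-base deletion-insertion
    c.<p1>_<p2>delins<SEQ> span deletion-insertion

Intronic offsets (``c.76+1G>A``), UTR coordinates (``c.-``, ``c.*``) and
genomic/protein expressions are deliberately unsupported: the pipeline
works on CDS-only variants, and intron records are filtered out before
sequence reconstruction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

SIGNIFICANCE_LABELS = ("Pathogenic", "Pathogeniclikely", "Benign",
                       "Benignlikely", "Uncertain")

#: Normalization of clinical-significance spellings found in the wild.
#: Shipped as data so other table dialects can be mapped without code
#: changes; keys are compared case-insensitively.
DEFAULT_SIGNIFICANCE_MAP = {
    "pathogenic": "Pathogenic",
    "likely pathogenic": "Pathogeniclikely",
    "pathogeniclikely": "Pathogeniclikely",
    "benign": "Benign",
    "likely benign": "Benignlikely",
    "benignlikely": "Benignlikely",
    "uncertain significance": "Uncertain",
    "uncertain": "Uncertain",
}

#: Logical column -> default header name in the variant table.
DEFAULT_COLUMNS = {
    "gene": "gene_symbol",
    "variant_id": "variant_id",
    "hgvs": "hgvs_c",
    "significance": "significance",
    "region": "region",
}

VARIANT_CLASSES = ("SNP", "deletion", "insertion", "duplication",
                   "deletion_insertion")


class VariantIOError(ValueError):
    """Base class; ``code`` is a stable machine-readable error code."""

    code = "variant_io_error"


class FastaFormatError(VariantIOError):
    code = "malformed_fasta"


class AlphabetError(VariantIOError):
    code = "non_acgt"


class FrameError(VariantIOError):
    code = "length_not_divisible_by_3"


class MissingColumnsError(VariantIOError):
    code = "missing_columns"


class UnsupportedHgvsError(VariantIOError):
    code = "unsupported_hgvs"


class PositionError(VariantIOError):
    code = "position_out_of_range"


class ReferenceMismatchError(VariantIOError):
    code = "reference_base_mismatch"


@dataclass(frozen=True)
class ReferenceCDS:
    """A reference coding sequence: ATG..stop, length divisible by 3."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise FastaFormatError("empty reference sequence")
        if set(seq) - set("ACGT"):
            bad = sorted(set(seq) - set("ACGT"))
            raise AlphabetError(f"non-ACGT characters in reference: {bad}")
        if len(seq) % 3 != 0:
            raise FrameError(
                f"reference length {len(seq)} not divisible by 3")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantRecord:
    """One parsed variant-table row (post region filter)."""

    gene_symbol: str
    variant_id: str
    hgvs_c: str
    significance: str
    variant_class: str
    region: str = "cDNA"


@dataclass
class VariantCDS:
    """A reconstructed full-length variant coding sequence plus its
    derived consequence annotations."""

    sequence: str
    frameshift: bool
    false_stop: bool
    consequence: str  # synonymous | nonsynonymous | frameshift | nonsense | other
    substitution_type: str | None = None  # e.g. "C>T"; SNVs only
    cds_position: int | None = None       # 1-based first affected base
    record: VariantRecord | None = None

    @property
    def residue_position(self) -> int | None:
        """1-based residue index of the first affected codon."""
        if self.cds_position is None:
            return None
        return 1 + (self.cds_position - 1) // 3


def read_reference_fasta(path: str | Path) -> ReferenceCDS:
    """Read the first record of a FASTA file as the reference CDS."""
    try:
        record = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise FastaFormatError(f"no FASTA records in {path}") from None
    return ReferenceCDS(id=record.id, sequence=str(record.seq).upper())


def detect_false_stop(sequence: str) -> bool:
    """True iff an in-frame stop codon occurs strictly before the final
    complete codon (frame 0; a trailing partial codon is ignored)."""
    if not sequence:
        raise VariantIOError("empty sequence")
    seq = sequence.upper()
    n_codons = len(seq) // 3
    stops = {"TAA", "TAG", "TGA"}
    return any(seq[3 * k:3 * k + 3] in stops for k in range(n_codons - 1))


_SNV_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_DEL_RE = re.compile(r"^c\.(\d+)(?:_(\d+))?del$")
_INS_RE = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")
_DUP_RE = re.compile(r"^c\.(\d+)(?:_(\d+))?dup$")
_DELINS_RE = re.compile(r"^c\.(\d+)(?:_(\d+))?delins([ACGT]+)$")


@dataclass(frozen=True)
class ParsedHgvs:
    kind: str            # SNP | deletion | insertion | duplication | deletion_insertion
    start: int           # 1-based inclusive
    end: int             # 1-based inclusive
    ref_base: str | None = None   # SNVs only
    alt: str | None = None        # inserted / substituted sequence


def parse_hgvs_c(hgvs_c: str) -> ParsedHgvs:
    """Parse an HGVS ``c.`` expression of the supported grammar."""
    hgvs = hgvs_c.strip()
    if m := _SNV_RE.match(hgvs):
        p = int(m.group(1))
        return ParsedHgvs("SNP", p, p, ref_base=m.group(2), alt=m.group(3))
    if m := _DELINS_RE.match(hgvs):  # before del: "delins" also matches _DEL_RE prefix logic
        p1 = int(m.group(1))
        p2 = int(m.group(2)) if m.group(2) else p1
        return ParsedHgvs("deletion_insertion", p1, p2, alt=m.group(3))
    if m := _DEL_RE.match(hgvs):
        p1 = int(m.group(1))
        p2 = int(m.group(2)) if m.group(2) else p1
        return ParsedHgvs("deletion", p1, p2)
    if m := _INS_RE.match(hgvs):
        p1, p2 = int(m.group(1)), int(m.group(2))
        if p2 != p1 + 1:
            raise UnsupportedHgvsError(
                f"insertion span must be adjacent bases: {hgvs!r}")
        return ParsedHgvs("insertion", p1, p2, alt=m.group(3))
    if m := _DUP_RE.match(hgvs):
        p1 = int(m.group(1))
        p2 = int(m.group(2)) if m.group(2) else p1
        return ParsedHgvs("duplication", p1, p2)
    raise UnsupportedHgvsError(f"unsupported HGVS expression {hgvs!r}")


def _translate(seq: str) -> str:
    return str(Seq(seq[:3 * (len(seq) // 3)]).translate())


def apply_variant(ref: ReferenceCDS, hgvs_c: str,
                  record: VariantRecord | None = None) -> VariantCDS:
    """Apply one HGVS ``c.`` variant to the reference CDS and annotate
    the resulting full-length sequence.

    The edit is performed in 0-based half-open coordinates internally;
    HGVS positions are 1-based inclusive.  For SNVs the stated reference
    base must match the reference sequence, otherwise
    :class:`ReferenceMismatchError` is raised.
    """
    parsed = parse_hgvs_c(hgvs_c)
    seq = ref.sequence
    L = len(seq)
    if not (1 <= parsed.start <= parsed.end <= L):
        raise PositionError(
            f"{hgvs_c!r}: span {parsed.start}_{parsed.end} outside [1, {L}]")
    i, j = parsed.start - 1, parsed.end  # 0-based half-open

    substitution_type = None
    if parsed.kind == "SNP":
        actual = seq[i]
        if actual != parsed.ref_base:
            raise ReferenceMismatchError(
                f"{hgvs_c!r}: reference has {actual} at position "
                f"{parsed.start}, not {parsed.ref_base}")
        edited = seq[:i] + parsed.alt + seq[j:]
        substitution_type = f"{parsed.ref_base}>{parsed.alt}"
    elif parsed.kind == "deletion":
        edited = seq[:i] + seq[j:]
    elif parsed.kind == "insertion":
        edited = seq[:j - 1] + parsed.alt + seq[j - 1:]
    elif parsed.kind == "duplication":
        edited = seq[:j] + seq[i:j] + seq[j:]
    else:  # deletion_insertion
        edited = seq[:i] + parsed.alt + seq[j:]

    frameshift = (len(edited) - L) % 3 != 0
    false_stop = detect_false_stop(edited)

    if parsed.kind == "SNP":
        codon_idx = i // 3
        old_codon = seq[3 * codon_idx:3 * codon_idx + 3]
        new_codon = edited[3 * codon_idx:3 * codon_idx + 3]
        stops = {"TAA", "TAG", "TGA"}
        if new_codon in stops and old_codon not in stops:
            consequence = "nonsense"
        elif _translate(edited) == _translate(seq):
            consequence = "synonymous"
        else:
            consequence = "nonsynonymous"
    elif frameshift:
        consequence = "frameshift"
    else:
        consequence = "other"

    return VariantCDS(sequence=edited, frameshift=frameshift,
                      false_stop=false_stop, consequence=consequence,
                      substitution_type=substitution_type,
                      cds_position=parsed.start, record=record)


def parse_variant_table(path: str | Path, *,
                        columns: dict[str, str] | None = None,
                        significance_map: dict[str, str] | None = None,
                        sep: str = "\t") -> list[VariantRecord]:
    """Parse a tab-delimited ClinVar-style variant table.

    Applies the cleaning rule: records located in an intron are removed,
    rows whose HGVS expression falls outside the supported coding
    grammar are dropped (each drop is logged with its reason), and
    clinical-significance spellings are normalised to the five canonical
    labels.
    """
    colmap = {**DEFAULT_COLUMNS, **(columns or {})}
    sigmap = {k.lower(): v for k, v in
              (significance_map or DEFAULT_SIGNIFICANCE_MAP).items()}
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    required = [colmap[k] for k in ("gene", "hgvs", "significance", "region")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnsError(f"missing required columns: {missing}")

    id_col = colmap["variant_id"] if colmap["variant_id"] in df.columns \
        else None
    records: list[VariantRecord] = []
    for idx, row in df.iterrows():
        variant_id = row[id_col] if id_col else f"row{idx}"
        region = row[colmap["region"]].strip()
        if "intron" in region.lower():
            continue
        sig_raw = row[colmap["significance"]].strip()
        significance = sigmap.get(sig_raw.lower())
        if significance is None:
            logger.info("dropping %s: unrecognised significance %r",
                        variant_id, sig_raw)
            continue
        hgvs = row[colmap["hgvs"]].strip()
        try:
            parsed = parse_hgvs_c(hgvs)
        except VariantIOError as exc:
            logger.info("dropping %s: %s", variant_id, exc)
            continue
        records.append(VariantRecord(
            gene_symbol=row[colmap["gene"]].strip(),
            variant_id=str(variant_id),
            hgvs_c=hgvs,
            significance=significance,
            variant_class=parsed.kind,
            region="cDNA" if region == "" else region,
        ))
    return records


def reconstruct_all(ref: ReferenceCDS, records: list[VariantRecord],
                    ) -> list[VariantCDS]:
    """Apply every record to the reference; records whose variant cannot
    be applied (position out of range, base mismatch) are dropped with a
    logged reason."""
    out = []
    for rec in records:
        try:
            out.append(apply_variant(ref, rec.hgvs_c, record=rec))
        except VariantIOError as exc:
            logger.info("dropping %s: %s", rec.variant_id, exc)
    return out


def write_variant_fasta(path: str | Path, variants: list[VariantCDS]) -> None:
    """Write reconstructed sequences as multi-FASTA."""
    with open(path, "w") as fh:
        for i, v in enumerate(variants):
            name = v.record.variant_id if v.record else f"variant{i}"
            fh.write(f">{name}\n")
            for k in range(0, len(v.sequence), 70):
                fh.write(v.sequence[k:k + 70] + "\n")


def annotations_frame(variants: list[VariantCDS]) -> pd.DataFrame:
    """Tabulate derived annotations for a list of reconstructed CDS."""
    rows = []
    for i, v in enumerate(variants):
        rec = v.record
        rows.append({
            "variant_id": rec.variant_id if rec else f"variant{i}",
            "gene_symbol": rec.gene_symbol if rec else "",
            "hgvs_c": rec.hgvs_c if rec else "",
            "significance": rec.significance if rec else "",
            "variant_class": rec.variant_class if rec else "",
            "cds_position": v.cds_position,
            "length": len(v.sequence),
            "frameshift": v.frameshift,
            "false_stop": v.false_stop,
            "substitution_type": v.substitution_type or "",
            "consequence": v.consequence,
        })
    return pd.DataFrame(rows)
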