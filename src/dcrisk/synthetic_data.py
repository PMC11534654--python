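"""Synthetic reference CDS and ClinVar-like variant tables with
class-correlated mutational signal.

The generator emulates the structure of a curated variant table for a
single large gene: a multi-kilobase reference CDS and a few hundred
variants per clinical-significance group.  Pathogenic-like variants are
dominated by frame-disrupting deletions/duplications and nonsense or
protein-changing substitutions with a spectrum biased toward
C>T / C>A / G>T / T>A, and sit preferentially in the 5' region;
benign-like variants are mostly synonymous wobble substitutions spread
uniformly.  The signal is implanted through the variant mechanism mix
only — features are never perturbed directly — so the full
HGVS-application and encoding path is exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import ReferenceCDS

_STOPS = {"TAA", "TAG", "TGA"}
_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Seq import Seq
        for a in "TCAG":
            for b in "TCAG":
                for c in "TCAG":
                    codon = a + b + c
                    _CODON_TABLE[codon] = str(Seq(codon).translate())
    return _CODON_TABLE


#: Spellings emitted in the synthetic table, exercising the
#: significance-normalisation map of the reader.
_EMITTED_SPELLING = {
    "Pathogenic": "Pathogenic",
    "Pathogeniclikely": "Likely pathogenic",
    "Benign": "Benign",
    "Benignlikely": "Likely benign",
    "Uncertain": "Uncertain significance",
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    ``reference_length`` is gene-scale (thousands of codons, default
    8,601 nt); ``counts`` gives variants per significance group.  The
    pathogenic mechanism mix and the substitution bias define the
    implanted class signal; ``five_prime_beta`` are the Beta-law shape
    parameters that skew pathogenic variant positions toward the 5'
    end of the CDS.
    """

    reference_length: int = 8601
    gc_content: float = 0.52
    counts: dict[str, int] = field(default_factory=lambda: {
        "Pathogenic": 400, "Benign": 200, "Benignlikely": 200,
        "Pathogeniclikely": 150, "Uncertain": 150})
    n_intron_rows: int = 30
    pathogenic_mix: dict[str, float] = field(default_factory=lambda: {
        "frameshift": 0.7, "nonsense": 0.2, "biased_snv": 0.1})
    benign_synonymous_fraction: float = 0.9
    biased_substitutions: dict[str, float] = field(default_factory=lambda: {
        "C>T": 0.4, "C>A": 0.2, "G>T": 0.2, "T>A": 0.2})
    five_prime_beta: tuple[float, float] = (1.2, 3.0)
    gene_symbol: str = "SIMGENE1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_length % 3 != 0 or self.reference_length < 300:
            raise ValueError("reference_length must be a multiple of 3 "
                             ">= 300")
        if not np.isclose(sum(self.pathogenic_mix.values()), 1.0):
            raise ValueError("pathogenic_mix fractions must sum to 1")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    """One master seed fans out to independent substreams (reference,
    variant positions, intron rows) via SeedSequence spawning."""
    children = np.random.SeedSequence(config.seed).spawn(3)
    names = ("reference", "variants", "intron")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def generate_reference(config: SimulationConfig | None = None,
                       rng: np.random.Generator | None = None,
                       ) -> ReferenceCDS:
    """A random CDS: starts ATG, ends TAA, no internal in-frame stop,
    realised GC within +/-2% of the target."""
    config = config or SimulationConfig()
    rng = rng or _streams(config)["reference"]
    L = config.reference_length
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, (1 - gc) / 2, gc / 2])  # T C A G
    bases = np.array(list("TCAG"))
    for _ in range(50):
        seq = list("".join(rng.choice(bases, size=L, p=p)))
        seq[0:3] = "ATG"
        seq[-3:] = "TAA"
        for k in range(1, L // 3 - 1):
            while "".join(seq[3 * k:3 * k + 3]) in _STOPS:
                seq[3 * k:3 * k + 3] = rng.choice(bases, size=3, p=p)
        s = "".join(seq)
        realized_gc = (s.count("G") + s.count("C")) / L
        if abs(realized_gc - gc) <= 0.02:
            return ReferenceCDS(id=f"{config.gene_symbol}_ref", sequence=s)
    raise ValueError(f"could not reach GC {gc:.2f} +/- 0.02 at length {L}")


def _position_weights(positions: np.ndarray, L: int,
                      beta: tuple[float, float] | None) -> np.ndarray:
    if beta is None:
        w = np.ones(len(positions))
    else:
        w = stats.beta.pdf((positions - 0.5) / L, *beta) + 1e-12
    return w / w.sum()


class _VariantFactory:
    """Draws HGVS expressions of the configured mechanisms against one
    reference; guarantees every expression applies cleanly."""

    def __init__(self, ref: ReferenceCDS, config: SimulationConfig,
                 rng: np.random.Generator):
        self.seq = ref.sequence
        self.L = len(ref.sequence)
        self.cfg = config
        self.rng = rng
        self.seen: set[str] = set()
        # all single substitutions that create an in-frame stop codon,
        # excluding the start and terminal codons
        self._stop_makers: list[tuple[int, str, str]] = []
        for k in range(1, self.L // 3 - 1):
            codon = self.seq[3 * k:3 * k + 3]
            for off in range(3):
                for alt in "TCAG":
                    if alt == codon[off]:
                        continue
                    new = codon[:off] + alt + codon[off + 1:]
                    if new in _STOPS:
                        self._stop_makers.append(
                            (3 * k + off + 1, codon[off], alt))

    def _unique(self, hgvs: str) -> bool:
        if hgvs in self.seen:
            return False
        self.seen.add(hgvs)
        return True

    def _pos_5prime(self, candidates: np.ndarray,
                    biased: bool) -> int:
        beta = self.cfg.five_prime_beta if biased else None
        w = _position_weights(candidates, self.L, beta)
        return int(self.rng.choice(candidates, p=w))

    def frameshift(self, biased_position: bool = True) -> str:
        for _ in range(200):
            span = int(self.rng.choice([1, 2, 4], p=[0.5, 0.3, 0.2]))
            kind = "del" if self.rng.random() < 0.5 else "dup"
            starts = np.arange(4, self.L - 2 - span)
            p1 = self._pos_5prime(starts, biased_position)
            p2 = p1 + span - 1
            hgvs = f"c.{p1}{kind}" if span == 1 else f"c.{p1}_{p2}{kind}"
            if self._unique(hgvs):
                return hgvs
        raise RuntimeError("exhausted unique frameshift variants")

    def nonsense(self, biased_position: bool = True) -> str:
        positions = np.array([p for p, _, _ in self._stop_makers])
        w = _position_weights(
            positions, self.L,
            self.cfg.five_prime_beta if biased_position else None)
        for _ in range(200):
            i = self.rng.choice(len(self._stop_makers), p=w)
            p, ref, alt = self._stop_makers[i]
            hgvs = f"c.{p}{ref}>{alt}"
            if self._unique(hgvs):
                return hgvs
        raise RuntimeError("exhausted unique nonsense variants")

    def biased_snv(self, biased_position: bool = True) -> str:
        """Protein-changing, non-stop SNV with the biased spectrum."""
        table = _codon_table()
        types = list(self.cfg.biased_substitutions)
        probs = np.array([self.cfg.biased_substitutions[t] for t in types])
        probs = probs / probs.sum()
        for _ in range(500):
            sub = types[self.rng.choice(len(types), p=probs)]
            src, alt = sub[0], sub[2]
            candidates = np.array(
                [i + 1 for i, b in enumerate(self.seq[3:-3], start=3)
                 if b == src])
            p = self._pos_5prime(candidates, biased_position)
            k, off = (p - 1) // 3, (p - 1) % 3
            codon = self.seq[3 * k:3 * k + 3]
            new = codon[:off] + alt + codon[off + 1:]
            if new in _STOPS or table[new] == table[codon]:
                continue
            hgvs = f"c.{p}{src}>{alt}"
            if self._unique(hgvs):
                return hgvs
        raise RuntimeError("exhausted unique biased SNVs")

    def synonymous_snv(self) -> str:
        table = _codon_table()
        for _ in range(500):
            k = int(self.rng.integers(1, self.L // 3 - 1))
            codon = self.seq[3 * k:3 * k + 3]
            options = []
            for off in range(3):
                for alt in "TCAG":
                    if alt == codon[off]:
                        continue
                    new = codon[:off] + alt + codon[off + 1:]
                    if new not in _STOPS and table[new] == table[codon]:
                        options.append((off, alt))
            if not options:
                continue
            off, alt = options[int(self.rng.integers(len(options)))]
            p = 3 * k + off + 1
            hgvs = f"c.{p}{codon[off]}>{alt}"
            if self._unique(hgvs):
                return hgvs
        raise RuntimeError("exhausted unique synonymous SNVs")

    def random_missense(self) -> str:
        """Unbiased protein-changing, non-stop SNV (uniform position)."""
        table = _codon_table()
        for _ in range(500):
            p = int(self.rng.integers(4, self.L - 3))
            k, off = (p - 1) // 3, (p - 1) % 3
            codon = self.seq[3 * k:3 * k + 3]
            alt = "TCAG"[int(self.rng.integers(4))]
            if alt == codon[off]:
                continue
            new = codon[:off] + alt + codon[off + 1:]
            if new in _STOPS or table[new] == table[codon]:
                continue
            hgvs = f"c.{p}{codon[off]}>{alt}"
            if self._unique(hgvs):
                return hgvs
        raise RuntimeError("exhausted unique missense SNVs")

    def pathogenic_like(self) -> tuple[str, str]:
        mix = self.cfg.pathogenic_mix
        mech = self.rng.choice(list(mix), p=np.array(list(mix.values())))
        if mech == "frameshift":
            return self.frameshift(), "frameshift"
        if mech == "nonsense":
            return self.nonsense(), "nonsense"
        return self.biased_snv(), "biased_snv"

    def benign_like(self) -> tuple[str, str]:
        if self.rng.random() < self.cfg.benign_synonymous_fraction:
            return self.synonymous_snv(), "synonymous"
        return self.random_missense(), "missense"


def _variant_class(hgvs: str) -> str:
    if "delins" in hgvs:
        return "deletion_insertion"
    if "del" in hgvs:
        return "deletion"
    if "dup" in hgvs:
        return "duplication"
    if "ins" in hgvs:
        return "insertion"
    return "SNP"


def generate_variant_table(ref: ReferenceCDS,
                           config: SimulationConfig | None = None,
                           ) -> tuple[pd.DataFrame, dict]:
    """Emit a ClinVar-style variant table plus ground truth.

    Returns the table (columns gene_symbol, variant_id, hgvs_c,
    significance, region) and a ground-truth dict mapping each
    variant_id to its group, generating mechanism and binary risk
    (1 pathogenic-like, 0 benign-like, None for intron rows).
    """
    config = config or SimulationConfig()
    streams = _streams(config)
    factory = _VariantFactory(ref, config, streams["variants"])
    rng_intron = streams["intron"]

    rows, truth = [], {}
    counter = 0

    def add(group: str, hgvs: str, mechanism: str, region: str,
            risk: int | None) -> None:
        nonlocal counter
        counter += 1
        vid = f"VAR{counter:06d}"
        rows.append({
            "gene_symbol": config.gene_symbol,
            "variant_id": vid,
            "hgvs_c": hgvs,
            "significance": _EMITTED_SPELLING[group],
            "region": region,
        })
        truth[vid] = {"group": group, "mechanism": mechanism,
                      "risk": risk,
                      "variant_class": _variant_class(hgvs)}

    for group in ("Pathogenic", "Pathogeniclikely"):
        for _ in range(config.counts.get(group, 0)):
            hgvs, mech = factory.pathogenic_like()
            add(group, hgvs, mech, "cDNA", 1)
    for group in ("Benign", "Benignlikely"):
        for _ in range(config.counts.get(group, 0)):
            hgvs, mech = factory.benign_like()
            add(group, hgvs, mech, "cDNA", 0)
    for _ in range(config.counts.get("Uncertain", 0)):
        if factory.rng.random() < 0.5:
            hgvs, mech = factory.pathogenic_like()
            risk = 1
        else:
            hgvs, mech = factory.benign_like()
            risk = 0
        add("Uncertain", hgvs, mech, "cDNA", risk)
    for _ in range(config.n_intron_rows):
        p = int(rng_intron.integers(10, len(ref.sequence) - 10))
        offset = int(rng_intron.integers(1, 20))
        hgvs = f"c.{p}+{offset}G>A"
        group = ("Benign", "Uncertain")[int(rng_intron.integers(2))]
        add(group, hgvs, "intronic", "intron", None)

    df = pd.DataFrame(rows).sample(
        frac=1.0, random_state=config.seed).reset_index(drop=True)
    return df, truth


def write_fixture(directory: str | Path,
                  config: SimulationConfig | None = None) -> dict[str, Path]:
    """Write reference FASTA, variant TSV and ground-truth JSON."""
    config = config or SimulationConfig()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ref = generate_reference(config)
    table, truth = generate_variant_table(ref, config)
    paths = {
        "reference": directory / "reference.fa",
        "variants": directory / "variants.tsv",
        "truth": directory / "ground_truth.json",
    }
    with open(paths["reference"], "w") as fh:
        fh.write(f">{ref.id}\n")
        for k in range(0, len(ref.sequence), 70):
            fh.write(ref.sequence[k:k + 70] + "\n")
    table.to_csv(paths["variants"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
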