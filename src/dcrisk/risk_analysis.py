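"""Downstream analytics of classifier predictions: risk calls for
uncertain variants, false-stop and variant-class summaries, SNV
substitution spectra and their correlation, and positional /
secondary-structure distributions of mutated residues."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composition import SequenceError, count_dcr, dcr_to_tensor
from .variant_io import VariantCDS

logger = logging.getLogger(__name__)

#: Fixed column order for substitution spectra (the 12 ordered base
#: changes, grouped by source base C, G, A, T).
SUBSTITUTION_TYPES = ["C>T", "C>A", "C>G", "G>A", "G>T", "G>C",
                      "A>T", "A>C", "A>G", "T>A", "T>C", "T>G"]

STRUCTURE_CLASSES = ("Loop", "Sheet", "Helix")


@dataclass
class PredictionResult:
    variant_id: str
    label: int             # 1 high risk, 0 low risk
    p0: float
    p1: float
    group: str             # source significance group


@dataclass
class SubstitutionSpectrum:
    """Percentages per ordered substitution type; sums to 100 over
    nonzero types (all-zero when the subset holds no SNVs)."""

    percentages: pd.Series  # indexed by SUBSTITUTION_TYPES
    group: str = ""
    n_snv: int = 0

    @property
    def values(self) -> np.ndarray:
        return self.percentages.to_numpy()


def predict_batch(model, variants: list[VariantCDS]) -> list[PredictionResult]:
    """Classify each reconstructed variant CDS with a trained model
    (a :class:`~dcrisk.cnn_classifier.CNN` or fitted results object).

    Sequences too short for the DCR encoder are skipped with a logged
    reason.
    """
    tensors, kept = [], []
    for i, v in enumerate(variants):
        try:
            tensors.append(dcr_to_tensor(count_dcr(v.sequence)))
        except SequenceError as exc:
            vid = v.record.variant_id if v.record else f"variant{i}"
            logger.info("skipping %s: %s", vid, exc)
            continue
        kept.append(i)
    if not kept:
        return []
    proba = model.predict_proba(np.stack(tensors))
    results = []
    for i, (p0, p1) in zip(kept, proba):
        v = variants[i]
        rec = v.record
        results.append(PredictionResult(
            variant_id=rec.variant_id if rec else f"variant{i}",
            label=int(p1 > p0),
            p0=float(p0), p1=float(p1),
            group=rec.significance if rec else ""))
    return results


def predictions_frame(results: list[PredictionResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def summarize_predictions(results: list[PredictionResult],
                          variants: list[VariantCDS]) -> dict:
    """Cross-tabulate predicted high-risk (label 1) variants by
    false-stop status and by variant class."""
    by_id = {}
    for i, v in enumerate(variants):
        vid = v.record.variant_id if v.record else f"variant{i}"
        by_id[vid] = v
    high = [by_id[r.variant_id] for r in results if r.label == 1]
    false_stop = pd.Series(
        {"Yes": sum(v.false_stop for v in high),
         "No": sum(not v.false_stop for v in high)}, name="count")
    classes = pd.Series(
        [v.record.variant_class if v.record else "unknown" for v in high],
        dtype=object).value_counts()
    return {"false_stop": false_stop,
            "variant_class": classes,
            "n_high_risk": len(high),
            "n_total": len(results)}


def substitution_spectrum(variants: list[VariantCDS],
                          group: str = "") -> SubstitutionSpectrum:
    """Percentage of each ordered base substitution among the SNVs of
    the subset (non-SNVs are ignored; scale-free under duplication)."""
    counts = pd.Series(0.0, index=SUBSTITUTION_TYPES)
    n = 0
    for v in variants:
        if v.substitution_type in counts.index:
            counts[v.substitution_type] += 1
            n += 1
    pct = counts * 100.0 / n if n else counts
    return SubstitutionSpectrum(percentages=pct, group=group, n_snv=n)


def spectrum_correlation(a: SubstitutionSpectrum,
                         b: SubstitutionSpectrum) -> dict:
    """Pearson correlation and least-squares slope between two spectra
    (same fixed type order); zero-variance input leaves r undefined."""
    x, y = a.values, b.values
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": None, "slope": None, "intercept": None,
                "p_value": None, "note": "zero-variance spectrum"}
    fit = stats.linregress(x, y)
    return {"r": float(fit.rvalue), "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "p_value": float(fit.pvalue)}


def sliding_window_mutation_freq(protein_positions, window: int = 10,
                                 step: int = 10,
                                 length: int | None = None) -> pd.DataFrame:
    """Count mutated residues per window along the protein.

    ``protein_positions`` is either a list of 1-based residue indices or
    a mapping ``group -> list of indices``; windows start at 1, 1+step,
    1+2*step, ... and span ``window`` residues (default: non-overlapping
    10-residue bins).
    """
    if window < step:
        raise ValueError("window must be >= step")
    if not isinstance(protein_positions, dict):
        protein_positions = {"all": list(protein_positions)}
    all_pos = [p for ps in protein_positions.values() for p in ps]
    if any(p < 1 for p in all_pos):
        raise ValueError("residue positions are 1-based (>= 1)")
    length = length or (max(all_pos) if all_pos else window)
    starts = np.arange(1, length + 1, step)
    out = {"window_start": starts, "window_end": starts + window - 1}
    for group, ps in protein_positions.items():
        ps = np.asarray(ps)
        out[group] = [int(((ps >= s) & (ps <= s + window - 1)).sum())
                      for s in starts]
    return pd.DataFrame(out)


def mutations_by_structure_class(residue_classes,
                                 positions_by_group: dict) -> pd.DataFrame:
    """Percentage of mutated residues in each secondary-structure class
    (Loop / Sheet / Helix) per group; rows sum to 100.

    ``residue_classes`` maps 1-based residue index to class (dict, or a
    DataFrame with columns ``residue`` and ``structure``); every queried
    position must be annotated.
    """
    if isinstance(residue_classes, pd.DataFrame):
        residue_classes = dict(zip(residue_classes["residue"],
                                   residue_classes["structure"]))
    rows = {}
    for group, positions in positions_by_group.items():
        missing = [p for p in positions if p not in residue_classes]
        if missing:
            raise ValueError(
                f"unannotated residue positions for group {group!r}: "
                f"{sorted(set(missing))[:10]}")
        counts = {c: 0 for c in STRUCTURE_CLASSES}
        for p in positions:
            cls = residue_classes[p]
            if cls not in counts:
                raise ValueError(f"unknown structure class {cls!r} "
                                 f"at residue {p}")
            counts[cls] += 1
        total = sum(counts.values())
        rows[group] = {c: (100.0 * v / total if total else 0.0)
                       for c, v in counts.items()}
    return pd.DataFrame(rows).T[list(STRUCTURE_CLASSES)]
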