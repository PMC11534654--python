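import numpy as np
import pandas as pd
import pytest

import dcrisk as d
from dcrisk.risk_analysis import SUBSTITUTION_TYPES, predictions_frame
from dcrisk.variant_io import VariantCDS, VariantRecord

from .oracles import pearson_r


def _vcds(vid, seq="ATGGCCAAATAG", sub=None, false_stop=False,
          vclass="SNP", significance="Uncertain"):
    rec = VariantRecord(gene_symbol="G1", variant_id=vid, hgvs_c="c.1A>T",
                        significance=significance, variant_class=vclass)
    return VariantCDS(sequence=seq, frameshift=False, false_stop=false_stop,
                      consequence="nonsynonymous", substitution_type=sub,
                      cds_position=1, record=rec)


class _ConstantModel:
    """Predicts label 1 with probability p1 for every input."""

    def __init__(self, p1=0.9):
        self.p1 = p1

    def predict_proba(self, X):
        n = len(X)
        return np.column_stack([np.full(n, 1 - self.p1),
                                np.full(n, self.p1)])


class TestPredictBatch:
    def test_empty_input(self):
        assert d.predict_batch(_ConstantModel(), []) == []

    def test_duplicates_identical(self):
        variants = [_vcds("a"), _vcds("b")]
        res = d.predict_batch(_ConstantModel(0.8), variants)
        assert res[0].label == res[1].label == 1
        assert res[0].p1 == res[1].p1 == pytest.approx(0.8)
        assert res[0].p0 + res[0].p1 == pytest.approx(1.0)

    def test_short_sequence_skipped(self, caplog):
        import logging

        variants = [_vcds("ok"), _vcds("short", seq="ATG")]
        with caplog.at_level(logging.INFO, logger="dcrisk.risk_analysis"):
            res = d.predict_batch(_ConstantModel(), variants)
        assert [r.variant_id for r in res] == ["ok"]
        assert any("short" in m for m in caplog.messages)

    def test_end_to_end_frameshifts_called_high_risk(
            self, small_trained_model, small_fixture):
        """Pathogenic-like frameshift variants from the generator are
        mostly labelled high-risk by the fixture-trained model."""
        truth = small_fixture["truth"]
        fs = [v for v in small_fixture["variants"]
              if truth[v.record.variant_id]["mechanism"] == "frameshift"]
        res = d.predict_batch(small_trained_model, fs)
        assert np.mean([r.label for r in res]) > 0.5


class TestSummarizePredictions:
    def test_counts(self):
        variants = [_vcds("a", false_stop=True, vclass="deletion"),
                    _vcds("b", false_stop=True, vclass="SNP"),
                    _vcds("c", false_stop=False, vclass="SNP"),
                    _vcds("d", false_stop=False, vclass="SNP")]
        res = d.predict_batch(_ConstantModel(0.9), variants)
        res[3].label = 0  # force one low-risk call
        summary = d.summarize_predictions(res, variants)
        assert summary["false_stop"]["Yes"] == 2
        assert summary["false_stop"]["No"] == 1
        assert summary["variant_class"]["SNP"] == 2
        assert summary["n_high_risk"] == 3 and summary["n_total"] == 4

    def test_all_low_risk(self):
        variants = [_vcds("a"), _vcds("b")]
        res = d.predict_batch(_ConstantModel(0.1), variants)
        summary = d.summarize_predictions(res, variants)
        assert summary["n_high_risk"] == 0 and summary["n_total"] == 2

    def test_matches_bruteforce_tally(self, small_trained_model,
                                      small_fixture):
        variants = small_fixture["variants"]
        res = d.predict_batch(small_trained_model, variants)
        summary = d.summarize_predictions(res, variants)
        frame = predictions_frame(res).merge(
            pd.DataFrame({"variant_id": [v.record.variant_id
                                         for v in variants],
                          "false_stop": [v.false_stop for v in variants]}))
        high = frame[frame.label == 1]
        assert summary["false_stop"]["Yes"] == int(high.false_stop.sum())
        assert summary["n_high_risk"] == len(high)


class TestSubstitutionSpectrum:
    def test_single_type(self):
        spec = d.substitution_spectrum([_vcds("a", sub="C>T"),
                                        _vcds("b", sub="C>T")])
        assert spec.percentages["C>T"] == 100.0
        assert spec.percentages.sum() == 100.0

    def test_four_types_equal(self):
        subs = ["C>T", "C>A", "G>T", "T>A"]
        spec = d.substitution_spectrum(
            [_vcds(f"v{i}", sub=s) for i, s in enumerate(subs)])
        for s in subs:
            assert spec.percentages[s] == 25.0

    def test_non_snv_ignored(self):
        spec = d.substitution_spectrum([_vcds("a", sub="C>T"),
                                        _vcds("b", sub=None)])
        assert spec.n_snv == 1 and spec.percentages["C>T"] == 100.0

    def test_duplication_invariant(self):
        variants = [_vcds("a", sub="C>T"), _vcds("b", sub="G>A")]
        once = d.substitution_spectrum(variants)
        twice = d.substitution_spectrum(variants * 2)
        pd.testing.assert_series_equal(once.percentages, twice.percentages)

    def test_fixed_type_order(self):
        spec = d.substitution_spectrum([])
        assert list(spec.percentages.index) == SUBSTITUTION_TYPES
        assert len(SUBSTITUTION_TYPES) == 12


class TestSpectrumCorrelation:
    def _spec(self, values):
        return d.SubstitutionSpectrum(
            percentages=pd.Series(values, index=SUBSTITUTION_TYPES))

    def test_identical(self, rng):
        a = self._spec(rng.random(12))
        out = d.spectrum_correlation(a, a)
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(1.0)

    def test_affine(self, rng):
        x = rng.random(12)
        out = d.spectrum_correlation(self._spec(x), self._spec(2 * x - 0.3))
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)

    def test_matches_closed_form(self, rng):
        x, y = rng.random(12), rng.random(12)
        out = d.spectrum_correlation(self._spec(x), self._spec(y))
        assert out["r"] == pytest.approx(pearson_r(x, y))

    def test_zero_variance_undefined(self):
        out = d.spectrum_correlation(self._spec(np.ones(12)),
                                     self._spec(np.arange(12.0)))
        assert out["r"] is None

    def test_predicted_spectrum_tracks_training_positive_spectrum(
            self, small_trained_model, small_fixture):
        """The substitution spectrum of predicted high-risk variants
        correlates strongly with the spectrum of labelled pathogenic
        variants when both share the implanted bias."""
        variants = small_fixture["variants"]
        path = [v for v in variants
                if v.record.significance == "Pathogenic"]
        rest = [v for v in variants
                if v.record.significance in ("Pathogeniclikely",
                                             "Uncertain")]
        res = d.predict_batch(small_trained_model, rest)
        high_ids = {r.variant_id for r in res if r.label == 1}
        predicted = [v for v in rest if v.record.variant_id in high_ids]
        a = d.substitution_spectrum(path, group="Pathogenic")
        b = d.substitution_spectrum(predicted, group="predicted")
        if a.n_snv and b.n_snv:
            out = d.spectrum_correlation(a, b)
            assert out["r"] > 0.9


class TestSlidingWindow:
    def test_two_windows(self):
        out = d.sliding_window_mutation_freq([5, 15], window=10, step=10)
        assert out["all"].tolist() == [1, 1]

    def test_single_bin(self):
        out = d.sliding_window_mutation_freq([2, 3, 7], window=10, step=10)
        assert out["all"].tolist() == [3]

    def test_matches_histogram_oracle(self, rng):
        positions = rng.integers(1, 501, size=200).tolist()
        out = d.sliding_window_mutation_freq(positions, window=10, step=10,
                                             length=500)
        expected, _ = np.histogram(positions,
                                   bins=np.arange(1, 512, 10))
        np.testing.assert_array_equal(out["all"].to_numpy(),
                                      expected[:len(out)])

    def test_per_group_tracks(self):
        out = d.sliding_window_mutation_freq(
            {"Pathogenic": [1, 2], "Benign": [15]}, window=10, step=10)
        assert out["Pathogenic"].tolist() == [2, 0]
        assert out["Benign"].tolist() == [0, 1]

    def test_window_smaller_than_step_rejected(self):
        with pytest.raises(ValueError):
            d.sliding_window_mutation_freq([1], window=5, step=10)


class TestStructureClasses:
    def test_all_loop(self):
        table = {i: "Loop" for i in range(1, 11)}
        out = d.mutations_by_structure_class(table, {"g": [1, 5, 9]})
        assert out.loc["g", "Loop"] == 100.0

    def test_mixed_percentages(self):
        table = {1: "Loop", 2: "Loop", 3: "Sheet", 4: "Helix"}
        out = d.mutations_by_structure_class(table, {"g": [1, 2, 3, 4]})
        assert out.loc["g"].tolist() == [50.0, 25.0, 25.0]
        assert out.loc["g"].sum() == 100.0

    def test_dataframe_annotation_input(self):
        table = pd.DataFrame({"residue": [1, 2, 3],
                              "structure": ["Loop", "Sheet", "Helix"]})
        out = d.mutations_by_structure_class(table, {"g": [1, 2, 3]})
        assert out.loc["g"].sum() == pytest.approx(100.0)

    def test_unannotated_position_errors(self):
        with pytest.raises(ValueError) as exc:
            d.mutations_by_structure_class({1: "Loop"}, {"g": [1, 99]})
        assert "99" in str(exc.value)
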