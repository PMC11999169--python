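"""Fold-change, hit flags, ternary direction scores and heatmap matrices."""

import warnings

import numpy as np
import pandas as pd
import pytest

from kinopipe import differential
from kinopipe.krsa import KinaseSubstrateMap
from kinopipe.qc import PeptideSignalMatrix


def _matrix(chip_values: dict, groups: dict) -> PeptideSignalMatrix:
    """chip_values: chip -> {sample -> {peptide -> signal}}."""
    frames = {}
    for chip, samples in chip_values.items():
        for sample, peps in samples.items():
            frames[(chip, sample)] = pd.Series(peps)
    df = pd.DataFrame(frames)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return PeptideSignalMatrix(df, groups)


@pytest.fixture
def two_chip_matrix():
    return _matrix(
        {"chip1": {"a1": {"p1": 100.0, "p2": 50.0}, "b1": {"p1": 200.0, "p2": 50.0}},
         "chip2": {"a1": {"p1": 100.0, "p2": 50.0}, "b1": {"p1": 200.0, "p2": 50.0}}},
        {"a1": "ctrl", "b1": "trt"})


class TestLog2FoldChange:
    def test_doubling_gives_log2fc_one(self, two_chip_matrix):
        fc = differential.log2_fold_change(two_chip_matrix, "ctrl", "trt")
        assert fc.loc["p1", "mean_log2fc"] == pytest.approx(1.0)
        assert fc.loc["p2", "mean_log2fc"] == pytest.approx(0.0)
        assert not fc.loc["p2", "flagged"] and not fc.loc["p2", "hit15"]

    def test_mean_exactly_at_threshold_not_flagged(self):
        # per-chip log2fc 0.3 and 0.1 -> mean 0.2, strict > keeps it unflagged
        m = _matrix(
            {"chip1": {"a1": {"p": 100.0}, "b1": {"p": 100.0 * 2 ** 0.3}},
             "chip2": {"a1": {"p": 100.0}, "b1": {"p": 100.0 * 2 ** 0.1}}},
            {"a1": "ctrl", "b1": "trt"})
        fc = differential.log2_fold_change(m, "ctrl", "trt")
        assert fc.loc["p", "mean_log2fc"] == pytest.approx(0.2)
        assert not fc.loc["p", "flagged"]

    def test_hit15_boundary_on_linear_scale(self):
        # a 15% increase is a hit, a 14% increase is not
        m = _matrix(
            {"chip1": {"a1": {"p15": 100.0, "p14": 100.0},
                       "b1": {"p15": 115.0, "p14": 114.0}}},
            {"a1": "ctrl", "b1": "trt"})
        fc = differential.log2_fold_change(m, "ctrl", "trt")
        assert bool(fc.loc["p15", "hit15"]) and not bool(fc.loc["p14", "hit15"])

    def test_antisymmetry_under_group_swap(self, two_chip_matrix):
        fwd = differential.log2_fold_change(two_chip_matrix, "ctrl", "trt")
        rev = differential.log2_fold_change(two_chip_matrix, "trt", "ctrl")
        assert np.allclose(fwd["mean_log2fc"], -rev["mean_log2fc"])

    def test_chip_missing_group_skipped(self):
        m = _matrix(
            {"chip1": {"a1": {"p": 100.0}, "b1": {"p": 200.0}},
             "chip2": {"b1": {"p": 999.0}}},
            {"a1": "ctrl", "b1": "trt"})
        with pytest.warns(UserWarning, match="skipped"):
            fc = differential.log2_fold_change(m, "ctrl", "trt")
        assert fc.loc["p", "mean_log2fc"] == pytest.approx(1.0)


class TestTernaryScore:
    KMAP = KinaseSubstrateMap({"K1": frozenset({"p1", "p2", "p3"}),
                               "K2": frozenset({"p4", "p5"}),
                               "K3": frozenset({"zz"})})

    def _fc(self, values: dict) -> pd.DataFrame:
        return pd.DataFrame({"mean_log2fc": pd.Series(values)})

    def test_rule_application(self):
        scores = differential.ternary_score(
            self._fc({"p1": 0.5, "p2": 0.3, "p3": -0.1}), self.KMAP)
        assert scores.loc["K1", "mean_value"] == pytest.approx(2 / 3)
        assert scores.loc["K1", "direction"] == "up"

    def test_balanced_substrates_no_change(self):
        scores = differential.ternary_score(
            self._fc({"p4": 0.25, "p5": -0.25}), self.KMAP)
        assert scores.loc["K2", "mean_value"] == 0.0
        assert scores.loc["K2", "direction"] == "no_change"

    def test_boundary_value_scores_zero(self):
        scores = differential.ternary_score(self._fc({"p4": 0.2, "p5": -0.2}),
                                            self.KMAP)
        assert scores.loc["K2", "mean_value"] == 0.0

    def test_unmapped_kinase_reports_no_data(self):
        scores = differential.ternary_score(self._fc({"p1": 0.5}), self.KMAP)
        assert scores.loc["K3", "direction"] == "no_data"

    def test_mean_bounded_and_order_invariant(self):
        vals = {"p1": 0.9, "p2": -0.9, "p3": 0.7, "p4": 0.3, "p5": -0.5}
        s1 = differential.ternary_score(self._fc(vals), self.KMAP)
        shuffled = dict(reversed(list(vals.items())))
        s2 = differential.ternary_score(self._fc(shuffled), self.KMAP)
        assert s1["mean_value"].dropna().between(-1, 1).all()
        pd.testing.assert_frame_equal(s1, s2)

    def test_direction_flips_under_negation(self):
        vals = {"p1": 0.5, "p2": 0.3, "p3": -0.1}
        up = differential.ternary_score(self._fc(vals), self.KMAP)
        down = differential.ternary_score(
            self._fc({k: -v for k, v in vals.items()}), self.KMAP)
        assert up.loc["K1", "direction"] == "up"
        assert down.loc["K1", "direction"] == "down"


class TestHeatmapMatrix:
    def test_row_z_score(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0], [4.0, 5.0, 9.0]],
                          index=["r1", "r2"], columns=["c1", "c2", "c3"])
        hm = differential.heatmap_matrix(df)
        np.testing.assert_allclose(hm.values.loc["r1"],
                                   np.array([-1, 0, 1]) / np.sqrt(2 / 3))

    def test_constant_row_zeroed_with_warning(self):
        df = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]],
                          index=["flat", "r2"], columns=list("abc"))
        with pytest.warns(UserWarning, match="zero-variance"):
            hm = differential.heatmap_matrix(df)
        assert np.allclose(hm.values.loc["flat"], 0.0)

    def test_ordering_deterministic(self):
        df = pd.DataFrame(np.arange(12).reshape(4, 3) % 5,
                          index=list("wxyz"), columns=list("abc")).astype(float)
        h1 = differential.heatmap_matrix(df)
        h2 = differential.heatmap_matrix(df)
        assert h1.row_order == h2.row_order and h1.col_order == h2.col_order

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            differential.heatmap_matrix(pd.DataFrame([[1.0, 2.0]]))
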