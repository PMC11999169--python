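"""Synthetic array generator: determinism, planted truth, table round-trips."""

import math

import numpy as np
import pandas as pd
import pytest

from kinopipe import differential, qc, simulate
from kinopipe.errors import ConfigurationError, FormatError


class TestLayouts:
    def test_grid_geometry(self, stk_layout, ptk_layout):
        assert stk_layout.n_peptides == 144 and (stk_layout.grid_rows,
                                                 stk_layout.grid_cols) == (12, 12)
        assert ptk_layout.n_peptides == 196 and (ptk_layout.grid_rows,
                                                 ptk_layout.grid_cols) == (14, 14)
        assert len(set(stk_layout.peptide_ids)) == 144

    def test_bad_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate.ArrayLayout("STK", 12, 12, tuple(f"p{i}" for i in range(10)))
        with pytest.raises(ConfigurationError):
            simulate.ArrayLayout("STK", 2, 2, ("a", "a", "b", "c"))


class TestConfigValidation:
    def test_planted_family_must_exist(self, stk_layout, stk_map):
        with pytest.raises(ConfigurationError, match="planted"):
            simulate.SimulationConfig(layout=stk_layout, kinase_map=stk_map,
                                      planted_effects={"NOT_A_FAMILY": 1.0})

    def test_exposures_must_increase(self, stk_layout, stk_map):
        with pytest.raises(ConfigurationError, match="increasing"):
            simulate.SimulationConfig(layout=stk_layout, kinase_map=stk_map,
                                      exposures_ms=(10.0, 10.0, 50.0))

    def test_failure_fractions_bounded(self, stk_layout, stk_map):
        with pytest.raises(ConfigurationError):
            simulate.SimulationConfig(layout=stk_layout, kinase_map=stk_map,
                                      dead_peptide_frac=0.6,
                                      saturating_peptide_frac=0.5)


class TestSimulateArrays:
    def test_deterministic_under_seed(self, clean_config):
        r1, t1 = simulate.simulate_arrays(clean_config)
        r2, t2 = simulate.simulate_arrays(clean_config)
        pd.testing.assert_frame_equal(r1, r2)
        assert t1.peptide_class == t2.peptide_class

    def test_planted_failure_counts_use_floor(self, stk_layout, stk_map):
        cfg = simulate.SimulationConfig(layout=stk_layout, kinase_map=stk_map,
                                        dead_peptide_frac=0.1,
                                        saturating_peptide_frac=0.05, seed=2)
        _, truth = simulate.simulate_arrays(cfg)
        assert len(truth.peptides_of_class("dead")) == math.floor(0.1 * 144) == 14
        assert len(truth.peptides_of_class("saturating")) == math.floor(0.05 * 144)

    def test_no_effect_noise_free_gives_zero_log2fc(self, clean_config):
        reads, _ = simulate.simulate_arrays(clean_config)
        fits = qc.apply_qc(qc.fit_kinetics(reads), min_signal=1.0)
        matrix = qc.build_signal_matrix(fits)
        fc = differential.log2_fold_change(matrix, "sedentary", "exercise")
        assert np.allclose(fc["mean_log2fc"], 0.0, atol=1e-12)
        assert not fc["flagged"].any() and not fc["hit15"].any()

    def test_noise_free_reads_are_exactly_linear(self, clean_config):
        reads, _ = simulate.simulate_arrays(clean_config)
        fits = qc.fit_kinetics(reads)
        assert np.allclose(fits["r_squared"], 1.0)
        # identical slope across groups for every peptide
        spread = fits.groupby("peptide_id")["slope"].agg(lambda s: s.max() - s.min())
        assert np.allclose(spread, 0.0, atol=1e-12)

    def test_intensities_nonnegative_and_finite(self, stk_layout, stk_map):
        cfg = simulate.SimulationConfig(layout=stk_layout, kinase_map=stk_map,
                                        noise_sd=50.0, dead_peptide_frac=0.2, seed=4)
        reads, _ = simulate.simulate_arrays(cfg)
        assert (reads["intensity"] >= 0).all()
        assert np.isfinite(reads["intensity"]).all()

    def test_planted_effect_recovered_as_mean_log2fc(self, stk_layout, stk_map):
        """Monte-Carlo: estimated substrate log2FC matches the planted +1.0
        within three standard errors across seeds."""
        effect = 1.0
        means = []
        for seed in range(12):
            cfg = simulate.SimulationConfig(
                layout=stk_layout, kinase_map=stk_map, n_chips=2,
                planted_effects={"IKK": effect}, noise_sd=2.0, seed=seed)
            reads, _ = simulate.simulate_arrays(cfg)
            fits = qc.apply_qc(qc.fit_kinetics(reads), min_signal=1.0)
            fc = differential.log2_fold_change(qc.build_signal_matrix(fits),
                                               "sedentary", "exercise")
            subs = sorted(set(stk_map.sets["IKK"]) & set(fc.index))
            means.append(fc.loc[subs, "mean_log2fc"].mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - effect) < 3 * max(se, 1e-6)


class TestReadTableIO:
    def test_round_trip_identity(self, clean_config, tmp_path):
        reads, _ = simulate.simulate_arrays(clean_config)
        path = tmp_path / "reads.tsv"
        simulate.write_reads(reads, path)
        back = simulate.read_reads(path)
        merged = reads.merge(back, on=["chip_id", "sample_id", "group",
                                       "peptide_id", "exposure_ms"])
        assert len(merged) == len(reads)
        assert np.allclose(merged["intensity_x"], merged["intensity_y"], rtol=1e-6)

    def test_empty_and_single_record_round_trip(self, tmp_path):
        empty = pd.DataFrame(columns=simulate.READ_COLUMNS)
        p = tmp_path / "empty.tsv"
        simulate.write_reads(empty, p)
        assert simulate.read_reads(p).empty
        one = pd.DataFrame([("c1", "s1", "g1", "p1", 10.0, 5.5)],
                           columns=simulate.READ_COLUMNS)
        p2 = tmp_path / "one.tsv"
        simulate.write_reads(one, p2)
        pd.testing.assert_frame_equal(simulate.read_reads(p2), one)

    @pytest.mark.parametrize("mutation, match", [
        (lambda d: d.rename(columns={"intensity": "signal"}), "missing column"),
        (lambda d: d.assign(intensity=["NA"]), "non-numeric"),
        (lambda d: d.assign(intensity=[-1.0]), "negative"),
        (lambda d: pd.concat([d, d]), "duplicate"),
    ])
    def test_malformed_tables_rejected(self, tmp_path, mutation, match):
        base = pd.DataFrame([("c1", "s1", "g1", "p1", 10.0, 5.5)],
                            columns=simulate.READ_COLUMNS)
        bad = mutation(base)
        p = tmp_path / "bad.tsv"
        bad.to_csv(p, sep="\t", index=False)
        with pytest.raises(FormatError, match=match):
            simulate.read_reads(p)
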