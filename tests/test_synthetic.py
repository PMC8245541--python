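"""The synthetic-data generators: determinism, ground truth, fixtures, blots."""

import numpy as np
import pandas as pd
import pytest

from bonlac import (
    SimConfig,
    SimConfigError,
    read_protein_groups,
    simulate_blot,
    simulate_experiment,
    unpaired_t_test,
    write_maxquant_fixture,
)
from bonlac.synthetic import FixtureError

from oracles import two_sample_t_power


class TestSimConfig:
    def test_invalid_fractions_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(frac_up=0.7, frac_down=0.5)

    def test_invalid_effects_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(effect_fc_up=0.9)
        with pytest.raises(SimConfigError):
            SimConfig(effect_fc_down=1.1)

    def test_nonfinite_parameter_rejected(self):
        with pytest.raises(SimConfigError, match="finite"):
            SimConfig(noise_sd_log2=float("nan"))

    def test_swap_pattern_length_checked(self):
        with pytest.raises(SimConfigError):
            SimConfig(n_replicates=5, swap_pattern=(True, False))

    def test_yaml_round_trip(self, tmp_path):
        config = SimConfig(n_proteins=50, seed=3, frac_up=0.1)
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        assert SimConfig.from_yaml(path) == config


class TestSimulateExperiment:
    def test_null_model_zero_noise_gives_unit_ratios(self):
        """No effects, no noise, no dropout: every oriented ratio is exactly 1.0."""
        config = SimConfig(
            n_proteins=20, noise_sd_log2=0.0, frac_up=0.0, frac_down=0.0, dropout=False
        )
        oriented = simulate_experiment(config).oriented
        assert (oriented.data.to_numpy() == 1.0).all()

    def test_determinism_contract(self):
        config = SimConfig(n_proteins=40, seed=7)
        a = simulate_experiment(config)
        b = simulate_experiment(config)
        pd.testing.assert_frame_equal(a.raw.data, b.raw.data)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert a.design == b.design

    def test_truth_table_consistency(self):
        config = SimConfig(n_proteins=200, frac_up=0.1, frac_down=0.2, seed=1)
        truth = simulate_experiment(config).truth
        assert len(truth) == 200
        assert (truth["true_class"] == "up").sum() == 20
        assert (truth["true_class"] == "down").sum() == 40
        assert (truth.loc[truth["true_class"] == "up", "true_fc"] == 1.6).all()
        assert (truth.loc[truth["true_class"] == "null", "true_fc"] == 1.0).all()

    def test_swapped_replicates_emit_inverted_raw_ratios(self):
        config = SimConfig(
            n_proteins=10, noise_sd_log2=0.0, frac_up=0.1, frac_down=0.0,
            dropout=False, swap_pattern=(False, True),
            n_replicates=2,
        )
        sim = simulate_experiment(config)
        up = sim.truth.index[sim.truth["true_class"] == "up"][0]
        assert sim.raw.data.loc[up, "rep1"] == pytest.approx(1.6)
        assert sim.raw.data.loc[up, "rep2"] == pytest.approx(1 / 1.6)
        assert sim.oriented.data.loc[up, "rep2"] == pytest.approx(1.6)

    def test_screen_recall_of_planted_up(self):
        """Strong effect, low noise: planted 'up' proteins recovered >= 95%."""
        from bonlac import run_screen

        hits = total = 0
        for seed in range(20):
            config = SimConfig(
                n_proteins=200, n_replicates=5, frac_up=0.1, frac_down=0.0,
                effect_fc_up=1.6, noise_sd_log2=0.1, dropout=False, seed=seed,
            )
            sim = simulate_experiment(config)
            calls = {c.protein_id: c.klass for c in run_screen(sim.oriented)}
            planted = sim.truth.index[sim.truth["true_class"] == "up"]
            hits += sum(calls[p] == "up" for p in planted)
            total += len(planted)
        assert hits / total >= 0.95

    def test_dropout_depends_on_abundance(self):
        config = SimConfig(n_proteins=600, seed=2)
        sim = simulate_experiment(config)
        # latent abundance is not exposed; proxy: missingness rises as the
        # detection midpoint rises past the abundance distribution
        high_mid = simulate_experiment(config.replace(dropout_midpoint=8.0))
        assert (
            high_mid.raw.data.isna().mean().mean()
            > sim.raw.data.isna().mean().mean()
        )


class TestSimulateBlot:
    def test_noise_free_null(self):
        """true_ratio 1, no noise: downstream t = 0, p = 1."""
        blot = simulate_blot(4, 4, true_ratio=1.0, noise_sd=0.0)
        in_lane = blot["band_density"] / blot["total_density"]
        r = unpaired_t_test(
            in_lane[blot["group"] == "WT"], in_lane[blot["group"] == "TG"]
        )
        assert r.t == 0.0 and r.p == 1.0

    def test_noise_free_ratio_exact(self):
        """true_ratio 2, no noise: normalized TG exactly twice the WT mean."""
        from bonlac import normalize_blot

        blot = simulate_blot(3, 3, true_ratio=2.0, noise_sd=0.0)
        rel = normalize_blot(blot)
        assert rel[blot["group"] == "TG"].tolist() == pytest.approx([2.0] * 3)

    def test_empirical_power_matches_noncentral_t(self):
        """Monte-Carlo power of the downstream test vs. the closed form."""
        for ratio, n_seeds in [(1.5, 500), (1.1, 1000)]:
            rejections = 0
            for seed in range(n_seeds):
                blot = simulate_blot(8, 8, true_ratio=ratio, noise_sd=0.1, seed=seed)
                in_lane = blot["band_density"] / blot["total_density"]
                r = unpaired_t_test(
                    in_lane[blot["group"] == "WT"], in_lane[blot["group"] == "TG"]
                )
                rejections += r.p < 0.05
            expected = two_sample_t_power(ratio - 1.0, 0.1, 8, 8)
            assert abs(rejections / n_seeds - expected) <= 0.05

    def test_negative_noise_rejected(self):
        with pytest.raises(SimConfigError):
            simulate_blot(3, 3, 1.0, noise_sd=-0.1)

    def test_small_groups_rejected(self):
        with pytest.raises(SimConfigError):
            simulate_blot(1, 4, 1.0, 0.1)


class TestMaxquantFixture:
    def test_round_trip_is_lossless(self, tmp_path):
        config = SimConfig(n_proteins=30, seed=5)
        sim = simulate_experiment(config)
        path = tmp_path / "proteinGroups.txt"
        write_maxquant_fixture(sim.raw, path)
        back, report = read_protein_groups(path)
        pd.testing.assert_frame_equal(
            back.data, sim.raw.data, check_names=False, check_column_type=False
        )
        pd.testing.assert_series_equal(back.genes, sim.raw.genes, check_names=False)
        assert report.total == 0

    def test_artifact_rows_sprinkled_and_filtered(self, tmp_path):
        sim = simulate_experiment(SimConfig(n_proteins=12, seed=5))
        path = tmp_path / "pg.txt"
        write_maxquant_fixture(sim.raw, path, n_contaminants=2, n_reverse=1)
        back, report = read_protein_groups(path)
        assert len(back.protein_ids) == 12
        assert (report.contaminant, report.reverse) == (2, 1)

    def test_empty_table_is_error_not_empty_file(self, tmp_path):
        empty = simulate_experiment(SimConfig(n_proteins=1, seed=0)).raw
        empty.data = empty.data.iloc[:0]
        path = tmp_path / "pg.txt"
        with pytest.raises(FixtureError):
            write_maxquant_fixture(empty, path)
        assert not path.exists()
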