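"""Synthetic-data generator: determinism, zero-noise invertibility, recovery."""

import numpy as np
import pytest

from hydrofrac.equilibration import process_equilibration_batch
from hydrofrac.fractionation import fractionation_table, tissue_offset
from hydrofrac.records import records_to_frame
from hydrofrac.re_model import REParameters, invert_table
from hydrofrac.synthetic import (
    SyntheticConfig,
    generate_equilibration_raw,
    generate_n_experiment,
    generate_pgm_experiment,
    generate_re_scenario,
)


class TestDeterminism:
    def test_same_seed_identical_output(self, default_config):
        assert generate_n_experiment(default_config) == generate_n_experiment(default_config)
        assert generate_pgm_experiment(default_config) == generate_pgm_experiment(default_config)

    def test_different_seeds_differ(self):
        a = generate_n_experiment(SyntheticConfig(seed=0))
        b = generate_n_experiment(SyntheticConfig(seed=1))
        assert a != b


class TestNGradient:
    def test_zero_noise_reproduces_configured_offsets(self, zero_noise_config):
        records = generate_n_experiment(zero_noise_config)
        assert tissue_offset(records, "water", "leaf", "root") == pytest.approx(29.6, abs=1e-9)
        for compound, offset in (("sugars", 17.3), ("starch", 104.5), ("cellulose", 12.3)):
            assert tissue_offset(records, compound, "root", "leaf") == pytest.approx(
                offset, abs=1e-9
            )

    def test_zero_noise_alkane_epsilon_a(self, zero_noise_config):
        table = fractionation_table(records_to_frame(generate_n_experiment(zero_noise_config)))
        alkanes = table[(table["kind"] == "epsilon_a") & (table["compound_a"] == "alkanes")]
        assert len(alkanes) > 0
        assert alkanes["value"].to_numpy() == pytest.approx(
            np.full(len(alkanes), -128.8), abs=1e-9
        )

    def test_treatment_amplitude_matches_config(self, zero_noise_config):
        df = records_to_frame(generate_n_experiment(zero_noise_config))
        for compound, amplitude in zero_noise_config.treatment_amplitudes.items():
            means = (
                df[(df["compound"] == compound) & (df["tissue"] == "leaf")]
                .groupby("treatment")["delta2H"].mean()
            )
            assert means.max() - means.min() == pytest.approx(amplitude, abs=1e-9)

    def test_flat_then_rising_with_break_at_25(self, zero_noise_config):
        df = records_to_frame(generate_n_experiment(zero_noise_config))
        means = (
            df[(df["compound"] == "sugars") & (df["tissue"] == "leaf")]
            .groupby("treatment")["delta2H"].mean()
        )
        assert means[100] == means[90] == means[75] == means[50] == means[25]
        assert means[25] < means[10] < means[0]

    def test_missingness_truncates_sparse_cells(self, default_config):
        df = records_to_frame(generate_n_experiment(default_config))
        counts = df.groupby(["compound", "treatment"])["replicate"].count()
        for treatment in (10, 0):
            assert counts[("cellulose", treatment)] == 2 * 3  # leaf + root, 3 reps
            assert counts[("alkane_C29", treatment)] == 3
        assert counts[("cellulose", 100)] == 2 * 5
        assert counts[("water", 0)] == 3 * 5  # water never truncated

    def test_noisy_offset_within_sampling_error(self):
        config = SyntheticConfig(seed=7)
        records = generate_n_experiment(config)
        observed = tissue_offset(records, "water", "leaf", "root")
        # paired diff of two sd-3 noises, 35 pairs: se ≈ 3·sqrt(2/35) ≈ 0.72
        assert observed == pytest.approx(29.6, abs=3 * 0.72)


class TestPgmExperiment:
    def test_zero_noise_genotype_offsets(self, zero_noise_config):
        df = records_to_frame(generate_pgm_experiment(zero_noise_config))
        means = df.groupby(["compound", "treatment"])["delta2H"].mean()
        for compound, offset in (("starch", 152.7), ("sugars", 75.0), ("cellulose", 38.7)):
            assert means[(compound, "pgm")] - means[(compound, "WT")] == pytest.approx(
                offset, abs=1e-9
            )
        for chain in (27, 29, 31, 33):
            key = f"alkane_C{chain}"
            assert means[(key, "pgm")] - means[(key, "WT")] == pytest.approx(0.0, abs=1e-9)

    def test_noisy_offsets_within_sampling_error(self):
        df = records_to_frame(generate_pgm_experiment(SyntheticConfig(seed=3)))
        means = df.groupby(["compound", "treatment"])["delta2H"].mean()
        se = 3.0 * np.sqrt(2.0 / 5.0)
        for compound, offset in (("starch", 152.7), ("sugars", 75.0), ("cellulose", 38.7)):
            diff = means[(compound, "pgm")] - means[(compound, "WT")]
            assert diff == pytest.approx(offset, abs=3 * se)


class TestEquilibrationSimulation:
    def test_zero_noise_round_trip(self):
        config = SyntheticConfig(noise_sd=0.0)
        truth_ne = [-80.0, -120.0, -60.0]
        truth_x = [0.35, 0.21, 0.0]
        outcome = process_equilibration_batch(
            generate_equilibration_raw(truth_ne, truth_x, config)
        )
        for result, ne, x in zip(outcome.results, truth_ne, truth_x):
            assert result.delta_ne == pytest.approx(ne, abs=1e-9)
            assert result.x_e == pytest.approx(x, abs=1e-9)

    def test_zero_x_e_pairs_match_up_to_noise(self):
        config = SyntheticConfig(noise_sd=2.0, seed=5)
        batch = generate_equilibration_raw([-90.0] * 50, [0.0] * 50, config)
        spreads = np.array([m.delta_e1 - m.delta_e2 for m in batch])
        assert abs(spreads.mean()) < 1.5
        assert spreads.std() == pytest.approx(2.0 * np.sqrt(2), rel=0.5)

    def test_mean_x_e_recovery_under_noise(self):
        config = SyntheticConfig(noise_sd=2.0, seed=11)
        n = 200
        outcome = process_equilibration_batch(
            generate_equilibration_raw([-100.0] * n, [0.21] * n, config)
        )
        recovered = np.array([r.x_e for r in outcome.results])
        assert abs(recovered.mean() - 0.21) < 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            generate_equilibration_raw([-80.0], [0.1, 0.2])


class TestREScenario:
    def test_zero_noise_inversion_exact(self):
        frame = generate_re_scenario(true_f=0.36, noise_sd=0.0, n=10, seed=2)
        out = invert_table(frame, REParameters())
        assert out["f"].item() == pytest.approx(0.36, abs=1e-9)

    def test_negative_f_recovered_and_flagged(self):
        frame = generate_re_scenario(true_f=-0.17, noise_sd=0.0, n=10, seed=2)
        out = invert_table(frame, REParameters(), per_replicate=False)
        assert out["f"].item() == pytest.approx(-0.17, abs=1e-9)
        assert out["f_out_of_range"].item()
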