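"""Tests for the synthetic dual-laser scan generator."""

import numpy as np
import pytest

from gasmas.gas_physics import AmbientConditions, peak_oxygen_mu_a_per_fraction, peak_water_mu_a
from gasmas.lines import h2o_line_820, o2_line_764
from gasmas.scan_synthesis import (
    GroundTruth,
    apply_mixing_bias,
    baseline_ramp,
    default_design,
    muscle_mu_eff,
    record_seed,
    sample_truth,
    simulate_experiment,
    simulate_scan,
)


class TestDefaultDesign:
    def test_thirty_configurations_fifteen_per_illumination(self):
        design = default_design()
        assert len(design.configs) == 30
        modes = [c.illumination for c in design.configs]
        assert modes.count("tracheal") == 15
        assert modes.count("dermal") == 15
        assert design.replicates == 21
        assert design.concentrations == (0.21, 0.30, 0.50, 1.00)

    def test_duplicate_positions_share_truth_key(self):
        design = default_design()
        by_pos = {
            (c.illumination, c.detector_position): design.truth_key(c)
            for c in design.configs
        }
        for mode in ("tracheal", "dermal"):
            assert by_pos[(mode, 10)] == by_pos[(mode, 11)]
            assert by_pos[(mode, 14)] == by_pos[(mode, 15)]
            assert by_pos[(mode, 9)] != by_pos[(mode, 10)]

    def test_config_ids_unique(self):
        design = default_design()
        ids = [c.config_id for c in design.configs]
        assert len(set(ids)) == 30


class TestSampleTruth:
    def test_same_seed_reproduces_truth(self, conditions):
        design = default_design()
        t1 = sample_truth(design, 5, conditions=conditions)
        t2 = sample_truth(design, 5, conditions=conditions)
        assert t1 == t2

    def test_pathlengths_within_support_and_shared_by_duplicates(self, conditions):
        design = default_design()
        truth = sample_truth(design, 5, conditions=conditions)
        for t in truth.values():
            assert 0.01 < t.true_pathlength < 0.20
        for config in design.configs:
            partner_key = design.truth_key(config)
            partner = next(
                c for c in design.configs if c.config_id == partner_key
            )
            assert (
                truth[config.config_id].true_pathlength
                == truth[partner.config_id].true_pathlength
            )

    def test_muscle_effective_attenuation_from_optical_properties(self):
        # mu_eff = sqrt(3 * mu_a * (mu_a + mu_s')) for the muscle rows
        assert muscle_mu_eff(764) == pytest.approx(np.sqrt(3 * 0.20 * (0.20 + 14.1)))
        assert muscle_mu_eff(820) == pytest.approx(np.sqrt(3 * 0.20 * (0.20 + 12.8)))

    def test_undetectable_fraction_assigned(self, conditions):
        design = default_design()
        truth = sample_truth(design, 5, conditions=conditions, n_undetectable=2)
        low = [t for t in truth.values() if t.tissue_transmission < 1e-5]
        assert len(low) == 2


class TestMixingBias:
    def test_zero_beta_is_identity(self):
        seq = [0.21, 0.30, 0.50, 1.00]
        assert apply_mixing_bias(seq, 0.0) == seq

    def test_hand_checked_recursion(self):
        effective = apply_mixing_bias([0.21, 0.30, 0.50, 1.00], 0.2)
        assert effective == pytest.approx([0.21, 0.282, 0.4564, 0.89128])

    def test_effective_below_nominal_for_increasing_sequence(self):
        seq = [0.21, 0.30, 0.50, 1.00]
        effective = apply_mixing_bias(seq, 0.35)
        assert all(e <= n + 1e-12 for e, n in zip(effective, seq))
        assert effective[-1] < 1.0

    def test_beta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_mixing_bias([0.21], 1.0)


class TestSimulateScan:
    def make_truth(self, conditions, length=0.05, transmission=0.5):
        return GroundTruth("cfg", length, 0.30, 0.30, transmission, conditions)

    def test_zero_pathlength_leaves_no_gas_imprint(self, conditions):
        truth = GroundTruth("cfg", 0.0, 0.21, 0.21, 0.5, conditions)
        scan = simulate_scan(truth, 820, 1, 0.0, 1, dark_noise=0.0)
        expected = 16.6 * baseline_ramp(scan.detuning) * 0.5
        np.testing.assert_allclose(scan.intensity, expected, rtol=1e-12)

    @pytest.mark.parametrize("channel", [764, 820])
    def test_noiseless_line_depth_equals_peak_absorbance(self, conditions, channel):
        truth = self.make_truth(conditions)
        # odd point count so the sweep grid contains the exact line center
        grid = np.linspace(-0.6, 0.6, 513)
        scan = simulate_scan(truth, channel, 1, 0.0, 1, dark_noise=0.0, grid=grid)
        center = np.argmin(np.abs(scan.detuning))
        assert scan.detuning[center] == 0.0
        power = {764: 20.3, 820: 16.6}[channel]
        baseline = power * baseline_ramp(scan.detuning) * 0.5
        absorbance = np.log(baseline[center] / scan.intensity[center])
        if channel == 820:
            mu_peak = peak_water_mu_a(conditions, h2o_line_820())
        else:
            mu_peak = 0.30 * peak_oxygen_mu_a_per_fraction(conditions, o2_line_764())
        assert absorbance == pytest.approx(mu_peak * 0.05 * 100, rel=1e-10)

    def test_transmission_scales_intensity_not_line_depth(self, conditions):
        bright = simulate_scan(self.make_truth(conditions, transmission=0.5),
                               820, 1, 0.0, 1, dark_noise=0.0)
        dim = simulate_scan(self.make_truth(conditions, transmission=0.05),
                            820, 1, 0.0, 1, dark_noise=0.0)
        np.testing.assert_allclose(bright.intensity / 0.5, dim.intensity / 0.05,
                                   rtol=1e-12)

    def test_seed_determinism(self, conditions):
        truth = self.make_truth(conditions)
        a = simulate_scan(truth, 820, 1, 1e-4, 99)
        b = simulate_scan(truth, 820, 1, 1e-4, 99)
        c = simulate_scan(truth, 820, 2, 1e-4, 100)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        assert not np.array_equal(a.intensity, c.intensity)


class TestSimulateExperiment:
    def test_record_count_arithmetic(self, conditions):
        design = default_design(replicates=3)
        truth = sample_truth(design, 1, conditions=conditions)
        dataset = simulate_experiment(design, truth, master_seed=1)
        assert len(dataset) == 30 * 3 * 4 * 2

    def test_truth_sidecar_pathlength_constant_across_concentrations(self, conditions):
        design = default_design(replicates=2)
        truth = sample_truth(design, 1, conditions=conditions)
        dataset = simulate_experiment(design, truth, master_seed=1)
        for config in design.configs:
            lengths = {
                dataset.truth[(config.config_id, conc)].true_pathlength
                for conc in design.concentrations
            }
            assert len(lengths) == 1

    def test_dataset_regenerates_identically_from_master_seed(self, conditions):
        design = default_design(n_tracheal=2, n_dermal=2, replicates=2)
        truth = sample_truth(design, 3, conditions=conditions, n_undetectable=0)
        d1 = simulate_experiment(design, truth, master_seed=3)
        d2 = simulate_experiment(design, truth, master_seed=3)
        for r1, r2 in zip(d1.records, d2.records):
            np.testing.assert_array_equal(r1.intensity, r2.intensity)
            assert r1.seed_used == r2.seed_used

    def test_record_seeds_stable_and_bounded(self):
        s = record_seed(7, "tracheal-g1-p01-right", 3, 0.30, 820)
        assert s == record_seed(7, "tracheal-g1-p01-right", 3, 0.30, 820)
        assert 0 <= s < 2**31
        assert s != record_seed(8, "tracheal-g1-p01-right", 3, 0.30, 820)
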