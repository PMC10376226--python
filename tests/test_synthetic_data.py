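import numpy as np
import pytest

import hopwave as hw
from hopwave.errors import ConfigurationError
from hopwave.synthetic_data import GroundTruth, SimulationConfig, generate_cohort, generate_trial


class TestConfigValidation:
    def test_minimum_group_size(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_per_group=1)

    def test_positive_phase_durations(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(phase_durations=(0.6, -0.1, 0.07))

    def test_missing_rate_bounds(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(missing_trial_rate=1.0)

    def test_int_group_size_broadcast(self):
        cfg = SimulationConfig(n_per_group=4)
        assert cfg.n_per_group == (4, 4)


class TestGenerateTrial:
    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(seed=3)
        t1, g1 = generate_trial(cfg, "ACLR", "index", "S1", 0)
        t2, g2 = generate_trial(cfg, "ACLR", "index", "S1", 0)
        assert np.array_equal(t1.emg.to_numpy(), t2.emg.to_numpy())
        assert np.array_equal(t1.vgrf, t2.vgrf)
        assert g1 == g2

    def test_zero_effect_group_symmetry(self):
        # with effect_size = 0 the group label has no influence at all:
        # the same substream produces bit-identical channels
        cfg = SimulationConfig(seed=4, effect_size=0.0)
        ta, _ = generate_trial(cfg, "ACLR", "index", "S1", 0)
        tc, _ = generate_trial(cfg, "Control", "index", "S1", 0)
        assert np.array_equal(ta.emg.to_numpy(), tc.emg.to_numpy())

    def test_nonzero_effect_changes_aclr_only(self):
        cfg = SimulationConfig(seed=4, effect_size=2.0)
        base = SimulationConfig(seed=4, effect_size=0.0)
        c0, _ = generate_trial(base, "Control", "index", "S1", 0)
        c1, _ = generate_trial(cfg, "Control", "index", "S1", 0)
        a0, _ = generate_trial(base, "ACLR", "index", "S1", 0)
        a1, _ = generate_trial(cfg, "ACLR", "index", "S1", 0)
        assert np.array_equal(c0.emg.to_numpy(), c1.emg.to_numpy())
        assert not np.array_equal(a0.emg.to_numpy(), a1.emg.to_numpy())

    def test_force_crosses_50N_exactly_at_t2(self):
        cfg = SimulationConfig(seed=5, duration_jitter=0.0, phase_durations=(0.6, 0.94, 0.07))
        trial, truth = generate_trial(cfg, "ACLR", "contralateral", "S9", 2)
        assert trial.vgrf[truth.t2 - 1] <= 50.0 < trial.vgrf[truth.t2]
        assert np.all(trial.vgrf[: truth.t2 - 4] == 0.0)
        assert trial.vgrf[truth.t3] == trial.vgrf.max()

    def test_requested_t2_position_honored(self):
        # with jitter off the timeline is fully determined by the config
        cfg = SimulationConfig(
            seed=0, duration_jitter=0.0, baseline_s=0.6, phase_durations=(0.6, 1.4, 0.08)
        )
        _, truth = generate_trial(cfg, "Control", "index", "SX", 0)
        assert truth.t2 == 1800 + 1800 + round(1.4 * 3000)

    def test_events_ordered_and_inside_trial(self):
        for seed in range(3):
            trial, truth = generate_trial(SimulationConfig(seed=seed), "ACLR", "index", "Q", 0)
            assert 0 < truth.t0 < truth.t1 < truth.t2 < truth.t3 < trial.n_samples

    def test_quiet_baseline_before_onset(self):
        cfg = SimulationConfig(seed=6, noise_sd=0.0, line_amplitude=0.0)
        trial, truth = generate_trial(cfg, "ACLR", "index", "S1", 0)
        assert np.all(trial.emg.to_numpy()[: truth.t0] == 0.0)

    def test_invalid_labels_rejected(self):
        cfg = SimulationConfig(seed=0)
        with pytest.raises(ConfigurationError):
            generate_trial(cfg, "Patient", "index", "S", 0)
        with pytest.raises(ConfigurationError):
            generate_trial(cfg, "ACLR", "left", "S", 0)

    def test_surgical_alias(self):
        cfg = SimulationConfig(seed=0)
        trial, _ = generate_trial(cfg, "ACLR", "surgical", "S", 0)
        assert trial.limb == "index"


class TestGenerateCohort:
    def test_study_sized_cohort_counts(self):
        cfg = SimulationConfig(n_per_group=(12, 11), missing_trial_rate=0.0, seed=1)
        cohort = generate_cohort(cfg)
        # trial-limb records per comparison side: 69 for the vs-control
        # comparison (11*3 + 12*3), 66 for the within-ACLR comparison
        n_aclr_contra = sum(
            1 for t, _ in cohort.trials if t.group == "ACLR" and t.limb == "contralateral"
        )
        n_ctrl_idx = sum(
            1 for t, _ in cohort.trials if t.group == "Control" and t.limb == "index"
        )
        n_aclr_all = sum(1 for t, _ in cohort.trials if t.group == "ACLR")
        assert n_aclr_contra + n_ctrl_idx == 69
        assert n_aclr_all == 66
        assert len(cohort.trials) == (12 + 11) * 2 * 3

    def test_no_missing_means_three_trials_each(self):
        cfg = SimulationConfig(n_per_group=(3, 3), missing_trial_rate=0.0, seed=2)
        cohort = generate_cohort(cfg)
        counts = {}
        for t, _ in cohort.trials:
            counts[(t.subject_id, t.limb)] = counts.get((t.subject_id, t.limb), 0) + 1
        assert set(counts.values()) == {3}

    def test_missing_rate_drops_trials(self):
        full = generate_cohort(SimulationConfig(n_per_group=(6, 6), seed=3))
        sparse = generate_cohort(
            SimulationConfig(n_per_group=(6, 6), seed=3, missing_trial_rate=0.3)
        )
        assert len(sparse.trials) < len(full.trials)

    def test_outcomes_one_per_subject(self):
        cfg = SimulationConfig(n_per_group=(4, 3), seed=4)
        cohort = generate_cohort(cfg)
        assert len(cohort.outcomes) == 7
        table = cohort.outcome_table()
        assert set(table["group"]) == {"ACLR", "Control"}
        assert (table["worms_total"] >= 0).all()

    def test_girth_worm_link_present(self):
        # the configured linear link must dominate at low noise
        cfg = SimulationConfig(n_per_group=(2, 40), seed=5, worm_noise_sd=0.5)
        table = generate_cohort(cfg).outcome_table()
        aclr = table[table["group"] == "ACLR"]
        slope = np.polyfit(aclr["girth_delta"], aclr["worms_total"], 1)[0]
        assert slope == pytest.approx(-20.8, abs=2.0)


class TestGroundTruth:
    def test_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            GroundTruth(t0=10, t1=5, t2=20, t3=30, group="ACLR", limb="index")
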