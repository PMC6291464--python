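import math

import numpy as np
import pytest

from plinet.connectivity import analytic_phase, pli_pair
from plinet.simulate import (CohortSpec, CouplingPair, CouplingSpec, demo_cohort_spec,
                             default_cohort_spec, derive_match_flags, generate_cohort,
                             generate_coupled_pair, generate_recording,
                             generate_trial_schedule)
from plinet.core import DEFAULT_MONTAGE_59, band_from_name


def estimate_pli(x, y):
    ph = analytic_phase(np.vstack([x, y]))
    return pli_pair(ph.phases[0], ph.phases[1])


class TestTrialSchedule:
    def test_paper_default_120_trials_39_matches(self):
        s = generate_trial_schedule("2-back", 3, 40, 39, seed=1)
        assert s.n_trials == 120
        assert s.n_matches == 39

    def test_shortest_no_match(self):
        s = generate_trial_schedule("2-back", 1, 3, 0, seed=1)
        assert s.n_trials == 3
        assert s.n_matches == 0

    def test_rescan_lag2_equality(self):
        s = generate_trial_schedule("2-back", 1, 10, 4, seed=7)
        flags = derive_match_flags(s.stimuli, "2-back")
        assert sum(flags) == 4
        assert flags == [t.is_match for t in s.trials]

    @pytest.mark.parametrize("seed", range(10))
    def test_rescan_matches_flags_every_seed(self, seed):
        s = generate_trial_schedule("2-back", 3, 40, 39, seed=seed)
        rederived = []
        for k in range(3):
            rederived.extend(derive_match_flags(s.stimuli[k * 40:(k + 1) * 40], "2-back"))
        assert rederived == [t.is_match for t in s.trials]

    def test_0back_match_means_character(self):
        s = generate_trial_schedule("0-back", 3, 40, 39, seed=3)
        assert s.n_matches == 39
        for t in s.trials:
            assert t.is_match == (t.stimulus_id != "*")

    def test_onset_spacing_5s(self):
        s = generate_trial_schedule("2-back", 2, 5, 2, seed=0)
        np.testing.assert_allclose(np.diff(s.onsets), 5.0)
        assert s.onsets[0] == pytest.approx(0.5)  # after fixation

    def test_infeasible_match_count_raises(self):
        with pytest.raises(ValueError):
            generate_trial_schedule("2-back", 1, 5, 4, seed=0)  # cap is 3

    def test_determinism(self):
        a = generate_trial_schedule("2-back", 3, 40, 39, seed=5)
        b = generate_trial_schedule("2-back", 3, 40, 39, seed=5)
        assert a.stimuli == b.stimuli

    def test_unknown_task_raises(self):
        with pytest.raises(ValueError):
            generate_trial_schedule("3-back", 1, 10, 2, seed=0)


class TestCouplingSpecs:
    def test_pair_validation(self):
        with pytest.raises(ValueError):
            CouplingPair(0, 0, 0.5)
        with pytest.raises(ValueError):
            CouplingPair(0, 1, 1.5)
        with pytest.raises(ValueError):
            CouplingPair(0, 1, 0.5, lag_angle=0.0)
        with pytest.raises(ValueError):
            CouplingPair(0, 1, 0.5, lag_angle=math.pi)

    def test_carrier_must_sit_in_band(self):
        band = band_from_name("theta")
        with pytest.raises(ValueError):
            CouplingSpec(band=band, pairs=(CouplingPair(0, 1, 0.5),), carrier_freq=20.0)

    def test_channel_reuse_within_spec_rejected(self):
        band = band_from_name("theta")
        with pytest.raises(ValueError):
            CouplingSpec(band=band, pairs=(CouplingPair(0, 1, 0.5),
                                           CouplingPair(1, 2, 0.5)))

    def test_missing_channel_rejected(self):
        band = band_from_name("theta")
        spec = CouplingSpec(band=band, pairs=(CouplingPair(0, 7, 0.5),))
        with pytest.raises(ValueError):
            generate_recording(4, 2.0, 100.0, (spec,), seed=0)


class TestCoupledPair:
    def test_full_coupling_gives_pli_one(self):
        x, y = generate_coupled_pair(10.0, 250.0, target_pli=1.0,
                                     lag_angle=math.pi / 4, carrier_freq=6.0,
                                     noise_sd=0.0, n_realizations=1, seed=0)
        assert estimate_pli(x, y) == pytest.approx(1.0, abs=0.02)

    def test_zero_coupling_converges_to_zero(self):
        # q = 0.5: |mean of m signs| ~ sqrt(2/(pi m)) -> small for large m
        ests = []
        for seed in range(10):
            x, y = generate_coupled_pair(100.0, 125.0, target_pli=0.0,
                                         carrier_freq=6.0, n_realizations=500,
                                         seed=seed)
            ests.append(estimate_pli(x, y))
        assert np.mean(ests) < 3.0 * math.sqrt(2 / (math.pi * 500)) + 0.05

    def test_monte_carlo_calibration_at_half(self):
        # binomial oracle: mean estimate within 3 SE of 0.5
        m = 200
        n_rep = 30
        ests = []
        for seed in range(n_rep):
            x, y = generate_coupled_pair(50.0, 250.0, target_pli=0.5,
                                         carrier_freq=6.0, n_realizations=m,
                                         seed=seed)
            ests.append(estimate_pli(x, y))
        se = math.sqrt(4 * 0.75 * 0.25 / m) / math.sqrt(n_rep)
        assert abs(np.mean(ests) - 0.5) < 3 * se + 0.01  # +0.01 folding bias slack

    def test_zero_duration_raises(self):
        with pytest.raises(ValueError):
            generate_coupled_pair(0.0, 250.0, target_pli=0.5, seed=0)


class TestGenerateRecording:
    def test_59ch_500hz_shape(self):
        rec = generate_recording(59, 3.5, 500.0, (), seed=0)
        assert rec.data.shape == (59, 1750)
        assert rec.labels == list(DEFAULT_MONTAGE_59)

    def test_uncoupled_channels_near_null_pli(self):
        # single 2.5-s theta segment of independent noise: PLI below 0.2
        from plinet.preprocess import bandpass_array
        rec = generate_recording(2, 2.5, 500.0, (), seed=4, noise_sd=1.0)
        band = band_from_name("theta")
        filtered = bandpass_array(rec.data, band, rec.fs)
        assert estimate_pli(filtered[0], filtered[1]) < 0.2

    def test_determinism(self):
        a = generate_recording(4, 2.0, 250.0, (), seed=9)
        b = generate_recording(4, 2.0, 250.0, (), seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_coupled_pair_carries_signal(self):
        band = band_from_name("theta")
        spec = CouplingSpec(band=band, pairs=(CouplingPair(0, 1, 1.0),))
        rec = generate_recording(3, 20.0, 250.0, (spec,), seed=1, noise_sd=0.0)
        est = estimate_pli(rec.data[0], rec.data[1])
        assert est > 0.8


class TestCohort:
    def test_default_spec_sizes(self):
        spec = default_cohort_spec()
        assert spec.groups["young"].n == 15
        assert spec.groups["senior"].n == 10

    def test_small_cohort_structure(self):
        spec = demo_cohort_spec(2, 2, n_epochs=2, n_channels=4, fs=100.0)
        cohort = generate_cohort(spec, seed=0)
        assert len(cohort.table) == 4
        assert len(cohort.recordings) == 12  # 4 subjects x 3 conditions
        for (subj, cond), rec in cohort.recordings.items():
            assert rec.condition == cond
            assert rec.n_channels == 4

    def test_behavior_columns_in_range(self):
        spec = demo_cohort_spec(3, 3, n_epochs=1, n_channels=2, fs=100.0)
        cohort = generate_cohort(spec, seed=2)
        for task in ("0-back", "2-back"):
            acc = cohort.table[f"accuracy_{task}"]
            assert ((acc >= 0) & (acc <= 1)).all()
            assert (cohort.table[f"rt_{task}"] > 0).all()

    def test_determinism(self):
        spec = demo_cohort_spec(2, 1, n_epochs=1, n_channels=2, fs=100.0)
        a = generate_cohort(spec, seed=3)
        b = generate_cohort(spec, seed=3)
        assert a.table.equals(b.table)
        for key in a.recordings:
            np.testing.assert_array_equal(a.recordings[key].data,
                                          b.recordings[key].data)

    def test_planted_group_ordering_recovered(self):
        # d = 1.5 planted on the 2-back targets: senior mean target exceeds
        # young mean target in nearly all replicate cohorts
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            spec = demo_cohort_spec(5, 5, effect_d=1.5, base_pli=0.35,
                                    between_sd=0.12, n_epochs=1, n_channels=2,
                                    fs=100.0, conditions=("2-back",))
            cohort = generate_cohort(spec, seed=seed)
            merged = cohort.targets.merge(cohort.table[["subject", "group"]])
            means = merged.groupby("group")["target_pli"].mean()
            wins += means["senior"] > means["young"]
        assert wins >= 95

    def test_invalid_group_spec(self):
        with pytest.raises(ValueError):
            demo_cohort_spec(0, 2)

    def test_missing_band_targets_rejected(self):
        spec = demo_cohort_spec(1, 1, n_epochs=1, n_channels=2, fs=100.0)
        with pytest.raises(ValueError):
            CohortSpec(groups=spec.groups, bands=("theta", "gamma"),
                       n_channels=2, fs=100.0)
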