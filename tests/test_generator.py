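"""Synthetic lifting-trial generator: sampling, physics, and determinism."""

import math

import numpy as np
import pytest
from scipy import stats

import liftrisk as lr
from liftrisk import generator as gen
from liftrisk.config import ConfigurationError, SimConfig

G = 9.81


def _noiseless_sim(**kwargs):
    return SimConfig(
        angle_noise_deg=0.0,
        lin_acc_noise_ms2=0.0,
        force_split_sd=0.0,
        cop_noise_m=0.0,
        trial_flexion_jitter_deg=0.0,
        **kwargs,
    )


def _profile(**kwargs):
    defaults = dict(participant_id=0, body_mass=75.0, stature=1.75)
    defaults.update(kwargs)
    return lr.AnthroProfile(**defaults)


class TestSampleParticipants:
    def test_seed_determinism(self):
        a = lr.sample_participants(10, seed=1)
        b = lr.sample_participants(10, seed=1)
        assert [(p.body_mass, p.stature) for p in a] == [(p.body_mass, p.stature) for p in b]

    def test_single_participant_rejected(self):
        with pytest.raises(ConfigurationError, match="leave-one-participant-out"):
            lr.sample_participants(1)

    def test_masses_uniform_in_range(self):
        profiles = lr.sample_participants(10_000, seed=5)
        masses = np.array([p.body_mass for p in profiles])
        assert masses.min() >= 60.0 and masses.max() <= 100.0
        p = stats.kstest(masses, stats.uniform(loc=60, scale=40).cdf).pvalue
        assert p > 0.01

    def test_hat_parameters_scale_with_stature(self):
        p = lr.sample_participants(2, seed=0)[0]
        assert p.hat_com_distance == pytest.approx(0.17 * p.stature)
        assert p.inertia_pivot > p.inertia_com > 0


class TestTaskGrid:
    def test_default_grid_covers_study_ranges(self):
        tasks = lr.build_task_grid()
        assert len(tasks) == 50
        masses = {t.box_mass for t in tasks}
        heights = {t.origin_height for t in tasks}
        assert min(masses) == 5.0 and max(masses) == 23.0
        assert min(heights) == 40.0 and max(heights) == 160.0

    def test_degenerate_grid_is_midpoint(self):
        tasks = lr.build_task_grid(n_masses=1, n_heights=1)
        assert len(tasks) == 1
        assert tasks[0].box_mass == 14.0
        assert tasks[0].origin_height == 100.0

    def test_all_pairs_unique(self):
        tasks = lr.build_task_grid(n_masses=3, n_heights=4)
        pairs = {(t.box_mass, t.origin_height) for t in tasks}
        assert len(tasks) == len(pairs) == 12

    def test_empty_range_rejected(self):
        with pytest.raises(ConfigurationError):
            lr.build_task_grid(mass_range=(10.0, 5.0))
        with pytest.raises(ConfigurationError):
            lr.build_task_grid(height_range=(100.0, 100.0), n_heights=3)


class TestSimulateLift:
    def test_quasi_static_oracle_hat_only(self):
        """With no box and no style noise, the peak equals m_HAT g r sin(theta)."""
        profile = _profile()
        task = lr.LiftTaskSpec(task_id=0, box_mass=0.0, origin_height=40.0)
        trial = lr.simulate_lift(profile, task, _noiseless_sim(), seed=0)
        theta = math.radians(gen.peak_flexion_angle(profile, task, _noiseless_sim()))
        oracle = profile.hat_mass * G * profile.hat_com_distance * math.sin(theta)
        assert trial.lumbar_moment_truth.max() == pytest.approx(oracle, rel=1e-9)

    def test_quasi_static_oracle_default_noise(self):
        profile = _profile()
        task = lr.LiftTaskSpec(task_id=0, box_mass=0.0, origin_height=40.0)
        trial = lr.simulate_lift(profile, task, SimConfig(), seed=0)
        theta = math.radians(gen.peak_flexion_angle(profile, task, SimConfig()))
        oracle = profile.hat_mass * G * profile.hat_com_distance * math.sin(theta)
        assert trial.lumbar_moment_truth.max() == pytest.approx(oracle, rel=0.05)

    def test_box_mass_does_not_enter_kinematics(self):
        profile = _profile()
        t5 = lr.simulate_lift(profile, lr.LiftTaskSpec(0, 5.0, 100.0), seed=2)
        t15 = lr.simulate_lift(profile, lr.LiftTaskSpec(1, 15.0, 100.0), seed=2)
        np.testing.assert_array_equal(t5.trunk_angles, t15.trunk_angles)
        np.testing.assert_array_equal(t5.trunk_lin_acc, t15.trunk_lin_acc)
        # held-phase quasi-static total force differs by exactly 10 kg of weight
        qs = gen.quasi_static_mask(t5) & t5.hold_mask
        f5 = (t5.foot_force_left + t5.foot_force_right)[qs]
        f15 = (t15.foot_force_left + t15.foot_force_right)[qs]
        np.testing.assert_allclose(f15 - f5, 10.0 * G, rtol=1e-9)

    def test_initial_quiet_standing(self):
        profile = _profile()
        trial = lr.simulate_lift(profile, lr.LiftTaskSpec(0, 12.0, 80.0), seed=0)
        total0 = trial.foot_force_left[0] + trial.foot_force_right[0]
        assert total0 == pytest.approx(profile.body_mass * G, rel=0.005)
        assert abs(trial.lumbar_moment_truth[0]) < 1e-9

    def test_quasi_static_force_balance_everywhere(self):
        profile = _profile()
        for task in (lr.LiftTaskSpec(0, 23.0, 40.0), lr.LiftTaskSpec(1, 5.0, 160.0)):
            trial = lr.simulate_lift(profile, task, seed=4)
            qs = gen.quasi_static_mask(trial)
            assert qs.any()
            total = trial.foot_force_left + trial.foot_force_right
            supported = gen.supported_weight(trial, profile.body_mass)
            rel = np.abs(total[qs] - supported[qs]) / supported[qs]
            assert rel.max() < 0.01

    def test_top_down_vs_bottom_up_agreement(self):
        profile = _profile()
        task = lr.LiftTaskSpec(0, 18.0, 60.0)
        noiseless = lr.simulate_lift(profile, task, _noiseless_sim(), seed=0)
        recomputed = gen.bottom_up_lumbar_moment(noiseless)
        rmse = np.sqrt(np.mean((recomputed - noiseless.lumbar_moment_truth) ** 2))
        assert rmse < 5.0
        assert rmse < 1e-9  # exact by the ground-wrench construction at zero noise

    def test_peak_moment_monotone_in_mass_and_height(self, default_profiles):
        profile = default_profiles[0]
        masses = np.linspace(5, 23, 5)
        heights = np.linspace(40, 160, 10)
        peaks = np.empty((5, 10))
        tid = 0
        for i, m in enumerate(masses):
            for j, h in enumerate(heights):
                t = lr.simulate_lift(profile, lr.LiftTaskSpec(tid, m, h), seed=1)
                peaks[i, j] = t.lumbar_moment_truth.max()
                tid += 1
        assert (np.diff(peaks, axis=0) >= -1e-9).all()   # non-decreasing in box mass
        assert (np.diff(peaks, axis=1) <= 1e-9).all()    # non-increasing in shelf height

    def test_incompatible_phase_durations_rejected(self):
        with pytest.raises(ConfigurationError, match="phase durations"):
            lr.simulate_lift(
                _profile(),
                lr.LiftTaskSpec(0, 10.0, 80.0),
                SimConfig(sample_rate_hz=1.0),
            )

    def test_flexion_mapping_out_of_range_rejected(self):
        sim = SimConfig(flexion_map_angles_deg=(170.0, 20.0), peak_flexion_cap_deg=135.0)
        with pytest.raises(ConfigurationError, match="peak flexion"):
            lr.simulate_lift(_profile(), lr.LiftTaskSpec(0, 10.0, 40.0), sim)

    def test_box_at_hands_increases_load_arm(self):
        # moderate flexion: the trunk-fixed anterior offset has a horizontal
        # component there (at 90 deg flexion "anterior" points at the floor)
        profile = _profile()
        task = lr.LiftTaskSpec(0, 23.0, 120.0)
        base = lr.simulate_lift(profile, task, _noiseless_sim(), seed=0)
        hands = lr.simulate_lift(profile, task, _noiseless_sim(box_at_hands=True), seed=0)
        assert hands.lumbar_moment_truth.max() > base.lumbar_moment_truth.max()
        assert hands.box_at_hands_flag and not base.box_at_hands_flag


class TestGenerateDataset:
    def test_trial_count(self, small_trials):
        profiles, tasks, trials, manifest = small_trials
        assert len(trials) == len(manifest) == 3 * 12

    def test_repetitions_multiply_count(self):
        profiles = lr.sample_participants(2, seed=0)
        tasks = lr.build_task_grid(n_masses=2, n_heights=2, repetitions=2)
        trials, manifest = lr.generate_dataset(profiles, tasks, seed=0)
        assert len(manifest) == 2 * 4 * 2

    def test_removing_participant_drops_rows(self):
        profiles = lr.sample_participants(3, seed=0)
        tasks = lr.build_task_grid(n_masses=2, n_heights=3)
        _, full = lr.generate_dataset(profiles, tasks, seed=0)
        _, less = lr.generate_dataset(profiles[:-1], tasks, seed=0)
        assert len(full) - len(less) == len(tasks)

    def test_manifest_byte_identical_across_runs(self, tmp_path):
        profiles = lr.sample_participants(2, seed=0)
        tasks = lr.build_task_grid(n_masses=2, n_heights=2)
        lr.generate_dataset(profiles, tasks, seed=9, out_dir=tmp_path / "a")
        lr.generate_dataset(profiles, tasks, seed=9, out_dir=tmp_path / "b")
        assert (tmp_path / "a/manifest.csv").read_bytes() == (
            tmp_path / "b/manifest.csv"
        ).read_bytes()

    def test_trial_csv_round_trip(self, tmp_path):
        profiles = lr.sample_participants(2, seed=0)
        tasks = [lr.LiftTaskSpec(0, 10.0, 80.0)]
        trials, manifest = lr.generate_dataset(
            profiles, tasks, seed=0, out_dir=tmp_path, write_trials=True
        )
        import pandas as pd

        df = pd.read_csv(tmp_path / manifest["file"].iloc[0])
        assert len(df) == trials[0].n_samples
        assert "lumbar_moment_truth_nm" in df.columns


class TestAnthroProfile:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"body_mass": -1.0},
            {"stature": 0.0},
            {"hat_mass_fraction": 1.0},
            {"hat_mass_fraction": 0.0},
        ],
    )
    def test_invalid_profiles_rejected(self, kwargs):
        with pytest.raises(ValueError):
            _profile(**kwargs)

    def test_prism_inertia(self):
        p = _profile()
        h, d = p.hat_prism_height, p.hat_prism_depth
        assert p.inertia_com == pytest.approx(p.hat_mass * (h**2 + d**2) / 12)
        assert p.inertia_pivot == pytest.approx(
            p.inertia_com + p.hat_mass * p.hat_com_distance**2
        )
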