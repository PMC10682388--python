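"""Generator contracts: trait structure, task-design invariants, determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from propriolearn.synthetic_cohort import (
    CohortConfig,
    StructuralTraitModel,
    generate_judgment_session,
    generate_memory_session,
    generate_reproduction,
    generate_target_trajectory,
    sample_traits,
    simulate_cohort,
)


def traits_array(profiles):
    return np.array([[p.a, p.m, p.l] for p in profiles])


class TestTraits:
    def test_chain_correlations_match_path_tracing(self, default_model):
        # Monte-Carlo oracle: corr(M, L) = coeff_ml, corr(A, L) = coeff_ml * coeff_am
        x = traits_array(sample_traits(default_model, 2000, seed=3))
        c = np.corrcoef(x.T)
        assert c[1, 2] == pytest.approx(0.70, abs=0.05)
        assert c[0, 2] == pytest.approx(0.70 * -0.39, abs=0.05)
        assert c[0, 1] == pytest.approx(-0.39, abs=0.05)

    def test_unit_variances(self, default_model):
        x = traits_array(sample_traits(default_model, 2000, seed=5))
        assert np.allclose(x.var(axis=0), 1.0, atol=0.1)

    def test_null_model_gives_uncorrelated_traits(self):
        model = StructuralTraitModel(coeff_am=0.0, coeff_ml=0.0, coeff_al=0.0)
        x = traits_array(sample_traits(model, 2000, seed=9))
        c = np.corrcoef(x.T)
        off = c[np.triu_indices(3, k=1)]
        assert np.all(np.abs(off) < 0.08)

    def test_gaussian_family_warns(self):
        model = StructuralTraitModel(noise_family="gaussian")
        with pytest.warns(UserWarning, match="unidentifiable"):
            sample_traits(model, 10, seed=1)

    def test_nonpositive_n_rejected(self, default_model):
        with pytest.raises(ValueError):
            sample_traits(default_model, 0, seed=1)

    def test_profile_invariants(self, default_model):
        for p in sample_traits(default_model, 200, seed=2):
            assert p.sigma_p > 0 and p.sigma_enc > 0
            assert 0.0 <= p.rho_pre <= p.rho_post <= 1.0
            assert 0.0 <= p.guess_rate < 1.0

    def test_stable_under_cohort_growth(self, default_model):
        small = sample_traits(default_model, 5, seed=4)
        large = sample_traits(default_model, 50, seed=4)
        assert traits_array(small) == pytest.approx(traits_array(large[:5]))


class TestMemorySession:
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_design_invariants_across_seeds(self, seed):
        cfg = CohortConfig()
        profile = sample_traits(StructuralTraitModel(), 1, seed=seed)[0]
        trials = generate_memory_session(
            profile, cfg, np.random.default_rng(seed)
        )
        assert len(trials) == 60
        assert sum(t.condition == "present" for t in trials) == 30
        positions = [t.matched_position for t in trials if t.condition == "present"]
        assert sorted(positions).count(1) == 10
        grid = cfg.angle_grid()
        for t in trials:
            angles = np.array(t.angles)
            assert np.min(np.diff(np.sort(angles))) >= 10.0
            assert all(a in grid for a in angles)
            if t.condition == "absent":
                assert np.min(np.abs(angles - t.test_angle)) >= 10.0
            else:
                assert t.test_angle == angles[t.matched_position - 1]

    def test_infinite_criterion_yields_all_present(self, default_model):
        from dataclasses import replace

        profile = replace(
            sample_traits(default_model, 1, seed=0)[0],
            match_criterion=1e9, guess_rate=0.0,
        )
        trials = generate_memory_session(profile, CohortConfig(), np.random.default_rng(0))
        assert all(t.response == "present" for t in trials)

    def test_noiseless_tight_criterion_is_perfect(self, default_model):
        from dataclasses import replace

        from propriolearn.memory_scoring import score_memory_session

        profile = replace(
            sample_traits(default_model, 1, seed=0)[0],
            sigma_enc=1e-9, decay_slope=0.0, match_criterion=5.0, guess_rate=0.0,
        )
        trials = generate_memory_session(
            profile, CohortConfig(), np.random.default_rng(1), sigma_floor=0.0
        )
        score = score_memory_session(trials)
        assert score.sensitivity == 1.0
        assert score.false_alarms == 0
        assert all(
            t.named_position == t.matched_position
            for t in trials
            if t.condition == "present"
        )


class TestJudgmentSession:
    def test_cell_balance(self, default_model):
        cfg = CohortConfig()
        profile = sample_traits(default_model, 1, seed=0)[0]
        trials = generate_judgment_session(profile, cfg, np.random.default_rng(0))
        assert len(trials) == 80
        df = pd.DataFrame([(t.reference, t.deviation) for t in trials])
        assert (df.value_counts() == 5).all()
        assert len(df.value_counts()) == 16

    def test_noiseless_limit_matches_sign(self, default_model):
        from dataclasses import replace

        profile = replace(sample_traits(default_model, 1, seed=0)[0], sigma_p=1e-9)
        trials = generate_judgment_session(profile, CohortConfig(), np.random.default_rng(0))
        for t in trials:
            assert t.response == ("larger" if t.deviation > 0 else "smaller")


class TestTargetTrajectory:
    def test_length_and_range(self):
        cfg = CohortConfig()
        for seed in range(10):
            traj = generate_target_trajectory(cfg, np.random.default_rng(seed))
            assert len(traj) == 2500
            assert traj.rate == 250.0
            assert np.all(traj.samples >= 0.0) and np.all(traj.samples <= 90.0)
            # starts and ends at the home angle
            assert abs(traj.samples[0]) < 1e-9 and abs(traj.samples[-1]) < 1e-9

    def test_zero_harmonics_constant_home(self):
        from dataclasses import replace

        cfg = replace(CohortConfig(), harmonics=(0, 0))
        traj = generate_target_trajectory(cfg, np.random.default_rng(0))
        assert np.all(traj.samples == 0.0)

    def test_amplitude_out_of_range_rejected(self):
        from dataclasses import replace

        cfg = replace(CohortConfig(), amplitude_deg=80.0)
        with pytest.raises(ValueError):
            generate_target_trajectory(cfg, np.random.default_rng(0))


class TestReproduction:
    def test_perfect_fidelity_recovers_target(self, default_model):
        from dataclasses import replace

        cfg = CohortConfig()
        target = generate_target_trajectory(cfg, np.random.default_rng(3))
        profile = replace(
            sample_traits(default_model, 1, seed=0)[0], rho_pre=1.0, rho_post=1.0
        )
        rep = generate_reproduction(
            profile, target, "post", np.random.default_rng(0),
            config=cfg, motor_noise_sd=0.0,
        )
        assert rep.samples == pytest.approx(target.samples)

    def test_zero_fidelity_uncorrelated(self, default_model):
        from dataclasses import replace

        from propriolearn.trajectory_similarity import xcorr_peak

        cfg = CohortConfig()
        target = generate_target_trajectory(cfg, np.random.default_rng(3))
        profile = replace(
            sample_traits(default_model, 1, seed=0)[0], rho_pre=0.0, rho_post=0.0
        )
        peaks = [
            xcorr_peak(
                target,
                generate_reproduction(
                    profile, target, "pre", np.random.default_rng(s),
                    config=cfg, motor_noise_sd=0.0,
                ),
            )[0]
            for s in range(8)
        ]
        assert np.mean(peaks) < 0.35  # decorrelated distractor bound

    def test_post_exceeds_pre_on_average(self, default_model):
        from propriolearn.trajectory_similarity import score_phase

        cfg = CohortConfig()
        target = generate_target_trajectory(cfg, np.random.default_rng(3))
        profile = sample_traits(default_model, 1, seed=0)[0]
        rng = np.random.default_rng(5)
        pre = [generate_reproduction(profile, target, "pre", rng, config=cfg) for _ in range(5)]
        post = [generate_reproduction(profile, target, "post", rng, config=cfg) for _ in range(5)]
        rp, _, _ = score_phase(target, pre)
        rq, _, _ = score_phase(target, post)
        assert np.mean(rq) > np.mean(rp)

    def test_unknown_phase_rejected(self, default_model):
        cfg = CohortConfig()
        target = generate_target_trajectory(cfg, np.random.default_rng(3))
        profile = sample_traits(default_model, 1, seed=0)[0]
        with pytest.raises(ValueError):
            generate_reproduction(profile, target, "mid", np.random.default_rng(0))


class TestSimulateCohort:
    def test_shapes_and_determinism(self, small_cohort):
        cohort = small_cohort
        assert len(cohort.profiles) == 25
        assert len(cohort.memory_trials) == 25 * 60
        assert len(cohort.judgment_trials) == 25 * 80
        for pid, phases in cohort.reproductions.items():
            assert len(phases["pre"]) == 5 and len(phases["post"]) == 5
        again = simulate_cohort(CohortConfig(n_participants=25, seed=11))
        pd.testing.assert_frame_equal(cohort.memory_trials, again.memory_trials)
        pd.testing.assert_frame_equal(cohort.judgment_trials, again.judgment_trials)
        assert cohort.target.samples == pytest.approx(again.target.samples)
        p = cohort.participant_ids()[3]
        assert cohort.reproductions[p]["post"][2].samples == pytest.approx(
            again.reproductions[p]["post"][2].samples
        )

    def test_zero_participants_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(CohortConfig(n_participants=0, seed=1))

    def test_save_round_trip(self, tmp_path, default_model):
        cohort = simulate_cohort(
            CohortConfig(n_participants=2, seed=3), default_model
        )
        cohort.save(tmp_path)
        assert (tmp_path / "memory_trials.csv").exists()
        assert (tmp_path / "cohort_config.yaml").exists()
        assert (tmp_path / "trajectories" / "target.csv").exists()
        reload = pd.read_csv(tmp_path / "memory_trials.csv")
        assert len(reload) == 120
        traj = pd.read_csv(tmp_path / "trajectories" / "p001_pre_1.csv")
        assert list(traj.columns) == ["time_s", "angle_deg"]
        assert len(traj) == 2500
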