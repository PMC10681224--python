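"""Generator properties: determinism, tempo, drift, sticking injection."""

import numpy as np
import pytest

from squatkin import (
    CohortConfig,
    SegmentLengths,
    StickingDipParams,
    TrialParams,
    compute_kinematics,
    detect_repetitions,
    generate_cohort,
    generate_trial,
    inject_sticking,
    make_ascent_fixture,
)
from squatkin.kinematics import MARKER_NAMES, ParameterError


class TestGenerateTrial:
    def test_deterministic_given_seed(self):
        p = TrialParams(seed=42, noise_sd_m=0.003)
        a, b = generate_trial(p), generate_trial(p)
        for m in MARKER_NAMES:
            assert np.array_equal(a.markers[m], b.markers[m])

    def test_different_seeds_differ(self):
        a = generate_trial(TrialParams(seed=1, noise_sd_m=0.003))
        b = generate_trial(TrialParams(seed=2, noise_sd_m=0.003))
        assert not np.array_equal(a.markers["trochanter"], b.markers["trochanter"])

    def test_zero_excursion_is_static_standing(self):
        p = TrialParams(noise_sd_m=0.0, rom_hip_deg=0.0, rom_knee_deg=0.0)
        traj = generate_trial(p)
        for m in MARKER_NAMES:
            assert np.allclose(traj.markers[m], traj.markers[m][0], atol=1e-12)

    def test_rep_count_and_period(self, clean_trial, clean_kin, clean_cycles):
        """45 bpm five-rep trial: 5 hip-height minima, 2.667 s per rep."""
        params, traj = clean_trial
        assert len(clean_cycles) == 5
        fs = traj.sampling_rate_hz
        durations = [(c.end_idx - c.start_idx) / fs for c in clean_cycles]
        assert np.allclose(durations, params.rep_period_s, atol=1.0 / fs)
        # hip height minima count equals rep count
        y = clean_kin.y_hip
        minima = np.flatnonzero((y[1:-1] < y[:-2]) & (y[1:-1] < y[2:]))
        assert len(minima) == 5

    def test_fatigue_drift_deepens_later_reps(self):
        p = TrialParams(n_reps=6, fatigue_drift=0.15, noise_sd_m=0.0)
        kin = compute_kinematics(generate_trial(p), cutoff_hz=None)
        cycles = detect_repetitions(kin)
        depths = [180.0 - kin.hip_deg[c.bottom_idx] for c in cycles]
        assert depths[-1] > depths[0]
        assert depths[-1] / depths[0] == pytest.approx(1.15, abs=0.01)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tempo_bpm": 0.0},
            {"tempo_bpm": float("nan")},
            {"n_reps": 2},
            {"noise_sd_m": -0.001},
            {"rom_hip_deg": 185.0},
            {"sampling_rate_hz": -1.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            TrialParams(**kwargs)

    def test_segment_lengths_must_be_positive(self):
        with pytest.raises(ParameterError):
            SegmentLengths(thigh_m=-0.1)


class TestInjectSticking:
    DIP = StickingDipParams(t_pre_s=0.06, t_dip_s=0.10, dip_depth_frac=0.3,
                            t_recover_s=0.2)

    def test_net_ascent_displacement_preserved(self, clean_trial, clean_kin,
                                               clean_cycles):
        _, traj = clean_trial
        out = inject_sticking(traj, 2, self.DIP)
        kin2 = compute_kinematics(out, cutoff_hz=None)
        cyc = clean_cycles[2]
        net0 = clean_kin.y_hip[cyc.end_idx] - clean_kin.y_hip[cyc.bottom_idx]
        net1 = kin2.y_hip[cyc.end_idx] - kin2.y_hip[cyc.bottom_idx]
        assert abs(net1 - net0) < 1e-6

    def test_other_reps_untouched(self, clean_trial, clean_cycles):
        _, traj = clean_trial
        out = inject_sticking(traj, 2, self.DIP)
        cyc = clean_cycles[2]
        mask = np.ones(traj.n_frames, dtype=bool)
        mask[cyc.start_idx : cyc.end_idx + 1] = False
        for m in MARKER_NAMES:
            assert np.array_equal(traj.markers[m][mask], out.markers[m][mask])

    def test_dip_longer_than_ascent_rejected(self, clean_trial):
        _, traj = clean_trial
        long_dip = StickingDipParams(t_pre_s=0.5, t_dip_s=0.5, dip_depth_frac=0.3,
                                     t_recover_s=0.5)
        with pytest.raises(ValueError, match="ascent"):
            inject_sticking(traj, 1, long_dip)

    def test_rep_index_out_of_range(self, clean_trial):
        _, traj = clean_trial
        with pytest.raises(IndexError):
            inject_sticking(traj, 99, self.DIP)


class TestGenerateCohort:
    def test_structure_and_determinism(self):
        cfg = CohortConfig(
            n_participants=6,
            llmr_values=(32.0, 33.0, 33.5, 34.5, 35.0, 36.0),
            seed=5,
        )
        p = TrialParams(n_reps=5, noise_sd_m=0.0)
        a = generate_cohort(cfg, p)
        b = generate_cohort(cfg, p)
        assert len(a) == 12  # 6 participants x 2 conditions
        assert {m.condition for m in a} == {"nonfatigue", "fatigue"}
        assert sum(m.group == "low" for m in a) == 6
        for ma, mb in zip(a, b):
            assert np.array_equal(
                ma.trajectory.markers["trochanter"],
                mb.trajectory.markers["trochanter"],
            )

    def test_null_condition_effect_gives_matched_pairs(self):
        cfg = CohortConfig(
            n_participants=4,
            llmr_values=(32.0, 33.0, 35.0, 36.0),
            condition_effects={},
            seed=9,
            rom_sd_deg=5.0,
            trial_rom_sd_deg=0.0,
        )
        p = TrialParams(n_reps=5, noise_sd_m=0.0)
        members = generate_cohort(cfg, p)
        by_pid = {}
        for m in members:
            by_pid.setdefault(m.participant_id, {})[m.condition] = m.trajectory
        for pair in by_pid.values():
            k0 = compute_kinematics(pair["nonfatigue"], cutoff_hz=None)
            k1 = compute_kinematics(pair["fatigue"], cutoff_hz=None)
            assert np.allclose(k0.hip_deg, k1.hip_deg, atol=1e-9)

    def test_llmr_median_split_sizes(self):
        cfg = CohortConfig(
            n_participants=5, llmr_values=(36.0, 32.0, 34.0, 33.0, 35.0), seed=0
        )
        members = generate_cohort(cfg, TrialParams(n_reps=3, noise_sd_m=0.0))
        groups = {m.participant_id: m.group for m in members}
        assert sum(g == "low" for g in groups.values()) == 2
        assert sum(g == "high" for g in groups.values()) == 3

    def test_llmr_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            CohortConfig(n_participants=3, llmr_values=(33.0, 35.0), seed=0)


class TestAscentFixture:
    def test_landmarks_at_requested_samples(self):
        dip = StickingDipParams(0.06, 0.10, 0.3, 0.2)
        fx = make_ascent_fixture(dip, 100.0)
        assert fx.landmarks == {"v0": 0, "vmax1": 6, "vmin": 16, "vmax2": 36}
        assert not fx.snapped
        v = fx.velocity
        assert v[0] == 0.0
        assert (v >= 0).all()
        assert v[16] == pytest.approx(0.7 * v[6])

    def test_off_grid_times_snap_with_warning(self):
        dip = StickingDipParams(0.063, 0.10, 0.3, 0.2)
        with pytest.warns(UserWarning, match="snapped"):
            fx = make_ascent_fixture(dip, 100.0)
        assert fx.snapped
        assert fx.landmarks["vmax1"] == 6
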