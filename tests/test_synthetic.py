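"""The phase-coupled cohort generator: determinism, PLV recovery, separation."""

import numpy as np
import pytest

from vnfc.connectivity import instantaneous_phase, plv_matrix_from_phases, plv_pair
from vnfc.synthetic import (
    SubjectModel,
    load_cohort,
    pure_region_channels,
    sample_subject,
    save_cohort,
    simulate_cohort,
    simulate_planted_cohort,
    simulate_recording,
)


def mean_windowed_plv(rec, win=160, hop=80):
    ph = instantaneous_phase(rec.data)
    n_w = (rec.n_samples - win) // hop + 1
    return np.mean(
        [plv_matrix_from_phases(ph[:, i * hop : i * hop + win]).values for i in range(n_w)],
        axis=0,
    )


class TestSampleSubject:
    def test_zero_strength_gives_zero_coupling(self):
        s = sample_subject(16, coupling_density=0.5, coupling_strength=0.0, seed=0)
        assert np.all(s.coupling == 0)

    def test_full_density_couples_every_pair(self):
        s = sample_subject(10, coupling_density=1.0, seed=0)
        off = ~np.eye(10, dtype=bool)
        assert np.all(s.coupling[off] > 0)

    def test_realized_density_within_one_edge(self):
        for density in (0.02, 0.1, 0.3):
            s = sample_subject(32, coupling_density=density, seed=3)
            n_pairs = 32 * 31 // 2
            got = int(np.count_nonzero(np.triu(s.coupling, 1)))
            assert abs(got - round(density * n_pairs)) <= 1

    def test_distinct_seeds_distinct_patterns(self):
        a = sample_subject(64, seed=1).coupling
        b = sample_subject(64, seed=2).coupling
        assert not np.array_equal(a, b)

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            sample_subject(8, coupling_density=0.0)
        with pytest.raises(ValueError):
            sample_subject(8, coupling_strength=1.5)

    def test_asymmetric_coupling_rejected(self):
        K = np.zeros((4, 4))
        K[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            SubjectModel(coupling=K)


class TestSimulateRecording:
    def test_deterministic_per_seed(self):
        s = sample_subject(8, seed=0, smoothing=0.0)
        a = simulate_recording(s, duration_s=2.0, seed=5)
        b = simulate_recording(s, duration_s=2.0, seed=5)
        np.testing.assert_array_equal(a.data, b.data)
        c = simulate_recording(s, duration_s=2.0, seed=6)
        assert not np.array_equal(a.data, c.data)

    def test_noiseless_identical_oscillators_fully_lock(self):
        # no coupling, no noise or drift, identical frequencies -> identical phases
        s = SubjectModel(
            coupling=np.zeros((4, 4)),
            freq_jitter=0.0,
            freq_drift_sd=0.0,
            noise_sd=0.0,
            phase_noise_sd=0.0,
            smoothing=0.0,
        )
        rec = simulate_recording(s, duration_s=2.0, seed=3)
        ph = instantaneous_phase(rec.data)
        # all channels share frequency; PLV of every pair is 1 up to edge effects
        core = ph[:, 40:-40]
        for i in range(1, 4):
            assert plv_pair(core[0], core[i]) > 0.999

    def test_uncoupled_channels_near_null_plv(self):
        s = SubjectModel(coupling=np.zeros((8, 8)), smoothing=0.0, subject_id="x")
        rec = simulate_recording(s, duration_s=40.0, seed=4)
        P = mean_windowed_plv(rec)
        off = P[~np.eye(8, dtype=bool)]
        # windowed null floor for T=160 samples of drifting phases
        assert off.mean() < 0.45

    def test_coupled_pair_beats_uncoupled_pair(self):
        """Directional check over seeded replicates."""
        K = np.zeros((4, 4))
        K[0, 1] = K[1, 0] = 1.0
        s = SubjectModel(coupling=K, smoothing=0.0)
        wins = 0
        reps = 20
        for seed in range(reps):
            rec = simulate_recording(s, duration_s=10.0, seed=seed)
            P = mean_windowed_plv(rec)
            wins += P[0, 1] > P[2, 3]
        assert wins >= 0.95 * reps

    def test_plv_monotone_in_coupling_strength(self):
        levels = [0.0, 0.3, 0.6, 1.0]
        means = []
        for strength in levels:
            K = np.zeros((2, 2))
            K[0, 1] = K[1, 0] = strength
            vals = []
            for seed in range(8):
                s = SubjectModel(coupling=K if strength else np.zeros((2, 2)), smoothing=0.0)
                rec = simulate_recording(s, duration_s=10.0, seed=seed)
                P = mean_windowed_plv(rec)
                vals.append(P[0, 1])
            means.append(np.mean(vals))
        assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))

    def test_invalid_durations(self):
        s = sample_subject(4, seed=0)
        with pytest.raises(ValueError):
            simulate_recording(s, duration_s=0.5)
        with pytest.raises(ValueError):
            simulate_recording(s, duration_s=2.0, fs=16.0)


class TestCohort:
    def test_shapes_and_labels(self, tiny_cohort):
        assert tiny_cohort.n_subjects == 4
        assert len(tiny_cohort.recordings) == 8
        ids = {r.subject_id for r in tiny_cohort.recordings}
        assert ids == set(tiny_cohort.subject_ids())

    def test_reproducible_from_seed(self):
        a = simulate_cohort(n_subjects=2, runs_per_subject=1, duration_s=2.0, seed=3)
        b = simulate_cohort(n_subjects=2, runs_per_subject=1, duration_s=2.0, seed=3)
        np.testing.assert_array_equal(a.recordings[0].data, b.recordings[0].data)
        np.testing.assert_array_equal(a.subjects[1].coupling, b.subjects[1].coupling)

    def test_max_separation_bounds_pattern_overlap(self):
        cohort = simulate_cohort(
            n_subjects=6, runs_per_subject=1, duration_s=1.0, separation=1.0, seed=9
        )
        iu = np.triu_indices(64, 1)
        for a in range(6):
            for b in range(a + 1, 6):
                ka = cohort.subjects[a].coupling[iu]
                kb = cohort.subjects[b].coupling[iu]
                r = np.corrcoef(ka, kb)[0, 1]
                assert r < 0.3  # only chance-level overlap at full separation

    def test_zero_separation_shares_backbone(self):
        cohort = simulate_cohort(
            n_subjects=3, runs_per_subject=1, duration_s=1.0, separation=0.0, seed=9
        )
        np.testing.assert_array_equal(
            cohort.subjects[0].coupling, cohort.subjects[1].coupling
        )

    def test_ground_truth_recovery_from_plv(self):
        """Estimated PLV correlates with the generating coupling matrix."""
        cohort = simulate_cohort(n_subjects=2, runs_per_subject=1, duration_s=60.0, seed=7)
        iu = np.triu_indices(64, 1)
        for subj, rec in zip(cohort.subjects, cohort.recordings[::1][:2]):
            P = mean_windowed_plv(rec)
            r = np.corrcoef(P[iu], subj.coupling[iu])[0, 1]
            assert r > 0.5

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            simulate_cohort(n_subjects=1)

    def test_hdf5_roundtrip(self, tmp_path, tiny_cohort):
        p = tmp_path / "cohort.h5"
        save_cohort(p, tiny_cohort)
        back = load_cohort(p)
        assert back.n_subjects == tiny_cohort.n_subjects
        np.testing.assert_array_equal(
            back.subjects[0].coupling, tiny_cohort.subjects[0].coupling
        )
        np.testing.assert_allclose(back.recordings[0].data, tiny_cohort.recordings[0].data)
        assert back.params == tiny_cohort.params


class TestPlantedCohort:
    def test_pure_region_channels_disjoint_from_other_regions(self, montage64):
        from vnfc.montage import REGION_NAMES, region_mask

        pool = set(pure_region_channels(montage64, "frontal").tolist())
        assert pool  # non-empty
        for other in REGION_NAMES:
            if other != "frontal":
                assert pool.isdisjoint(region_mask(montage64, other).channels)

    def test_coupling_confined_to_region(self, montage64):
        cohort = simulate_planted_cohort(region="frontal", duration_s=1.0, seed=2)
        pool = set(pure_region_channels(montage64, "frontal").tolist())
        for subj in cohort.subjects:
            rows, cols = np.nonzero(subj.coupling)
            assert set(rows.tolist()) <= pool and set(cols.tolist()) <= pool
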