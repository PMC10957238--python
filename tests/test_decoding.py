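"""Time-resolved group decoding, cross-decoding, searchlight and ability
decoding."""

import numpy as np
import pytest

import eegability as ea
from conftest import make_epochs, make_two_group_cohort
from eegability.decoding import permutation_pvalues


def _noise_cohort(rng, n_per_group=4, n_trials=80, n_ch=6, n_t=10, signal=None):
    """Hand-built cohort of pure-noise epochs, optionally with a per-group
    signal added (signal: callable(group01) -> (n_ch, n_t) pattern)."""
    epochs, groups = {}, {}
    for g, prefix in ((1, "sub-SR"), (0, "sub-TR")):
        for k in range(n_per_group):
            pid = f"{prefix}{k + 1:02d}"
            data = rng.normal(size=(n_trials, n_ch, n_t))
            if signal is not None:
                data = data + signal(g)
            stim = rng.integers(0, 4, size=n_trials)
            epochs[pid] = make_epochs(data, stimulus_id=stim)
            groups[pid] = "super" if g else "typical"
    return make_two_group_cohort(epochs, groups)


class TestGroupDecoding:
    def test_identical_epochs_in_both_groups_are_chance(self):
        """Duplicating the same trials into both groups leaves nothing to
        decode."""
        rng = np.random.default_rng(0)
        shared = rng.normal(size=(400, 6, 8))
        epochs, groups = {}, {}
        for pid, g in [("sub-SR01", "super"), ("sub-SR02", "super"),
                       ("sub-TR01", "typical"), ("sub-TR02", "typical")]:
            epochs[pid] = make_epochs(shared.copy())
            groups[pid] = g
        co = make_two_group_cohort(epochs, groups)
        tc = ea.timecourse_group_decoding(co, n_folds=5, n_repetitions=2, seed=1)
        assert np.abs(tc.values - 0.5).max() < 0.1

    def test_planted_effect_peaks_in_planted_window(self, coupled_cohort):
        tc = ea.timecourse_group_decoding(
            coupled_cohort, n_folds=5, n_repetitions=1, seed=3
        )
        t = tc.times_ms
        peak_early = t[(t > 50) & (t < 400)][
            np.argmax(tc.values[(t > 50) & (t < 400)])
        ]
        assert 120 <= peak_early <= 180
        baseline = tc.values[t < 0]
        assert np.abs(baseline - 0.5).mean() < 0.05

    def test_single_group_rejected(self, typical_cohort):
        with pytest.raises(ValueError, match="both groups"):
            ea.timecourse_group_decoding(typical_cohort, seed=0)

    def test_grouped_cv_leaves_test_participants_unseen(self, coupled_cohort):
        tc = ea.timecourse_group_decoding(
            coupled_cohort, n_folds=4, n_repetitions=1, grouped_cv=True, seed=5
        )
        t = tc.times_ms
        window = (t >= 130) & (t <= 170)
        assert tc.values[window].mean() > 0.55


class TestCrossDecoding:
    def test_same_condition_reduces_to_group_decoding(self, coupled_cohort):
        a = ea.cross_decode(coupled_cohort, "face", "face", n_folds=3,
                            n_repetitions=1, seed=7)
        b = ea.timecourse_group_decoding(coupled_cohort, "face", n_folds=3,
                                         n_repetitions=1, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_shared_effect_transfers_across_conditions(self, coupled_cohort):
        tc = ea.cross_decode(coupled_cohort, "face", "nonface", n_folds=3,
                             n_repetitions=1, seed=8)
        t = tc.times_ms
        assert tc.values[(t >= 130) & (t <= 170)].mean() > 0.55

    def test_face_only_effect_does_not_transfer(self, stim20):
        geoms = ea.make_latent_geometries(
            stim20,
            [ea.GeometrySpec(name="faces", kind="block", center_ms=150.0,
                             width_ms=20.0, ability_coupling=0.8,
                             categories=("face",))],
            seed=4,
        )
        co = ea.simulate_cohort(
            stim20, geoms, n_super=4, n_typical=4, n_trials_per_participant=200,
            n_channels=8, sampling_rate=64.0, n_sessions=1,
            epoch_window_ms=(0.0, 400.0), noise_sd=2.0, seed=12,
        )
        face = ea.cross_decode(co, "face", "face", n_folds=3, n_repetitions=1, seed=9)
        cross = ea.cross_decode(co, "face", "nonface", n_folds=3, n_repetitions=1, seed=9)
        t = face.times_ms
        window = (t >= 130) & (t <= 170)
        assert face.values[window].mean() > 0.6
        assert abs(cross.values[window].mean() - 0.5) < 0.06


class TestExcludeResponseTrials:
    def test_counts_and_noop(self, coupled_cohort):
        out = ea.exclude_response_trials(coupled_cohort)
        for pid, es in out.epochs.items():
            orig = coupled_cohort.epochs[pid]
            expect = int((~orig.trials["response_made"]).sum())
            assert es.n_trials == expect
            assert not es.trials["response_made"].any()
        # roughly 10% repeats at default hit rate -> most trials survive
        total = sum(es.n_trials for es in out.epochs.values())
        orig_total = sum(es.n_trials for es in coupled_cohort.epochs.values())
        assert 0.85 < total / orig_total < 0.95

    def test_all_response_trials_rejected(self):
        rng = np.random.default_rng(0)
        es = make_epochs(
            rng.normal(size=(10, 3, 4)), response_made=np.ones(10, bool)
        )
        co = make_two_group_cohort({"sub-SR01": es}, {"sub-SR01": "super"})
        with pytest.raises(ValueError, match="no trials"):
            ea.exclude_response_trials(co)


class TestSearchlight:
    def test_recovers_channel_carrying_the_effect(self):
        """Group difference planted on channel 0 only: the searchlight map
        peaks at channel 0 or a neighbour containing it."""
        rng = np.random.default_rng(1)

        def signal(g):
            pat = np.zeros((6, 10))
            pat[0, :] = 1.5 * g
            return pat

        co = _noise_cohort(rng, n_per_group=4, n_trials=60, signal=signal)
        maps = ea.searchlight_group_decoding(
            co, windows=[None], searchlight_size=2, n_folds=3, n_repetitions=1, seed=2
        )
        m = maps[0]
        pos = co.epochs["sub-SR01"].channel_positions
        d = np.linalg.norm(pos - pos[0], axis=1)
        neighbours_of_0 = set(np.argsort(d)[:2]) | {0}
        assert int(np.argmax(m.auc)) in neighbours_of_0
        assert m.auc.shape == (6,)
        assert m.searchlight_size == 2

    def test_null_cohort_map_near_chance(self):
        rng = np.random.default_rng(2)
        co = _noise_cohort(rng, n_per_group=3, n_trials=60)
        maps = ea.searchlight_group_decoding(
            co, windows=[(30.0, 90.0)], searchlight_size=3, n_folds=3,
            n_repetitions=1, seed=3,
        )
        assert np.abs(maps[0].auc - 0.5).max() < 0.12

    def test_full_searchlight_equals_whole_scalp(self):
        rng = np.random.default_rng(3)
        co = _noise_cohort(rng, n_per_group=2, n_trials=40, n_ch=4)
        maps = ea.searchlight_group_decoding(
            co, windows=[(0.0, 100.0)], searchlight_size=4, n_folds=2,
            n_repetitions=1, seed=4,
        )
        np.testing.assert_allclose(maps[0].auc, maps[0].auc[0])

    def test_oversized_searchlight_rejected(self):
        rng = np.random.default_rng(4)
        co = _noise_cohort(rng, n_per_group=2, n_trials=20, n_ch=4)
        with pytest.raises(ValueError, match="searchlight_size"):
            ea.searchlight_group_decoding(co, searchlight_size=5, seed=0)


class TestAbilityDecoding:
    def test_deterministic_given_seed(self, typical_cohort):
        a = ea.ability_decoding_timecourse(typical_cohort, n_repetitions=2, seed=6)
        b = ea.ability_decoding_timecourse(typical_cohort, n_repetitions=2, seed=6)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.metric == "spearman_rho"

    def test_scores_independent_of_eeg_give_null_rho(self, stim20):
        geoms = ea.make_latent_geometries(
            stim20,
            [ea.GeometrySpec(name="g", kind="block", center_ms=150.0,
                             width_ms=20.0, ability_coupling=0.0)],
            seed=5,
        )
        co = ea.simulate_cohort(
            stim20, geoms, n_super=0, n_typical=8, n_trials_per_participant=80,
            n_channels=8, sampling_rate=64.0, n_sessions=1,
            epoch_window_ms=(0.0, 400.0), noise_sd=2.0, seed=14,
        )
        tc = ea.ability_decoding_timecourse(co, n_repetitions=4, seed=15)
        assert abs(tc.values.mean()) < 0.15

    def test_constant_scores_rejected(self, stim20, planted_geometries):
        co = ea.simulate_cohort(
            stim20, planted_geometries, n_super=0, n_typical=4,
            n_trials_per_participant=40, n_channels=4, sampling_rate=64.0,
            n_sessions=1, typical_range=(70, 70), seed=16,
        )
        with pytest.raises(ValueError, match="non-constant"):
            ea.ability_decoding_timecourse(co, seed=0)

    def test_trial_level_option_runs(self, typical_cohort):
        tc = ea.ability_decoding_timecourse(
            typical_cohort, n_repetitions=1, trial_level=True, seed=17
        )
        assert np.all(np.abs(tc.values) <= 1.0)


class TestPermutationMachinery:
    def test_p_value_conventions(self):
        null = np.array([[0.1], [0.2], [0.3]])
        assert permutation_pvalues(np.array([0.4]), null)[0] == pytest.approx(1 / 4)
        assert permutation_pvalues(np.array([0.05]), null)[0] == pytest.approx(1.0)

    def test_permutation_null_wrapper(self, coupled_cohort):
        tc = ea.permutation_null(
            "group", coupled_cohort, n_permutations=9, n_folds=3,
            n_repetitions=1, seed=18,
        )
        assert tc.null_distribution.shape == (9, len(tc.times_ms))
        assert np.all(tc.p_values > 0) and np.all(tc.p_values <= 1)
        with pytest.raises(ValueError, match="kind"):
            ea.permutation_null("nope", coupled_cohort)
        with pytest.raises(ValueError, match="n_permutations"):
            ea.permutation_null("group", coupled_cohort, n_permutations=0)
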