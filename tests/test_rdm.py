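"""RDM construction, vectorization, subsetting and aggregation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

import eegability as ea
from conftest import make_epochs
from eegability.rdm import RDM


def _corr_distance_bruteforce(a):
    n = a.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = 1 - np.corrcoef(a[:, i], a[:, j])[0, 1]
    return out


class TestVectorize:
    @pytest.mark.parametrize("n,expected", [(2, 1), (3, 3), (10, 45)])
    def test_upper_triangle_length(self, n, expected):
        m = np.zeros((n, n))
        assert len(ea.vectorize_rdm(m)) == expected

    def test_row_major_order(self):
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        np.testing.assert_array_equal(ea.vectorize_rdm(m), [1, 2, 3])

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ea.vectorize_rdm(np.array([[0, 1.0], [2.0, 0]]))

    @given(st.integers(2, 12), st.integers(0, 1000))
    def test_devectorize_roundtrip(self, n, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        v = ea.vectorize_rdm(m)
        np.testing.assert_array_equal(ea.devectorize_rdm(v), m)

    def test_bad_vector_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ea.devectorize_rdm(np.arange(4.0))


class TestActivationRdm:
    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 4))
        rdm = ea.activation_rdm(a)
        np.testing.assert_allclose(rdm.matrix, _corr_distance_bruteforce(a), atol=1e-12)

    def test_extreme_cells(self):
        base = np.random.default_rng(1).normal(size=(6, 1))
        a = np.hstack([base, base, -base])
        rdm = ea.activation_rdm(a)
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert rdm.matrix[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_zero_variance_column_reported(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(6, 3))
        a[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            rdm = ea.activation_rdm(a)
        assert np.isnan(rdm.matrix[0, 1])
        assert np.isfinite(rdm.matrix[0, 2])

    def test_invariant_to_positive_scaling(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 5))
        scaled = a * rng.uniform(0.5, 3.0, size=5)
        np.testing.assert_allclose(
            ea.activation_rdm(a).matrix, ea.activation_rdm(scaled).matrix, atol=1e-12
        )


class TestEmbeddingRdm:
    def test_hand_computed_angles(self):
        # vectors at 0, 90 and 180 degrees in the plane
        e = np.array([[1.0, 0.0, -1.0], [0.0, 1.0, 0.0]])
        rdm = ea.embedding_rdm(e)
        assert rdm.matrix[0, 1] == pytest.approx(1.0)
        assert rdm.matrix[0, 2] == pytest.approx(2.0)
        assert rdm.matrix[1, 2] == pytest.approx(1.0)

    def test_scale_invariance_exact(self):
        rng = np.random.default_rng(4)
        e = rng.normal(size=(6, 4))
        scaled = e * rng.uniform(0.1, 5.0, size=4)
        np.testing.assert_allclose(
            ea.embedding_rdm(e).matrix, ea.embedding_rdm(scaled).matrix, atol=1e-12
        )

    def test_multiple_raters_averaged(self):
        rng = np.random.default_rng(5)
        e1, e2 = rng.normal(size=(2, 4, 5))
        mean = (ea.embedding_rdm(e1).matrix + ea.embedding_rdm(e2).matrix) / 2
        np.testing.assert_allclose(ea.embedding_rdm([e1, e2]).matrix, mean, atol=1e-12)

    def test_zero_vector_rejected(self):
        e = np.zeros((3, 2))
        e[:, 0] = 1.0
        with pytest.raises(ValueError, match="zero"):
            ea.embedding_rdm(e)


class TestAggregateLayers:
    def _rdms(self, k=3, n=4, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(k):
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            out.append(RDM(m, "pearson_distance", np.arange(n)))
        return out

    def test_singleton_blocks_are_identity(self):
        rdms = self._rdms()
        out = ea.aggregate_layer_rdms(rdms, [[0], [1], [2]])
        for a, b in zip(out, rdms):
            np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_block_means_verified_cellwise(self):
        rdms = self._rdms()
        out = ea.aggregate_layer_rdms(rdms, [[0, 1], [2]])
        np.testing.assert_allclose(
            out[0].matrix, (rdms[0].matrix + rdms[1].matrix) / 2
        )
        np.testing.assert_array_equal(out[1].matrix, rdms[2].matrix)

    def test_partition_violations_rejected(self):
        rdms = self._rdms()
        with pytest.raises(ValueError, match="partition"):
            ea.aggregate_layer_rdms(rdms, [[0, 1]])
        with pytest.raises(ValueError, match="partition"):
            ea.aggregate_layer_rdms(rdms, [[0, 1], [1, 2]])

    def test_mismatched_stimuli_rejected(self):
        a = self._rdms(k=1)[0]
        b = RDM(np.zeros((5, 5)), "pearson_distance", np.arange(5))
        with pytest.raises(ValueError, match="stimulus"):
            ea.aggregate_layer_rdms([a, b], [[0, 1]])


class TestBehavioralAveraging:
    def test_identical_raters_kept(self):
        m = ea.devectorize_rdm(np.arange(1.0, 7.0))
        avg, excluded = ea.average_behavioral_rdms([m, m, m, m])
        assert excluded == []
        np.testing.assert_array_equal(avg.matrix, m)

    def test_infinite_sd_is_plain_mean(self):
        rng = np.random.default_rng(6)
        mats = []
        for _ in range(4):
            m = rng.random((5, 5))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            mats.append(m)
        avg, excluded = ea.average_behavioral_rdms(mats, exclusion_sd=np.inf)
        assert excluded == []
        np.testing.assert_allclose(avg.matrix, np.mean(mats, axis=0))

    def test_planted_outliers_excluded(self):
        rng = np.random.default_rng(7)
        target = ea.devectorize_rdm(rng.uniform(1, 2, size=45))
        rdms = ea.simulate_behavioral_rdms(
            target, n_raters=12, noise_sd=0.05, n_outliers=2, seed=3
        )
        _, excluded = ea.average_behavioral_rdms(rdms, exclusion_sd=2.0)
        assert excluded == [10, 11]

    def test_too_few_raters_rejected(self):
        m = np.zeros((3, 3))
        with pytest.raises(ValueError, match="3 raters"):
            ea.average_behavioral_rdms([m, m])


class TestPairSubsets:
    def test_class_sizes_and_partition(self, stim49):
        ff = ea.pair_class_mask(stim49, "face-face")
        fn = ea.pair_class_mask(stim49, "face-nonface")
        nn = ea.pair_class_mask(stim49, "nonface-nonface")
        assert ff.sum() == 24 * 23 // 2 == 276
        assert fn.sum() == 24 * 25 == 600
        assert nn.sum() == 25 * 24 // 2 == 300
        assert not (ff & fn).any() and not (ff & nn).any() and not (fn & nn).any()
        assert (ff | fn | nn).all()

    def test_subset_values_roundtrip(self, stim49):
        rng = np.random.default_rng(8)
        m = rng.random((49, 49))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        rdm = RDM(m, "behavioral", stim49.ids)
        parts = [
            ea.subset_rdm_pairs(rdm, stim49, c)
            for c in ("face-face", "face-nonface", "nonface-nonface")
        ]
        assert sum(len(p) for p in parts) == len(ea.vectorize_rdm(rdm))
        assert set(np.concatenate(parts)) == set(ea.vectorize_rdm(rdm))

    def test_unknown_class_rejected(self, stim49):
        with pytest.raises(ValueError, match="pair_class"):
            ea.pair_class_mask(stim49, "face-vs-scene")


class TestBrainRdm:
    def test_identical_stimulus_distributions_give_chance(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(120, 6, 5))
        stim = np.r_[np.zeros(60, int), np.ones(60, int)]
        es = make_epochs(data, stimulus_id=stim)
        tc = ea.brain_rdm_timecourse(es, n_folds=5, n_repetitions=2, seed=10)
        cell = tc.data[:, 0, 1]
        assert abs(cell.mean() - 0.5) < 0.05

    def test_sensor_noiseless_geometry_recovered(self, stim20):
        """With no sensor noise the pairwise AUC RDM at the profile peak
        rank-matches the planted geometry (trial count near the emulated
        design's ~3,200 per participant)."""
        geom = ea.make_latent_geometries(
            stim20,
            [ea.GeometrySpec(name="g", kind="random", n_dims=4,
                             center_ms=150.0, width_ms=20.0)],
            seed=2,
        )[0]
        co = ea.simulate_cohort(
            stim20, [geom], n_super=1, n_typical=0, n_trials_per_participant=2000,
            n_channels=16, sampling_rate=64.0, n_sessions=1,
            epoch_window_ms=(100.0, 200.0), noise_sd=0.0, seed=19,
        )
        es = co.epochs["sub-SR01"]
        tc = ea.brain_rdm_timecourse(es, n_folds=5, n_repetitions=2, seed=20)
        peak = np.argmin(np.abs(tc.times_ms - 150.0))
        rho = spearmanr(
            tc.vectors()[peak], ea.vectorize_rdm(geom.target_rdm),
            nan_policy="omit",
        ).statistic
        assert rho > 0.9

    def test_shuffled_labels_center_on_chance(self, coupled_cohort):
        es = coupled_cohort.epochs["sub-SR01"]
        rng = np.random.default_rng(21)
        shuffled = es.trials.copy()
        shuffled["stimulus_id"] = rng.permutation(shuffled["stimulus_id"].to_numpy())
        es2 = make_epochs(
            es.data, sfreq=es.sfreq, t0_ms=es.times_ms[0],
            stimulus_id=shuffled["stimulus_id"].to_numpy(),
        )
        tc = ea.brain_rdm_timecourse(es2, n_folds=5, n_repetitions=1, seed=22)
        cells = tc.vectors()
        assert abs(np.nanmean(cells) - 0.5) < 0.01

    def test_low_trial_stimulus_reported_as_missing(self):
        rng = np.random.default_rng(10)
        stim = np.r_[np.zeros(30, int), np.ones(30, int), np.full(4, 2)]
        es = make_epochs(rng.normal(size=(64, 4, 3)), stimulus_id=stim)
        with pytest.warns(UserWarning, match="fewer than"):
            tc = ea.brain_rdm_timecourse(es, n_folds=5, n_repetitions=1, seed=23)
        assert np.isnan(tc.data[:, 0, 2]).all()
        assert np.isfinite(tc.data[:, 0, 1]).all()
        v = tc.vectors()[0]
        assert np.isnan(v).sum() == 2  # pairs (0,2) and (1,2)


class TestCrossParticipantSimilarity:
    def _tc(self, vec_rdms, times):
        data = np.stack([ea.devectorize_rdm(v) for v in vec_rdms])
        return ea.RDMTimecourse(data, times, "behavioral", np.arange(data.shape[1]))

    def test_identical_rdms_give_similarity_one(self):
        rng = np.random.default_rng(11)
        times = np.arange(5.0)
        base = rng.random((5, 10))
        tcs = {f"sub-SR{i:02d}": self._tc(base, times) for i in range(1, 4)}
        tcs.update({f"sub-TR{i:02d}": self._tc(base, times) for i in range(1, 4)})
        groups = {p: ("super" if "SR" in p else "typical") for p in tcs}
        out = ea.rdm_cross_participant_similarity(tcs, groups, n_permutations=19, seed=0)
        np.testing.assert_allclose(out.group_means["super"], 1.0, atol=1e-9)
        np.testing.assert_allclose(out.group_means["typical"], 1.0, atol=1e-9)

    def test_independent_rdms_near_zero_and_no_group_difference(self):
        rng = np.random.default_rng(12)
        times = np.arange(12.0)
        tcs, groups = {}, {}
        for i in range(1, 6):
            for prefix, g in (("sub-SR", "super"), ("sub-TR", "typical")):
                pid = f"{prefix}{i:02d}"
                tcs[pid] = self._tc(rng.random((12, 45)), times)
                groups[pid] = g
        out = ea.rdm_cross_participant_similarity(tcs, groups, n_permutations=99, seed=1)
        assert abs(np.mean(out.group_means["super"])) < 0.1
        assert not [c for c in out.cluster_result.clusters if c.p_value < 0.05]

    def test_single_participant_group_rejected(self):
        times = np.arange(3.0)
        rng = np.random.default_rng(13)
        tcs = {
            "sub-SR01": self._tc(rng.random((3, 6)), times),
            "sub-TR01": self._tc(rng.random((3, 6)), times),
            "sub-TR02": self._tc(rng.random((3, 6)), times),
        }
        groups = {p: ("super" if "SR" in p else "typical") for p in tcs}
        with pytest.raises(ValueError, match="fewer than two"):
            ea.rdm_cross_participant_similarity(tcs, groups)


class TestRdmInvariants:
    def test_metric_ranges_enforced(self):
        with pytest.raises(ValueError, match="range"):
            RDM(np.array([[0, 3.0], [3.0, 0]]), "pearson_distance", np.arange(2))
        with pytest.raises(ValueError, match="unknown metric"):
            RDM(np.zeros((2, 2)), "mahalanobis", np.arange(2))

    def test_cv_auc_diagonal_is_undefined(self):
        m = np.full((3, 3), 0.7)
        np.fill_diagonal(m, 0.0)
        rdm = RDM(m, "cv_auc", np.arange(3))
        assert np.isnan(np.diag(rdm.matrix)).all()
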