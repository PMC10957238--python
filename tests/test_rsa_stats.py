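"""Gaussian-copula MI/CMI estimators and cluster permutation inference."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import eegability as ea
from eegability.rdm import RDM, RDMTimecourse, devectorize_rdm
from eegability.rsa_stats import _mi_bias_bits


def _bivariate(r, n, seed):
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n)
    return z[:, 0], z[:, 1]


def discrete_plugin_mi(x, y, bins=4):
    """Independent oracle: plug-in MI of quantile-discretized variables."""
    qx = np.searchsorted(np.quantile(x, [0.25, 0.5, 0.75]), x)
    qy = np.searchsorted(np.quantile(y, [0.25, 0.5, 0.75]), y)
    joint = np.zeros((bins, bins))
    for a, b in zip(qx, qy):
        joint[a, b] += 1
    joint /= joint.sum()
    px, py = joint.sum(1), joint.sum(0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz])))


class TestCopulaMi:
    def test_matches_gaussian_closed_form(self):
        for r in (0.0, 0.5, 0.866):
            x, y = _bivariate(r, 10_000, seed=int(r * 100))
            mi = ea.gaussian_copula_mi(x, y)
            assert abs(mi - (-0.5 * np.log2(1 - r**2))) < 0.02

    def test_independent_inputs_near_zero(self):
        x, y = _bivariate(0.0, 10_000, seed=1)
        assert abs(ea.gaussian_copula_mi(x, y)) < 0.02

    @given(st.integers(0, 500))
    def test_invariant_to_monotone_transforms(self, seed):
        """Rank-based estimation is exactly invariant to strictly monotone
        transforms of either input."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        base = ea.gaussian_copula_mi(x, y)
        assert ea.gaussian_copula_mi(np.exp(2 * x), y) == base
        assert ea.gaussian_copula_mi(x, y**3) == base

    def test_perfect_dependence_capped(self):
        x = np.arange(50.0)
        with pytest.warns(UserWarning, match="perfect dependence"):
            mi = ea.gaussian_copula_mi(x, 2 * x + 1)
        assert np.isfinite(mi) and mi > 5

    def test_bias_correction_centers_null(self):
        rng = np.random.default_rng(2)
        raw, corrected = [], []
        for _ in range(100):
            x, y = rng.normal(size=(2, 100))
            raw.append(ea.gaussian_copula_mi(x, y))
            corrected.append(ea.gaussian_copula_mi(x, y, bias_correction=True))
        assert np.mean(raw) > 0
        assert abs(np.mean(corrected)) < abs(np.mean(raw))
        assert _mi_bias_bits(100) > 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="constant"):
            ea.gaussian_copula_mi(np.ones(20), np.arange(20.0))
        with pytest.raises(ValueError, match="equal length"):
            ea.gaussian_copula_mi(np.arange(20.0), np.arange(21.0))
        with pytest.raises(ValueError, match="10 observations"):
            ea.gaussian_copula_mi(np.arange(5.0), np.arange(5.0))

    def test_tracks_discrete_oracle_over_dependence_strengths(self):
        """Across planted dependence strengths the copula estimate on
        4-level discretized variables orders exactly like the plug-in
        discrete MI."""
        from scipy.stats import spearmanr

        strengths = np.linspace(0.05, 0.9, 10)
        copula, plugin = [], []
        for k, r in enumerate(strengths):
            x, y = _bivariate(r, 50_000, seed=100 + k)
            qx = np.searchsorted(np.quantile(x, [0.25, 0.5, 0.75]), x).astype(float)
            qy = np.searchsorted(np.quantile(y, [0.25, 0.5, 0.75]), y).astype(float)
            copula.append(ea.gaussian_copula_mi(qx, qy))
            plugin.append(discrete_plugin_mi(x, y))
        assert spearmanr(copula, plugin).statistic == pytest.approx(1.0)


class TestCopulaCmi:
    def test_conditioning_on_itself_gives_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        y = 0.8 * x + 0.6 * rng.normal(size=2000)
        with pytest.warns(UserWarning):
            cmi = ea.gaussian_copula_cmi(x, y, y)
        assert cmi == pytest.approx(0.0, abs=1e-9)

    def test_independent_conditioner_recovers_mi(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=10_000)
        y = 0.7 * x + rng.normal(size=10_000)
        z = rng.normal(size=10_000)
        mi = ea.gaussian_copula_mi(x, y)
        cmi = ea.gaussian_copula_cmi(x, y, z)
        assert abs(cmi - mi) < 0.03

    def test_partial_correlation_closed_form(self):
        """For a jointly Gaussian triple, CMI = −½·log2(1 − ρ²_xy·z)."""
        rng = np.random.default_rng(5)
        cov = np.array([[1.0, 0.6, 0.5], [0.6, 1.0, 0.4], [0.5, 0.4, 1.0]])
        s = rng.multivariate_normal(np.zeros(3), cov, size=50_000)
        p = (0.6 - 0.5 * 0.4) / np.sqrt((1 - 0.25) * (1 - 0.16))
        expected = -0.5 * np.log2(1 - p**2)
        cmi = ea.gaussian_copula_cmi(s[:, 0], s[:, 1], s[:, 2])
        assert abs(cmi - expected) < 0.03

    def test_cmi_never_exceeds_joint_mi(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            x = rng.normal(size=1176)
            y = 0.5 * x + rng.normal(size=1176)
            z = 0.3 * x + rng.normal(size=1176)
            cmi = ea.gaussian_copula_cmi(x, y, z)
            assert cmi >= -0.01  # non-negative up to estimator tolerance


class TestRsaTimecourse:
    def _brain(self, seed=0, T=8, n=12):
        rng = np.random.default_rng(seed)
        data = np.stack(
            [devectorize_rdm(rng.random(n * (n - 1) // 2)) for _ in range(T)]
        )
        return RDMTimecourse(data, np.arange(T, dtype=float), "behavioral", np.arange(n))

    def test_self_model_is_maximal_at_its_sample(self):
        brain = self._brain(seed=7)
        model = RDM(brain.data[3], "behavioral", brain.stimulus_ids)
        with pytest.warns(UserWarning, match="perfect dependence"):
            tc = ea.rsa_timecourse(brain, model)
        assert np.argmax(tc.values) == 3

    def test_conditioning_on_the_model_kills_the_timecourse(self):
        brain = self._brain(seed=8)
        model = RDM(brain.data[2] + 0.01, "behavioral", brain.stimulus_ids)
        with pytest.warns(UserWarning):
            tc = ea.rsa_timecourse(brain, model, conditioning=model)
        assert np.all(np.abs(tc.values) < 1e-9)

    def test_pair_class_restriction(self, stim20):
        rng = np.random.default_rng(9)
        T, n = 4, stim20.n_stimuli
        data = np.stack(
            [devectorize_rdm(rng.random(n * (n - 1) // 2)) for _ in range(T)]
        )
        brain = RDMTimecourse(data, np.arange(T, dtype=float), "behavioral", stim20.ids)
        model = RDM(devectorize_rdm(rng.random(n * (n - 1) // 2)), "behavioral", stim20.ids)
        tc = ea.rsa_timecourse(brain, model, pair_class="face-face", stimuli=stim20)
        assert len(tc.values) == T

    def test_too_few_surviving_pairs_rejected(self):
        brain = self._brain(seed=10, n=5)  # 10 pairs
        data = brain.data.copy()
        data[:, 0, 1] = data[:, 1, 0] = np.nan
        brain = RDMTimecourse(data, brain.times_ms, "behavioral", brain.stimulus_ids)
        model = RDM(devectorize_rdm(np.arange(1.0, 11.0)), "behavioral", brain.stimulus_ids)
        with pytest.raises(ValueError, match="10 usable pairs"):
            ea.rsa_timecourse(brain, model)

    def test_mismatched_stimuli_rejected(self):
        brain = self._brain(seed=11)
        model = RDM(np.zeros((5, 5)), "behavioral", np.arange(5))
        with pytest.raises(ValueError, match="stimulus set"):
            ea.rsa_timecourse(brain, model)


class TestClusterPermutation:
    def test_identical_groups_produce_no_significant_cluster(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(6, 40))
        res = ea.cluster_permutation_test(a, a.copy(), n_permutations=99, seed=0)
        assert res.significant() == []
        np.testing.assert_allclose(res.t_values, 0.0, atol=1e-9)

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(13)
        T = 80
        a = rng.normal(size=(8, T))
        b = rng.normal(size=(8, T))
        window = slice(30, 60)  # 30 contiguous samples
        a[:, window] += 2.0
        res = ea.cluster_permutation_test(a, b, n_permutations=199, seed=1)
        sig = res.significant()
        assert len(sig) >= 1
        covered = np.zeros(T, dtype=bool)
        for c in sig:
            covered[int(c.start_ms) : int(c.end_ms) + 1] = True
        assert covered[window].mean() >= 0.8
        assert all(c.sign == 1 for c in sig)

    def test_swapping_groups_flips_signs_only(self):
        rng = np.random.default_rng(14)
        a = rng.normal(size=(6, 30))
        b = rng.normal(size=(6, 30))
        a[:, 10:20] += 1.5
        r1 = ea.cluster_permutation_test(a, b, n_permutations=99, seed=2)
        r2 = ea.cluster_permutation_test(b, a, n_permutations=99, seed=2)
        assert [c.size for c in r1.clusters] == [c.size for c in r2.clusters]
        assert [c.sign for c in r1.clusters] == [-c.sign for c in r2.clusters]
        # the permutation null is re-drawn, so p agrees to Monte Carlo error
        for c1, c2 in zip(r1.clusters, r2.clusters):
            assert abs(c1.p_value - c2.p_value) <= 0.03

    def test_invariant_to_monotone_time_relabeling(self):
        rng = np.random.default_rng(15)
        a = rng.normal(size=(5, 25))
        b = rng.normal(size=(5, 25)) + 0.8
        t1 = np.arange(25.0)
        t2 = np.exp(t1 / 10.0)  # strictly increasing relabeling
        r1 = ea.cluster_permutation_test(a, b, times_ms=t1, n_permutations=99, seed=3)
        r2 = ea.cluster_permutation_test(a, b, times_ms=t2, n_permutations=99, seed=3)
        assert [(c.size, c.sign, c.p_value) for c in r1.clusters] == [
            (c.size, c.sign, c.p_value) for c in r2.clusters
        ]

    def test_invalid_inputs(self):
        a = np.zeros((3, 10))
        with pytest.raises(ValueError, match="time axis"):
            ea.cluster_permutation_test(a, np.zeros((3, 12)))
        with pytest.raises(ValueError, match="2 participants"):
            ea.cluster_permutation_test(a[:1], a)
        with pytest.raises(ValueError, match="n_permutations"):
            ea.cluster_permutation_test(a, a, n_permutations=0)
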