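"""Scatter matrices, validity indices, k vote and the permutation null."""

import numpy as np
import pytest
from sklearn.metrics import calinski_harabasz_score

import mddsubtypes as m


@pytest.fixture()
def toy_1d():
    """The hand-checked 1-D dataset: T = 82, W = 1, B = 81 at the 2+2 split."""
    data = np.array([[0.0], [1.0], [9.0], [10.0]])
    labels = np.array([0, 0, 1, 1])
    return data, labels


class TestScatterMatrices:
    def test_hand_computed_1d(self, toy_1d):
        data, labels = toy_1d
        t, w, b = m.scatter_matrices(data, labels)
        assert t[0, 0] == pytest.approx(82.0)
        assert w[0, 0] == pytest.approx(1.0)
        assert b[0, 0] == pytest.approx(81.0)

    def test_identity_t_equals_w_plus_b(self, rng):
        for _ in range(20):
            data = rng.normal(size=(rng.integers(10, 40), rng.integers(2, 6)))
            labels = rng.integers(0, 3, size=len(data))
            if len(np.unique(labels)) < 2:
                continue
            t, w, b = m.scatter_matrices(data, labels)
            assert np.allclose(t, w + b, atol=1e-8)

    def test_singletons_give_w_zero(self, rng):
        data = rng.normal(size=(5, 3))
        t, w, b = m.scatter_matrices(data, np.arange(5))
        assert np.allclose(w, 0.0, atol=1e-12)
        assert np.allclose(b, t, atol=1e-8)

    def test_empty_cluster_rejected(self, rng):
        data = rng.normal(size=(4, 2))
        with pytest.raises(ValueError):
            m.scatter_matrices(data, np.array([0, 0, 2, 2]))


class TestValidityIndices:
    def test_calinski_harabasz_hand_value(self, toy_1d):
        data, labels = toy_1d
        (iv,) = m.validity_index(data, {2: labels}, "calinski_harabasz")
        assert iv.value == pytest.approx(162.0)

    def test_calinski_harabasz_matches_sklearn(self, rng):
        data = rng.normal(size=(60, 5))
        labels = m.ward_tree(data).cut(3)
        (iv,) = m.validity_index(data, {3: labels}, "calinski_harabasz")
        assert iv.value == pytest.approx(
            calinski_harabasz_score(data, labels), rel=1e-9)

    def test_friedman_zero_when_one_cluster(self, rng):
        data = rng.normal(size=(30, 3))
        (iv,) = m.validity_index(data, {1: np.zeros(30, dtype=int)},
                                 "friedman")
        assert iv.value == pytest.approx(0.0, abs=1e-10)

    def test_silhouette_approaches_one_with_separation(self):
        base = np.random.default_rng(0).normal(size=(30, 2))
        labels = np.repeat([0, 1, 2], 10)
        vals = []
        for sep in (5.0, 50.0):
            data = base + sep * np.array([[0, 0], [1, 0], [0, 1]])[labels]
            (iv,) = m.validity_index(data, {3: labels}, "silhouette")
            vals.append(iv.value)
        assert vals[0] < vals[1] < 1.0
        assert vals[1] > 0.95

    def test_scott_friedman_invariant_to_relabeling_and_order(self, rng):
        data = rng.normal(size=(40, 4))
        labels = m.ward_tree(data).cut(3)
        perm = rng.permutation(40)
        relabel = np.array([2, 0, 1])[labels]
        for name in ("scott", "friedman"):
            (a,) = m.validity_index(data, {3: labels}, name)
            (b,) = m.validity_index(data[perm], {3: labels[perm]}, name)
            (c,) = m.validity_index(data, {3: relabel}, name)
            assert a.value == pytest.approx(b.value, rel=1e-9)
            assert a.value == pytest.approx(c.value, rel=1e-9)

    def test_scott_definition(self, rng):
        data = rng.normal(size=(50, 3))
        labels = m.ward_tree(data).cut(2)
        t, w, _ = m.scatter_matrices(data, labels)
        (iv,) = m.validity_index(data, {2: labels}, "scott")
        expected = 50 * np.log(np.linalg.det(t) / np.linalg.det(w))
        assert iv.value == pytest.approx(expected, rel=1e-9)

    def test_friedman_definition(self, rng):
        data = rng.normal(size=(50, 3))
        labels = m.ward_tree(data).cut(3)
        t, w, b = m.scatter_matrices(data, labels)
        (iv,) = m.validity_index(data, {3: labels}, "friedman")
        assert iv.value == pytest.approx(np.trace(np.linalg.inv(w) @ b),
                                         rel=1e-9)


class TestSelectK:
    def test_recovers_planted_k_noiseless(self, noiseless_cohort):
        matrix, _ = noiseless_cohort
        model = m.SymptomSubtypeModel(matrix)
        report = model.select_k((2, 5))
        assert report.chosen_k == 3
        assert report.strict_majority

    def test_recovers_planted_k_with_noise(self, noisy_cohort):
        matrix, _ = noisy_cohort
        report = m.SymptomSubtypeModel(matrix).select_k((2, 5))
        assert report.chosen_k == 3

    def test_trivial_range(self, rng):
        data = rng.normal(size=(30, 4))
        report = m.select_k(data, (2, 2))
        assert report.chosen_k == 2

    def test_votes_accounted_for(self, noisy_cohort):
        matrix, _ = noisy_cohort
        report = m.SymptomSubtypeModel(matrix).select_k((2, 5))
        assert sum(report.vote_counts.values()) == len(report.votes)
        assert len(report.votes) + len(report.degenerate_indices) == len(
            m.DEFAULT_BATTERY)
        assert report.k_range[0] <= report.chosen_k <= report.k_range[1]

    def test_recovery_rate_across_100_simulations(self):
        # planted separation above the documented threshold (latent noise
        # 0.5, study-like profiles): the vote recovers k=3 in >=95% of runs
        hits = 0
        for seed in range(100):
            spec = m.CohortSpec(120, m.study_profiles(), noise_sd=0.5,
                                seed=seed)
            matrix, _ = m.generate_symptom_cohort(spec)
            hits += m.SymptomSubtypeModel(matrix).select_k((2, 5)).chosen_k == 3
        assert hits >= 95

    def test_null_data_votes_scatter_away_from_planted_k(self):
        # structure-free data: the vote never concentrates on k=3 (the
        # planted truth elsewhere) and spreads over several candidate k
        for seed in range(4):
            matrix = m.generate_null_cohort(120, seed=seed)
            scaled = m.scale_items(matrix)
            report = m.select_k(scaled.values, (2, 5))
            total = sum(report.vote_counts.values())
            assert report.vote_counts.get(3, 0) <= total / 2
            assert len(report.vote_counts) >= 2

    def test_bad_range_rejected(self, rng):
        data = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            m.select_k(data, (1, 3))


class TestPermutationTest:
    def test_planted_structure_is_significant(self, noisy_cohort):
        matrix, _ = noisy_cohort
        scaled = m.scale_items(matrix)
        report = m.permutation_test_index(scaled.values, 3, "scott",
                                          n_perm=199, seed=0)
        assert report.p_value <= 0.01

    def test_p_value_formula_and_bounds(self):
        matrix = m.generate_null_cohort(60, seed=3)
        scaled = m.scale_items(matrix)
        report = m.permutation_test_index(scaled.values, 3, "scott",
                                          n_perm=99, seed=1)
        finite = report.null_values[np.isfinite(report.null_values)]
        expected = (1 + (finite >= report.observed).sum()
                    + report.n_degenerate) / (99 + 1)
        assert report.p_value == pytest.approx(expected)
        assert 0.0 < report.p_value <= 1.0

    def test_reproducible_given_seed(self):
        matrix = m.generate_null_cohort(50, seed=2)
        scaled = m.scale_items(matrix)
        a = m.permutation_test_index(scaled.values, 2, "friedman",
                                     n_perm=99, seed=7)
        b = m.permutation_test_index(scaled.values, 2, "friedman",
                                     n_perm=99, seed=7)
        assert np.array_equal(a.null_values, b.null_values)
        assert a.p_value == b.p_value

    def test_small_n_perm_rejected(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            m.permutation_test_index(rng.normal(size=(30, 3)), 2,
                                     n_perm=10, seed=0)
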