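"""BUILD initialisation, the FASTPAM1 swap phase and its bookkeeping oracle."""

import itertools

import numpy as np
import pytest

from cellpam import (
    DissimilarityMatrix,
    adjusted_rand_index,
    assign_labels,
    compute_dissimilarity,
    pam,
    pam_build,
    pam_fastpam1,
    pam_lab,
)
from cellpam.pam import PAM, swap_delta_td

from conftest import naive_td


def naive_greedy_build(square, k):
    """Independent O(n²k) greedy: same contract as BUILD, written naively."""
    n = square.shape[0]
    medoids = [int(np.argmin(square.sum(axis=1)))]
    while len(medoids) < k:
        best, best_gain = None, np.inf
        dn = square[medoids].min(axis=0)
        for x in range(n):
            if x in medoids:
                continue
            gain = np.minimum(square[x] - dn, 0.0).sum()
            if gain < best_gain:
                best, best_gain = x, gain
        medoids.append(best)
    return medoids


def random_dissim(rng, n):
    X = rng.random((n, 4)) * 10
    return compute_dissimilarity(X, "L2")


class TestBuild:
    def test_line_fixture_k1(self):
        # points at {0,1,5}: total L1 distances are 6, 5, 9 -> medoid is 1
        D = compute_dissimilarity(np.array([[0.0], [1.0], [5.0]]), "L1")
        medoids, _, td = pam_build(D, 1)
        assert list(medoids) == [1]
        assert td == 5.0

    def test_k_equals_n_gives_zero_td(self, rng):
        D = random_dissim(rng, 7)
        medoids, _, td = pam_build(D, 7)
        assert sorted(medoids) == list(range(7))
        assert td == 0.0

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            pam_build(random_dissim(rng, 5), 6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        D = random_dissim(rng, 15)
        sq = D.to_square()
        medoids, _, td = pam_build(D, 3)
        assert list(medoids) == naive_greedy_build(sq, 3)
        assert td == pytest.approx(naive_td(sq, medoids), rel=1e-12)

    def test_build_td_not_below_exhaustive_optimum(self, rng):
        D = random_dissim(rng, 15)
        sq = D.to_square()
        _, _, td = pam_build(D, 3)
        best = min(
            naive_td(sq, m) for m in itertools.combinations(range(15), 3)
        )
        assert td >= best - 1e-12


class TestFastpam1:
    def test_two_pair_line_reaches_optimum(self, line_dissim):
        # tight pairs {0,1} and {10,11}; start from the worst split
        res = pam_fastpam1(line_dissim, [0, 1])
        assert res.td == 2.0
        sq = line_dissim.to_square()
        best = min(naive_td(sq, m) for m in itertools.combinations(range(4), 2))
        assert res.td == best
        assert sorted(m // 2 for m in res.medoids) == [0, 1]  # one medoid per pair

    def test_locally_optimal_start_does_nothing(self, line_dissim):
        res = pam_fastpam1(line_dissim, [0, 2])
        assert res.iterations == 0
        assert list(res.medoids) == [0, 2]
        assert res.converged

    @pytest.mark.parametrize("seed", range(8))
    def test_delta_td_bookkeeping_equals_naive_recompute(self, seed):
        """The O(n) incremental ΔTD equals brute-force TD difference for
        every candidate swap at every iteration of a run."""
        rng = np.random.default_rng(seed)
        n, k = 12, 3
        D = random_dissim(rng, n)
        sq = D.to_square()
        medoids, _, _ = pam_build(D, k)
        medoids = list(medoids)
        for _ in range(10):
            delta = swap_delta_td(D, medoids)
            td0 = naive_td(sq, medoids)
            for c in range(n):
                if c in medoids:
                    continue
                for i in range(k):
                    trial = list(medoids)
                    trial[i] = c
                    naive = naive_td(sq, trial) - td0
                    assert delta[c, i] == pytest.approx(naive, abs=1e-9)
            flat = int(np.argmin(delta))
            c, i = divmod(flat, k)
            if not delta[c, i] < 0:
                break
            medoids[i] = c

    @pytest.mark.parametrize("seed", range(8))
    def test_converged_set_is_single_swap_optimal(self, seed):
        rng = np.random.default_rng(100 + seed)
        D = random_dissim(rng, 11)
        sq = D.to_square()
        res = pam(D, 3)
        final = naive_td(sq, res.medoids)
        for c in range(11):
            if c in res.medoids:
                continue
            for i in range(3):
                trial = list(res.medoids)
                trial[i] = c
                assert naive_td(sq, trial) >= final - 1e-9

    def test_max_iter_flags_non_convergence(self, rng):
        D = random_dissim(rng, 30)
        medoids, _, _ = pam_build(D, 4)
        res = pam_fastpam1(D, medoids, max_iter=0)
        full = pam_fastpam1(D, medoids)
        if full.iterations > 0:
            assert not res.converged
        assert res.td >= full.td


class TestPamEndToEnd:
    def test_deterministic_bit_identical_runs(self, rng):
        D = random_dissim(rng, 40)
        a = pam(D, 5)
        b = pam(D, 5)
        np.testing.assert_array_equal(a.medoids, b.medoids)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.td == b.td and a.td_trace == b.td_trace

    def test_td_trace_strictly_decreasing(self, rng):
        D = random_dissim(rng, 50)
        res = pam(D, 4)
        trace = np.array(res.td_trace)
        assert (np.diff(trace) < 0).all()
        assert res.td == trace[-1]
        # td recomputable from D and medoids
        assert res.td == pytest.approx(naive_td(D.to_square(), res.medoids), rel=1e-9)

    def test_swap_never_increases_build_td(self, rng):
        D = random_dissim(rng, 35)
        _, _, td_build = pam_build(D, 4)
        res = pam(D, 4)
        assert res.td <= td_build
        assert (res.td < td_build) == (res.iterations > 0)

    def test_cluster_sizes_sum_to_n_all_nonempty(self, rng):
        D = random_dissim(rng, 30)
        res = pam(D, 5)
        counts = np.bincount(res.labels, minlength=5)
        assert counts.sum() == 30
        assert (counts > 0).all()
        # every medoid labels its own cluster
        for i, m in enumerate(res.medoids):
            assert res.labels[m] == i

    def test_permutation_equivariance(self, rng):
        X = rng.random((20, 5))
        perm = rng.permutation(20)
        res_a = pam(compute_dissimilarity(X, "L2"), 3)
        res_b = pam(compute_dissimilarity(X[perm], "L2"), 3)
        assert sorted(perm[res_b.medoids]) == sorted(res_a.medoids)

    def test_lab_init_seeded_and_valid(self, rng):
        D = random_dissim(rng, 60)
        a = pam(D, 4, init="lab", seed=11)
        b = pam(D, 4, init="lab", seed=11)
        np.testing.assert_array_equal(a.medoids, b.medoids)
        assert a.converged

    def test_k_equals_n(self, rng):
        D = random_dissim(rng, 6)
        res = pam(D, 6)
        assert res.td == 0.0

    def test_well_separated_recovery(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [40, 0], [0, 40]], dtype=float)
        truth = np.repeat([0, 1, 2], 30)
        X = centers[truth] + rng.normal(0, 1.0, size=(90, 2))
        res = pam(compute_dissimilarity(X, "L2"), 3)
        assert adjusted_rand_index(truth, res.labels) == 1.0

    def test_mid_k_range_converges_td_monotone(self):
        rng = np.random.default_rng(2)
        X = rng.random((300, 6))
        D = compute_dissimilarity(X, "L2")
        tds = []
        for k in (25, 35, 45):
            res = pam(D, k)
            assert res.converged
            tds.append(res.td)
        assert tds[0] >= tds[1] >= tds[2]


class TestAssignLabels:
    def test_equidistant_goes_to_lower_medoid(self):
        D = DissimilarityMatrix.from_square(
            np.array([[0.0, 2.0, 1.0], [2.0, 0.0, 1.0], [1.0, 1.0, 0.0]]), "L1"
        )
        labels = assign_labels(D, [0, 1])  # point 2 is 1 away from both
        assert labels[2] == 0

    def test_labels_match_brute_force_argmin(self, rng):
        D = random_dissim(rng, 25)
        medoids = [3, 11, 19]
        labels = assign_labels(D, medoids)
        table = D.to_square()[:, medoids]
        np.testing.assert_array_equal(labels, table.argmin(axis=1))


class TestEstimatorApi:
    def test_fit_sets_sklearn_style_attributes(self, rng):
        X = rng.random((30, 4))
        est = PAM(n_clusters=3, metric="L2").fit(X)
        assert est.labels_.shape == (30,)
        assert len(est.medoid_indices_) == 3
        assert est.inertia_ == pytest.approx(
            naive_td(est.dissimilarity_.to_square(), est.medoid_indices_)
        )
        assert est.converged_

    def test_get_set_params_round_trip(self):
        est = PAM(n_clusters=7, metric="L1")
        params = est.get_params()
        assert params["n_clusters"] == 7
        est.set_params(n_clusters=4)
        assert est.n_clusters == 4
        with pytest.raises(ValueError, match="invalid parameter"):
            est.set_params(bogus=1)

    def test_precomputed_fit_predict(self, rng):
        D = random_dissim(rng, 20)
        labels = PAM(n_clusters=2).fit_predict(D)
        assert set(labels) == {0, 1}
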