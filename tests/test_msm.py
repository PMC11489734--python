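"""MSM estimation, validation, coarse-graining and kinetics."""

import numpy as np
import pytest

from symgate._markov import simulate_chain, stationary_distribution
from symgate.msm import (
    KB_KCAL_PER_MOL_K,
    MarkovStateModel,
    ck_test,
    cluster_microstates,
    count_matrix,
    estimate_msm,
    free_energies,
    implied_timescales,
    mfpt,
    open_burst_durations,
    pcca_coarse_grain,
    reversible_mle,
    sample_posterior,
    score_vamp2,
    vamp2_from_counts,
)
from symgate.msm import _burst_lengths


def _msm_from_matrix(t, lag=1):
    """Wrap an exact transition matrix as a fitted MarkovStateModel."""
    t = np.asarray(t, dtype=float)
    m = MarkovStateModel(lag=lag, reversible=True)
    m.transition_matrix_ = t
    m.stationary_distribution_ = stationary_distribution(t)
    m.active_set_ = np.arange(t.shape[0])
    m.count_matrix_ = t * 1000.0
    m.count_matrix_full_ = m.count_matrix_
    return m


class TestClustering:
    def test_single_cluster_labels_everything_zero(self, rng):
        d = cluster_microstates(rng.normal(size=(50, 2)), k=1, seed=0)
        assert np.all(d.sequences[0] == 0)

    def test_separated_blobs_partition_exactly(self, rng):
        a = rng.normal(0.0, 1.0, size=(200, 2))
        b = rng.normal(100.0, 1.0, size=(200, 2))
        d = cluster_microstates(np.vstack([a, b]), k=2, seed=0)
        labels = d.sequences[0]
        assert len(set(labels[:200])) == 1 and len(set(labels[200:])) == 1
        assert labels[0] != labels[-1]
        # every frame is assigned to its nearest center
        x = np.vstack([a, b])
        nearest = np.argmin(
            np.linalg.norm(x[:, None] - d.centers[None], axis=2), axis=1
        )
        assert np.array_equal(labels, nearest)

    def test_seeded_determinism(self, rng):
        x = rng.normal(size=(300, 2))
        d1 = cluster_microstates(x, k=10, seed=42)
        d2 = cluster_microstates(x, k=10, seed=42)
        assert np.array_equal(d1.sequences[0], d2.sequences[0])

    def test_k_larger_than_data_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_microstates(rng.normal(size=(5, 2)), k=10, seed=0)


class TestEstimation:
    def test_symmetric_counts_give_symmetric_chain(self):
        t, pi = reversible_mle(np.array([[9.0, 1.0], [1.0, 9.0]]))
        assert np.allclose(t, [[0.9, 0.1], [0.1, 0.9]], atol=1e-10)
        assert np.allclose(pi, [0.5, 0.5], atol=1e-10)

    def test_reversible_mle_matches_grid_search(self):
        """Brute-force likelihood maximization over 2-state chains."""
        c = np.array([[8.0, 2.0], [1.0, 9.0]])
        grid = np.linspace(1e-3, 0.999, 1000)
        best, best_ll = None, -np.inf
        for t01 in grid:
            ll0 = c[0, 0] * np.log(1 - t01) + c[0, 1] * np.log(t01)
            for t10 in grid:
                ll = ll0 + c[1, 0] * np.log(t10) + c[1, 1] * np.log(1 - t10)
                if ll > best_ll:
                    best_ll, best = ll, (t01, t10)
        t, _ = reversible_mle(c)
        assert t[0, 1] == pytest.approx(best[0], abs=2e-3)
        assert t[1, 0] == pytest.approx(best[1], abs=2e-3)

    def test_detailed_balance_on_random_counts(self, rng):
        c = rng.integers(1, 50, size=(5, 5)).astype(float)
        t, pi = reversible_mle(c)
        assert np.allclose(t.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(pi @ t, pi, atol=1e-10)
        assert np.allclose(pi[:, None] * t, (pi[:, None] * t).T, atol=1e-10)

    def test_fit_restricts_to_largest_connected_set(self):
        # states 0-1 communicate; state 2 is a sink reached once
        seq = np.array([0, 1, 0, 1, 0, 1, 0, 2, 2, 2])
        m = MarkovStateModel(lag=1).fit([seq])
        assert set(m.active_set_) == {0, 1}

    def test_lag_in_time_units_must_divide(self):
        from symgate.msm import DiscreteTrajectorySet

        t = np.array([[0.7, 0.3], [0.3, 0.7]])
        d = DiscreteTrajectorySet(
            sequences=[simulate_chain(t, 200, rng=0)], n_states=2,
            frame_interval=2.0,
        )
        m = estimate_msm(d, 4.0, lag_in_frames=False)
        assert m.lag == 2
        with pytest.raises(ValueError, match="multiple"):
            estimate_msm(d, 3.0, lag_in_frames=False)


class TestImpliedTimescales:
    def test_closed_form_two_state(self):
        m = _msm_from_matrix([[0.9, 0.1], [0.1, 0.9]])
        assert m.timescales(1)[0] == pytest.approx(-1.0 / np.log(0.8), abs=1e-10)
        assert m.timescales(1)[0] == pytest.approx(4.4814, abs=1e-3)

    def test_flat_in_lag_for_markovian_data(self):
        t = np.array([[0.95, 0.05], [0.1, 0.9]])
        seq = simulate_chain(t, 200_000, rng=3)
        table = implied_timescales([seq], lags=[1, 2, 5, 10], n_timescales=1)
        exact = -1.0 / np.log(np.sort(np.linalg.eigvals(t))[0].real)
        assert np.all(np.abs(table["t2"] / exact - 1.0) < 0.1)

    def test_negative_eigenvalue_flagged_undefined(self):
        m = _msm_from_matrix([[0.05, 0.95], [0.95, 0.05]])
        assert np.isnan(m.timescales(1)[0])


class TestChapmanKolmogorov:
    def test_identity_at_single_step_and_consistency(self):
        t = np.array([[0.95, 0.05], [0.1, 0.9]])
        seq = simulate_chain(t, 100_000, rng=7)
        m = MarkovStateModel(lag=2).fit([seq])
        res = ck_test(m, np.array([0, 1]), steps=5, sequences=[seq], seed=0)
        assert np.allclose(res.predicted[:, 0], res.estimated[:, 0], atol=1e-8)
        assert res.max_deviation_sigmas() < 4.0

    def test_non_markovian_process_fails_visibly(self):
        # hidden 4-cycle observed through a 2-state projection: strongly
        # non-Markovian at the observed level
        hidden = np.array(
            [
                [0.02, 0.98, 0.0, 0.0],
                [0.0, 0.02, 0.98, 0.0],
                [0.0, 0.0, 0.02, 0.98],
                [0.98, 0.0, 0.0, 0.02],
            ]
        )
        seq = simulate_chain(hidden, 100_000, rng=11) // 2
        m = MarkovStateModel(lag=1).fit([seq])
        res = ck_test(m, np.array([0, 1]), steps=4, sequences=[seq], seed=0)
        assert res.max_deviation_sigmas() > 3.0


class TestVamp2:
    def test_perfect_two_state_score(self):
        t = np.array([[0.9, 0.1], [0.1, 0.9]])  # eigenvalues 1, 0.8
        pi = np.array([0.5, 0.5])
        n = 1e6
        c0t = n * pi[:, None] * t
        score = vamp2_from_counts(c0t.sum(1) / n, c0t / n, c0t.sum(0) / n)
        assert score == pytest.approx(1.0 + 0.8**2, abs=1e-9)
        assert score == pytest.approx(1.64, abs=1e-9)

    def test_single_state_scores_one(self):
        seq = np.zeros(1000, dtype=int)
        assert score_vamp2([seq], lag=1, n_splits=None) == pytest.approx(1.0)

    def test_merging_states_never_increases_score(self, rng):
        # exact covariances of a 3-state chain, all 2-state lumpings
        t = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.25, 0.7]])
        pi = stationary_distribution(t)
        c = pi[:, None] * t
        full = vamp2_from_counts(c.sum(1), c, c.sum(0))
        for merge in ([0, 1], [0, 2], [1, 2]):
            agg = np.zeros((3, 2))
            for s in range(3):
                agg[s, 0 if s in merge else 1] = 1.0
            cm = agg.T @ c @ agg
            lumped = vamp2_from_counts(cm.sum(1), cm, cm.sum(0))
            assert lumped <= full + 1e-9

    def test_cross_validated_score_near_exact(self):
        t = np.array([[0.9, 0.1], [0.1, 0.9]])
        seqs = [simulate_chain(t, 20_000, rng=s) for s in range(4)]
        score = score_vamp2(seqs, lag=1, n_splits=4, seed=0)
        assert score == pytest.approx(1.64, abs=0.05)


class TestPcca:
    def test_memberships_are_a_valid_partition_of_unity(self, rng):
        c = rng.integers(1, 30, size=(8, 8)).astype(float)
        m = MarkovStateModel(lag=1).fit(
            [simulate_chain(c / c.sum(1, keepdims=True), 5000, rng=1)]
        )
        macro = pcca_coarse_grain(m, 3)
        chi = macro.memberships
        assert np.all(chi >= -1e-12) and np.all(chi <= 1 + 1e-12)
        assert np.allclose(chi.sum(axis=1), 1.0, atol=1e-10)
        assert np.isclose(macro.macro_pi.sum(), 1.0, atol=1e-10)

    def test_metastable_blocks_recovered(self):
        eps = 1e-4
        t = np.array(
            [
                [0.5 - eps, 0.5, eps, 0.0],
                [0.5, 0.5 - eps, 0.0, eps],
                [eps, 0.0, 0.5 - eps, 0.5],
                [0.0, eps, 0.5, 0.5 - eps],
            ]
        )
        macro = pcca_coarse_grain(_msm_from_matrix(t), 2)
        a = macro.assignments
        assert a[0] == a[1] and a[2] == a[3] and a[0] != a[2]

    def test_m_equal_k_is_identity_like(self):
        t = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        macro = pcca_coarse_grain(_msm_from_matrix(t), 3)
        assert set(macro.assignments) == {0, 1, 2}
        assert np.all(macro.memberships.max(axis=1) > 0.95)

    def test_non_reversible_input_rejected(self):
        t = np.array([[0.1, 0.9, 0.0], [0.0, 0.1, 0.9], [0.9, 0.0, 0.1]])
        m = _msm_from_matrix(t)
        with pytest.raises(ValueError, match="reversible"):
            pcca_coarse_grain(m, 2)


class TestFreeEnergies:
    def test_equal_populations_are_degenerate(self):
        assert np.allclose(free_energies([0.5, 0.5]), [0.0, 0.0])

    def test_efold_ratio_is_one_kt(self):
        p = np.array([np.e, 1.0])
        dg = free_energies(p / p.sum(), temperature=300.0)
        assert dg[0] == 0.0
        assert dg[1] == pytest.approx(0.59616, abs=1e-4)
        assert KB_KCAL_PER_MOL_K * 300.0 == pytest.approx(0.59616, abs=1e-5)

    def test_zero_population_flagged_infinite(self):
        dg = free_energies([1.0, 0.0])
        assert dg[0] == 0.0 and np.isinf(dg[1])


class TestMfpt:
    def test_geometric_escape(self):
        t = np.array([[0.9, 0.1], [0.5, 0.5]])
        assert mfpt(t, [0], [1], lag_time=100.0) == pytest.approx(1000.0)

    def test_matches_monte_carlo_first_passage(self, rng):
        for trial in range(3):
            t = rng.random((4, 4)) + 0.1
            t /= t.sum(axis=1, keepdims=True)
            predicted = mfpt(t, [0], [3])
            pi = stationary_distribution(t)
            n_walkers = 3000
            times = np.zeros(n_walkers)
            cum = np.cumsum(t, axis=1)
            for w in range(n_walkers):
                state, steps = 0, 0
                local = np.random.default_rng(1000 * trial + w)
                while state != 3:
                    state = int(
                        np.searchsorted(cum[state], local.random(), side="right")
                    )
                    steps += 1
                times[w] = steps
            se = times.std(ddof=1) / np.sqrt(n_walkers)
            assert abs(times.mean() - predicted) < 3 * se + 1e-9

    def test_source_target_overlap_rejected(self):
        t = np.array([[0.9, 0.1], [0.1, 0.9]])
        with pytest.raises(ValueError, match="disjoint"):
            mfpt(t, [0], [0])


class TestPosterior:
    def test_concentrates_on_mle_for_huge_counts(self):
        c = 1e6 * np.array([[0.8, 0.2], [0.3, 0.7]])
        ens = sample_posterior(c, n_samples=10, seed=0, reversible=True)
        t_mle, _ = reversible_mle(c)
        assert np.all(np.abs(ens.matrices - t_mle) / t_mle < 0.01)

    def test_nonreversible_rows_match_dirichlet_conjugacy(self):
        c = np.array([[40.0, 10.0, 10.0], [5.0, 50.0, 5.0], [10.0, 10.0, 40.0]])
        ens = sample_posterior(c, n_samples=4000, seed=1, reversible=False)
        mean = ens.matrices.mean(axis=0)
        expected = c / c.sum(axis=1, keepdims=True)
        # Dirichlet(c_i) mean with its own MC error
        mc_err = ens.matrices.std(axis=0) / np.sqrt(4000)
        assert np.all(np.abs(mean - expected) < 4 * mc_err + 1e-4)

    def test_reproducible_under_fixed_seed(self):
        c = np.array([[30.0, 5.0], [5.0, 30.0]])
        a = sample_posterior(c, n_samples=5, seed=9)
        b = sample_posterior(c, n_samples=5, seed=9)
        assert np.array_equal(a.matrices, b.matrices)

    def test_reversible_samples_satisfy_detailed_balance(self):
        c = np.array([[30.0, 5.0, 2.0], [4.0, 40.0, 6.0], [3.0, 5.0, 20.0]])
        ens = sample_posterior(c, n_samples=10, seed=2, reversible=True)
        for t, pi in zip(ens.matrices, ens.stationary):
            flux = pi[:, None] * t
            assert np.allclose(flux, flux.T, atol=1e-10)

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError, match="empty rows"):
            sample_posterior(np.array([[1.0, 0.0], [0.0, 0.0]]), 5, seed=0)


class TestBursts:
    def test_never_leaving_open_gives_single_full_burst(self):
        t = np.array([[0.7, 0.3], [0.4, 0.6]])
        durations = open_burst_durations(
            t, np.array([0, 0]), open_label=0, n_steps=500, seed=0
        )
        assert durations.tolist() == [500]

    def test_geometric_burst_length(self):
        p = 0.01
        t = np.array([[1 - p, p], [0.5, 0.5]])
        durations = open_burst_durations(
            t, np.array([0, 1]), open_label=0, n_steps=400_000, seed=3
        )
        se = durations.std(ddof=1) / np.sqrt(len(durations))
        assert abs(durations.mean() - 1 / p) < 3 * se

    def test_merge_gap_semantics_on_crafted_sequence(self):
        seq = np.array([1, 0, 1])  # open, closed, open
        assert _burst_lengths(seq, 1, merge_gap=0).tolist() == [1, 1]
        assert _burst_lengths(seq, 1, merge_gap=2).tolist() == [3]

    def test_empty_open_state_rejected(self):
        t = np.array([[0.9, 0.1], [0.1, 0.9]])
        with pytest.raises(ValueError, match="empty"):
            open_burst_durations(t, np.array([0, 0]), 1, 100, seed=0)
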