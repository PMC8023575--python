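"""Balance-equation solve, free energies, global statistics, rate matrix,
and the first-passage linear system."""

import numpy as np
import pytest

from vtmm import (
    CellStatistics,
    aggregate_escape_rates,
    build_uniform_tessellation,
    free_energy_profile,
    global_milestone_statistics,
    mfpt,
    rate_matrix,
    solve_stationary,
)
from vtmm.constants import KB_KCAL_MOL_K
from vtmm.errors import (
    DegenerateSamplingError,
    InconsistentStatisticsError,
    InvalidArgumentError,
    NoUniqueSolutionError,
    UnreachableMilestoneError,
)


def stats_for(cell, n_mil, bc, occupancy, N=None, R=None, T=0.0):
    return CellStatistics(
        cell_index=cell,
        N_alpha=np.zeros((n_mil, n_mil)) if N is None else np.asarray(N, float),
        R_alpha=np.zeros(n_mil) if R is None else np.asarray(R, float),
        T_alpha=T,
        occupancy_time=occupancy,
        boundary_crossings=np.asarray(bc, float),
    )


class TestEscapeRates:
    def test_symmetric_two_cell_rates(self):
        tess = build_uniform_tessellation(0, 1, 2)
        stats = [
            stats_for(0, 1, bc=[0, 10], occupancy=100.0),
            stats_for(1, 1, bc=[10, 0], occupancy=100.0),
        ]
        K = aggregate_escape_rates(stats, tess)
        assert K[0, 1] == pytest.approx(0.1)
        assert K[1, 0] == pytest.approx(0.1)

    def test_zero_sampling_names_the_cell(self):
        tess = build_uniform_tessellation(0, 1, 2)
        stats = [stats_for(0, 1, [0, 5], 10.0), stats_for(1, 1, [5, 0], 0.0)]
        with pytest.raises(DegenerateSamplingError, match="cell 1"):
            aggregate_escape_rates(stats, tess)

    def test_disconnected_cells_fail_downstream(self):
        tess = build_uniform_tessellation(0, 1, 3)
        stats = [
            stats_for(0, 2, [0, 5], 10.0),
            stats_for(1, 2, [5, 0], 10.0),  # never crosses toward cell 2
            stats_for(2, 2, [0, 0], 10.0),
        ]
        K = aggregate_escape_rates(stats, tess)
        assert K[1, 2] == 0 and K[2, 1] == 0
        with pytest.raises(NoUniqueSolutionError) as err:
            solve_stationary(K)
        assert len(err.value.components) == 2


class TestStationarySolve:
    def test_symmetric_rates_give_uniform_pi(self):
        K = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(solve_stationary(K), [0.5, 0.5])

    def test_two_state_balance_by_hand(self):
        # pi_1*K12 = pi_2*K21 with K12 = 2*K21  ->  pi = (1/3, 2/3)
        K = np.array([[0.0, 2.0], [1.0, 0.0]])
        assert np.allclose(solve_stationary(K), [1 / 3, 2 / 3])

    def test_three_state_chain_against_direct_null_space(self):
        rng = np.random.default_rng(5)
        K = np.zeros((4, 4))
        for i in range(3):
            K[i, i + 1] = rng.uniform(0.5, 2)
            K[i + 1, i] = rng.uniform(0.5, 2)
        pi = solve_stationary(K)
        # independent oracle: eigenvector of the generator transpose
        G = K - np.diag(K.sum(1))
        w, v = np.linalg.eig(G.T)
        null = np.real(v[:, np.argmin(np.abs(w))])
        null = null / null.sum()
        assert np.allclose(pi, null, atol=1e-10)
        assert pi.sum() == pytest.approx(1.0)


class TestFreeEnergy:
    def test_uniform_probability_is_flat_profile(self):
        F = free_energy_profile(np.full(5, 0.2), temperature=310.0)
        assert np.allclose(F - F[0], 0.0)

    def test_ratio_nine_to_one_at_310K(self):
        F = free_energy_profile(np.array([0.9, 0.1]), temperature=310.0)
        expected = KB_KCAL_MOL_K * 310.0 * np.log(9.0)
        assert F[1] - F[0] == pytest.approx(expected, rel=1e-12)
        assert F[1] - F[0] == pytest.approx(1.354, abs=2e-3)

    def test_most_probable_cell_is_free_energy_minimum(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(10))
        F = free_energy_profile(pi)
        assert np.argmax(pi) == np.nanargmin(F)

    def test_unsampled_cell_reported_not_infinite(self):
        with pytest.warns(RuntimeWarning, match="unsampled"):
            F = free_energy_profile(np.array([0.5, 0.5, 0.0]))
        assert np.isnan(F[2]) and np.isfinite(F[:2]).all()

    def test_unnormalized_pi_rejected(self):
        with pytest.raises(InvalidArgumentError):
            free_energy_profile(np.array([0.5, 0.3]))


class TestGlobalStatistics:
    def test_single_cell_reduces_to_per_cell_rates(self):
        s = stats_for(0, 2, [0, 0], 10.0, N=[[0, 4], [2, 0]], R=[6, 3], T=10.0)
        N, R = global_milestone_statistics([s], np.array([1.0]))
        assert np.allclose(N, np.array([[0, 0.4], [0.2, 0]]))
        assert np.allclose(R, [0.6, 0.3])

    def test_two_cell_weighted_sum_arithmetic(self):
        # pi = (0.25, 0.75), per-cell rates 0.02 and 0.04 -> 0.035
        s1 = stats_for(0, 1, [0, 0], 10.0, N=[[0.0]], R=[0], T=50.0)
        s1.N_alpha = np.array([[1.0]])  # rate 1/50 = 0.02
        s2 = stats_for(1, 1, [0, 0], 10.0, N=[[0.0]], R=[0], T=25.0)
        s2.N_alpha = np.array([[1.0]])  # rate 1/25 = 0.04
        N, _ = global_milestone_statistics([s1, s2], np.array([0.25, 0.75]))
        assert N[0, 0] == pytest.approx(0.035)

    def test_zero_weight_cell_contributes_nothing(self):
        s1 = stats_for(0, 1, [0, 0], 10.0, N=[[5.0]], R=[5], T=10.0)
        s2 = stats_for(1, 1, [0, 0], 10.0, N=[[100.0]], R=[9], T=10.0)
        N, R = global_milestone_statistics([s1, s2], np.array([1.0, 0.0]))
        assert N[0, 0] == pytest.approx(0.5)
        assert R[0] == pytest.approx(0.5)

    def test_length_mismatch_rejected(self):
        s = stats_for(0, 1, [0, 0], 1.0, T=1.0)
        with pytest.raises(InvalidArgumentError):
            global_milestone_statistics([s], np.array([0.5, 0.5]))


class TestRateMatrix:
    def test_rate_is_count_over_residence(self):
        q = rate_matrix(np.array([[0, 5.0], [0, 0]]), np.array([10.0, 1.0]))
        assert q[0, 1] == pytest.approx(0.5)

    def test_rows_sum_to_zero_generator(self):
        rng = np.random.default_rng(3)
        N = rng.uniform(0, 2, (4, 4))
        R = rng.uniform(1, 2, 4)
        q = rate_matrix(N, R)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        off = q - np.diag(np.diag(q))
        assert (off >= 0).all()

    def test_transitions_without_residence_is_inconsistent(self):
        with pytest.raises(InconsistentStatisticsError):
            rate_matrix(np.array([[0, 1.0], [0, 0]]), np.array([0.0, 1.0]))


class TestMFPT:
    def test_two_milestones_exponential_escape(self):
        q = rate_matrix(np.array([[0, 3.0], [0, 0]]), np.array([6.0, 1.0]))
        res = mfpt(q, target=1)
        assert res.tau[0] == pytest.approx(2.0)  # 1/k with k = 0.5
        assert res.tau[1] == 0.0

    def test_birth_death_chain_hand_solved(self):
        # q12 = q21 = q23 = q32 = 1/ps, target = milestone 3 (index 2).
        # Hand solve of the linear system (tau3 = 0):
        #   -tau1 + tau2 = -1;  tau1 - 2*tau2 = -1  ->  tau1 = 3, tau2 = 2
        q = np.array([[-1.0, 1.0, 0.0], [1.0, -2.0, 1.0], [0.0, 1.0, -1.0]])
        res = mfpt(q, target=2)
        assert res.tau[0] == pytest.approx(3.0, rel=1e-12)
        assert res.tau[1] == pytest.approx(2.0, rel=1e-12)

    def test_birth_death_chain_against_jump_simulation(self):
        # independent oracle: direct continuous-time Markov-chain simulation
        rng = np.random.default_rng(42)
        n_rep = 40_000
        total = 0.0
        for _ in range(n_rep):
            state, t = 0, 0.0
            while state != 2:
                rate = 1.0 if state == 0 else 2.0
                t += rng.exponential(1.0 / rate)
                if state == 0:
                    state = 1
                else:
                    state = 0 if rng.random() < 0.5 else 2
            total += t
        sim = total / n_rep  # SE ~ sqrt(var)/sqrt(n) ~ 0.013
        q = np.array([[-1.0, 1.0, 0.0], [1.0, -2.0, 1.0], [0.0, 1.0, -1.0]])
        assert mfpt(q, target=2).tau[0] == pytest.approx(sim, abs=0.05)

    def test_target_may_sit_at_either_end(self):
        q = np.array([[-1.0, 1.0, 0.0], [1.0, -2.0, 1.0], [0.0, 1.0, -1.0]])
        res = mfpt(q, target=0)
        assert res.tau[0] == 0.0
        assert res.tau[2] == pytest.approx(3.0)
        assert res.tau[1] == pytest.approx(2.0)

    def test_tau_at_target_is_zero_always(self):
        rng = np.random.default_rng(9)
        N = rng.uniform(0.1, 1, (5, 5))
        N = np.triu(N, 1) + np.tril(N, -1)
        mask = np.abs(np.arange(5)[:, None] - np.arange(5)[None, :]) == 1
        N = np.where(mask, N, 0.0)
        q = rate_matrix(N, rng.uniform(0.5, 1, 5))
        for k in range(5):
            assert mfpt(q, target=k).tau[k] == 0.0

    def test_unreachable_milestone_raises(self):
        # milestones 0-1 disconnected from 2
        q = np.array([[-1.0, 1.0, 0.0], [1.0, -1.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(UnreachableMilestoneError):
            mfpt(q, target=2)

    def test_additional_absorbing_milestones(self):
        q = np.array([[-1.0, 1.0, 0.0], [1.0, -2.0, 1.0], [0.0, 1.0, -1.0]])
        res = mfpt(q, target=2, absorbing=[0])
        # from milestone 1, either neighbor absorbs: tau = 1/(total rate)
        assert res.tau[1] == pytest.approx(0.5)
        assert res.tau[0] == 0.0
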