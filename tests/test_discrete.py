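"""Discrete active-inference core against its exact oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from actinf.discrete import (
    Beliefs,
    DiscreteModel,
    SamplingKernel,
    agency_free_action,
    discrete_free_energy,
    entropy_decomposition,
    exact_smoother,
    init_beliefs,
    normalize_columns,
    run_episode,
    select_control_action,
    value_iteration,
    variational_sweep,
)
from actinf.fixtures import (
    ToyMDPSpec,
    make_deterministic_mdp,
    make_diffuse_mdp,
    make_toy_mdp,
)
from conftest import kl_divergence


class TestNormalizeColumns:
    def test_identity_unchanged(self):
        assert np.allclose(normalize_columns(np.eye(3)), np.eye(3))

    def test_symmetric_column(self):
        out = normalize_columns(np.array([[1.0], [1.0]]))
        assert np.allclose(out, [[0.5], [0.5]])

    @given(
        arrays(float, (3, 3), elements=st.floats(0.01, 10.0)).filter(
            lambda M: M.sum(axis=0).min() > 0
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_columns_sum_to_one_and_preserve_ratios(self, M):
        out = normalize_columns(M)
        assert np.allclose(out.sum(axis=0), 1.0, atol=1e-12)
        # proportionality within columns preserved
        j = 0
        ratios = M[:, j] / M[:, j].sum()
        assert np.allclose(out[:, j], ratios)

    def test_zero_column_reports_index(self):
        M = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="column 1"):
            normalize_columns(M)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            normalize_columns(np.array([[-1.0], [2.0]]))


class TestValueIteration:
    def test_single_state_accumulates_reward(self):
        Tr = np.ones((2, 1, 1))
        V, policy = value_iteration(Tr, np.array([3.0]), horizon=4)
        assert np.allclose(V[0], 3.0 * 5)
        assert policy.shape == (4, 1)

    def test_two_state_chain_prefers_rewarding_state(self):
        # action 0 stays, action 1 moves 0 -> 1; reward only in state 1
        Tr = np.zeros((2, 2, 2))
        Tr[0] = np.eye(2)
        Tr[1][:, 0] = [0, 1]
        Tr[1][:, 1] = [0, 1]
        V, policy = value_iteration(Tr, np.array([0.0, 1.0]), horizon=2)
        assert policy[0, 0] == 1  # exhaustive enumeration agrees: go to state 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sequence_enumeration_deterministic(self, seed):
        """On deterministic transitions, V(x) equals the max over all 3^3
        enumerated action sequences of cumulative reward (open-loop and
        closed-loop optima coincide when transitions are deterministic)."""
        Tr, rew = make_deterministic_mdp(3, 3, seed=seed)
        H = 3
        V, _ = value_iteration(Tr, rew, H)
        r = rew.r
        for x0 in range(3):
            best = -np.inf
            for seq in itertools.product(range(3), repeat=H):
                x = x0
                total = r[x]
                for a in seq:
                    x = int(np.argmax(Tr[a][:, x]))
                    total += r[x]
                best = max(best, total)
            assert np.isclose(V[0, x0], best, atol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_policy_enumeration_stochastic(self, seed):
        """On stochastic transitions, V equals the max over all enumerated
        time-dependent policies (closed-loop brute force)."""
        rng = np.random.default_rng(seed)
        n, na, H = 3, 3, 2
        Tr = np.stack([normalize_columns(rng.random((n, n))) for _ in range(na)])
        r = rng.normal(size=n)
        V, _ = value_iteration(Tr, r, H)
        policies = list(itertools.product(range(na), repeat=n))
        for x0 in range(n):
            best = -np.inf
            for pi0 in policies:
                for pi1 in policies:
                    p = np.zeros(n)
                    p[x0] = 1.0
                    total = r[x0]
                    for pi in (pi0, pi1):
                        p = sum(
                            Tr[pi[x]][:, x] * p[x] for x in range(n) if p[x] > 0
                        )
                        total += p @ r
                    best = max(best, total)
            assert np.isclose(V[0, x0], best, atol=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            value_iteration(np.ones((1, 2, 2)) / 2, np.zeros(3), 2)


class TestAgencyFreeAction:
    def test_single_action_returned(self):
        Tr = np.ones((1, 2, 2)) / 2
        R = SamplingKernel(np.ones((1, 2, 2)) / 2)
        a = agency_free_action(np.array([1.0, 0.0]), np.zeros(2, int), Tr, np.eye(2), R, 0)
        assert a == 0

    def test_symmetric_tie_breaks_low(self):
        Tr = np.ones((3, 2, 2)) / 2
        R = SamplingKernel(np.ones((3, 2, 2)) / 2)
        A = np.ones((2, 2)) / 2  # identical likelihood columns
        a = agency_free_action(np.full(2, 0.5), np.zeros(2, int), Tr, A, R, 0)
        assert a == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_bellman_equivalence_on_deterministic_mdps(self, seed):
        """With a delta posterior, deterministic transitions, identity
        likelihood and R mirroring the transitions, the free-energy action
        equals the Bellman-optimal action at every visited state."""
        Tr, rew = make_deterministic_mdp(4, 3, seed=seed)
        H = 6
        V, policy = value_iteration(Tr, rew, H)
        R = SamplingKernel(Tr.copy())
        A = np.eye(4)
        x = int(np.random.default_rng(seed).integers(4))
        for t in range(H):
            post = np.zeros(4)
            post[x] = 1.0
            a = agency_free_action(post, policy[t], Tr, A, R, x)
            assert a == policy[t, x]
            x = int(np.argmax(Tr[a][:, x]))


class TestExactSmoother:
    def test_prior_only_t1_delta(self):
        c = np.array([0.0, 1.0])
        B = [np.eye(2)]
        model = DiscreteModel(np.eye(2), B, c, np.array([1.0]), T=1)
        alpha, beta, _ = exact_smoother(model, [])
        assert np.allclose(alpha[1], c)

    def test_uniform_likelihood_leaves_prior(self):
        """With an uninformative likelihood the posterior equals the prior
        (same smoother run without observations)."""
        model, _, _, _ = make_toy_mdp(ToyMDPSpec(n_states=3, n_actions=2, horizon=2, seed=1))
        uniform_A = np.ones((3, 3)) / 3
        m2 = DiscreteModel(uniform_A, model.B, model.c, model.d, model.T)
        a_obs, b_obs, _ = exact_smoother(m2, [0])
        a_none, b_none, _ = exact_smoother(m2, [])
        assert np.allclose(a_obs, a_none, atol=1e-12)
        assert np.allclose(b_obs, b_none, atol=1e-12)

    def test_hand_enumeration_2x2(self):
        """Marginals equal an independent hand enumeration over all joint
        sequences of a 2-state/2-control/T=2 model with one observation."""
        model, _, _, _ = make_toy_mdp(ToyMDPSpec(n_states=2, n_actions=2, horizon=2, seed=3))
        obs = [1]
        alpha, beta, logev = exact_smoother(model, obs)
        # independent enumeration written longhand
        logs = []
        marg_x = np.zeros((3, 2))
        marg_u = np.zeros((2, 2))
        total = 0.0
        for x0 in range(2):
            for x1 in range(2):
                for x2 in range(2):
                    for u1 in range(2):
                        for u2 in range(2):
                            p = (
                                model.A[obs[0], x0]
                                * model.c[x2]
                                * model.B[u1][x0, x1]
                                * model.d[u1]
                                * model.B[u2][x1, x2]
                                * model.d[u2]
                            )
                            total += p
                            for t, x in enumerate((x0, x1, x2)):
                                marg_x[t, x] += p
                            marg_u[0, u1] += p
                            marg_u[1, u2] += p
        assert np.isclose(logev, np.log(total), atol=1e-10)
        assert np.allclose(alpha, marg_x / total, atol=1e-10)
        assert np.allclose(beta, marg_u / total, atol=1e-10)

    def test_enumeration_guard(self):
        model, _, _, _ = make_toy_mdp(
            ToyMDPSpec(n_states=6, n_actions=3, horizon=4, seed=0)
        )
        model.T = 12  # blow past the guard
        with pytest.raises(ValueError, match="guard"):
            exact_smoother(model, [0])


class TestVariationalSweep:
    def test_uniform_model_is_fixed_point(self):
        n, nu, T = 3, 2, 2
        B = [np.ones((n, n)) / n for _ in range(nu)]
        model = DiscreteModel(np.ones((n, n)) / n, B, np.ones(n) / n, np.ones(nu) / nu, T)
        b = init_beliefs(model, [0])
        out = variational_sweep(model, [0], b, n_iterations=5)
        assert np.allclose(out.alpha[1:], 1.0 / n)
        assert np.allclose(out.beta, 1.0 / nu)

    def test_identity_likelihood_pins_observed_states(self):
        model, R, _, _ = make_toy_mdp(ToyMDPSpec(seed=2))
        obs = [1, 3]
        b = variational_sweep(model, obs, init_beliefs(model, obs), 10)
        for t, s in enumerate(obs):
            assert np.isclose(b.alpha[t, s], 1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_marginals_match_enumeration_on_diffuse_toys(self, seed):
        """Converged mean-field marginals vs the exact smoother (KL <= 1e-3)
        in the weak-coupling regime where the posterior nearly factorizes."""
        nx, nu, T = (4, 3, 3) if seed % 2 else (3, 2, 2)
        model, R = make_diffuse_mdp(nx, nu, T, seed=seed)
        obs = [int(np.random.default_rng(seed + 99).integers(nx))]
        exact_a, exact_b, _ = exact_smoother(model, obs)
        b = variational_sweep(model, obs, init_beliefs(model, obs), 300, tol=1e-14)
        for t in range(T + 1):
            assert kl_divergence(exact_a[t], b.alpha[t]) <= 1e-3
        for t in range(T):
            assert kl_divergence(exact_b[t], b.beta[t]) <= 1e-3

    @pytest.mark.parametrize("seed", range(4))
    def test_control_posteriors_exact_when_states_observed(self, seed):
        """With every pre-terminal state observed (identity likelihood), the
        posterior over controls factorizes exactly and the sweep recovers it."""
        model, R, _, _ = make_toy_mdp(ToyMDPSpec(horizon=3, seed=seed))
        rng = np.random.default_rng(seed)
        s = int(rng.integers(model.n_obs))
        obs = [s]
        for _ in range(model.T - 1):
            a = int(rng.integers(model.n_controls))
            s = int(rng.choice(model.n_obs, p=R.R[a][:, s]))
            obs.append(s)
        exact_a, exact_b, _ = exact_smoother(model, obs)
        b = variational_sweep(model, obs, init_beliefs(model, obs), 50, tol=1e-14)
        for t in range(model.T):
            assert kl_divergence(exact_b[t], b.beta[t]) <= 1e-9

    def test_beliefs_stay_normalized(self):
        model, _, _, _ = make_toy_mdp(ToyMDPSpec(seed=5))
        b = variational_sweep(model, [0], init_beliefs(model, [0]), 8)
        b.validate()


class TestFreeEnergy:
    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_negative_log_evidence(self, seed):
        """F >= -ln P(s|m) for arbitrary valid beliefs (Gibbs inequality),
        tested over random belief settings on random small models."""
        model, _, _, _ = make_toy_mdp(ToyMDPSpec(n_states=3, n_actions=2, horizon=2, seed=seed))
        obs = [0]
        _, _, logev = exact_smoother(model, obs)
        rng = np.random.default_rng(seed)
        for _ in range(5):
            alpha = rng.random((model.T + 1, model.n_states)) + 0.05
            alpha /= alpha.sum(axis=1, keepdims=True)
            beta = rng.random((model.T, model.n_controls)) + 0.05
            beta /= beta.sum(axis=1, keepdims=True)
            F = discrete_free_energy(model, Beliefs(alpha, beta), obs)
            assert F >= -logev - 1e-9

    def test_tight_when_posterior_factorizes(self):
        """On a model whose exact posterior factorizes (uniform likelihood,
        independent time slices), plugging in the exact marginals attains
        the bound."""
        n, nu, T = 3, 2, 2
        rng = np.random.default_rng(0)
        # control-independent transitions make the posterior a Markov chain;
        # with no observations and uniform B the slices decouple entirely
        B = [np.ones((n, n)) / n for _ in range(nu)]
        c = rng.dirichlet(np.ones(n))
        model = DiscreteModel(np.ones((n, n)) / n, B, c, np.ones(nu) / nu, T)
        alpha, beta, logev = exact_smoother(model, [])
        F = discrete_free_energy(model, Beliefs(alpha, beta), [])
        assert np.isclose(F, -logev, atol=1e-10)

    def test_sweeps_never_increase_free_energy(self):
        model, _, _, _ = make_toy_mdp(ToyMDPSpec(seed=7))
        obs = [0]
        b = init_beliefs(model, obs)
        prev = discrete_free_energy(model, b, obs)
        for _ in range(15):
            b = variational_sweep(model, obs, b, 1)
            F = discrete_free_energy(model, b, obs)
            assert F <= prev + 1e-12
            prev = F


class TestSelectControlAction:
    def test_delta_belief_exact_match(self):
        n = 3
        R = np.zeros((2, n, n))
        R[0][:, :] = np.eye(n)  # stay
        R[1] = np.roll(np.eye(n), 1, axis=0)  # advance
        beliefs = Beliefs(
            np.array([[1, 0, 0], [0, 1, 0.0]]), np.array([[0.5, 0.5]])
        )
        a = select_control_action(beliefs, 0, SamplingKernel(R), np.eye(n), 0)
        assert a == 1

    def test_identical_rows_tie_to_low_index(self):
        n = 2
        R = np.stack([np.eye(n), np.eye(n)])
        beliefs = Beliefs(np.array([[1, 0], [0, 1.0]]), np.array([[0.5, 0.5]]))
        a = select_control_action(beliefs, 0, SamplingKernel(R), np.eye(n), 0)
        assert a == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_direct_objective(self, seed):
        """Matches brute-force evaluation of the expected-log-likelihood
        objective over all actions on random 4-state toys."""
        model, R, _, _ = make_toy_mdp(ToyMDPSpec(seed=seed))
        b = variational_sweep(model, [0], init_beliefs(model, [0]), 8)
        a = select_control_action(b, 0, R, model.A, 0)
        logA = np.log(np.maximum(model.A, 1e-16))
        vals = [
            sum(
                R.R[ai][s2, 0] * (logA[s2] @ b.alpha[1])
                for s2 in range(model.n_obs)
            )
            for ai in range(model.n_controls)
        ]
        assert a == int(np.argmax(vals))


class TestRunEpisode:
    def test_fixed_point_toy_stays_home(self):
        """Terminal prior at the start state with self-transitions available:
        the final modal state equals the start state."""
        n, nu = 3, 2
        stay = np.eye(n) * 0.9 + np.ones((n, n)) * 0.1 / n
        shift_m = np.roll(np.eye(n), 1, axis=0) * 0.9 + np.ones((n, n)) * 0.1 / n
        B = [normalize_columns(stay.T), normalize_columns(shift_m.T)]
        R = SamplingKernel(np.stack([normalize_columns(stay), normalize_columns(shift_m)]))
        c = np.zeros(n)
        c[1] = 1.0
        model = DiscreteModel(np.eye(n), B, c, np.ones(nu) / nu, T=4)
        trace = run_episode(model, R, start_state=1, n_sweeps_per_step=8)
        assert trace.states[-1] == 1

    def test_trace_lengths_and_modes_agree_without_noise(self):
        # permutation transitions: a fully deterministic kernel whose
        # transpose still has no zero columns
        n, nu = 4, 2
        P0 = np.roll(np.eye(n), 1, axis=0)
        P1 = np.eye(n)[:, ::-1]
        R = SamplingKernel(np.stack([P0, P1]))
        B = [P0.T.copy(), P1.T.copy()]
        c = np.zeros(n)
        c[2] = 1.0
        model = DiscreteModel(np.eye(n), B, c, np.ones(nu) / nu, T=4)
        t_modal = run_episode(model, R, 0, mode="modal")
        t_sampled = run_episode(model, R, 0, mode="sampled", seed=1)
        assert len(t_modal.states) == model.T + 1
        assert len(t_modal.actions) == model.T
        # fully deterministic kernel: sampling and modal propagation coincide
        assert t_modal.states == t_sampled.states

    def test_sampled_mode_is_reproducible(self):
        model, R, _, _ = make_toy_mdp(ToyMDPSpec(seed=4, determinism=0.6))
        t1 = run_episode(model, R, 0, mode="sampled", seed=42)
        t2 = run_episode(model, R, 0, mode="sampled", seed=42)
        assert t1.states == t2.states


class TestEntropyDecomposition:
    def test_independent_uniform(self):
        H_joint, H_S, H_cond, MI = entropy_decomposition(np.full((2, 2), 0.25))
        assert np.isclose(MI, 0.0, atol=1e-12)
        assert np.isclose(H_cond, np.log(2), atol=1e-12)

    def test_perfectly_correlated(self):
        H_joint, H_S, H_cond, MI = entropy_decomposition(np.diag([0.5, 0.5]))
        assert np.isclose(MI, np.log(2), atol=1e-12)
        assert np.isclose(H_cond, 0.0, atol=1e-12)

    @given(arrays(float, (4, 4), elements=st.floats(0.01, 1.0)))
    @settings(max_examples=50, deadline=None)
    def test_identities_hold_on_random_joints(self, J):
        J = J / J.sum()
        H_joint, H_S, H_cond, MI = entropy_decomposition(J)
        p_psi = J.sum(axis=0)
        H_psi = -float(np.sum(p_psi * np.log(p_psi)))
        assert abs(H_joint - (H_S + H_cond)) < 1e-12
        assert abs(H_cond - (H_psi - MI)) < 1e-12

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            entropy_decomposition(np.array([[1.5, -0.5], [0.0, 0.0]]))
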