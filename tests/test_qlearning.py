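import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from pupilrl.qlearning import (
    AgentParams,
    batch_nll,
    choice_prob,
    compute_trajectory,
    encode_trials,
    negative_log_likelihood,
    transfer_values,
    update_q,
)
from pupilrl.task import TaskConfig, simulate_agent


def _make_trial(i, pair, choice, outcome, rt=0.8):
    from pupilrl.task import TrialRecord

    t0 = 10.0 * i
    return TrialRecord(
        phase="learning", run_index=0, trial_index=i, pair=pair, choice=choice,
        outcome=outcome, rt=rt, t_fixation=t0, t_options_on=t0 + 0.5,
        t_choice=t0 + 0.5 + rt, t_feedback=t0 + 0.5 + rt + 1.5,
        t_options_off=t0 + 0.5 + rt + 2.0,
    )


class TestUpdateQ:
    def test_zero_rate_identity(self):
        assert update_q(0.5, 1, AgentParams(0.0, 0.3, 1.0)) == 0.5

    def test_gain_update(self):
        assert update_q(0.5, 1, AgentParams(0.5, 0.3, 1.0)) == pytest.approx(0.75)

    def test_loss_update(self):
        assert update_q(0.5, 0, AgentParams(0.5, 0.2, 1.0)) == pytest.approx(0.40)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            update_q(1.5, 1, AgentParams(0.5, 0.5, 1.0))
        with pytest.raises(ValueError):
            update_q(0.5, 2, AgentParams(0.5, 0.5, 1.0))

    @given(
        q=hst.floats(0.0, 1.0),
        r=hst.integers(0, 1),
        ag=hst.floats(0.0, 1.0),
        al=hst.floats(0.0, 1.0),
    )
    def test_boundedness(self, q, r, ag, al):
        out = update_q(q, r, AgentParams(ag, al, 1.0))
        assert 0.0 <= out <= 1.0


class TestChoiceProb:
    def test_symmetry(self):
        for beta in (0.0, 1.0, 50.0, 100.0):
            assert choice_prob(0.3, 0.3, beta) == pytest.approx(0.5)

    def test_flat_at_beta_zero(self):
        assert choice_prob(0.9, 0.1, 0.0) == pytest.approx(0.5)

    def test_hand_value(self):
        # beta * (q_a - q_b) = 3 -> logistic(3)
        assert choice_prob(0.8, 0.2, 5.0) == pytest.approx(1.0 / (1.0 + np.exp(-3.0)), abs=1e-12)

    def test_stable_at_beta_100(self):
        p = choice_prob(1.0, 0.0, 100.0)
        assert np.isfinite(p)
        assert p == pytest.approx(1.0, abs=1e-10)  # saturates to 1.0 in float64
        assert choice_prob(0.0, 1.0, 100.0) == pytest.approx(0.0, abs=1e-10)

    @given(qa=hst.floats(0.0, 1.0), qb=hst.floats(0.0, 1.0), beta=hst.floats(0.0, 100.0))
    @settings(max_examples=200)
    def test_conservation(self, qa, qb, beta):
        assert choice_prob(qa, qb, beta) + choice_prob(qb, qa, beta) == pytest.approx(1.0, abs=1e-12)


def _oracle_nll_and_trajectory(trials, ag, al, beta):
    """Independent brute-force loop over the update and choice rules."""
    q = {o: 0.5 for o in "ABCDEF"}
    nll = 0.0
    rows = []
    for t in trials:
        a, b = t.pair
        c, u = t.choice, (t.pair[1] if t.choice == t.pair[0] else t.pair[0])
        ea, eb = np.exp(beta * q[a]), np.exp(beta * q[b])
        p_choice = (ea if c == a else eb) / (ea + eb)
        if 0.15 <= t.rt <= 3.5:
            nll -= np.log(p_choice)
        rows.append((q[c], q[u], t.outcome - q[c]))
        q[c] = q[c] + (ag if t.outcome == 1 else al) * (t.outcome - q[c])
    return nll, np.array(rows), q


class TestLikelihood:
    def test_single_symmetric_trial(self):
        trials = [_make_trial(0, ("A", "B"), "A", 1)]
        nll = negative_log_likelihood(trials, AgentParams(0.3, 0.1, 5.0))
        assert nll == pytest.approx(-np.log(0.5))

    def test_beta_zero_gives_nlog2(self, default_config, agent_params):
        trials, _ = simulate_agent(agent_params, default_config, seed=0)
        learning = [t for t in trials if t.phase == "learning"]
        nll = negative_log_likelihood(learning, AgentParams(0.4, 0.2, 0.0))
        assert nll == pytest.approx(len(learning) * np.log(2.0))

    def test_three_trial_hand_chain(self):
        trials = [
            _make_trial(0, ("A", "B"), "A", 1),
            _make_trial(1, ("A", "B"), "A", 0),
            _make_trial(2, ("A", "B"), "B", 1),
        ]
        params = AgentParams(0.5, 0.25, 4.0)
        expected, _, _ = _oracle_nll_and_trajectory(trials, 0.5, 0.25, 4.0)
        assert negative_log_likelihood(trials, params) == pytest.approx(expected, abs=1e-12)

    def test_oracle_equivalence_random_sequence(self, rng):
        cfg = TaskConfig(n_runs_learning=1, trials_per_run=51, n_runs_transfer=0)
        trials, _ = simulate_agent(AgentParams(0.6, 0.3, 3.0), cfg, seed=17)
        trials = [t for t in trials if t.phase == "learning"][:50]
        params = AgentParams(0.35, 0.15, 7.0)
        oracle, rows, _ = _oracle_nll_and_trajectory(trials, 0.35, 0.15, 7.0)
        assert negative_log_likelihood(trials, params) == pytest.approx(oracle, abs=1e-10)
        traj = compute_trajectory(trials, params)
        np.testing.assert_allclose(traj.q_chosen, rows[:, 0], atol=1e-10)
        np.testing.assert_allclose(traj.q_unchosen, rows[:, 1], atol=1e-10)
        np.testing.assert_allclose(traj.rpe, rows[:, 2], atol=1e-10)

    def test_excluded_rt_dropped_but_updates(self):
        fast = _make_trial(0, ("A", "B"), "A", 1, rt=0.1)  # below the 150 ms floor
        slow = _make_trial(1, ("A", "B"), "A", 1)
        params = AgentParams(0.5, 0.5, 2.0)
        nll = negative_log_likelihood([fast, slow], params)
        # only the second trial scores, with Q already updated to 0.75 by the first
        p = choice_prob(0.75, 0.5, 2.0)
        assert nll == pytest.approx(-np.log(p))

    def test_missing_outcome_raises(self):
        t = _make_trial(0, ("A", "B"), "A", None)
        with pytest.raises(ValueError, match="no outcome"):
            negative_log_likelihood([t], AgentParams(0.5, 0.5, 1.0))


class TestTrajectory:
    def test_initialization(self, default_config, agent_params):
        trials, _ = simulate_agent(agent_params, default_config, seed=2)
        learning = [t for t in trials if t.phase == "learning"]
        traj = compute_trajectory(learning, agent_params)
        assert traj.q_chosen[0] == 0.5
        assert traj.q_unchosen[0] == 0.5
        assert traj.rpe[0] == pytest.approx(learning[0].outcome - 0.5)
        assert np.all(traj.q_by_option[0] == 0.5)

    def test_full_update_tracks_last_outcome(self):
        trials = [
            _make_trial(0, ("A", "B"), "A", 1),
            _make_trial(1, ("A", "B"), "A", 0),
            _make_trial(2, ("A", "B"), "A", 1),
        ]
        traj = compute_trajectory(trials, AgentParams(1.0, 1.0, 1.0))
        np.testing.assert_allclose(traj.q_chosen, [0.5, 1.0, 0.0])

    def test_only_chosen_option_updates(self, default_config, agent_params):
        trials, _ = simulate_agent(agent_params, default_config, seed=3)
        learning = [t for t in trials if t.phase == "learning"]
        traj = compute_trajectory(learning, agent_params)
        opt_idx = {o: i for i, o in enumerate("ABCDEF")}
        for i in range(1, 40):
            changed = np.flatnonzero(traj.q_by_option[i] != traj.q_by_option[i - 1])
            assert set(changed) <= {opt_idx[trials[i - 1].choice]}

    def test_convergence_to_reward_probability(self, rng):
        # fixed option repeatedly chosen: expected terminal Q -> p
        alpha, p, n_seq, n_tr = 0.2, 0.7, 1000, 200
        q = np.full(n_seq, 0.5)
        r = (rng.random((n_seq, n_tr)) < p).astype(float)
        for t in range(n_tr):
            q += alpha * (r[:, t] - q)
        assert abs(q.mean() - p) < 0.05

    def test_batch_nll_matches_scalar(self, default_config):
        subs, params = [], []
        for seed, p in [(0, AgentParams(0.5, 0.2, 8.0)), (1, AgentParams(0.2, 0.6, 2.0))]:
            trials, _ = simulate_agent(p, default_config, seed)
            subs.append([t for t in trials if t.phase == "learning"])
            params.append(p)
        data = encode_trials(subs)
        got = batch_nll(
            data,
            np.array([p.alpha_gain for p in params]),
            np.array([p.alpha_loss for p in params]),
            np.array([p.beta for p in params]),
        )
        want = [negative_log_likelihood(s, p) for s, p in zip(subs, params)]
        np.testing.assert_allclose(got, want, atol=1e-10)


class TestTransferValues:
    def test_lookup(self, default_config, agent_params):
        trials, traj = simulate_agent(agent_params, default_config, seed=11)
        transfer = [t for t in trials if t.phase == "transfer"]
        qc, qu = transfer_values(traj.final_q, transfer)
        t0 = transfer[0]
        assert qc[0] == traj.final_q[t0.choice]

    def test_all_equal_values_give_zero_delta(self, default_config, agent_params):
        trials, _ = simulate_agent(agent_params, default_config, seed=11)
        transfer = [t for t in trials if t.phase == "transfer"]
        final_q = {o: 0.5 for o in "ABCDEF"}
        qc, qu = transfer_values(final_q, transfer)
        np.testing.assert_array_equal(qc - qu, 0.0)

    def test_frozen_across_repeats(self, default_config, agent_params):
        trials, traj = simulate_agent(agent_params, default_config, seed=11)
        transfer = [t for t in trials if t.phase == "transfer"]
        qc, _ = transfer_values(traj.final_q, transfer)
        by_key = {}
        for t, v in zip(transfer, qc):
            by_key.setdefault((t.pair, t.choice), set()).add(v)
        assert all(len(vs) == 1 for vs in by_key.values())

    def test_missing_option_raises(self, default_config, agent_params):
        trials, _ = simulate_agent(agent_params, default_config, seed=11)
        transfer = [t for t in trials if t.phase == "transfer"]
        with pytest.raises(KeyError):
            transfer_values({"A": 0.5}, transfer)
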