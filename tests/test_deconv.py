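import numpy as np
import pytest

from pupilrl.deconv import (
    DEFAULT_LAMBDA_GRID,
    RegressorSpec,
    build_design_matrix,
    cross_validate_lambda,
    deconvolve,
    default_learning_specs,
    default_transfer_specs,
    ridge_solve,
    zscore,
)
from pupilrl.qlearning import AgentParams, transfer_values
from pupilrl.task import TaskConfig, simulate_agent


class TestBuildDesignMatrix:
    def test_single_event_stick_structure(self):
        spec = RegressorSpec("ev", "transient", np.array([2.0]), (0.0, 1.0))
        dm = build_design_matrix([spec], n_samples=100, fs=20.0)
        X = dm.X.toarray()
        assert X.shape == (100, 21)
        assert np.all(X.sum(axis=0) == 1.0)
        # lag 0 column has its 1 at the event sample
        sl, lags = dm.column_slice("ev")
        col0 = X[:, sl][:, lags == 0.0].ravel()
        assert col0[40] == 1.0

    def test_zero_covariate_contributes_nothing(self):
        spec = RegressorSpec(
            "cov", "covariate", np.array([1.0, 2.0]), (0.0, 0.5),
            covariate_values=np.array([0.0, 1.5]),
        )
        dm = build_design_matrix([spec], n_samples=100, fs=20.0)
        X = dm.X.toarray()
        assert np.all(X[15:30] == 0.0)  # nothing around the zero-valued event
        assert X[40:, :].sum() > 0

    def test_boxcar_height_is_inverse_mean_rt(self):
        durations = np.array([1.0, 2.0])
        spec = RegressorSpec("box", "boxcar", np.array([1.0, 5.0]), durations=durations)
        dm = build_design_matrix([spec], n_samples=200, fs=20.0)
        col = dm.X.toarray()[:, 0]
        assert col.max() == pytest.approx(1.0 / 1.5)
        assert (col > 0).sum() == 20 + 40

    def test_self_consistency_oracle(self, rng):
        # y = X @ beta_true recovered exactly by least squares on full-rank designs
        events_a = np.array([1.0, 4.1, 7.3, 10.6])
        events_b = np.array([2.55, 6.2, 9.05])
        specs = [
            RegressorSpec("a", "transient", events_a, (0.0, 0.5)),
            RegressorSpec("b", "transient", events_b, (0.0, 0.5)),
        ]
        dm = build_design_matrix(specs, n_samples=300, fs=20.0)
        beta_true = rng.normal(size=dm.n_columns)
        y = dm.X @ beta_true
        got = ridge_solve(dm, y, lam=0.0)
        Xc = dm.dense_centered()
        # compare in the centered model: projections must agree
        np.testing.assert_allclose(Xc @ got, Xc @ beta_true, atol=1e-8)

    def test_duplicate_names_rejected(self):
        spec = RegressorSpec("x", "transient", np.array([1.0]), (0.0, 0.5))
        with pytest.raises(ValueError, match="unique"):
            build_design_matrix([spec, spec], n_samples=100, fs=20.0)

    def test_event_outside_recording_rejected(self):
        spec = RegressorSpec("x", "transient", np.array([99.0]), (0.0, 0.5))
        with pytest.raises(ValueError, match="outside"):
            build_design_matrix([spec], n_samples=100, fs=20.0)

    def test_window_truncation_warns(self):
        spec = RegressorSpec("x", "transient", np.array([4.8]), (0.0, 1.0))
        with pytest.warns(UserWarning, match="truncated"):
            build_design_matrix([spec], n_samples=100, fs=20.0)


class TestRidgeSolve:
    def test_identity_closed_form(self):
        beta = ridge_solve(np.eye(1), np.array([2.0]), lam=1.0)
        assert beta[0] == pytest.approx(1.0)

    def test_lambda_zero_is_ols(self, rng):
        X = rng.normal(size=(50, 30))
        y = rng.normal(size=50)
        got = ridge_solve(X, y, lam=0.0)
        want = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(got, want, atol=1e-8)

    def test_oracle_direct_inversion(self, rng):
        for _ in range(5):
            X = rng.normal(size=(50, 30))
            y = rng.normal(size=50)
            lam = rng.uniform(0.01, 1.0)
            want = np.linalg.inv(X.T @ X + lam * np.eye(30)) @ X.T @ y
            np.testing.assert_allclose(ridge_solve(X, y, lam), want, atol=1e-8)

    def test_shrinkage_monotone_in_lambda(self, rng):
        X = rng.normal(size=(60, 20))
        y = rng.normal(size=60)
        norms = [np.linalg.norm(ridge_solve(X, y, lam)) for lam in [0.0, 0.1, 0.5, 1.0, 10.0]]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_large_lambda_shrinks_to_zero(self, rng):
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        assert np.linalg.norm(ridge_solve(X, y, lam=1e9)) < 1e-5

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            ridge_solve(np.eye(2), np.zeros(2), lam=-0.1)


class TestCrossValidateLambda:
    def test_collinear_noisy_prefers_positive_lambda(self, rng):
        hits = 0
        for rep in range(7):
            r = np.random.default_rng(100 + rep)
            base = r.normal(size=(400, 4))
            X = np.column_stack([base, base + 0.01 * r.normal(size=(400, 4))])
            beta = r.normal(size=8)
            y = X @ beta + 2.0 * r.normal(size=400)
            lam, _ = cross_validate_lambda(X, y, seed=rep)
            hits += lam > 0
        assert hits >= 4

    def test_orthonormal_noiseless_selects_zero(self, rng):
        X = np.linalg.qr(rng.normal(size=(200, 10)))[0]
        Xc = X - X.mean(axis=0)
        y = Xc @ rng.normal(size=10)
        lam, scores = cross_validate_lambda(Xc, y, seed=0)
        assert lam == 0.0

    def test_deterministic(self, rng):
        X = rng.normal(size=(150, 10))
        y = rng.normal(size=150)
        a = cross_validate_lambda(X, y, seed=42)
        b = cross_validate_lambda(X, y, seed=42)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1], b[1])

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            cross_validate_lambda(np.eye(10), np.zeros(10), grid=np.array([]))

    def test_grid_outside_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            cross_validate_lambda(np.eye(10), np.zeros(10), grid=np.array([2.0]))


@pytest.fixture(scope="module")
def lti_session():
    """Small noiseless LTI session with the default learning design."""
    from pupilrl.preproc import PupilTimeSeries
    from pupilrl.synth import SynthSpec, generate_session

    config = TaskConfig(n_runs_learning=2, n_runs_transfer=1)
    trials, traj = simulate_agent(AgentParams(0.5, 0.2, 8.0), config, seed=21)
    spec = SynthSpec(noise_sd=0.0, blink_rate=0.0, saccade_rate=0.0)
    raw, _, truth = generate_session(trials, traj, spec, seed=5, config=config)
    parts = []
    for run in np.unique(raw.run_id):
        m = raw.run_id == run
        parts.append((raw.times[m][::5], raw.values[m][::5] - spec.baseline, raw.run_id[m][::5]))
    ts20 = PupilTimeSeries(
        np.concatenate([p[0] for p in parts]),
        np.concatenate([p[1] for p in parts]),
        20.0,
        np.concatenate([p[2] for p in parts]),
    )
    return config, trials, traj, ts20, truth


class TestDeconvolve:
    def test_noiseless_recovery(self, lti_session):
        from pupilrl.preproc import PupilTimeSeries

        config, trials, traj, ts20, truth = lti_session
        learning = [t for t in trials if t.phase == "learning"]
        m = np.isin(ts20.run_id, sorted({t.run_index for t in learning}))
        tsl = PupilTimeSeries(ts20.times[m], ts20.values[m], 20.0, ts20.run_id[m])
        res = deconvolve(tsl, default_learning_specs(learning, traj), lam=0.0)
        for name in ("options_on", "choice", "feedback", "q_chosen_choice", "rpe_fb"):
            bt = truth["learning"]["betas"][name]
            assert np.corrcoef(bt, res.betas[name])[0, 1] > 0.99

    def test_zero_covariate_betas_stay_zero(self, lti_session):
        from pupilrl.preproc import PupilTimeSeries

        config, trials, traj, ts20, truth = lti_session
        learning = [t for t in trials if t.phase == "learning"]
        m = np.isin(ts20.run_id, sorted({t.run_index for t in learning}))
        tsl = PupilTimeSeries(ts20.times[m], ts20.values[m], 20.0, ts20.run_id[m])
        res = deconvolve(tsl, default_learning_specs(learning, traj), lam=0.0)
        # q_unchosen_choice planted at zero amplitude
        assert np.abs(res.betas["q_unchosen_choice"]).max() < 1e-6

    def test_all_zero_signal(self, lti_session):
        config, trials, traj, _, _ = lti_session
        learning = [t for t in trials if t.phase == "learning"]
        specs = default_learning_specs(learning, traj)
        n = int((max(t.t_options_off for t in learning) + 5) * 20)
        y = np.zeros(n)
        res = deconvolve(y, specs, fs=20.0, lam=0.1)
        for b in res.betas.values():
            np.testing.assert_allclose(b, 0.0, atol=1e-10)

    def test_transfer_null_covariate(self, lti_session):
        from pupilrl.preproc import PupilTimeSeries

        config, trials, traj, ts20, truth = lti_session
        transfer = [t for t in trials if t.phase == "transfer"]
        qc, qu = transfer_values(traj.final_q, transfer)
        m = np.isin(ts20.run_id, sorted({t.run_index for t in transfer}))
        tst = PupilTimeSeries(ts20.times[m], ts20.values[m], 20.0, ts20.run_id[m])
        res = deconvolve(tst, default_transfer_specs(transfer, qc, qu, config), lam=0.0)
        assert np.abs(res.betas["q_chosen_choice"]).max() < 1e-6

    def test_delta_value_course(self, lti_session):
        from pupilrl.preproc import PupilTimeSeries

        config, trials, traj, ts20, _ = lti_session
        learning = [t for t in trials if t.phase == "learning"]
        m = np.isin(ts20.run_id, sorted({t.run_index for t in learning}))
        tsl = PupilTimeSeries(ts20.times[m], ts20.values[m], 20.0, ts20.run_id[m])
        res = deconvolve(tsl, default_learning_specs(learning, traj), lam=0.0)
        dv = res.delta_value_course("q_chosen_choice", "q_unchosen_choice")
        np.testing.assert_allclose(
            dv, res.betas["q_chosen_choice"] - res.betas["q_unchosen_choice"]
        )


class TestDefaultSpecs:
    def test_learning_design_composition(self, lti_session):
        _, trials, traj, _, _ = lti_session
        learning = [t for t in trials if t.phase == "learning"]
        specs = {s.name: s for s in default_learning_specs(learning, traj)}
        assert specs["options_on"].window == (-0.5, 3.0)
        assert specs["choice"].window == (-2.0, 1.5)
        assert specs["feedback"].window == (-0.5, 3.0)
        assert specs["decision_boxcar"].kind == "boxcar"
        assert {"fixation", "options_off"} <= set(specs)
        for cov in ("q_chosen_choice", "q_unchosen_choice", "q_chosen_fb", "q_unchosen_fb", "rpe_fb"):
            assert specs[cov].kind == "covariate"
            assert specs[cov].covariate_values.mean() == pytest.approx(0.0, abs=1e-9)
            assert specs[cov].covariate_values.std() == pytest.approx(1.0, abs=1e-9)

    def test_transfer_design_composition(self, lti_session):
        config, trials, traj, _, _ = lti_session
        transfer = [t for t in trials if t.phase == "transfer"]
        qc, qu = transfer_values(traj.final_q, transfer)
        names = {s.name for s in default_transfer_specs(transfer, qc, qu, config)}
        assert "feedback" not in names
        assert "rpe_fb" not in names
        assert any(n.startswith("conflict_") for n in names)

    def test_zscore_degenerate(self):
        np.testing.assert_array_equal(zscore(np.full(5, 3.0)), np.zeros(5))
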