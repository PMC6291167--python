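"""Core Q-learning computations: value updates, softmax choice, likelihood, trajectories.

Values start at 0.5 for every option, only the chosen option is updated, and
positive/negative outcomes use separate learning rates.  Trajectories report
the *pre-update* values (the beliefs that drove each choice), so the signed
prediction error is simply ``outcome - q_chosen``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AgentParams",
    "QTrajectory",
    "update_q",
    "choice_prob",
    "negative_log_likelihood",
    "compute_trajectory",
    "transfer_values",
    "EncodedTrials",
    "encode_trials",
    "batch_nll",
]

Q_INIT = 0.5
_OPT_INDEX = {o: i for i, o in enumerate("ABCDEF")}


@dataclass(frozen=True)
class AgentParams:
    """Subject-level parameters: gain/loss learning rates and softmax inverse temperature."""

    alpha_gain: float
    alpha_loss: float
    beta: float

    def validate(self) -> None:
        if not (0.0 <= self.alpha_gain <= 1.0):
            raise ValueError(f"alpha_gain out of [0, 1]: {self.alpha_gain}")
        if not (0.0 <= self.alpha_loss <= 1.0):
            raise ValueError(f"alpha_loss out of [0, 1]: {self.alpha_loss}")
        if not (0.0 <= self.beta <= 100.0):
            raise ValueError(f"beta out of [0, 100]: {self.beta}")


@dataclass
class QTrajectory:
    """Per-trial covariates for the learning phase, plus the end-of-learning values."""

    q_chosen: np.ndarray
    q_unchosen: np.ndarray
    rpe: np.ndarray
    q_by_option: np.ndarray  # (n_trials, 6), pre-update values
    final_q: dict[str, float] = field(default_factory=dict)

    @property
    def delta_value(self) -> np.ndarray:
        return self.q_chosen - self.q_unchosen

    def __len__(self) -> int:
        return len(self.q_chosen)


def update_q(q: float, r: int, params: AgentParams) -> float:
    """One value update: q + alpha_gain*(r - q) if rewarded, alpha_loss*(r - q) otherwise."""
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q out of [0, 1]: {q}")
    if r not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1, got {r!r}")
    alpha = params.alpha_gain if r == 1 else params.alpha_loss
    return q + alpha * (r - q)


def choice_prob(q_a: float, q_b: float, beta: float) -> float:
    """Softmax probability of choosing A over B, computed with max-subtraction.

    Stable at beta = 100 where the naive exponentials overflow.
    """
    za, zb = beta * q_a, beta * q_b
    m = max(za, zb)
    ea, eb = np.exp(za - m), np.exp(zb - m)
    return float(ea / (ea + eb))


def _log_choice_prob(q_c: float, q_u: float, beta: float) -> float:
    # log P(chosen) = -log(1 + exp(beta*(q_u - q_c)))
    return float(-np.logaddexp(0.0, beta * (q_u - q_c)))


def _check_learning_order(trials) -> None:
    idx = [t.trial_index for t in trials]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValueError("learning trials must be in session order")


def negative_log_likelihood(
    trials,
    params: AgentParams,
    rt_floor: float = 0.15,
    rt_deadline: float = 3.5,
) -> float:
    """-sum log P(choice) over learning trials with in-window RTs.

    Trials with out-of-window RTs are dropped from the likelihood, but their
    outcomes still update the Q-values (the agent experienced the feedback).
    """
    _check_learning_order(trials)
    q = np.full(6, Q_INIT)
    nll = 0.0
    for t in trials:
        if t.outcome is None:
            raise ValueError(f"trial {t.trial_index} has no outcome")
        a, b = t.pair
        c = t.choice
        u = b if c == a else a
        qc, qu = q[_OPT_INDEX[c]], q[_OPT_INDEX[u]]
        if rt_floor <= t.rt <= rt_deadline:
            nll -= _log_choice_prob(qc, qu, params.beta)
        q[_OPT_INDEX[c]] = update_q(qc, t.outcome, params)
    return float(nll)


def compute_trajectory(trials, params: AgentParams) -> QTrajectory:
    """Evolve Q-values over the learning phase and collect per-trial covariates."""
    _check_learning_order(trials)
    n = len(trials)
    q = np.full(6, Q_INIT)
    q_c = np.empty(n)
    q_u = np.empty(n)
    rpe = np.empty(n)
    q_by = np.empty((n, 6))
    for i, t in enumerate(trials):
        if t.outcome is None:
            raise ValueError(f"trial {t.trial_index} has no outcome")
        a, b = t.pair
        c = t.choice
        u = b if c == a else a
        q_by[i] = q
        q_c[i] = q[_OPT_INDEX[c]]
        q_u[i] = q[_OPT_INDEX[u]]
        rpe[i] = t.outcome - q_c[i]
        q[_OPT_INDEX[c]] = update_q(q_c[i], t.outcome, params)
    final_q = {o: float(q[i]) for o, i in _OPT_INDEX.items()}
    return QTrajectory(q_chosen=q_c, q_unchosen=q_u, rpe=rpe, q_by_option=q_by, final_q=final_q)


def transfer_values(final_q: dict[str, float], transfer_trials) -> tuple[np.ndarray, np.ndarray]:
    """Look up frozen end-of-learning values for each transfer choice; no updating."""
    q_c = np.empty(len(transfer_trials))
    q_u = np.empty(len(transfer_trials))
    for i, t in enumerate(transfer_trials):
        a, b = t.pair
        c = t.choice
        u = b if c == a else a
        if c not in final_q or u not in final_q:
            raise KeyError(f"option missing from final_q on trial {t.trial_index}")
        q_c[i] = final_q[c]
        q_u[i] = final_q[u]
    return q_c, q_u


# ---------------------------------------------------------------------------
# Vectorized likelihood over a cohort (used by the hierarchical sampler).


@dataclass
class EncodedTrials:
    """Learning trials of one or more subjects packed into integer arrays.

    All arrays have shape (n_subjects, n_trials); subjects must share the trial
    count (true for the simulated task, where no trials are omitted).
    """

    chosen: np.ndarray  # option index 0..5
    unchosen: np.ndarray
    outcome: np.ndarray  # 0/1
    include: np.ndarray  # bool, RT within window

    @property
    def n_subjects(self) -> int:
        return self.chosen.shape[0]

    @property
    def n_modeled(self) -> np.ndarray:
        return self.include.sum(axis=1)


def encode_trials(subject_trials, rt_floor: float = 0.15, rt_deadline: float = 3.5) -> EncodedTrials:
    if subject_trials and not isinstance(subject_trials[0], list):
        subject_trials = [subject_trials]
    counts = {len(s) for s in subject_trials}
    if len(counts) != 1:
        raise ValueError("all subjects must have the same number of learning trials")
    n_subj, n_tr = len(subject_trials), counts.pop()
    chosen = np.empty((n_subj, n_tr), dtype=np.int64)
    unchosen = np.empty_like(chosen)
    outcome = np.empty_like(chosen)
    include = np.empty((n_subj, n_tr), dtype=bool)
    for s, trials in enumerate(subject_trials):
        _check_learning_order(trials)
        for i, t in enumerate(trials):
            a, b = t.pair
            c = t.choice
            u = b if c == a else a
            chosen[s, i] = _OPT_INDEX[c]
            unchosen[s, i] = _OPT_INDEX[u]
            outcome[s, i] = t.outcome
            include[s, i] = rt_floor <= t.rt <= rt_deadline
    return EncodedTrials(chosen, unchosen, outcome, include)


def batch_nll(
    data: EncodedTrials,
    alpha_gain: np.ndarray,
    alpha_loss: np.ndarray,
    beta: np.ndarray,
) -> np.ndarray:
    """Per-subject negative log likelihood, vectorized across subjects.

    Parameters are arrays of shape (n_subjects,).  Matches
    :func:`negative_log_likelihood` applied subject by subject.
    """
    n_subj, n_tr = data.chosen.shape
    rows = np.arange(n_subj)
    q = np.full((n_subj, 6), Q_INIT)
    nll = np.zeros(n_subj)
    for t in range(n_tr):
        c = data.chosen[:, t]
        u = data.unchosen[:, t]
        qc = q[rows, c]
        qu = q[rows, u]
        logp = -np.logaddexp(0.0, beta * (qu - qc))
        nll -= np.where(data.include[:, t], logp, 0.0)
        r = data.outcome[:, t]
        lr = np.where(r == 1, alpha_gain, alpha_loss)
        q[rows, c] = qc + lr * (r - qc)
    return nll
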