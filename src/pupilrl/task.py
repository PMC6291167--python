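"""Probabilistic selection task: schedules, feedback sampling and agent simulation.

The task presents three fixed option pairs during learning (high-probability
option rewarded 80/70/60% of the time) and all 15 unordered pairs during a
no-feedback transfer phase.  Schedules carry a full set of per-trial event
timestamps on a single session clock so that downstream pupil modules can lock
regressors to fixation onset, option onset, choice, feedback and option offset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .qlearning import AgentParams, QTrajectory, choice_prob, compute_trajectory, update_q

OPTIONS = ("A", "B", "C", "D", "E", "F")

__all__ = [
    "OPTIONS",
    "PairSpec",
    "EventTiming",
    "TaskConfig",
    "TrialRecord",
    "build_schedule",
    "sample_feedback",
    "simulate_agent",
    "run_spans",
]


@dataclass(frozen=True)
class PairSpec:
    """One learning pair: the high-probability option, its partner, and p(reward | high)."""

    hi: str
    lo: str
    p_hi: float

    @property
    def name(self) -> str:
        return self.hi + self.lo

    def members(self) -> tuple[str, str]:
        return (self.hi, self.lo)


@dataclass(frozen=True)
class EventTiming:
    """Gaussian means/SDs (seconds) for the within-trial event intervals."""

    fix_mean: float = 0.5
    fix_sd: float = 0.2
    fb_delay_mean: float = 1.5
    fb_delay_sd: float = 0.3
    iti_mean: float = 3.0
    iti_sd: float = 0.3
    # jittered so the options-off event is not sample-locked to feedback/choice
    fb_duration: float = 0.5
    fb_duration_sd: float = 0.1
    run_break: float = 20.0  # pause between runs; keeps padded run spans disjoint


def _default_pairs() -> list[PairSpec]:
    return [PairSpec("A", "B", 0.8), PairSpec("C", "D", 0.7), PairSpec("E", "F", 0.6)]


def _all_unordered_pairs() -> list[tuple[str, str]]:
    return list(itertools.combinations(OPTIONS, 2))


@dataclass
class TaskConfig:
    pairs: list[PairSpec] = field(default_factory=_default_pairs)
    reward_magnitude: float = 0.1
    n_runs_learning: int = 6
    trials_per_run: int = 60
    n_runs_transfer: int = 5
    transfer_pairs: list[tuple[str, str]] = field(default_factory=_all_unordered_pairs)
    rt_deadline: float = 3.5
    rt_floor: float = 0.15
    timing: EventTiming = field(default_factory=EventTiming)
    # simulated RT model (log-normal, truncated to [rt_floor, rt_deadline])
    rt_median: float = 0.8
    rt_sigma: float = 0.3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.pairs:
            raise ValueError("at least one option pair is required")
        for p in self.pairs:
            if not (0.5 < p.p_hi <= 1.0):
                raise ValueError(f"p_reward_hi must be in (0.5, 1.0], got {p.p_hi} for {p.name}")
        if self.trials_per_run % len(self.pairs) != 0:
            raise ValueError(
                f"trials_per_run={self.trials_per_run} not divisible by {len(self.pairs)} pairs"
            )
        if self.n_runs_transfer > 0 and self.trials_per_run % len(self.transfer_pairs) != 0:
            raise ValueError(
                f"trials_per_run={self.trials_per_run} not divisible by "
                f"{len(self.transfer_pairs)} transfer pairs"
            )
        if not (0 <= self.rt_floor < self.rt_deadline):
            raise ValueError("rt_floor must be non-negative and below rt_deadline")

    def pair_by_name(self, name: str) -> PairSpec:
        for p in self.pairs:
            if p.name == name or p.name == name[::-1]:
                return p
        raise KeyError(f"unknown learning pair {name!r}")

    def option_probability(self, option: str) -> float:
        """Experimental reward probability of a single option (complement for low options)."""
        for p in self.pairs:
            if option == p.hi:
                return p.p_hi
            if option == p.lo:
                return 1.0 - p.p_hi
        raise KeyError(f"option {option!r} not part of any configured pair")


@dataclass
class TrialRecord:
    """One task trial; ``choice``/``outcome`` are None on schedule skeletons.

    Transfer trials never carry an outcome or a feedback timestamp.
    """

    phase: str  # "learning" | "transfer"
    run_index: int
    trial_index: int
    pair: tuple[str, str]
    choice: str | None
    outcome: int | None
    rt: float
    t_fixation: float
    t_options_on: float
    t_choice: float
    t_feedback: float  # nan for transfer trials
    t_options_off: float
    side_left: str = ""

    @property
    def pair_name(self) -> str:
        return "".join(self.pair)

    def validate(self) -> None:
        if self.phase not in ("learning", "transfer"):
            raise ValueError(f"bad phase {self.phase!r}")
        if abs((self.t_choice - self.t_options_on) - self.rt) > 1e-9:
            raise ValueError("rt must equal t_choice - t_options_on")
        stamps = [self.t_fixation, self.t_options_on, self.t_choice]
        if self.phase == "learning":
            stamps.append(self.t_feedback)
        stamps.append(self.t_options_off)
        if not all(b > a for a, b in zip(stamps, stamps[1:])):
            raise ValueError("timestamps must be strictly increasing within a trial")
        if self.phase == "transfer" and self.outcome is not None:
            raise ValueError("transfer trials cannot have an outcome")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float = 0.05) -> float:
    x = rng.normal(mean, sd)
    return float(max(x, lo))


def _draw_rt(rng: np.random.Generator, config: TaskConfig) -> float:
    while True:
        rt = float(np.exp(np.log(config.rt_median) + config.rt_sigma * rng.standard_normal()))
        if config.rt_floor <= rt <= config.rt_deadline:
            return rt


def build_schedule(config: TaskConfig, seed: int) -> list[TrialRecord]:
    """Build the full session schedule: pair order and event timestamps, no choices.

    Pair order is a per-run shuffle of a balanced pair list, which guarantees
    the exact per-pair presentation counts.  All timestamps live on one
    continuous session clock.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    clock = 0.0
    tm = config.timing

    def emit(phase: str, run: int, idx: int, pair: tuple[str, str], clock: float) -> tuple[TrialRecord, float]:
        t_fix = clock
        t_on = t_fix + _trunc_normal(rng, tm.fix_mean, tm.fix_sd)
        rt = _draw_rt(rng, config)
        t_choice = t_on + rt
        if phase == "learning":
            t_fb = t_choice + _trunc_normal(rng, tm.fb_delay_mean, tm.fb_delay_sd)
            t_off = t_fb + _trunc_normal(rng, tm.fb_duration, tm.fb_duration_sd)
        else:
            t_fb = float("nan")
            t_off = t_choice + _trunc_normal(rng, tm.fb_duration, tm.fb_duration_sd)
        side_left = pair[rng.integers(2)]
        rec = TrialRecord(
            phase=phase, run_index=run, trial_index=idx, pair=pair,
            choice=None, outcome=None, rt=rt,
            t_fixation=t_fix, t_options_on=t_on, t_choice=t_choice,
            t_feedback=t_fb, t_options_off=t_off, side_left=side_left,
        )
        clock = t_off + _trunc_normal(rng, tm.iti_mean, tm.iti_sd)
        return rec, clock

    idx = 0
    for run in range(config.n_runs_learning):
        if run > 0:
            clock += tm.run_break
        reps = config.trials_per_run // len(config.pairs)
        order = [p.members() for p in config.pairs] * reps
        rng.shuffle(order)  # type: ignore[arg-type]
        for pair in order:
            rec, clock = emit("learning", run, idx, tuple(pair), clock)
            trials.append(rec)
            idx += 1

    for run in range(config.n_runs_transfer):
        clock += tm.run_break
        reps = config.trials_per_run // len(config.transfer_pairs)
        order = list(config.transfer_pairs) * reps
        rng.shuffle(order)  # type: ignore[arg-type]
        for pair in order:
            rec, clock = emit("transfer", config.n_runs_learning + run, idx, tuple(pair), clock)
            trials.append(rec)
            idx += 1

    return trials


def sample_feedback(
    pair: PairSpec, choice: str, config: TaskConfig, rng: np.random.Generator
) -> int:
    """Bernoulli reward draw: p = p_hi for the pair's high option, 1 - p_hi otherwise."""
    if choice not in pair.members():
        raise ValueError(f"choice {choice!r} not in pair {pair.name}")
    p = pair.p_hi if choice == pair.hi else 1.0 - pair.p_hi
    return int(rng.random() < p)


def simulate_agent(
    params: AgentParams, config: TaskConfig, seed: int
) -> tuple[list[TrialRecord], QTrajectory]:
    """Simulate a softmax Q-learning agent on a freshly built schedule.

    Learning-phase choices come from the softmax over the current Q-values of
    the presented pair; each outcome updates the chosen option's Q.  Transfer
    choices use the frozen end-of-learning Q-values and receive no feedback.
    """
    params.validate()
    schedule = build_schedule(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA6E27]))

    q = {opt: 0.5 for opt in OPTIONS}
    out: list[TrialRecord] = []
    for rec in schedule:
        a, b = rec.pair
        p_a = choice_prob(q[a], q[b], params.beta)
        choice = a if rng.random() < p_a else b
        if rec.phase == "learning":
            pair_spec = config.pair_by_name(rec.pair_name)
            r = sample_feedback(pair_spec, choice, config, rng)
            out.append(replace(rec, choice=choice, outcome=r))
            q[choice] = update_q(q[choice], r, params)
        else:
            out.append(replace(rec, choice=choice, outcome=None))

    learning = [t for t in out if t.phase == "learning"]
    traj = compute_trajectory(learning, params)
    return out, traj


def run_spans(trials: list[TrialRecord], pad_pre: float = 2.0, pad_post: float = 4.0):
    """(run_index, t_start, t_end) per run, padded around the first/last trial events."""
    spans = []
    for run in sorted({t.run_index for t in trials}):
        rs = [t for t in trials if t.run_index == run]
        t0 = min(t.t_fixation for t in rs) - pad_pre
        t1 = max(t.t_options_off for t in rs) + pad_post
        spans.append((run, t0, t1))
    return spans
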