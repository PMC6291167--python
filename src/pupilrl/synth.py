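"""Synthetic pupil recordings with known ground truth.

Sessions are generated from the same linear time-invariant event model the
deconvolution assumes: every design-matrix column contributes its ground-truth
response time course, covariate amplitudes are planted effect sizes, and the
signal is completed with 1/f background noise, IRF-shaped blink/saccade
nuisance responses, and sharp blink artifacts.  Because the signal is exactly
``X @ beta_true`` plus additive nuisance terms, recovery can be tested at any
noise level, down to machine precision when noise is switched off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import deconv as dc
from .hierfit import to_native
from .preproc import Annotations, IRFParams, PupilTimeSeries, pupil_irf
from .qlearning import transfer_values
from .task import TaskConfig, run_spans, simulate_agent

__all__ = ["SynthSpec", "generate_session", "generate_cohort", "colored_noise"]


def _default_effects() -> dict[str, float]:
    # Planted sign pattern: positive pre-choice chosen-value slope, opposite
    # chosen/unchosen slopes on the early feedback dilation, negative slope of
    # the late feedback component on signed prediction errors, and no value
    # modulation in the transfer phase.
    return {
        "q_chosen_choice": 0.3,
        "q_unchosen_choice": 0.0,
        "q_chosen_fb": -0.2,
        "q_unchosen_fb": 0.2,
        "rpe_fb": -0.3,
        "q_chosen_choice_transfer": 0.0,
        "q_unchosen_choice_transfer": 0.0,
    }


def _default_gains() -> dict[str, float]:
    return {
        "options_on": 0.3,
        "choice": 0.4,
        "feedback_early": 0.5,
        "feedback_late": -0.65,
        "fixation": 0.1,
        "options_off": 0.1,
        "conflict_large": 0.3,
        "conflict_medium": 0.2,
        "conflict_small": 0.1,
    }


@dataclass
class SynthSpec:
    irf: IRFParams = field(default_factory=IRFParams)
    effect_sizes: dict[str, float] = field(default_factory=_default_effects)
    base_gains: dict[str, float] = field(default_factory=_default_gains)
    boxcar_amplitude: float = 0.2  # sustained z-units during the decision interval
    noise_sd: float = 0.5
    noise_exponent: float = 1.0
    blink_rate: float = 3.0  # events / minute
    saccade_rate: float = 6.0  # events / minute
    big_saccade_frac: float = 0.05  # fraction of saccades exceeding the rejection threshold
    blink_drop: float = 4.0  # artifact depth in raw units
    blink_gain: float = -0.3  # IRF-shaped nuisance response gains
    saccade_gain: float = -0.1
    fs_raw: float = 100.0
    baseline: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.blink_rate < 0 or self.saccade_rate < 0:
            raise ValueError("event rates must be non-negative")


def colored_noise(n: int, exponent: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, scaled to ``sd``."""
    if sd == 0.0 or n < 2:
        return np.zeros(n)
    white = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(white * scale, n)
    return x / x.std() * sd


def _erlang(lags: np.ndarray, t_max: float, w: float) -> np.ndarray:
    h = np.where(lags > 0, lags, 0.0)
    out = h**w * np.exp(-w * h / t_max)
    return out / (t_max**w * np.exp(-w))


def _kernel(name: str, lags: np.ndarray, spec: SynthSpec) -> np.ndarray:
    """Ground-truth response shape (peak ~1) for a named regressor."""
    g = spec.base_gains
    if name in ("options_on", "fixation", "options_off"):
        return _erlang(lags, spec.irf.t_max, spec.irf.w)
    if name == "choice" or name.startswith("q_") and name.endswith("choice"):
        # dilation building up before the behavioral report
        return _erlang(lags + 2.0, 1.2, 6.0)
    if name == "feedback":
        return (
            g["feedback_early"] * _erlang(lags, 0.8, 8.0)
            + g["feedback_late"] * _erlang(lags, 2.2, 6.0)
        )
    if name in ("q_chosen_fb", "q_unchosen_fb"):
        return _erlang(lags, 0.8, 8.0)  # early dilation component
    if name == "rpe_fb":
        return _erlang(lags, 2.2, 6.0)  # late constriction component
    if name.startswith("conflict_"):
        return _erlang(lags, 0.9, 8.0)  # post-choice dilation
    raise KeyError(f"no ground-truth kernel for regressor {name!r}")


def _true_beta(name: str, lags: np.ndarray, spec: SynthSpec, phase: str, mean_rt: float) -> np.ndarray:
    if name == "decision_boxcar":
        # design column height is 1/mean(RT); planted sustained level is boxcar_amplitude
        return np.array([spec.boxcar_amplitude * mean_rt])
    shape = _kernel(name, lags, spec)
    if name == "feedback":
        return shape  # gains already folded in
    if name in ("options_on", "choice", "fixation", "options_off") or name.startswith("conflict_"):
        return spec.base_gains[name] * shape
    key = name + ("_transfer" if phase == "transfer" else "")
    es = spec.effect_sizes.get(key, spec.effect_sizes.get(name, 0.0))
    return es * shape


def _phase_truth(dm: dc.DesignMatrix, spec: SynthSpec, phase: str, mean_rt: float):
    betas: dict[str, np.ndarray] = {}
    lags: dict[str, np.ndarray] = {}
    vec = np.empty(dm.n_columns)
    for name in dm.regressor_names():
        sl, lag = dm.column_slice(name)
        b = _true_beta(name, lag, spec, phase, mean_rt)
        betas[name] = b
        lags[name] = lag
        vec[sl] = b
    return vec, betas, lags


def generate_session(
    trials,
    trajectory,
    spec: SynthSpec,
    seed: int,
    config: TaskConfig,
):
    """Synthesize one subject's raw pupil recording plus its ground truth.

    Returns ``(raw, annotations, truth)`` where ``truth`` maps phase ->
    {"betas": {...}, "lags": {...}} in the exact shape of deconvolution output.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5D11]))
    spans = run_spans(trials)
    if max(t.t_options_off for t in trials) > spans[-1][2]:
        raise ValueError("events extend beyond the session duration")

    # analysis-rate grid on which the LTI signal is composed
    fs = 20.0
    times20, runs20 = [], []
    for run, t0, t1 in spans:
        n = int(np.floor((t1 - t0) * fs)) + 1
        times20.append(t0 + np.arange(n) / fs)
        runs20.append(np.full(n, run, dtype=np.int64))
    times20 = np.concatenate(times20)
    runs20 = np.concatenate(runs20)
    y20 = np.zeros(len(times20))

    truth: dict[str, dict] = {}
    learning = [t for t in trials if t.phase == "learning"]
    transfer = [t for t in trials if t.phase == "transfer"]
    if learning:
        specs = dc.default_learning_specs(trials, trajectory)
        dm = dc.build_design_matrix(specs, len(times20), fs=fs, times=times20)
        mean_rt = float(np.mean([t.rt for t in learning]))
        vec, betas, lags = _phase_truth(dm, spec, "learning", mean_rt)
        y20 += dm.X @ vec
        truth["learning"] = {"betas": betas, "lags": lags}
    if transfer:
        qc, qu = transfer_values(trajectory.final_q, transfer)
        specs = dc.default_transfer_specs(trials, qc, qu, config)
        dm = dc.build_design_matrix(specs, len(times20), fs=fs, times=times20)
        mean_rt = float(np.mean([t.rt for t in transfer]))
        vec, betas, lags = _phase_truth(dm, spec, "transfer", mean_rt)
        y20 += dm.X @ vec
        truth["transfer"] = {"betas": betas, "lags": lags}

    # upsample the composed signal to the raw recording rate, per run
    times_raw, vals_raw, runs_raw = [], [], []
    annotations = Annotations()
    for run, t0, t1 in spans:
        n = int(np.floor((t1 - t0) * spec.fs_raw)) + 1
        t = t0 + np.arange(n) / spec.fs_raw
        sel = runs20 == run
        v = np.interp(t, times20[sel], y20[sel])
        v = v + colored_noise(n, spec.noise_exponent, spec.noise_sd, rng)
        dur_min = (t1 - t0) / 60.0

        # nuisance events: IRF-shaped responses plus, for blinks, a sharp artifact
        n_blinks = rng.poisson(spec.blink_rate * dur_min)
        n_sacc = rng.poisson(spec.saccade_rate * dur_min)
        blink_starts = np.sort(rng.uniform(t0 + 1.0, t1 - 2.0, n_blinks))
        kernel = pupil_irf(spec.fs_raw, spec.irf)
        for bs in blink_starts:
            b_dur = rng.uniform(0.1, 0.3)
            be = bs + b_dur
            annotations.blinks.append((float(bs), float(be)))
            i0 = int(round((be - t0) * spec.fs_raw))
            seg = v[i0 : i0 + len(kernel)]
            seg += spec.blink_gain * kernel[: len(seg)]
            j0 = int(round((bs - t0) * spec.fs_raw))
            j1 = int(round((be - t0) * spec.fs_raw))
            v[max(j0, 0) : min(j1 + 1, n)] -= spec.blink_drop
        sacc_times = np.sort(rng.uniform(t0 + 1.0, t1 - 2.0, n_sacc))
        for st in sacc_times:
            big = rng.random() < spec.big_saccade_frac
            amp = float(rng.uniform(3.5, 6.0)) if big else float(np.exp(rng.normal(0.0, 0.5)))
            annotations.saccades.append((float(st), amp))
            i0 = int(round((st - t0) * spec.fs_raw))
            seg = v[i0 : i0 + len(kernel)]
            seg += spec.saccade_gain * kernel[: len(seg)]

        times_raw.append(t)
        vals_raw.append(spec.baseline + v)
        runs_raw.append(np.full(n, run, dtype=np.int64))

    raw = PupilTimeSeries(
        np.concatenate(times_raw),
        np.concatenate(vals_raw),
        spec.fs_raw,
        np.concatenate(runs_raw),
    )
    return raw, annotations, truth


def generate_cohort(
    n_subjects: int = 34,
    group_mu=(0.0, 0.0, 0.0),
    group_delta=(1.2, 1.2, 1.2),
    config: TaskConfig | None = None,
    spec: SynthSpec | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> list[dict]:
    """Sample agents from the probit-normal hierarchy and synthesize a cohort.

    Returns one record per subject with the simulated behavior, raw pupil
    recording, annotations, ground-truth betas and generating parameters.
    With ``outdir`` the cohort is also written in the pipeline's interchange
    formats with a JSON manifest.
    """
    from . import io as pio

    config = config or TaskConfig()
    spec = spec or SynthSpec()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0407]))
    sub_seeds = rng.integers(0, 2**31 - 1, size=(n_subjects, 2))

    records = []
    for s in range(n_subjects):
        z = np.asarray(group_mu) + np.asarray(group_delta) * rng.standard_normal(3)
        params = to_native(z)
        trials, traj = simulate_agent(params, config, int(sub_seeds[s, 0]))
        raw, annotations, truth = generate_session(trials, traj, spec, int(sub_seeds[s, 1]), config)
        records.append({
            "subject": s,
            "params": params,
            "z_true": z,
            "trials": trials,
            "trajectory": traj,
            "pupil": raw,
            "annotations": annotations,
            "truth": truth,
        })

    if outdir is not None:
        outdir = Path(outdir)
        manifest = {"n_subjects": n_subjects, "seed": seed, "subjects": []}
        for rec in records:
            sdir = outdir / f"sub-{rec['subject']:02d}"
            sdir.mkdir(parents=True, exist_ok=True)
            pio.write_trials(sdir / "trials.tsv", rec["trials"])
            pio.write_pupil(sdir / "pupil.tsv", rec["pupil"])
            pio.write_annotations(sdir / "annotations.tsv", rec["annotations"])
            p = rec["params"]
            manifest["subjects"].append({
                "subject": rec["subject"],
                "dir": sdir.name,
                "alpha_gain": p.alpha_gain,
                "alpha_loss": p.alpha_loss,
                "beta": p.beta,
                "effect_sizes": spec.effect_sizes,
            })
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return records
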