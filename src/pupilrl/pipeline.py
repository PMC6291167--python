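"""End-to-end pipeline runner binding the stages into reproducible run directories.

Stage outputs land under ``<out>/<stage>/`` with a JSON manifest per stage
(config hash, seeds, package version, input checksums).  Re-running with an
identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import deconv as dc
from . import io as pio
from . import preproc as pp
from . import stats as st
from .config import PipelineConfig
from .hierfit import fit_hierarchical, simulate_from_fit, summarize_fit
from .qlearning import AgentParams, QTrajectory, compute_trajectory, transfer_values
from .synth import generate_cohort

log = logging.getLogger("pupilrl")

STAGES = ("simulate", "fit", "preprocess", "deconvolve", "stats")

LEARNING_COVARIATES = ("q_chosen_choice", "q_unchosen_choice", "q_chosen_fb", "q_unchosen_fb", "rpe_fb")
TRANSFER_COVARIATES = ("q_chosen_choice", "q_unchosen_choice")


class MissingArtifactError(RuntimeError):
    pass


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"stage '{needed_by}' needs '{path}' — run the '{stage}' stage first"
        )
    return path


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(stage_dir: Path, config: PipelineConfig, inputs: list[Path]) -> None:
    manifest = {
        "config_digest": config.digest(),
        "seeds": config.to_dict()["seeds"],
        "version": __version__,
        "inputs": {str(p): _checksum(p) for p in inputs},
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _subject_dirs(data_dir: Path) -> list[Path]:
    return sorted(p for p in data_dir.iterdir() if p.is_dir() and p.name.startswith("sub-"))


def run_pipeline(config: PipelineConfig, out: str | Path, stages=STAGES) -> Path:
    """Run the requested stages in canonical order; returns the run directory."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    order = [s for s in STAGES if s in stages]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage in order:
        log.info("running stage %s", stage)
        globals()[f"_stage_{stage}"](config, out)
    return out


def _stage_simulate(config: PipelineConfig, out: Path) -> None:
    data_dir = out / "data"
    data_dir.mkdir(exist_ok=True)
    generate_cohort(
        n_subjects=config.cohort.n_subjects,
        group_mu=config.cohort.group_mu,
        group_delta=config.cohort.group_delta,
        config=config.task,
        spec=config.synth,
        seed=config.seeds.simulate,
        outdir=data_dir,
    )
    _write_manifest(data_dir, config, [])


def _stage_fit(config: PipelineConfig, out: Path) -> None:
    data_dir = _require(out / "data", "simulate", "fit")
    fit_dir = out / "fit"
    fit_dir.mkdir(exist_ok=True)
    subject_trials = []
    inputs = []
    for sdir in _subject_dirs(data_dir):
        path = _require(sdir / "trials.tsv", "simulate", "fit")
        inputs.append(path)
        trials = pio.read_trials(path)
        subject_trials.append([t for t in trials if t.phase == "learning"])
    import dataclasses

    sampler = dataclasses.replace(config.model.sampler, seed=config.seeds.fit)
    post = fit_hierarchical(
        subject_trials,
        sampler=sampler,
        priors=config.model.priors,
        variant=config.model.variant,
        rt_floor=config.preproc.rt_floor,
        rt_deadline=config.preproc.rt_deadline,
    )
    from .qlearning import encode_trials

    summary = summarize_fit(post, encode_trials(subject_trials))
    pio.write_table(fit_dir / "summary.tsv", summary.table)
    pio.write_table(fit_dir / "posterior.tsv", post.to_long_frame())
    rhat = pd.DataFrame(sorted(post.rhat.items()), columns=["quantity", "rhat"])
    pio.write_table(fit_dir / "rhat.tsv", rhat)
    acc = simulate_from_fit(summary, config.task, n_reps=config.model.n_sim_reps,
                            seed=config.seeds.fit)
    rows = []
    pair_names = [p.name for p in config.task.pairs]
    for s in range(acc.shape[0]):
        for run in range(acc.shape[1]):
            for pi, pname in enumerate(pair_names):
                rows.append({"subject": s, "run": run, "pair": pname, "sim_accuracy": acc[s, run, pi]})
    pio.write_table(fit_dir / "simulated_accuracy.tsv", pd.DataFrame(rows))
    _write_manifest(fit_dir, config, inputs)


def _preprocess_subject(config: PipelineConfig, sdir: Path) -> tuple[pp.PupilTimeSeries, pp.Annotations]:
    cfg = config.preproc
    raw = pio.read_pupil(sdir / "pupil.tsv")
    ann = pio.read_annotations(sdir / "annotations.tsv")
    ts = pp.interpolate_blinks(raw, ann, margin=cfg.blink_margin)
    residual = pp.detect_residual_blinks(ts, k=cfg.residual_blink_k, margin=cfg.blink_margin)
    if residual:
        ts = pp.interpolate_blinks(ts, pp.Annotations(blinks=residual), margin=cfg.blink_margin)
    ts = pp.bandpass(ts, low=cfg.low_hz, high=cfg.high_hz, order=cfg.filter_order)
    ts = pp.zscore_and_resample(ts, target_fs=cfg.target_fs)
    blink_ends = np.array([b[1] for b in ann.blinks])
    sacc_times = np.array([s[0] for s in ann.saccades])
    ts, _ = pp.remove_nuisance_responses(ts, blink_ends, sacc_times, irf=cfg.irf)
    return ts, ann


def _stage_preprocess(config: PipelineConfig, out: Path) -> None:
    data_dir = _require(out / "data", "simulate", "preprocess")
    pre_dir = out / "preproc"
    pre_dir.mkdir(exist_ok=True)
    inputs = []
    reports = []
    for sdir in _subject_dirs(data_dir):
        inputs += [sdir / "pupil.tsv", sdir / "annotations.tsv", sdir / "trials.tsv"]
        ts, ann = _preprocess_subject(config, sdir)
        pio.write_pupil(pre_dir / f"{sdir.name}.tsv", ts)
        trials = pio.read_trials(sdir / "trials.tsv")
        kept, report = pp.reject_trials(
            trials, ann.saccades, threshold=config.preproc.saccade_threshold,
            rt_floor=config.preproc.rt_floor, rt_deadline=config.preproc.rt_deadline,
        )
        pio.write_trials(pre_dir / f"{sdir.name}_kept_trials.tsv", kept)
        report["subject"] = sdir.name
        reports.append(report)
    pio.write_table(pre_dir / "rejection_report.tsv", pd.DataFrame(reports))
    _write_manifest(pre_dir, config, inputs)


def _subset_trajectory(traj: QTrajectory, idx: np.ndarray) -> QTrajectory:
    return QTrajectory(
        q_chosen=traj.q_chosen[idx], q_unchosen=traj.q_unchosen[idx],
        rpe=traj.rpe[idx], q_by_option=traj.q_by_option[idx], final_q=traj.final_q,
    )


def _phase_series(ts: pp.PupilTimeSeries, runs: set[int]) -> pp.PupilTimeSeries:
    sel = np.isin(ts.run_id, sorted(runs))
    return pp.PupilTimeSeries(ts.times[sel], ts.values[sel], ts.fs, ts.run_id[sel])


def deconvolve_subject(
    config: PipelineConfig,
    ts: pp.PupilTimeSeries,
    kept_trials,
    params: AgentParams,
    seed: int = 0,
) -> dict[str, dc.DeconvResult]:
    """Deconvolve one subject's learning and transfer phases.

    Single-trial covariates come from the Q-trajectory under ``params``; the
    trajectory consumes every learning trial but only kept trials enter the
    design.
    """
    all_learning = [t for t in kept_trials if t.phase == "learning"]
    traj = compute_trajectory(all_learning, params)
    results: dict[str, dc.DeconvResult] = {}
    grid = np.linspace(0.0, 1.0, config.deconv.lambda_grid_size)

    learning_runs = {t.run_index for t in all_learning}
    ts_learn = _phase_series(ts, learning_runs)
    specs = dc.default_learning_specs(all_learning, traj)
    results["learning"] = dc.deconvolve(
        ts_learn, specs, grid=grid, n_splits=config.deconv.n_splits,
        test_frac=config.deconv.test_frac, seed=seed,
    )

    transfer = [t for t in kept_trials if t.phase == "transfer"]
    if transfer:
        qc, qu = transfer_values(traj.final_q, transfer)
        specs_t = dc.default_transfer_specs(transfer, qc, qu, config.task)
        ts_trans = _phase_series(ts, {t.run_index for t in transfer})
        results["transfer"] = dc.deconvolve(
            ts_trans, specs_t, grid=grid, n_splits=config.deconv.n_splits,
            test_frac=config.deconv.test_frac, seed=seed + 1,
        )
    return results


def _stage_deconvolve(config: PipelineConfig, out: Path) -> None:
    pre_dir = _require(out / "preproc", "preprocess", "deconvolve")
    fit_path = _require(out / "fit" / "summary.tsv", "fit", "deconvolve")
    dec_dir = out / "deconv"
    dec_dir.mkdir(exist_ok=True)
    summary = pio.read_table(fit_path)
    inputs = [fit_path]
    for sdir in _subject_dirs(out / "data"):
        sub = int(sdir.name.split("-")[1])
        ts = pio.read_pupil(pre_dir / f"{sdir.name}.tsv")
        kept = pio.read_trials(pre_dir / f"{sdir.name}_kept_trials.tsv")
        inputs += [pre_dir / f"{sdir.name}.tsv", pre_dir / f"{sdir.name}_kept_trials.tsv"]
        row = summary.loc[summary["subject"] == sub].iloc[0]
        params = AgentParams(float(row["alpha_gain"]), float(row["alpha_loss"]), float(row["beta"]))
        results = deconvolve_subject(config, ts, kept, params, seed=config.seeds.deconvolve + sub)
        for phase, res in results.items():
            pio.write_betas(dec_dir / f"{sdir.name}_{phase}_betas.tsv", res)
            sidecar = {
                "lambda_star": res.lambda_star,
                "cv_scores": list(map(float, res.cv_scores)),
                "lambda_grid": list(map(float, res.lambda_grid)),
                "n_splits": res.n_splits,
                "seed": config.seeds.deconvolve + sub,
            }
            (dec_dir / f"{sdir.name}_{phase}.json").write_text(json.dumps(sidecar, indent=2))
    _write_manifest(dec_dir, config, inputs)


def _stack_betas(dec_dir: Path, phase: str, name: str):
    """(subjects x lags) matrix of one regressor's betas plus the lag grid."""
    mats, lags = [], None
    for path in sorted(dec_dir.glob(f"sub-*_{phase}_betas.tsv")):
        betas, lag_map = pio.read_betas(path)
        if name not in betas:
            continue
        mats.append(betas[name])
        lags = lag_map[name]
    if not mats:
        raise MissingArtifactError(f"no '{name}' betas found for phase '{phase}' in {dec_dir}")
    return np.vstack(mats), lags


def _stage_stats(config: PipelineConfig, out: Path) -> None:
    dec_dir = _require(out / "deconv", "deconvolve", "stats")
    fit_path = _require(out / "fit" / "summary.tsv", "fit", "stats")
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    cfg = config.stats
    seed = config.seeds.stats

    cluster_rows = []
    tidy_rows = []
    for phase, names in (("learning", LEARNING_COVARIATES), ("transfer", TRANSFER_COVARIATES)):
        try:
            for name in names:
                data, lags = _stack_betas(dec_dir, phase, name)
                res = st.cluster_permutation_test(
                    data, times=lags, n_perm=cfg.n_perm, alpha=cfg.alpha, seed=seed
                )
                for c in res.clusters:
                    cluster_rows.append({
                        "phase": phase, "regressor": name, "start_s": c.start_s,
                        "end_s": c.end_s, "size": c.size, "p": c.p_corrected, "sign": c.sign,
                    })
                summ = st.interval_summary(data, lags, (-2.0, 0.0), alignment="event_end")
                for s, v in enumerate(summ):
                    tidy_rows.append({"phase": phase, "regressor": name, "subject": s,
                                      "pre_event_mean": v})
        except MissingArtifactError:
            if phase == "learning":
                raise
    pio.write_table(stats_dir / "clusters.tsv", pd.DataFrame(cluster_rows))
    pio.write_table(stats_dir / "interval_summaries.tsv", pd.DataFrame(tidy_rows))

    # across-subject GLM: feedback response amplitude ~ model parameters
    summary = pio.read_table(fit_path)
    fb, fb_lags = _stack_betas(dec_dir, "learning", "feedback")
    amps = np.array([
        st.feedback_amplitude(fb_lags, fb[s], cfg.amplitude_early, cfg.amplitude_late)
        for s in range(fb.shape[0])
    ])
    predictors = summary[["alpha_gain", "alpha_loss", "beta"]].to_numpy(float)
    glm = st.bootstrap_glm(
        amps, predictors, predictor_names=["alpha_gain", "alpha_loss", "beta"],
        n_boot=cfg.n_boot, seed=seed,
    )
    pio.write_table(stats_dir / "bootstrap_glm.tsv", glm.to_frame())
    amp_table = pd.DataFrame({"subject": np.arange(len(amps)), "feedback_amplitude": amps})
    pio.write_table(stats_dir / "feedback_amplitudes.tsv", amp_table)
    _write_manifest(stats_dir, config, [fit_path])
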