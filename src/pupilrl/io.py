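"""Tab-separated readers/writers for every interchange format in the pipeline.

All formats are plain text with documented headers; writers and readers
round-trip exactly (up to float formatting at 12 significant digits).
Proprietary eye-tracker files are out of scope: convert them to the
``pupil.tsv`` / ``annotations.tsv`` formats documented below.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preproc import Annotations, PupilTimeSeries
from .task import TrialRecord

__all__ = [
    "write_trials", "read_trials",
    "write_pupil", "read_pupil",
    "write_annotations", "read_annotations",
    "write_betas", "read_betas",
    "write_table", "read_table",
]

TRIAL_COLUMNS = [
    "phase", "run", "trial", "pair", "choice", "outcome", "rt",
    "t_fixation", "t_options_on", "t_choice", "t_feedback", "t_options_off",
    "side_left",
]


def _fmt(x: float) -> str:
    if isinstance(x, float) and np.isnan(x):
        return ""
    return repr(float(x))


def write_trials(path: str | Path, trials: list[TrialRecord]) -> None:
    """Trial table: one row per trial; empty fields encode missing outcome/feedback."""
    with open(path, "w") as fh:
        fh.write("\t".join(TRIAL_COLUMNS) + "\n")
        for t in trials:
            row = [
                t.phase, str(t.run_index), str(t.trial_index), t.pair_name,
                t.choice or "", "" if t.outcome is None else str(t.outcome),
                _fmt(t.rt), _fmt(t.t_fixation), _fmt(t.t_options_on),
                _fmt(t.t_choice), _fmt(t.t_feedback), _fmt(t.t_options_off),
                t.side_left,
            ]
            fh.write("\t".join(row) + "\n")


def read_trials(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != TRIAL_COLUMNS:
        raise ValueError(f"malformed trial table header in {path}")
    out: list[TrialRecord] = []
    for _, r in df.iterrows():
        rec = TrialRecord(
            phase=r["phase"],
            run_index=int(r["run"]),
            trial_index=int(r["trial"]),
            pair=(r["pair"][0], r["pair"][1]),
            choice=r["choice"] or None,
            outcome=None if r["outcome"] == "" else int(r["outcome"]),
            rt=float(r["rt"]),
            t_fixation=float(r["t_fixation"]),
            t_options_on=float(r["t_options_on"]),
            t_choice=float(r["t_choice"]),
            t_feedback=float(r["t_feedback"]) if r["t_feedback"] else float("nan"),
            t_options_off=float(r["t_options_off"]),
            side_left=r["side_left"],
        )
        rec.validate()
        out.append(rec)
    return out


def write_pupil(path: str | Path, ts: PupilTimeSeries) -> None:
    """Pupil trace: time_s, diameter, run; uniform sampling within each run."""
    df = pd.DataFrame({"time_s": ts.times, "diameter": ts.values, "run": ts.run_id})
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_pupil(path: str | Path, fs: float | None = None) -> PupilTimeSeries:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["time_s", "diameter", "run"]:
        raise ValueError(f"malformed pupil trace header in {path}")
    times = df["time_s"].to_numpy(float)
    runs = df["run"].to_numpy(np.int64)
    for run in np.unique(runs):
        t = times[runs == run]
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotone timestamps in run {run} of {path}")
    if fs is None:
        first = times[runs == runs[0]]
        if len(first) < 2:
            raise ValueError("cannot infer sampling rate from a single sample")
        fs = 1.0 / float(np.median(np.diff(first)))
    return PupilTimeSeries(times, df["diameter"].to_numpy(float), fs, runs)


def write_annotations(path: str | Path, ann: Annotations) -> None:
    """Artifacts: event_type in {blink_start, blink_end, saccade}, time_s, amplitude_deg."""
    with open(path, "w") as fh:
        fh.write("event_type\ttime_s\tamplitude_deg\n")
        for start, end in ann.blinks:
            fh.write(f"blink_start\t{_fmt(start)}\t\n")
            fh.write(f"blink_end\t{_fmt(end)}\t\n")
        for t, amp in ann.saccades:
            fh.write(f"saccade\t{_fmt(t)}\t{_fmt(amp)}\n")


def read_annotations(path: str | Path) -> Annotations:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != ["event_type", "time_s", "amplitude_deg"]:
        raise ValueError(f"malformed annotation header in {path}")
    ann = Annotations()
    pending_start: float | None = None
    for _, r in df.iterrows():
        kind = r["event_type"]
        t = float(r["time_s"])
        if kind == "blink_start":
            if pending_start is not None:
                raise ValueError("blink_start without matching blink_end")
            pending_start = t
        elif kind == "blink_end":
            if pending_start is None:
                raise ValueError("blink_end without blink_start")
            ann.blinks.append((pending_start, t))
            pending_start = None
        elif kind == "saccade":
            ann.saccades.append((t, float(r["amplitude_deg"])))
        else:
            raise ValueError(f"unknown event_type {kind!r}")
    if pending_start is not None:
        raise ValueError("unterminated blink interval")
    return ann


def write_betas(path: str | Path, result) -> None:
    """Deconvolved responses: regressor, lag_s, beta."""
    rows = []
    for name, beta in result.betas.items():
        for lag, b in zip(result.lags[name], beta):
            rows.append({"regressor": name, "lag_s": lag, "beta": b})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_betas(path: str | Path) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["regressor", "lag_s", "beta"]:
        raise ValueError(f"malformed beta table header in {path}")
    betas: dict[str, np.ndarray] = {}
    lags: dict[str, np.ndarray] = {}
    for name, g in df.groupby("regressor", sort=False):
        betas[name] = g["beta"].to_numpy(float)
        lags[name] = g["lag_s"].to_numpy(float)
    return betas, lags


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
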