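"""Pupil preprocessing: blink interpolation, band-pass, z-scoring, resampling,
nuisance-response removal and trial rejection.

The canonical pupil impulse response used for nuisance regression is the
Erlang-form kernel h(t) = t^w * exp(-w * t / t_max), unit-peak normalized,
with shape w = 10.1 and peak latency t_max = 0.93 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "PupilTimeSeries",
    "Annotations",
    "IRFParams",
    "pupil_irf",
    "interpolate_blinks",
    "detect_residual_blinks",
    "bandpass",
    "zscore_and_resample",
    "remove_nuisance_responses",
    "reject_trials",
]


@dataclass
class PupilTimeSeries:
    """Uniformly sampled pupil signal; ``run_id`` marks run membership per sample."""

    times: np.ndarray
    values: np.ndarray
    fs: float
    run_id: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.run_id = np.asarray(self.run_id, dtype=np.int64)
        if not (len(self.times) == len(self.values) == len(self.run_id)):
            raise ValueError("times, values and run_id must have equal length")

    def runs(self):
        for run in np.unique(self.run_id):
            yield int(run), np.flatnonzero(self.run_id == run)

    def copy(self) -> "PupilTimeSeries":
        return PupilTimeSeries(self.times.copy(), self.values.copy(), self.fs, self.run_id.copy())


@dataclass
class Annotations:
    """Artifact annotations: blink intervals and saccade events with amplitudes (deg)."""

    blinks: list[tuple[float, float]] = field(default_factory=list)
    saccades: list[tuple[float, float]] = field(default_factory=list)  # (time, amplitude)


@dataclass(frozen=True)
class IRFParams:
    w: float = 10.1
    t_max: float = 0.93
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")


def pupil_irf(fs: float, params: IRFParams = IRFParams(), duration: float = 4.0) -> np.ndarray:
    """Sampled canonical IRF, unit peak at t_max, scaled by ``gain``."""
    t = np.arange(0.0, duration, 1.0 / fs)
    h = t**params.w * np.exp(-params.w * t / params.t_max)
    peak = params.t_max**params.w * np.exp(-params.w)
    return params.gain * h / peak


def interpolate_blinks(
    ts: PupilTimeSeries, annotations: Annotations, margin: float = 0.2
) -> PupilTimeSeries:
    """Linearly interpolate across each blink, from ``margin`` s before to after.

    Blinks spanning a run boundary are interpolated within each run segment
    separately (the boundary samples anchor the interpolation).
    """
    out = ts.copy()
    for start, end in annotations.blinks:
        lo, hi = start - margin, end + margin
        for _, idx in out.runs():
            t = out.times[idx]
            bad = (t >= lo) & (t <= hi)
            if not bad.any() or bad.all():
                continue
            good = ~bad
            out.values[idx[bad]] = np.interp(t[bad], t[good], out.values[idx[good]])
    return out


def detect_residual_blinks(
    ts: PupilTimeSeries, k: float = 6.0, margin: float = 0.2
) -> list[tuple[float, float]]:
    """Flag unlabeled blink-like transients from peaks in the rate of change.

    A sample is suspect when its absolute first difference exceeds ``k`` robust
    (MAD-based) standard deviations; adjacent suspects merge into intervals.
    """
    intervals: list[tuple[float, float]] = []
    for _, idx in ts.runs():
        v = ts.values[idx]
        t = ts.times[idx]
        dv = np.diff(v)
        mad = np.median(np.abs(dv - np.median(dv)))
        robust_sd = 1.4826 * mad
        if robust_sd == 0.0:
            continue
        bad = np.abs(dv) > k * robust_sd
        if not bad.any():
            continue
        hits = np.flatnonzero(bad)
        gap = max(1, int(round(0.05 * ts.fs)))
        start = hits[0]
        prev = hits[0]
        for h in hits[1:]:
            if h - prev > gap:
                intervals.append((float(t[start]), float(t[min(prev + 1, len(t) - 1)])))
                start = h
            prev = h
        intervals.append((float(t[start]), float(t[min(prev + 1, len(t) - 1)])))
    return intervals


def bandpass(
    ts: PupilTimeSeries, low: float = 0.05, high: float = 4.0, order: int = 3
) -> PupilTimeSeries:
    """Zero-phase Butterworth band-pass applied per run."""
    if ts.fs <= 2.0 * high:
        raise ValueError(f"sampling rate {ts.fs} Hz too low for {high} Hz cutoff")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=ts.fs, output="sos")
    out = ts.copy()
    min_len = 3 * (2 * order + 1)
    for _, idx in out.runs():
        if len(idx) < min_len:
            raise ValueError(f"run too short ({len(idx)} samples) for filter warm-up")
        out.values[idx] = signal.sosfiltfilt(sos, out.values[idx])
    return out


def zscore_and_resample(ts: PupilTimeSeries, target_fs: float = 20.0) -> PupilTimeSeries:
    """Standardize each run to mean 0 / SD 1, then decimate to ``target_fs``."""
    from fractions import Fraction

    frac = Fraction(target_fs / ts.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    times_out, vals_out, runs_out = [], [], []
    for run, idx in ts.runs():
        v = ts.values[idx]
        sd = v.std()
        if sd == 0.0:
            raise ValueError(f"run {run} has zero variance")
        z = (v - v.mean()) / sd
        if (up, down) == (1, 1):
            res = z
        else:
            res = signal.resample_poly(z, up, down)
        t0 = ts.times[idx][0]
        times_out.append(t0 + np.arange(len(res)) / target_fs)
        vals_out.append(res)
        runs_out.append(np.full(len(res), run, dtype=np.int64))
    return PupilTimeSeries(
        np.concatenate(times_out), np.concatenate(vals_out), target_fs, np.concatenate(runs_out)
    )


def _event_regressor(
    ts: PupilTimeSeries, event_times: np.ndarray, irf: IRFParams
) -> np.ndarray:
    """Impulse train at the event times convolved with the canonical IRF, per run."""
    kernel = pupil_irf(ts.fs, irf)
    out = np.zeros(len(ts.values))
    for _, idx in ts.runs():
        t = ts.times[idx]
        train = np.zeros(len(idx))
        sel = (event_times >= t[0]) & (event_times <= t[-1])
        pos = np.round((event_times[sel] - t[0]) * ts.fs).astype(int)
        pos = pos[(pos >= 0) & (pos < len(idx))]
        np.add.at(train, pos, 1.0)
        out[idx] = np.convolve(train, kernel)[: len(idx)]
    return out


def remove_nuisance_responses(
    ts: PupilTimeSeries,
    blink_events: np.ndarray,
    saccade_events: np.ndarray,
    irf: IRFParams = IRFParams(),
) -> tuple[PupilTimeSeries, np.ndarray]:
    """Regress out IRF-convolved blink and saccade responses; return residuals.

    Blink events are anchored at blink end, saccade events at onset.  With no
    events the input passes through unchanged (coefficients are zero).
    """
    blink_events = np.asarray(blink_events, dtype=float)
    saccade_events = np.asarray(saccade_events, dtype=float)
    cols = []
    if blink_events.size:
        cols.append(_event_regressor(ts, blink_events, irf))
    else:
        cols.append(np.zeros(len(ts.values)))
    if saccade_events.size:
        cols.append(_event_regressor(ts, saccade_events, irf))
    else:
        cols.append(np.zeros(len(ts.values)))
    X = np.column_stack(cols)
    if not np.any(X):
        return ts.copy(), np.zeros(2)
    coef, *_ = np.linalg.lstsq(X, ts.values, rcond=None)
    out = ts.copy()
    out.values = ts.values - X @ coef
    return out, coef


def reject_trials(
    trials,
    saccade_events,
    threshold: float = 3.3,
    rt_floor: float = 0.15,
    rt_deadline: float = 3.5,
):
    """Drop trials with an over-threshold saccade in the decision interval or a bad RT.

    Returns (kept_trials, report) where the report gives counts and the
    fraction removed.
    """
    sacc = np.asarray(saccade_events, dtype=float).reshape(-1, 2) if len(saccade_events) else np.empty((0, 2))
    kept = []
    n_sacc = n_rt = 0
    for t in trials:
        bad_rt = not (rt_floor <= t.rt <= rt_deadline)
        in_window = (sacc[:, 0] >= t.t_options_on) & (sacc[:, 0] <= t.t_choice) if len(sacc) else np.array([], dtype=bool)
        bad_sacc = bool(np.any(sacc[in_window, 1] > threshold)) if len(sacc) else False
        if bad_rt:
            n_rt += 1
        elif bad_sacc:
            n_sacc += 1
        else:
            kept.append(t)
    n = len(list(trials))
    report = {
        "n_total": n,
        "n_rejected_rt": n_rt,
        "n_rejected_saccade": n_sacc,
        "fraction_removed": (n_rt + n_sacc) / n if n else 0.0,
    }
    return kept, report
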