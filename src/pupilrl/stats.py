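"""Group-level inference on deconvolved time courses.

Cluster-based permutation tests (sign-flip null, maximal cluster size),
interval-summed normalized coefficients, bootstrap across-subject GLMs, and a
peak-to-trough amplitude of the biphasic feedback response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Cluster",
    "ClusterTestResult",
    "BootstrapGLMResult",
    "cluster_permutation_test",
    "interval_summary",
    "bootstrap_glm",
    "feedback_amplitude",
]


@dataclass(frozen=True)
class Cluster:
    start_s: float
    end_s: float
    size: int
    p_corrected: float
    sign: int


@dataclass
class ClusterTestResult:
    t_values: np.ndarray
    clusters: list[Cluster]
    alpha: float
    n_permutations: int

    def significant(self, level: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected <= level]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"start_s": c.start_s, "end_s": c.end_s, "size": c.size,
                 "p": c.p_corrected, "sign": c.sign}
                for c in self.clusters
            ]
        )


def _t_onesample(data: np.ndarray) -> np.ndarray:
    """Per-timepoint one-sample t statistic across subjects (axis 0)."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    sd = np.where(sd == 0.0, np.inf, sd)
    return mean / (sd / np.sqrt(n))


def _clusters_from_mask(t: np.ndarray, crit: float) -> list[tuple[int, int, int]]:
    """(start, stop, sign) of contiguous supra-threshold runs sharing a sign."""
    supra = np.abs(t) > crit
    out = []
    i = 0
    n = len(t)
    while i < n:
        if not supra[i]:
            i += 1
            continue
        sign = 1 if t[i] > 0 else -1
        j = i
        while j < n and supra[j] and (1 if t[j] > 0 else -1) == sign:
            j += 1
        out.append((i, j, sign))
        i = j
    return out


def _max_cluster_sizes(data: np.ndarray, flips: np.ndarray, crit: float) -> np.ndarray:
    """Maximal cluster size for each sign-flip permutation (vectorized)."""
    # flipped (n_perm, n_subj, n_time) t-stats computed without materializing copies
    n_subj = data.shape[0]
    flipped_mean = (flips @ data) / n_subj  # (n_perm, n_time)
    flipped_sq = (data**2).sum(axis=0) / n_subj  # flips^2 = 1
    var = (flipped_sq - flipped_mean**2) * n_subj / (n_subj - 1)
    sd = np.sqrt(np.maximum(var, 1e-300))
    t = flipped_mean / (sd / np.sqrt(n_subj))
    out = np.zeros(len(flips), dtype=np.int64)
    for p in range(len(flips)):
        sizes = [j - i for i, j, _ in _clusters_from_mask(t[p], crit)]
        out[p] = max(sizes) if sizes else 0
    return out


def cluster_permutation_test(
    subject_by_time: np.ndarray,
    times: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterTestResult:
    """One-sample cluster test against zero with a sign-flip permutation null.

    Per timepoint, a two-tailed t-test at ``alpha`` forms clusters of
    contiguous supra-threshold samples (same sign); cluster size in samples is
    compared against the permutation distribution of maximal cluster sizes.
    Corrected p-values count null maxima strictly larger than the observed
    size, smoothed as (1 + #{null > observed}) / (1 + n_perm) so that p never
    drops below 1/(n_perm + 1).
    """
    data = np.atleast_2d(np.asarray(subject_by_time, dtype=float))
    n_subj, n_time = data.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if times is None:
        times = np.arange(n_time, dtype=float)
    times = np.asarray(times, dtype=float)
    crit = sps.t.ppf(1.0 - alpha / 2.0, n_subj - 1)
    t_obs = _t_onesample(data)
    observed = _clusters_from_mask(t_obs, crit)

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    null_max = _max_cluster_sizes(data, flips, crit)

    clusters = []
    for i, j, sign in observed:
        size = j - i
        p = (1.0 + np.sum(null_max > size)) / (1.0 + n_perm)
        clusters.append(Cluster(float(times[i]), float(times[j - 1]), size, float(p), sign))
    return ClusterTestResult(t_values=t_obs, clusters=clusters, alpha=alpha, n_permutations=n_perm)


def interval_summary(
    subject_by_time: np.ndarray,
    lags: np.ndarray,
    interval: tuple[float, float],
    alignment: str = "event_start",
) -> np.ndarray:
    """Per-subject summed coefficients over an interval, normalized by sample count.

    With ``alignment='event_end'`` the interval is clipped at lag 0 so that
    post-event (post-choice) effects are discarded.
    """
    data = np.atleast_2d(np.asarray(subject_by_time, dtype=float))
    lags = np.asarray(lags, dtype=float)
    lo, hi = interval
    if alignment == "event_end":
        hi = min(hi, 0.0)
    elif alignment != "event_start":
        raise ValueError(f"unknown alignment {alignment!r}")
    sel = (lags >= lo - 1e-9) & (lags <= hi + 1e-9)
    if not sel.any():
        raise ValueError("interval selects no samples")
    return data[:, sel].sum(axis=1) / sel.sum()


@dataclass
class BootstrapGLMResult:
    predictors: list[str]
    coef: np.ndarray  # (n_predictors,) or (n_predictors, n_time)
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    p_values: np.ndarray  # per predictor (scalar response) or per predictor/time
    n_boot: int
    collinear: bool = False

    def to_frame(self, times: np.ndarray | None = None) -> pd.DataFrame:
        rows = []
        if self.coef.ndim == 1:
            for i, name in enumerate(self.predictors):
                rows.append({"predictor": name, "time_s": np.nan, "beta": self.coef[i],
                             "ci_lo": self.ci_lo[i], "ci_hi": self.ci_hi[i], "p": self.p_values[i]})
        else:
            tvec = times if times is not None else np.arange(self.coef.shape[1])
            for i, name in enumerate(self.predictors):
                for j, t in enumerate(tvec):
                    rows.append({"predictor": name, "time_s": t, "beta": self.coef[i, j],
                                 "ci_lo": self.ci_lo[i, j], "ci_hi": self.ci_hi[i, j],
                                 "p": self.p_values[i, j]})
        return pd.DataFrame(rows)


def bootstrap_glm(
    responses: np.ndarray,
    predictors: np.ndarray,
    predictor_names: list[str] | None = None,
    n_boot: int = 10000,
    seed: int = 0,
    ci: float = 68.0,
) -> BootstrapGLMResult:
    """Across-subject GLM with subject-resampling bootstrap.

    ``responses`` is (n_subjects,) or (n_subjects, n_time); ``predictors`` is
    (n_subjects, n_predictors), standardized across subjects internally.  The
    GLM regresses responses on all predictors jointly (plus intercept); 68%
    bands come from bootstrap percentiles and two-sided p-values from the tail
    fraction of the bootstrap distribution around zero.
    """
    y = np.asarray(responses, dtype=float)
    P = np.atleast_2d(np.asarray(predictors, dtype=float))
    if P.shape[0] != y.shape[0]:
        raise ValueError("one predictor row per subject is required")
    n_subj, n_pred = P.shape
    if predictor_names is None:
        predictor_names = [f"x{i}" for i in range(n_pred)]
    sd = P.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    Pz = (P - P.mean(axis=0)) / sd
    X = np.column_stack([np.ones(n_subj), Pz])
    collinear = np.linalg.cond(X) > 1e8

    scalar = y.ndim == 1
    Y = y[:, None] if scalar else y

    coef_full = np.linalg.lstsq(X, Y, rcond=None)[0][1:]  # drop intercept
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot,) + coef_full.shape)
    for b in range(n_boot):
        idx = rng.integers(0, n_subj, size=n_subj)
        boots[b] = np.linalg.lstsq(X[idx], Y[idx], rcond=None)[0][1:]
    half = (100.0 - ci) / 2.0
    lo = np.percentile(boots, half, axis=0)
    hi = np.percentile(boots, 100.0 - half, axis=0)
    frac_below = (boots < 0.0).mean(axis=0)
    p = 2.0 * np.minimum(frac_below, 1.0 - frac_below)
    if scalar:
        coef_full, lo, hi, p = coef_full[:, 0], lo[:, 0], hi[:, 0], p[:, 0]
    return BootstrapGLMResult(
        predictors=list(predictor_names), coef=coef_full, ci_lo=lo, ci_hi=hi,
        p_values=p, n_boot=n_boot, collinear=bool(collinear),
    )


def feedback_amplitude(
    lags: np.ndarray,
    beta: np.ndarray,
    early_window: tuple[float, float] = (0.5, 1.5),
    late_window: tuple[float, float] = (1.5, 3.0),
) -> float:
    """Peak-to-trough amplitude: early-dilation max minus late-constriction min."""
    lags = np.asarray(lags, dtype=float)
    beta = np.asarray(beta, dtype=float)
    early = (lags >= early_window[0]) & (lags <= early_window[1])
    late = (lags >= late_window[0]) & (lags <= late_window[1])
    if not early.any() or not late.any():
        raise ValueError("amplitude windows outside the estimated lags")
    return float(beta[early].max() - beta[late].min())
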