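"""FIR deconvolution of event-related pupil responses via cross-validated ridge.

The design matrix holds one column per (regressor, lag): shifted event
indicators for transient regressors, indicator-times-value columns for
single-trial covariates, and a single sustained boxcar column spanning each
decision interval with height 1 / mean(RT).  Columns and the signal are
mean-centered before solving and no intercept is added; the ridge estimate is
(X'X + lambda*I)^-1 X'y with the penalty chosen by cross-validation over
contiguous train/test splits.

The design matrix is stored sparse; centering is folded into the Gram matrix
algebraically (X_c'X_c = X'X - n * mu mu') so that large sessions stay cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "RegressorSpec",
    "DesignMatrix",
    "DeconvResult",
    "build_design_matrix",
    "ridge_solve",
    "cross_validate_lambda",
    "deconvolve",
    "default_learning_specs",
    "default_transfer_specs",
    "zscore",
]

DEFAULT_LAMBDA_GRID = np.linspace(0.0, 1.0, 21)


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


@dataclass
class RegressorSpec:
    """One named regressor: transient stick, sustained boxcar, or covariate."""

    name: str
    kind: str  # "transient" | "boxcar" | "covariate"
    event_times: np.ndarray
    window: tuple[float, float] | None = None
    covariate_values: np.ndarray | None = None
    durations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.kind not in ("transient", "boxcar", "covariate"):
            raise ValueError(f"unknown regressor kind {self.kind!r}")
        if self.kind in ("transient", "covariate"):
            if self.window is None or not self.window[0] < self.window[1]:
                raise ValueError(f"regressor {self.name!r} needs a valid (start, end) window")
        if self.kind == "covariate":
            if self.covariate_values is None or len(self.covariate_values) != len(self.event_times):
                raise ValueError(f"covariate {self.name!r} needs one value per event")
            self.covariate_values = np.asarray(self.covariate_values, dtype=float)
        if self.kind == "boxcar":
            if self.durations is None or len(self.durations) != len(self.event_times):
                raise ValueError(f"boxcar {self.name!r} needs one duration per event")
            self.durations = np.asarray(self.durations, dtype=float)


@dataclass
class DesignMatrix:
    """Sparse (uncentered) FIR design with per-column (name, lag) bookkeeping."""

    X: sparse.csr_matrix
    columns: list[tuple[str, float]]
    fs: float
    times: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    @property
    def col_means(self) -> np.ndarray:
        return np.asarray(self.X.mean(axis=0)).ravel()

    def dense_centered(self) -> np.ndarray:
        return self.X.toarray() - self.col_means

    def column_slice(self, name: str) -> tuple[slice, np.ndarray]:
        """(column slice, lag array in seconds) for one regressor."""
        idx = [i for i, (n, _) in enumerate(self.columns) if n == name]
        if not idx:
            raise KeyError(f"no regressor named {name!r}")
        if idx != list(range(idx[0], idx[-1] + 1)):
            raise ValueError(f"columns of {name!r} are not contiguous")
        lags = np.array([self.columns[i][1] for i in idx])
        return slice(idx[0], idx[-1] + 1), lags

    def regressor_names(self) -> list[str]:
        seen: list[str] = []
        for n, _ in self.columns:
            if n not in seen:
                seen.append(n)
        return seen


def build_design_matrix(
    specs: list[RegressorSpec],
    n_samples: int,
    fs: float = 20.0,
    times: np.ndarray | None = None,
) -> DesignMatrix:
    """Assemble the sparse FIR design matrix.

    ``times`` maps sample index to session time (defaults to a uniform grid
    starting at 0); event times snap to the nearest sample.  Event windows that
    extend past the recording are truncated with a warning.
    """
    if times is None:
        times = np.arange(n_samples) / fs
    else:
        times = np.asarray(times, dtype=float)
        if len(times) != n_samples:
            raise ValueError("times must have n_samples entries")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("regressor names must be unique")

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    columns: list[tuple[str, float]] = []
    col_ofs = 0
    truncated = 0

    def snap(t: np.ndarray) -> np.ndarray:
        i = np.searchsorted(times, t)
        i = np.clip(i, 1, n_samples - 1)
        left_closer = (t - times[i - 1]) <= (times[i] - t)
        return np.where(left_closer, i - 1, i)

    for spec in specs:
        if np.any(spec.event_times < times[0] - 1e-9) or np.any(spec.event_times > times[-1] + 1e-9):
            raise ValueError(f"events of {spec.name!r} fall outside the recording")
        base = snap(spec.event_times)
        if spec.kind in ("transient", "covariate"):
            lo = int(round(spec.window[0] * fs))
            hi = int(round(spec.window[1] * fs))
            weights = (
                spec.covariate_values if spec.kind == "covariate" else np.ones(len(base))
            )
            for lag in range(lo, hi + 1):
                r = base + lag
                ok = (r >= 0) & (r < n_samples)
                truncated += int((~ok).sum())
                rows.append(r[ok])
                cols.append(np.full(ok.sum(), col_ofs, dtype=np.int64))
                vals.append(np.asarray(weights)[ok].astype(float))
                columns.append((spec.name, lag / fs))
                col_ofs += 1
        else:  # boxcar
            height = 1.0 / float(np.mean(spec.durations))
            r_all = []
            for t0, dur in zip(spec.event_times, spec.durations):
                i0 = int(snap(np.array([t0]))[0])
                n_steps = max(1, int(round(dur * fs)))
                r = np.arange(i0, min(i0 + n_steps, n_samples))
                r_all.append(r)
            r_all = np.concatenate(r_all)
            rows.append(r_all)
            cols.append(np.full(len(r_all), col_ofs, dtype=np.int64))
            vals.append(np.full(len(r_all), height))
            columns.append((spec.name, 0.0))
            col_ofs += 1

    if truncated:
        warnings.warn(f"{truncated} design-matrix entries truncated at recording edges", stacklevel=2)
    X = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_samples, col_ofs),
    ).tocsr()
    return DesignMatrix(X=X, columns=columns, fs=fs, times=times)


def _centered_system(X, y: np.ndarray):
    """Centered Gram matrix and cross-product for a sparse (or dense) design."""
    n = X.shape[0]
    yc = y - y.mean()
    if sparse.issparse(X):
        G = np.asarray((X.T @ X).todense())
        mu = np.asarray(X.mean(axis=0)).ravel()
        b = np.asarray(X.T @ yc).ravel()
    else:
        G = X.T @ X
        mu = X.mean(axis=0)
        b = X.T @ yc
    G = G - n * np.outer(mu, mu)
    return G, b


def ridge_solve(X, y: np.ndarray, lam: float) -> np.ndarray:
    """Solve (X'X + lambda*I) beta = X'y.

    Accepts a plain (already centered) array or a :class:`DesignMatrix`, whose
    columns and signal are centered internally.  ``lam = 0`` reproduces
    ordinary least squares on full-rank designs.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    y = np.asarray(y, dtype=float)
    if isinstance(X, DesignMatrix):
        # eigen-clipped path: at lam = 0 a (near-)singular Gram falls back to
        # the minimum-norm least-squares solution instead of exploding
        G, b = _centered_system(X.X, y)
        return _solve_path(G, b, np.array([lam]))[0]
    X = np.asarray(X, dtype=float)
    G = X.T @ X
    b = X.T @ y
    A = G + lam * np.eye(G.shape[0])
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def _solve_path(G: np.ndarray, b: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Ridge solutions for every lambda via one eigendecomposition of the Gram."""
    w, V = np.linalg.eigh(G)
    w = np.maximum(w, 0.0)
    tol = 1e-10 * max(float(w[-1]), 1.0)
    bV = V.T @ b
    betas = np.empty((len(grid), len(b)))
    for i, lam in enumerate(grid):
        d = w + lam
        ok = d > tol
        coef = np.where(ok, bV / np.where(ok, d, 1.0), 0.0)
        betas[i] = V @ coef
    return betas


def cross_validate_lambda(
    X,
    y: np.ndarray,
    grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_splits: int = 20,
    test_frac: float = 0.2,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Pick the ridge penalty by out-of-sample R^2 over contiguous splits.

    Each split holds out one contiguous block (``test_frac`` of the samples) at
    a random offset, preserving the temporal autocorrelation of the signal.
    Ties break toward the smaller lambda.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    if np.any(grid < 0) or np.any(grid > 1):
        raise ValueError("lambda grid must lie in [0, 1]")
    order = np.argsort(grid, kind="stable")
    grid = grid[order]
    y = np.asarray(y, dtype=float)
    Xs = X.X if isinstance(X, DesignMatrix) else sparse.csr_matrix(np.asarray(X, dtype=float))
    n = Xs.shape[0]
    test_len = max(1, int(round(test_frac * n)))
    rng = np.random.default_rng(seed)
    scores = np.zeros(len(grid))
    for _ in range(n_splits):
        start = int(rng.integers(0, n - test_len + 1))
        test = np.arange(start, start + test_len)
        train = np.concatenate([np.arange(0, start), np.arange(start + test_len, n)])
        Xtr, Xte = Xs[train], Xs[test]
        ytr, yte = y[train], y[test]
        G, b = _centered_system(Xtr, ytr)
        mu = np.asarray(Xtr.mean(axis=0)).ravel()
        betas = _solve_path(G, b, grid)
        yte_c = yte - ytr.mean()
        ss_tot = float(np.sum(yte_c**2))
        pred_raw = np.asarray(Xte @ betas.T)  # (test_len, n_lambda)
        for i in range(len(grid)):
            pred = pred_raw[:, i] - mu @ betas[i]
            ss_res = float(np.sum((yte_c - pred) ** 2))
            scores[i] += (1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0
    scores /= n_splits
    best = int(np.argmax(scores))  # first max -> smallest lambda among ties
    return float(grid[best]), scores


@dataclass
class DeconvResult:
    """Deconvolved per-regressor response time courses and the chosen penalty."""

    betas: dict[str, np.ndarray]
    lags: dict[str, np.ndarray]
    lambda_star: float
    cv_scores: np.ndarray
    lambda_grid: np.ndarray
    n_splits: int
    beta_vector: np.ndarray = field(repr=False, default=None)

    def delta_value_course(self, chosen: str, unchosen: str) -> np.ndarray:
        """Difference of chosen- and unchosen-value responses (shared lag grid)."""
        if not np.array_equal(self.lags[chosen], self.lags[unchosen]):
            raise ValueError("regressors are on different lag grids")
        return self.betas[chosen] - self.betas[unchosen]


def deconvolve(
    ts,
    specs: list[RegressorSpec],
    fs: float = 20.0,
    grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_splits: int = 20,
    test_frac: float = 0.2,
    seed: int = 0,
    lam: float | None = None,
) -> DeconvResult:
    """Build the design, cross-validate the penalty (unless ``lam`` is given), solve.

    ``ts`` is a preprocessed PupilTimeSeries or a plain signal array at ``fs``.
    """
    if hasattr(ts, "values") and hasattr(ts, "times"):
        y = np.asarray(ts.values, dtype=float)
        times = np.asarray(ts.times, dtype=float)
        fs = ts.fs
    else:
        y = np.asarray(ts, dtype=float)
        times = None
    dm = build_design_matrix(specs, n_samples=len(y), fs=fs, times=times)
    if lam is None:
        lambda_star, cv_scores = cross_validate_lambda(
            dm, y, grid=grid, n_splits=n_splits, test_frac=test_frac, seed=seed
        )
    else:
        lambda_star, cv_scores = float(lam), np.full(len(np.asarray(grid)), np.nan)
    beta = ridge_solve(dm, y, lambda_star)
    betas: dict[str, np.ndarray] = {}
    lags: dict[str, np.ndarray] = {}
    for name in dm.regressor_names():
        sl, lag = dm.column_slice(name)
        betas[name] = beta[sl]
        lags[name] = lag
    return DeconvResult(
        betas=betas, lags=lags, lambda_star=lambda_star,
        cv_scores=cv_scores, lambda_grid=np.asarray(grid, dtype=float),
        n_splits=n_splits, beta_vector=beta,
    )


# ---------------------------------------------------------------------------
# Default regressor sets


OPTIONS_WINDOW = (-0.5, 3.0)
CHOICE_WINDOW = (-2.0, 1.5)
FEEDBACK_WINDOW = (-0.5, 3.0)


def default_learning_specs(trials, trajectory) -> list[RegressorSpec]:
    """The learning-phase design: 3 transients, 1 boxcar, 2 nuisance sticks,
    and z-scored chosen/unchosen-value and prediction-error covariates."""
    learning = [t for t in trials if t.phase == "learning"]
    if len(learning) != len(trajectory):
        raise ValueError("trials and trajectory are not aligned")
    t_on = np.array([t.t_options_on for t in learning])
    t_choice = np.array([t.t_choice for t in learning])
    t_fb = np.array([t.t_feedback for t in learning])
    t_fix = np.array([t.t_fixation for t in learning])
    t_off = np.array([t.t_options_off for t in learning])
    rts = np.array([t.rt for t in learning])
    qc = zscore(trajectory.q_chosen)
    qu = zscore(trajectory.q_unchosen)
    rpe = zscore(trajectory.rpe)
    return [
        RegressorSpec("options_on", "transient", t_on, OPTIONS_WINDOW),
        RegressorSpec("choice", "transient", t_choice, CHOICE_WINDOW),
        RegressorSpec("feedback", "transient", t_fb, FEEDBACK_WINDOW),
        RegressorSpec("decision_boxcar", "boxcar", t_on, durations=rts),
        RegressorSpec("fixation", "transient", t_fix, OPTIONS_WINDOW),
        RegressorSpec("options_off", "transient", t_off, OPTIONS_WINDOW),
        RegressorSpec("q_chosen_choice", "covariate", t_choice, CHOICE_WINDOW, covariate_values=qc),
        RegressorSpec("q_unchosen_choice", "covariate", t_choice, CHOICE_WINDOW, covariate_values=qu),
        RegressorSpec("q_chosen_fb", "covariate", t_fb, FEEDBACK_WINDOW, covariate_values=qc),
        RegressorSpec("q_unchosen_fb", "covariate", t_fb, FEEDBACK_WINDOW, covariate_values=qu),
        RegressorSpec("rpe_fb", "covariate", t_fb, FEEDBACK_WINDOW, covariate_values=rpe),
    ]


def _conflict_bin(p_diff_pct: float) -> str:
    # experimental value-difference bins; smaller differences = larger conflict
    if p_diff_pct <= 25.0:
        return "large"
    if p_diff_pct <= 45.0:
        return "medium"
    return "small"


def default_transfer_specs(trials, q_chosen, q_unchosen, config) -> list[RegressorSpec]:
    """Transfer-phase design: no feedback regressors; adds choice-conflict sticks
    binned by the experimental reward-probability differences."""
    transfer = [t for t in trials if t.phase == "transfer"]
    if len(transfer) != len(q_chosen):
        raise ValueError("trials and transfer values are not aligned")
    t_on = np.array([t.t_options_on for t in transfer])
    t_choice = np.array([t.t_choice for t in transfer])
    t_fix = np.array([t.t_fixation for t in transfer])
    t_off = np.array([t.t_options_off for t in transfer])
    rts = np.array([t.rt for t in transfer])
    qc = zscore(np.asarray(q_chosen))
    qu = zscore(np.asarray(q_unchosen))
    specs = [
        RegressorSpec("options_on", "transient", t_on, OPTIONS_WINDOW),
        RegressorSpec("choice", "transient", t_choice, CHOICE_WINDOW),
        RegressorSpec("decision_boxcar", "boxcar", t_on, durations=rts),
        RegressorSpec("fixation", "transient", t_fix, OPTIONS_WINDOW),
        RegressorSpec("options_off", "transient", t_off, OPTIONS_WINDOW),
        RegressorSpec("q_chosen_choice", "covariate", t_choice, CHOICE_WINDOW, covariate_values=qc),
        RegressorSpec("q_unchosen_choice", "covariate", t_choice, CHOICE_WINDOW, covariate_values=qu),
    ]
    bins: dict[str, list[float]] = {"small": [], "medium": [], "large": []}
    for t in transfer:
        a, b = t.pair
        diff = 100.0 * abs(config.option_probability(a) - config.option_probability(b))
        bins[_conflict_bin(diff)].append(t.t_choice)
    for level, times_ in bins.items():
        if times_:
            specs.append(
                RegressorSpec(f"conflict_{level}", "transient", np.asarray(times_), CHOICE_WINDOW)
            )
    return specs
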