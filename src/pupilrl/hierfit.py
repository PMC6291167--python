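"""Hierarchical Bayesian estimation of Q-learning parameters.

Per-subject parameters live on an unbounded probit scale: alpha = Phi(z'),
beta = 100 * Phi(z'), with z' drawn from group-level normal distributions.
Group means get a normal prior and group SDs a uniform prior; both literals
are configurable (the printed N(1,0) group-mean prior is degenerate and is
implemented as N(0,1) by default).

Sampling uses adaptive Metropolis-within-Gibbs: per-subject random-walk
updates on z' (vectorized across subjects), exact Gibbs draws for the group
means, and random-walk updates for the group SDs.  Convergence is summarized
with the rank-normalized split-Rhat statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import gaussian_kde

from .qlearning import AgentParams, EncodedTrials, batch_nll, encode_trials

__all__ = [
    "PriorConfig",
    "SamplerConfig",
    "GroupPosterior",
    "FitSummary",
    "to_native",
    "log_joint",
    "fit_hierarchical",
    "posterior_mode",
    "summarize_fit",
    "simulate_from_fit",
    "compare_models",
]

VARIANT_PARAMS = {
    "two_alpha": ("alpha_gain", "alpha_loss", "beta"),
    "one_alpha": ("alpha", "beta"),
}
RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class PriorConfig:
    """Group-level prior literals (all configurable)."""

    mu_mean: float = 0.0
    mu_sd: float = 1.0
    sd_low: float = 1.0
    sd_high: float = 1.5


@dataclass(frozen=True)
class SamplerConfig:
    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for Rhat")
        if self.n_warmup < 1 or self.n_draws < 1:
            raise ValueError("n_warmup and n_draws must be positive")


def _native_scale(name: str, z: np.ndarray) -> np.ndarray:
    """Probit transform onto the parameter's native bounds."""
    return 100.0 * ndtr(z) if name.startswith("beta") else ndtr(z)


def to_native(z_prime) -> AgentParams:
    """Map a transformed (z'_aG, z'_aL, z'_beta) triple to native AgentParams."""
    z = np.asarray(z_prime, dtype=float)
    if z.shape != (3,):
        raise ValueError("expected a transformed triple")
    return AgentParams(
        alpha_gain=float(ndtr(z[0])),
        alpha_loss=float(ndtr(z[1])),
        beta=float(100.0 * ndtr(z[2])),
    )


def _params_from_z(z: np.ndarray, variant: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Native (alpha_gain, alpha_loss, beta) arrays from a (n_subj, P) z matrix."""
    if variant == "two_alpha":
        ag = ndtr(z[:, 0])
        al = ndtr(z[:, 1])
        beta = 100.0 * ndtr(z[:, 2])
    elif variant == "one_alpha":
        ag = al = ndtr(z[:, 0])
        beta = 100.0 * ndtr(z[:, 1])
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return ag, al, beta


def _norm_logpdf(x, mu, sd):
    return -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def log_joint(
    data: EncodedTrials | None,
    z: np.ndarray,
    mu: np.ndarray,
    delta: np.ndarray,
    priors: PriorConfig = PriorConfig(),
    variant: str = "two_alpha",
) -> float:
    """Log of the full joint: group priors + subject-level normals + choice likelihood.

    Returns -inf when any group SD is outside the uniform prior support.
    ``data=None`` (or zero subjects) reduces to the prior terms alone.
    """
    mu = np.asarray(mu, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < priors.sd_low) or np.any(delta > priors.sd_high):
        return float("-inf")
    lp = float(np.sum(_norm_logpdf(mu, priors.mu_mean, priors.mu_sd)))
    lp -= mu.size * np.log(priors.sd_high - priors.sd_low)  # uniform prior density
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.size:
        lp += float(np.sum(_norm_logpdf(z, mu, delta)))
    if data is not None and data.n_subjects:
        ag, al, beta = _params_from_z(z, variant)
        lp -= float(np.sum(batch_nll(data, ag, al, beta)))
    return lp


@dataclass
class GroupPosterior:
    """MCMC samples of the hierarchical model, with convergence diagnostics."""

    param_names: tuple[str, ...]
    mu: np.ndarray  # (chains, draws, P)
    delta: np.ndarray  # (chains, draws, P)
    z: np.ndarray  # (chains, draws, n_subjects, P)
    rhat: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    variant: str = "two_alpha"

    @property
    def n_subjects(self) -> int:
        return self.z.shape[2]

    def native_subject_draws(self, subject: int, name: str) -> np.ndarray:
        """Pooled native-scale draws of one subject's parameter."""
        k = self.param_names.index(name)
        return _native_scale(name, self.z[:, :, subject, k].ravel())

    def group_mean_ci(self, name: str, level: float = 0.95) -> tuple[float, float, float]:
        """(posterior mean, lo, hi) credible interval for a group mean mu_z'."""
        k = self.param_names.index(name)
        draws = self.mu[:, :, k].ravel()
        half = 100.0 * (1.0 - level) / 2.0
        lo, hi = np.percentile(draws, [half, 100.0 - half])
        return float(draws.mean()), float(lo), float(hi)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        n_chains, n_draws, _ = self.mu.shape
        chain = np.repeat(np.arange(n_chains), n_draws)
        draw = np.tile(np.arange(n_draws), n_chains)
        for k, name in enumerate(self.param_names):
            rows.append(pd.DataFrame({
                "chain": chain, "draw": draw,
                "quantity": f"mu_{name}", "value": self.mu[:, :, k].ravel(),
            }))
            rows.append(pd.DataFrame({
                "chain": chain, "draw": draw,
                "quantity": f"delta_{name}", "value": self.delta[:, :, k].ravel(),
            }))
            for s in range(self.n_subjects):
                rows.append(pd.DataFrame({
                    "chain": chain, "draw": draw,
                    "quantity": f"z_{name}_s{s}", "value": self.z[:, :, s, k].ravel(),
                }))
        return pd.concat(rows, ignore_index=True)


def _rhat(samples: np.ndarray) -> float:
    """Rank-normalized split-Rhat of a (chains, draws) array."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(samples.astype(float)))


def _run_chain(
    data: EncodedTrials,
    priors: PriorConfig,
    variant: str,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
):
    names = VARIANT_PARAMS[variant]
    n_p = len(names)
    n_subj = data.n_subjects

    z = 0.5 * rng.standard_normal((n_subj, n_p))
    mu = z.mean(axis=0)
    delta = np.full(n_p, 0.5 * (priors.sd_low + priors.sd_high))
    scales = np.full((n_subj, n_p), 0.5)  # per-subject: identifiability varies widely
    delta_steps = np.full(n_p, 0.1)

    def nll_of(zmat: np.ndarray) -> np.ndarray:
        ag, al, beta = _params_from_z(zmat, variant)
        return batch_nll(data, ag, al, beta)

    cur_nll = nll_of(z)
    mu_out = np.empty((n_draws, n_p))
    delta_out = np.empty((n_draws, n_p))
    z_out = np.empty((n_draws, n_subj, n_p))
    acc_z = np.zeros((n_subj, n_p))
    acc_d = np.zeros(n_p)
    n_since = 0

    # running per-subject covariance (Welford) feeding joint ridge-following proposals
    jscale = np.full(n_subj, 0.8)
    acc_joint = np.zeros(n_subj)
    w_count = 0
    w_mean = np.zeros((n_subj, n_p))
    w_m2 = np.zeros((n_subj, n_p, n_p))
    chol = np.tile(0.3 * np.eye(n_p), (n_subj, 1, 1))

    total = n_warmup + n_draws
    for it in range(total):
        # 1) per-subject random-walk update of each z' coordinate, all subjects at once
        for k in range(n_p):
            prop = z.copy()
            prop[:, k] = z[:, k] + scales[:, k] * rng.standard_normal(n_subj)
            prop_nll = nll_of(prop)
            log_ratio = (
                (-prop_nll + _norm_logpdf(prop[:, k], mu[k], delta[k]))
                - (-cur_nll + _norm_logpdf(z[:, k], mu[k], delta[k]))
            )
            accept = np.log(rng.random(n_subj)) < log_ratio
            z[accept, k] = prop[accept, k]
            cur_nll = np.where(accept, prop_nll, cur_nll)
            acc_z[:, k] += accept

        # 1b) joint per-subject proposal along the adapted posterior covariance;
        #     essential for subjects whose learning rate and beta form a ridge
        eps = rng.standard_normal((n_subj, n_p))
        step = np.einsum("spq,sq->sp", chol, eps)
        prop = z + jscale[:, None] * step
        prop_nll = nll_of(prop)
        log_ratio = (
            (-prop_nll + _norm_logpdf(prop, mu, delta).sum(axis=1))
            - (-cur_nll + _norm_logpdf(z, mu, delta).sum(axis=1))
        )
        accept = np.log(rng.random(n_subj)) < log_ratio
        z[accept] = prop[accept]
        cur_nll = np.where(accept, prop_nll, cur_nll)
        acc_joint += accept

        # update covariance accumulators
        w_count += 1
        d0 = z - w_mean
        w_mean += d0 / w_count
        w_m2 += np.einsum("sp,sq->spq", d0, z - w_mean)

        # 2) exact Gibbs draw of each group mean (normal prior is conjugate)
        prec = n_subj / delta**2 + 1.0 / priors.mu_sd**2
        mean = (z.sum(axis=0) / delta**2 + priors.mu_mean / priors.mu_sd**2) / prec
        mu = mean + rng.standard_normal(n_p) / np.sqrt(prec)

        # 3) random-walk update of each group SD inside its uniform support
        for k in range(n_p):
            d_prop = delta[k] + delta_steps[k] * rng.standard_normal()
            if priors.sd_low <= d_prop <= priors.sd_high:
                log_ratio = float(
                    np.sum(_norm_logpdf(z[:, k], mu[k], d_prop))
                    - np.sum(_norm_logpdf(z[:, k], mu[k], delta[k]))
                )
                if np.log(rng.random()) < log_ratio:
                    delta[k] = d_prop
                    acc_d[k] += 1.0
        n_since += 1

        # adapt proposal scales toward ~0.35 acceptance during warmup
        if it < n_warmup and n_since == 25:
            scales *= np.exp(np.clip(acc_z / n_since - 0.35, -0.5, 0.5))
            np.clip(scales, 0.01, 10.0, out=scales)
            delta_steps *= np.exp(np.clip(acc_d / n_since - 0.35, -0.5, 0.5))
            jscale *= np.exp(np.clip(acc_joint / n_since - 0.3, -0.5, 0.5))
            np.clip(jscale, 0.05, 5.0, out=jscale)
            if w_count > 50:
                cov = w_m2 / (w_count - 1) + 1e-6 * np.eye(n_p)
                chol = np.linalg.cholesky(cov)
            acc_z[:] = 0.0
            acc_d[:] = 0.0
            acc_joint[:] = 0.0
            n_since = 0

        if it >= n_warmup:
            j = it - n_warmup
            mu_out[j] = mu
            delta_out[j] = delta
            z_out[j] = z

    return mu_out, delta_out, z_out


def fit_hierarchical(
    subject_trials,
    sampler: SamplerConfig = SamplerConfig(),
    priors: PriorConfig = PriorConfig(),
    variant: str = "two_alpha",
    rt_floor: float = 0.15,
    rt_deadline: float = 3.5,
) -> GroupPosterior:
    """Fit the hierarchical model by MCMC and attach Rhat for every quantity.

    ``subject_trials`` is a list of per-subject learning-trial lists (or an
    already-encoded :class:`EncodedTrials`).  Only trials with RTs inside
    [rt_floor, rt_deadline] contribute to the likelihood.
    """
    sampler.validate()
    if isinstance(subject_trials, EncodedTrials):
        data = subject_trials
    else:
        data = encode_trials(subject_trials, rt_floor=rt_floor, rt_deadline=rt_deadline)
    if data.n_subjects == 0:
        raise ValueError("no subjects to fit")
    names = VARIANT_PARAMS[variant]

    seeds = np.random.SeedSequence(sampler.seed).spawn(sampler.n_chains)
    mus, deltas, zs = [], [], []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        m, d, zz = _run_chain(data, priors, variant, sampler.n_warmup, sampler.n_draws, rng)
        mus.append(m)
        deltas.append(d)
        zs.append(zz)
    post = GroupPosterior(
        param_names=names,
        mu=np.stack(mus),
        delta=np.stack(deltas),
        z=np.stack(zs),
        variant=variant,
    )

    rhat: dict[str, float] = {}
    for k, name in enumerate(names):
        rhat[f"mu_{name}"] = _rhat(post.mu[:, :, k])
        rhat[f"delta_{name}"] = _rhat(post.delta[:, :, k])
        for s in range(data.n_subjects):
            rhat[f"z_{name}_s{s}"] = _rhat(post.z[:, :, s, k])
    post.rhat = rhat
    post.converged = bool(max(rhat.values()) <= RHAT_THRESHOLD)
    if not post.converged:
        warnings.warn(
            f"max Rhat {max(rhat.values()):.3f} exceeds {RHAT_THRESHOLD}; "
            "treat estimates with caution",
            stacklevel=2,
        )
    return post


def posterior_mode(samples: np.ndarray) -> float:
    """Mode of a kernel-density estimate over the draws, on a 512-point grid.

    Uses Silverman's rule for the bandwidth; constant samples return the
    constant directly.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2 or np.ptp(x) == 0.0:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


@dataclass
class FitSummary:
    """Per-subject posterior-mode point estimates with likelihood-based scores."""

    table: pd.DataFrame  # columns: subject, alpha_gain, alpha_loss, beta, nll, k, n, aic, bic
    variant: str = "two_alpha"

    def params_for(self, subject: int) -> AgentParams:
        row = self.table.loc[self.table["subject"] == subject].iloc[0]
        return AgentParams(
            alpha_gain=float(row["alpha_gain"]),
            alpha_loss=float(row["alpha_loss"]),
            beta=float(row["beta"]),
        )


def summarize_fit(post: GroupPosterior, data: EncodedTrials) -> FitSummary:
    """Posterior modes per subject, plus nll/AIC/BIC at those point estimates."""
    names = post.param_names
    k_free = len(names)
    rows = []
    for s in range(post.n_subjects):
        est = {name: posterior_mode(post.native_subject_draws(s, name)) for name in names}
        if post.variant == "one_alpha":
            ag = al = est["alpha"]
        else:
            ag, al = est["alpha_gain"], est["alpha_loss"]
        beta = est["beta"]
        one = EncodedTrials(
            chosen=data.chosen[s : s + 1],
            unchosen=data.unchosen[s : s + 1],
            outcome=data.outcome[s : s + 1],
            include=data.include[s : s + 1],
        )
        nll = float(batch_nll(one, np.array([ag]), np.array([al]), np.array([beta]))[0])
        n = int(one.n_modeled[0])
        rows.append({
            "subject": s, "alpha_gain": ag, "alpha_loss": al, "beta": beta,
            "nll": nll, "k": k_free, "n": n,
            "aic": 2.0 * k_free + 2.0 * nll,
            "bic": k_free * np.log(n) + 2.0 * nll,
        })
    return FitSummary(table=pd.DataFrame(rows), variant=post.variant)


def simulate_from_fit(fit: FitSummary, config, n_reps: int = 100, seed: int = 0) -> np.ndarray:
    """Simulate choices with each subject's point estimate and average accuracy.

    Returns an (n_subjects, n_runs_learning, n_pairs) accuracy array, where
    accuracy is the fraction of trials on which the high-probability option of
    the pair was chosen, averaged over ``n_reps`` simulations.
    """
    from .task import simulate_agent  # deferred: task imports qlearning

    subjects = fit.table["subject"].tolist()
    pair_names = [p.name for p in config.pairs]
    acc = np.zeros((len(subjects), config.n_runs_learning, len(pair_names)))
    seeds = np.random.SeedSequence(seed).spawn(len(subjects))
    for si, subject in enumerate(subjects):
        params = fit.params_for(subject)
        sub_seeds = seeds[si].generate_state(n_reps)
        for rep in range(n_reps):
            trials, _ = simulate_agent(params, config, int(sub_seeds[rep]))
            for run in range(config.n_runs_learning):
                for pi, pname in enumerate(pair_names):
                    sel = [
                        t for t in trials
                        if t.phase == "learning" and t.run_index == run and t.pair_name == pname
                    ]
                    hi = config.pair_by_name(pname).hi
                    acc[si, run, pi] += np.mean([t.choice == hi for t in sel])
        acc[si] /= n_reps
    return acc


def compare_models(
    subject_trials,
    sampler: SamplerConfig = SamplerConfig(),
    priors: PriorConfig = PriorConfig(),
) -> pd.DataFrame:
    """Fit the one- and two-learning-rate variants and tabulate per-subject AIC/BIC."""
    data = subject_trials if isinstance(subject_trials, EncodedTrials) else encode_trials(subject_trials)
    frames = []
    for variant in ("one_alpha", "two_alpha"):
        post = fit_hierarchical(data, sampler=sampler, priors=priors, variant=variant)
        summ = summarize_fit(post, data)
        t = summ.table[["subject", "nll", "aic", "bic"]].copy()
        t["variant"] = variant
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
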