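"""Hierarchical Bayesian estimation of drift-diffusion parameters.

Subjects' parameters are modelled as draws from group-level distributions:
normal for drift ``v``, zero-truncated normal for bound separation ``a``
and non-decision time ``t0``, and logit-normal for the relative start
``z`` (the group location is kept on the probability scale).  Hyperpriors
are bounded uniforms.  Sampling is Metropolis-within-Gibbs with Gaussian
random-walk proposals, adapted during burn-in and frozen afterwards.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_ndtr, logit

from ._kernels import subject_logliks

__all__ = [
    "GroupHyperParams",
    "MCMCConfig",
    "PosteriorSamples",
    "HDInterval",
    "fit_hierarchical_ddm",
    "gelman_rubin",
    "hdi",
    "compare_groups",
]

PARAM_NAMES = ("v", "a", "z", "t0")
GROUP_NAMES = tuple(f"{k}_{p}" for p in PARAM_NAMES for k in ("mu", "sigma"))

# uniform hyperprior bounds (log-millisecond time axis)
PRIOR_BOUNDS = {
    "mu_v": (-5.0, 5.0),
    "mu_a": (1e-6, 10.0),
    "mu_z": (1e-6, 1.0 - 1e-6),
    "mu_t0": (0.0, 12.0),
    "sigma_v": (1e-6, 5.0),
    "sigma_a": (1e-6, 5.0),
    "sigma_z": (1e-6, 5.0),
    "sigma_t0": (1e-6, 5.0),
}


@dataclass(frozen=True)
class GroupHyperParams:
    """Group-level location and spread for each diffusion parameter."""

    mu_v: float
    sigma_v: float
    mu_a: float
    sigma_a: float
    mu_z: float
    sigma_z: float
    mu_t0: float
    sigma_t0: float

    def __post_init__(self) -> None:
        for name in ("sigma_v", "sigma_a", "sigma_z", "sigma_t0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu_a <= 0 or self.mu_t0 < 0:
            raise ValueError("group means for a and t0 must be positive")
        if not 0 < self.mu_z < 1:
            raise ValueError("group mean for z must lie in (0, 1)")

    def sample_subjects(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        """Draw per-subject parameters from the group distributions."""
        v = rng.normal(self.mu_v, self.sigma_v, n)
        a = _sample_truncnorm(self.mu_a, self.sigma_a, n, rng)
        z = expit(rng.normal(logit(self.mu_z), self.sigma_z, n))
        t0 = _sample_truncnorm(self.mu_t0, self.sigma_t0, n, rng)
        return pd.DataFrame({"v": v, "a": a, "z": z, "t0": t0})


def _sample_truncnorm(mu, sigma, n, rng):
    out = rng.normal(mu, sigma, n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mu, sigma, bad.sum())
        bad = out <= 0
    return out


@dataclass(frozen=True)
class MCMCConfig:
    n_samples: int = 2000
    burn_in: int = 500
    thin: int = 1
    n_chains: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_samples:
            raise ValueError("burn_in must be smaller than n_samples")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_samples - self.burn_in) // self.thin


@dataclass
class HDInterval:
    lower: float
    upper: float
    mass: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower must not exceed upper")

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


@dataclass
class PosteriorSamples:
    """Retained MCMC draws: group arrays are (n_chains, n_draws), subject
    arrays are (n_chains, n_draws, n_subjects)."""

    group: dict
    subject: dict
    subject_ids: list
    config: MCMCConfig
    acceptance: dict = field(default_factory=dict)
    data_hash: str = ""

    @property
    def n_chains(self) -> int:
        return next(iter(self.group.values())).shape[0]

    def pooled(self, parameter: str) -> np.ndarray:
        """Draws pooled across chains, concatenated in chain-index order."""
        if parameter not in self.group:
            raise KeyError(f"unknown parameter {parameter!r}")
        return self.group[parameter].reshape(-1)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.group.items():
            pooled = arr.reshape(-1)
            iv = hdi(pooled, 0.95)
            rows.append(
                {
                    "parameter": name,
                    "mean": pooled.mean(),
                    "sd": pooled.std(ddof=1),
                    "hdi_lower": iv.lower,
                    "hdi_upper": iv.upper,
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Long CSV-ready layout: chain, iteration, parameter, value."""
        recs = []
        for name, arr in self.group.items():
            n_chains, n_draws = arr.shape
            recs.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(n_chains), n_draws),
                        "iteration": np.tile(np.arange(n_draws), n_chains),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(recs, ignore_index=True)

    def manifest(self) -> dict:
        return {
            "config": {
                "n_samples": self.config.n_samples,
                "burn_in": self.config.burn_in,
                "thin": self.config.thin,
                "n_chains": self.config.n_chains,
                "seed": self.config.seed,
            },
            "data_hash": self.data_hash,
            "acceptance": self.acceptance,
            "gelman_rubin": gelman_rubin(self) if self.n_chains >= 2 else None,
        }


# ---------------------------------------------------------------------------
# group log densities

_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


def _norm_logpdf(x, mu, sigma):
    return -0.5 * ((x - mu) / sigma) ** 2 - np.log(sigma) - _LOG_SQRT_2PI


def _group_logpdf(name, x, mu, sigma):
    """Log density of subject values ``x`` under the group model."""
    if name == "v":
        return _norm_logpdf(x, mu, sigma)
    if name in ("a", "t0"):  # zero-truncated normal
        out = np.where(x > 0, _norm_logpdf(x, mu, sigma), -np.inf)
        return out - log_ndtr(mu / sigma)
    if name == "z":  # logit-normal with group location on probability scale
        lx = logit(x)
        return _norm_logpdf(lx, logit(mu), sigma) - np.log(x * (1.0 - x))
    raise KeyError(name)


def _in_domain(name, x):
    if name == "v":
        return np.isfinite(x)
    if name in ("a", "t0"):
        return x > 0
    return (x > 0) & (x < 1)


# ---------------------------------------------------------------------------
# sampler


def _prepare(trials: pd.DataFrame):
    needed = {"participant_id", "rt", "response"}
    missing = needed - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    ids = sorted(trials["participant_id"].unique().tolist())
    idx = trials["participant_id"].map({p: i for i, p in enumerate(ids)}).to_numpy(np.int64)
    rt = trials["rt"].to_numpy(float)
    if not np.all(np.isfinite(rt)) or np.any(rt <= 0):
        raise ValueError("rt column must be finite and positive on the model's time axis")
    upper = trials["response"].to_numpy()
    if upper.dtype != bool:
        upper = np.asarray(upper, dtype=bool)
    counts = np.bincount(idx, minlength=len(ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 subjects")
    if counts.min() < 10:
        raise ValueError("need at least 10 trials per subject")
    return ids, idx, rt, upper


def fit_hierarchical_ddm(trials: pd.DataFrame, config: MCMCConfig) -> PosteriorSamples:
    """Fit the hierarchical diffusion model to a veracity-coded trial table.

    ``trials`` needs columns ``participant_id``, ``rt`` (log-ms axis) and
    ``response`` (True = upper/veracity-promoting bound).  An empty table is
    allowed and yields draws from the hyperprior.
    """
    if len(trials) == 0:
        ids, idx = [], np.empty(0, np.int64)
        rt = np.empty(0)
        upper = np.empty(0, bool)
    else:
        ids, idx, rt, upper = _prepare(trials)

    h = hashlib.sha256()
    h.update(rt.tobytes())
    h.update(upper.tobytes())
    h.update(idx.tobytes())
    data_hash = h.hexdigest()[:16]

    root = np.random.SeedSequence(config.seed)
    chain_seeds = root.spawn(config.n_chains)

    group_draws = {n: np.empty((config.n_chains, config.n_draws)) for n in GROUP_NAMES}
    subj_draws = {
        p: np.empty((config.n_chains, config.n_draws, len(ids))) for p in PARAM_NAMES
    }
    acceptance = {}
    for c, ss in enumerate(chain_seeds):
        g, s, acc = _run_chain(ids, idx, rt, upper, config, np.random.default_rng(ss))
        for n in GROUP_NAMES:
            group_draws[n][c] = g[n]
        for p in PARAM_NAMES:
            subj_draws[p][c] = s[p]
        acceptance[f"chain_{c}"] = acc

    return PosteriorSamples(
        group=group_draws,
        subject=subj_draws,
        subject_ids=ids,
        config=config,
        acceptance=acceptance,
        data_hash=data_hash,
    )


def _init_state(ids, idx, rt, upper, rng):
    n = len(ids)
    subj = {}
    if n:
        min_rt = np.full(n, np.inf)
        np.minimum.at(min_rt, idx, rt)
        frac_up = np.bincount(idx, weights=upper, minlength=n) / np.bincount(idx, minlength=n)
        subj["t0"] = np.maximum(min_rt - 0.2 - 0.2 * rng.random(n), 1e-3)
        subj["a"] = np.full(n, 2.0) + 0.1 * rng.standard_normal(n)
        subj["z"] = np.full(n, 0.5) + 0.02 * rng.standard_normal(n)
        subj["v"] = np.clip(2.0 * (frac_up - 0.5), -2, 2) + 0.05 * rng.standard_normal(n)
    else:
        subj = {p: np.empty(0) for p in PARAM_NAMES}

    group = {}
    for p in PARAM_NAMES:
        lo, hi = PRIOR_BOUNDS[f"mu_{p}"]
        if n:
            m = subj[p].mean()
            group[f"mu_{p}"] = float(np.clip(m, lo + 1e-4, hi - 1e-4))
            group[f"sigma_{p}"] = 0.3
        else:
            group[f"mu_{p}"] = float(lo + (hi - lo) * rng.random())
            group[f"sigma_{p}"] = float(0.1 + 4.0 * rng.random())
    return group, subj


def _run_chain(ids, idx, rt, upper, config, rng):
    n_subj = len(ids)
    group, subj = _init_state(ids, idx, rt, upper, rng)

    def lik(v, a, z, t0):
        if n_subj == 0:
            return np.empty(0)
        return subject_logliks(rt, upper, idx, n_subj, v, a, z, t0)

    cur_ll = lik(subj["v"], subj["a"], subj["z"], subj["t0"])

    subj_scale = {p: np.full(n_subj, s) for p, s in
                  zip(PARAM_NAMES, (0.3, 0.2, 0.05, 0.05))}
    group_scale = {n: 0.1 for n in GROUP_NAMES}
    subj_acc = {p: np.zeros(n_subj) for p in PARAM_NAMES}
    group_acc = {n: 0.0 for n in GROUP_NAMES}
    window = 0

    n_draws = config.n_draws
    g_out = {n: np.empty(n_draws) for n in GROUP_NAMES}
    s_out = {p: np.empty((n_draws, n_subj)) for p in PARAM_NAMES}
    k = 0

    ADAPT_EVERY = 25
    GROUP_SCANS = 5
    for sweep in range(1, config.n_samples + 1):
        adapting = sweep <= config.burn_in

        # --- subject-level blocks, vectorised across subjects ------------
        for p in PARAM_NAMES:
            if n_subj == 0:
                break
            cur = subj[p]
            prop = cur + subj_scale[p] * rng.standard_normal(n_subj)
            ok = _in_domain(p, prop)
            prop_eff = np.where(ok, prop, cur)
            args = {q: subj[q] for q in PARAM_NAMES}
            args[p] = prop_eff
            new_ll = lik(args["v"], args["a"], args["z"], args["t0"])
            mu, sg = group[f"mu_{p}"], group[f"sigma_{p}"]
            logr = (
                new_ll
                - cur_ll
                + _group_logpdf(p, prop_eff, mu, sg)
                - _group_logpdf(p, cur, mu, sg)
            )
            accept = ok & (np.log(rng.random(n_subj)) < logr)
            subj[p] = np.where(accept, prop_eff, cur)
            cur_ll = np.where(accept, new_ll, cur_ll)
            if adapting:
                subj_acc[p] += accept

        # --- group-level blocks -------------------------------------------
        # several cheap scans per sweep: group conditionals cost nothing
        # next to a likelihood pass, and extra scans speed hyper mixing
        for _scan in range(GROUP_SCANS):
          for p in PARAM_NAMES:
            for kind in ("mu", "sigma"):
                name = f"{kind}_{p}"
                lo, hi = PRIOR_BOUNDS[name]
                cur = group[name]
                prop = cur + group_scale[name] * rng.standard_normal()
                if not lo < prop < hi:
                    continue
                mu_c, sg_c = group[f"mu_{p}"], group[f"sigma_{p}"]
                mu_p, sg_p = (prop, sg_c) if kind == "mu" else (mu_c, prop)
                if n_subj:
                    logr = float(
                        np.sum(_group_logpdf(p, subj[p], mu_p, sg_p))
                        - np.sum(_group_logpdf(p, subj[p], mu_c, sg_c))
                    )
                else:
                    logr = 0.0  # flat prior: always accept in-bounds moves
                if np.log(rng.random()) < logr:
                    group[name] = prop
                    if adapting:
                        group_acc[name] += 1.0

        # --- proposal adaptation (burn-in only) ---------------------------
        window += 1
        if adapting and window == ADAPT_EVERY:
            for p in PARAM_NAMES:
                rate = subj_acc[p] / ADAPT_EVERY
                subj_scale[p] *= np.exp(1.5 * (rate - 0.35))
                subj_scale[p] = np.clip(subj_scale[p], 1e-4, 5.0)
                subj_acc[p][:] = 0
            for name in GROUP_NAMES:
                rate = group_acc[name] / (ADAPT_EVERY * GROUP_SCANS)
                group_scale[name] *= float(np.exp(1.5 * (rate - 0.35)))
                group_scale[name] = float(np.clip(group_scale[name], 1e-4, 5.0))
                group_acc[name] = 0.0
            window = 0
        elif window == ADAPT_EVERY:
            window = 0

        # --- retention ----------------------------------------------------
        if sweep > config.burn_in and (sweep - config.burn_in) % config.thin == 0:
            for n in GROUP_NAMES:
                g_out[n][k] = group[n]
            for p in PARAM_NAMES:
                s_out[p][k] = subj[p]
            k += 1

    acc_summary = {
        "group_scales": {n: group_scale[n] for n in GROUP_NAMES},
        "subject_scale_means": {p: float(subj_scale[p].mean()) if n_subj else None
                                for p in PARAM_NAMES},
    }
    return g_out, s_out, acc_summary


# ---------------------------------------------------------------------------
# diagnostics and comparisons


def gelman_rubin(samples: PosteriorSamples | dict) -> dict:
    """Classical potential-scale-reduction factor per monitored parameter.

    Computed from the between- and within-chain variances of the retained
    draws; requires at least two chains of equal length.
    """
    group = samples.group if isinstance(samples, PosteriorSamples) else samples
    out = {}
    for name, arr in group.items():
        arr = np.asarray(arr, float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("Gelman-Rubin needs >= 2 chains of equal length")
        m, n = arr.shape
        chain_means = arr.mean(axis=1)
        w = arr.var(axis=1, ddof=1).mean()
        b = n * chain_means.var(ddof=1)
        if w == 0:
            out[name] = 1.0
            continue
        var_hat = (n - 1) / n * w + b / n
        # the finite-sample estimator dips below 1 when chains agree; floor it
        out[name] = float(max(1.0, np.sqrt(var_hat / w)))
    return out


def hdi(draws: np.ndarray, mass: float = 0.95) -> HDInterval:
    """Shortest contiguous interval containing ``ceil(mass * n)`` draws."""
    draws = np.asarray(draws, float).ravel()
    if draws.size == 0:
        raise ValueError("hdi needs a non-empty sample")
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(draws)
    n = x.size
    m = int(np.ceil(mass * n))
    if m >= n:
        return HDInterval(float(x[0]), float(x[-1]), mass)
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return HDInterval(float(x[i]), float(x[i + m - 1]), mass)


def compare_groups(
    post_a: PosteriorSamples,
    post_b: PosteriorSamples,
    parameter: str,
    mass: float = 0.95,
):
    """HDI of the difference ``parameter_a - parameter_b`` of pooled draws.

    Returns ``(HDInterval, credible)`` where ``credible`` is True when the
    interval excludes zero.
    """
    da = post_a.pooled(parameter)
    db = post_b.pooled(parameter)
    n = min(da.size, db.size)
    diff = da[:n] - db[:n]
    iv = hdi(diff, mass)
    return iv, not iv.contains(0.0)


def save_posterior(samples: PosteriorSamples, draws_path, manifest_path) -> None:
    samples.to_frame().to_csv(draws_path, index=False)
    with open(manifest_path, "w") as fh:
        json.dump(samples.manifest(), fh, indent=2, sort_keys=True)
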