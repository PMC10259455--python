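"""End-to-end orchestration: simulate cohorts, fit per feedback group,
compare posteriors, run parameter recovery and posterior-predictive checks,
and write a reproducible results bundle with a hashed manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import REFERENCE_CI, POOLING, ExperimentConfig, child_seed
from .inference import (
    GroupHyperParams,
    MCMCConfig,
    PosteriorSamples,
    compare_groups,
    fit_hierarchical_ddm,
    gelman_rubin,
    hdi,
)
from .metrics import oneway_anova, sharing_discernment, veracity_coded_discernment
from .synth import (
    default_reaction_profile,
    derive_feedback,
    generate_participants,
    generate_posts,
    simulate_reaction_study,
    simulate_sharing_study,
)

__all__ = ["simulate_experiment", "run_recovery", "posterior_predictive", "run_full_pipeline"]

GROUP_LOCATIONS = ("mu_v", "mu_a", "mu_z", "mu_t0")


def simulate_experiment(config: ExperimentConfig) -> dict:
    """Simulate all trial tables of a sharing experiment (one cohort per
    environment, feedback taken from a reaction-study simulation)."""
    posts = generate_posts(config.n_true, config.n_false, seed=child_seed(config.seed, "posts"))
    profile = default_reaction_profile()
    raters = generate_participants(
        100, "baseline", seed=child_seed(config.seed, "participants", 999), prefix="rater"
    )
    reactions = simulate_reaction_study(
        posts, raters, profile, seed=child_seed(config.seed, "reactions")
    )
    posts = derive_feedback(reactions, posts)

    tables = {}
    for i, env in enumerate(config.environments):
        hyper = config.hypers[POOLING[env]]
        cohort = generate_participants(
            config.cohorts[env],
            env,
            hyper=hyper,
            seed=child_seed(config.seed, "participants", i),
            prefix=f"{env}_",
        )
        tables[env] = simulate_sharing_study(
            posts, cohort, seed=child_seed(config.seed, "sharing", i)
        )
    return {"posts": posts, "reactions": reactions, "trials": tables}


def _fit_pooled(tables: dict, config: ExperimentConfig) -> dict:
    """Fit one hierarchical model per pooled feedback group."""
    fits = {}
    for g, group in enumerate(config.fit_groups):
        envs = [e for e in config.environments if POOLING[e] == group]
        trials = pd.concat([tables[e] for e in envs], ignore_index=True)
        mcmc = MCMCConfig(
            n_samples=config.mcmc.n_samples,
            burn_in=config.mcmc.burn_in,
            thin=config.mcmc.thin,
            n_chains=config.mcmc.n_chains,
            seed=child_seed(config.seed, "fit", g),
        )
        fits[group] = fit_hierarchical_ddm(trials, mcmc)
    return fits


def run_recovery(config: ExperimentConfig, experiment_label: str | None = None) -> dict:
    """Simulate cohorts from the generating group parameters, refit each
    pooled group, and report how well the posteriors recover the inputs.

    Returns a dict with a per-(group, parameter) recovery table, pairwise
    drift comparisons, the behavioral discernment block, and the fits.
    """
    if config.mcmc.n_draws < 10:
        raise ValueError("MCMC config retains too few draws for recovery")
    label = experiment_label or config.template
    sim = simulate_experiment(config)
    fits = _fit_pooled(sim["trials"], config)

    rows = []
    for group, post in fits.items():
        gen = config.hypers[group]
        ci_table = REFERENCE_CI.get((label, group), {})
        for name in GROUP_LOCATIONS:
            gen_val = getattr(gen, name)
            draws = post.pooled(name)
            iv = hdi(draws, 0.95)
            ci = ci_table.get(name)
            rows.append(
                {
                    "group": group,
                    "parameter": name,
                    "generating": gen_val,
                    "posterior_mean": float(draws.mean()),
                    "posterior_sd": float(draws.std(ddof=1)),
                    "hdi_lower": iv.lower,
                    "hdi_upper": iv.upper,
                    "in_recovered_hdi": bool(iv.contains(gen_val)),
                    "reference_ci_lower": None if ci is None else ci[0],
                    "reference_ci_upper": None if ci is None else ci[1],
                    "in_reference_ci": None if ci is None else bool(ci[0] <= draws.mean() <= ci[1]),
                }
            )
    recovery = pd.DataFrame(rows)

    comparisons = []
    groups = list(fits)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for name in GROUP_LOCATIONS:
                iv, credible = compare_groups(fits[groups[i]], fits[groups[j]], name)
                comparisons.append(
                    {
                        "group_a": groups[i],
                        "group_b": groups[j],
                        "parameter": name,
                        "diff_hdi_lower": iv.lower,
                        "diff_hdi_upper": iv.upper,
                        "credible": credible,
                    }
                )

    behav = _behavior_block(sim["trials"])
    return {
        "recovery": recovery,
        "comparisons": pd.DataFrame(comparisons),
        "behavior": behav,
        "fits": fits,
        "tables": sim,
    }


def _behavior_block(tables: dict) -> dict:
    frames = []
    for env, t in tables.items():
        d = sharing_discernment(t)
        d["environment"] = env
        frames.append(d)
    disc = pd.concat(frames, ignore_index=True)
    anova = oneway_anova(disc["value"], disc["environment"])
    means = disc.groupby("environment")["value"].agg(["mean", "sem"]).reset_index()
    return {"discernment": disc, "means": means, "anova": anova}


def posterior_predictive(
    group_params: dict,
    design: dict,
    seed: int = 0,
) -> dict:
    """Simulate a cohort per environment at exactly the design's dimensions
    (``design[env] = (n_subjects, n_trials)``) and compare veracity-coded
    discernment across environments with a one-way ANOVA.

    ``group_params`` maps each environment in the design to its
    ``GroupHyperParams`` (e.g. posterior means of a fit).
    """
    missing = set(design) - set(group_params)
    if missing:
        raise ValueError(f"no parameters for environments {sorted(missing)}")
    frames = []
    for i, (env, (n_subj, n_trials)) in enumerate(sorted(design.items())):
        if n_subj < 1 or n_trials < 1:
            raise ValueError("design dimensions must be >= 1")
        n_true = n_trials // 2 + n_trials % 2
        posts = generate_posts(n_true, n_trials - n_true, seed=child_seed(seed, "posts", i))
        cohort = generate_participants(
            n_subj,
            env if env in POOLING else "baseline",
            hyper=group_params[env],
            seed=child_seed(seed, "ppc", 2 * i),
            prefix=f"ppc_{env}_",
        )
        t = simulate_sharing_study(posts, cohort, seed=child_seed(seed, "ppc", 2 * i + 1))
        t["environment"] = env
        frames.append(t)
    trials = pd.concat(frames, ignore_index=True)

    disc = []
    for env, sub in trials.groupby("environment"):
        d = veracity_coded_discernment(sub)
        d["environment"] = env
        disc.append(d)
    disc = pd.concat(disc, ignore_index=True)
    anova = oneway_anova(disc["value"], disc["environment"]) if disc["environment"].nunique() > 1 else None
    return {"trials": trials, "discernment": disc, "anova": anova}


# ---------------------------------------------------------------------------
# full bundle


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_pipeline(config: ExperimentConfig, out_dir, overwrite: bool = False) -> dict:
    """Simulate, summarize, fit, diagnose and compare; write everything to
    ``out_dir`` and return the manifest (also written as JSON).

    Refuses to touch a directory holding earlier outputs unless
    ``overwrite`` is set.  Identical (config, seed) pairs produce
    byte-identical manifests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")

    sim = simulate_experiment(config)
    files = {}

    def write_csv(name, df):
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        files[name] = _sha256(path)

    write_csv("posts.csv", sim["posts"])
    write_csv("reactions.csv", sim["reactions"])
    for env, t in sim["trials"].items():
        write_csv(f"trials_{env}.csv", t)

    behav = _behavior_block(sim["trials"])
    write_csv("discernment.csv", behav["discernment"])
    write_csv("discernment_means.csv", behav["means"])

    fits = _fit_pooled(sim["trials"], config)
    diagnostics = {}
    for group, post in fits.items():
        write_csv(f"posterior_{group}.csv", post.to_frame())
        diagnostics[group] = gelman_rubin(post) if post.n_chains >= 2 else None

    comparisons = []
    groups = list(fits)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for name in GROUP_LOCATIONS:
                iv, credible = compare_groups(fits[groups[i]], fits[groups[j]], name)
                comparisons.append(
                    {
                        "group_a": groups[i],
                        "group_b": groups[j],
                        "parameter": name,
                        "diff_hdi_lower": iv.lower,
                        "diff_hdi_upper": iv.upper,
                        "credible": credible,
                    }
                )
    write_csv("comparisons.csv", pd.DataFrame(comparisons))

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "anova": {k: (list(v) if isinstance(v, tuple) else v) for k, v in behav["anova"].items()},
        "gelman_rubin": diagnostics,
        "files": files,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
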