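"""Experiment templates, generating group parameters, and seed splitting.

The printed group estimates used as generating values for the sharing
experiments (drift, bound separation, relative start, non-decision time on
the log-ms axis):

===============  =======  ========  ======  ======
fit group        drift v  bound a   start z  t0
===============  =======  ========  ======  ======
exp2 baseline      0.098    2.153    0.497   7.025
exp2 dis_like      0.100    2.373    0.491   6.936
exp2 dis_trust     0.216    2.403    0.480   6.681
exp3 baseline      0.006    2.238    0.500   6.900
exp3 dis_like      0.037    2.207    0.500   7.051
exp3 dis_trust     0.120    2.209    0.489   7.076
===============  =======  ========  ======  ======

Group spreads are not printed anywhere; the defaults below are chosen so
that subject-level heterogeneity is comparable to the implied posterior
widths (see the package README).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .inference import GroupHyperParams, MCMCConfig

__all__ = [
    "ExperimentConfig",
    "EXP2_GROUP_VALUES",
    "EXP3_GROUP_VALUES",
    "REFERENCE_CI",
    "POOLING",
    "default_exp2_config",
    "default_exp3_config",
    "load_config",
    "child_seed",
]

#: default group spreads (v, a, logit-z, t0) used wherever only group
#: means are known
DEFAULT_SPREADS = {"sigma_v": 0.2, "sigma_a": 0.35, "sigma_z": 0.15, "sigma_t0": 0.3}


def _hyper(v, a, z, t0, **over) -> GroupHyperParams:
    kw = dict(DEFAULT_SPREADS)
    kw.update(over)
    return GroupHyperParams(mu_v=v, mu_a=a, mu_z=z, mu_t0=t0, **kw)


EXP2_GROUP_VALUES = {
    "baseline": _hyper(0.098, 2.153, 0.497, 7.025),
    "dis_like": _hyper(0.100, 2.373, 0.491, 6.936),
    "dis_trust": _hyper(0.216, 2.403, 0.480, 6.681),
}

EXP3_GROUP_VALUES = {
    "baseline": _hyper(0.006, 2.238, 0.500, 6.900),
    "dis_like": _hyper(0.037, 2.207, 0.500, 7.051),
    "dis_trust": _hyper(0.120, 2.209, 0.489, 7.076),
}

#: published 95% credible intervals for the group locations, keyed as
#: (experiment, fit group) -> parameter -> (lower, upper)
REFERENCE_CI = {
    ("exp2", "baseline"): {"mu_v": (0.039, 0.158), "mu_a": (2.090, 2.214),
                           "mu_z": (0.486, 0.508), "mu_t0": (6.898, 7.154)},
    ("exp2", "dis_like"): {"mu_v": (0.056, 0.145), "mu_a": (2.281, 2.466),
                           "mu_z": (0.483, 0.500), "mu_t0": (6.802, 7.071)},
    ("exp2", "dis_trust"): {"mu_v": (0.170, 0.262), "mu_a": (2.280, 2.529),
                            "mu_z": (0.471, 0.490), "mu_t0": (6.425, 6.940)},
    ("exp3", "baseline"): {"mu_v": (-0.027, 0.037), "mu_a": (2.153, 2.328),
                           "mu_z": (0.490, 0.510), "mu_t0": (6.762, 7.040)},
    ("exp3", "dis_like"): {"mu_v": (0.002, 0.069), "mu_a": (2.132, 2.286),
                           "mu_z": (0.490, 0.511), "mu_t0": (6.918, 7.186)},
    ("exp3", "dis_trust"): {"mu_v": (0.086, 0.155), "mu_a": (2.134, 2.286),
                            "mu_z": (0.476, 0.500), "mu_t0": (6.944, 7.208)},
}

#: environment -> fit group: trust+distrust pool together, like+dislike pool
POOLING = {
    "baseline": "baseline",
    "like": "dis_like",
    "dislike": "dis_like",
    "like_dislike": "dis_like",
    "trust": "dis_trust",
    "distrust": "dis_trust",
    "trust_distrust": "dis_trust",
}

_TEMPLATE_ENVS = {
    "exp1": ("baseline",),
    "exp2": ("baseline", "like", "dislike", "trust", "distrust"),
    "exp3": ("baseline", "like_dislike", "trust_distrust"),
}

# cohort sizes per environment as reported for the sharing experiments
_EXP2_COHORTS = {"baseline": 59, "like": 89, "dislike": 45, "trust": 46, "distrust": 49}
_EXP3_COHORTS = {"baseline": 126, "like_dislike": 128, "trust_distrust": 137}


@dataclass
class ExperimentConfig:
    template: str
    n_true: int = 50
    n_false: int = 50
    cohorts: dict = field(default_factory=dict)  # environment -> n subjects
    hypers: dict = field(default_factory=dict)  # fit group -> GroupHyperParams
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.template not in _TEMPLATE_ENVS:
            raise ValueError(f"unknown template {self.template!r}")
        allowed = set(_TEMPLATE_ENVS[self.template])
        extra = set(self.cohorts) - allowed
        if extra:
            raise ValueError(f"environments {sorted(extra)} invalid for {self.template}")
        for env, n in self.cohorts.items():
            if n < 1:
                raise ValueError(f"cohort size for {env} must be >= 1")

    @property
    def environments(self) -> tuple:
        return tuple(e for e in _TEMPLATE_ENVS[self.template] if e in self.cohorts)

    @property
    def fit_groups(self) -> tuple:
        seen = []
        for env in self.environments:
            g = POOLING[env]
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def to_dict(self) -> dict:
        return {
            "template": self.template,
            "n_true": self.n_true,
            "n_false": self.n_false,
            "cohorts": dict(self.cohorts),
            "hypers": {
                g: {k: getattr(h, k) for k in
                    ("mu_v", "sigma_v", "mu_a", "sigma_a", "mu_z", "sigma_z",
                     "mu_t0", "sigma_t0")}
                for g, h in self.hypers.items()
            },
            "mcmc": {
                "n_samples": self.mcmc.n_samples,
                "burn_in": self.mcmc.burn_in,
                "thin": self.mcmc.thin,
                "n_chains": self.mcmc.n_chains,
                "seed": self.mcmc.seed,
            },
            "seed": self.seed,
        }


def default_exp2_config(seed: int = 0, mcmc: MCMCConfig | None = None) -> ExperimentConfig:
    return ExperimentConfig(
        template="exp2",
        n_true=50,
        n_false=50,
        cohorts=dict(_EXP2_COHORTS),
        hypers=dict(EXP2_GROUP_VALUES),
        mcmc=mcmc or MCMCConfig(seed=seed),
        seed=seed,
    )


def default_exp3_config(seed: int = 0, mcmc: MCMCConfig | None = None) -> ExperimentConfig:
    return ExperimentConfig(
        template="exp3",
        n_true=20,
        n_false=20,
        cohorts=dict(_EXP3_COHORTS),
        hypers=dict(EXP3_GROUP_VALUES),
        mcmc=mcmc or MCMCConfig(seed=seed),
        seed=seed,
    )


def load_config(path) -> ExperimentConfig:
    """Read an ExperimentConfig from a YAML file; missing hyper fields fall
    back to the defaults for the chosen template."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    template = raw["template"]
    base = default_exp2_config() if template == "exp2" else (
        default_exp3_config() if template == "exp3" else None
    )
    hypers = dict(base.hypers) if base else {}
    for g, spec in (raw.get("hypers") or {}).items():
        hypers[g] = GroupHyperParams(**spec)
    mcmc = MCMCConfig(**(raw.get("mcmc") or {}))
    return ExperimentConfig(
        template=template,
        n_true=raw.get("n_true", base.n_true if base else 50),
        n_false=raw.get("n_false", base.n_false if base else 50),
        cohorts=raw.get("cohorts", dict(base.cohorts) if base else {}),
        hypers=hypers,
        mcmc=mcmc,
        seed=raw.get("seed", 0),
    )


# ---------------------------------------------------------------------------
# seed splitting: every stage derives its own child seed from the master
# seed through a fixed counter, so stages can be re-run in isolation.

_STAGES = ("posts", "participants", "reactions", "sharing", "ratings", "fit", "ppc", "recovery")


def child_seed(master: int, stage: str, index: int = 0) -> int:
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(master, spawn_key=(_STAGES.index(stage), index))
    return int(ss.generate_state(1)[0])
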