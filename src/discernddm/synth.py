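"""Synthetic generation of the three simulated social-media experiments.

Produces reaction tables (multi-select like/dislike/trust/distrust or skip),
per-post feedback counts, diffusion-generated sharing trials, belief-accuracy
ratings and memory-check outcomes, all as tidy pandas tables and all
deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ddm import DDMParams
from ._kernels import simulate_trials as _sim_kernel
from .ddm import SIM_DT
from .inference import GroupHyperParams

__all__ = [
    "BUTTONS",
    "TOPICS",
    "ENVIRONMENTS",
    "ParticipantProfile",
    "ReactionProfile",
    "default_reaction_profile",
    "partisan_reaction_profile",
    "generate_posts",
    "generate_participants",
    "simulate_reaction_study",
    "derive_feedback",
    "simulate_sharing_study",
    "simulate_belief_ratings",
    "exclude_failed_checks",
]

BUTTONS = ("like", "dislike", "trust", "distrust")
TOPICS = ("politics", "science", "health", "environment", "society", "other")
PARTIES = ("Democrat", "Republican")
ENVIRONMENTS = ("baseline", "like", "dislike", "trust", "distrust", "like_dislike", "trust_distrust")

#: buttons displayed as feedback in each sharing environment
ENV_BUTTONS = {
    "baseline": (),
    "like": ("like",),
    "dislike": ("dislike",),
    "trust": ("trust",),
    "distrust": ("distrust",),
    "like_dislike": ("like", "dislike"),
    "trust_distrust": ("trust", "distrust"),
}

N_MEMORY_CHECKS = 5


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    party: str = "Democrat"
    environment: str = "baseline"
    individual_ddm: DDMParams | None = None
    memory_checks_failed: int = 0

    def __post_init__(self) -> None:
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {self.environment!r}")
        if not 0 <= self.memory_checks_failed <= N_MEMORY_CHECKS:
            raise ValueError("memory_checks_failed must lie in [0, 5]")


@dataclass(frozen=True)
class ReactionProfile:
    """Button-press probabilities conditioned on post veracity.

    ``p_true[b]`` / ``p_false[b]`` are per-button selection probabilities
    given that the post is not skipped; buttons are selected independently
    (multi-select).  ``skip_true`` / ``skip_false`` gate everything: a skip
    draw suppresses all buttons.  ``party_multipliers`` optionally scale a
    party's probabilities per button (clipped to [0, 1]); the default is
    symmetric across parties.
    """

    p_true: dict
    p_false: dict
    skip_true: float = 0.0
    skip_false: float = 0.0
    party_multipliers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.p_true, self.p_false):
            for b in BUTTONS:
                p = d.get(b, 0.0)
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability for {b!r} outside [0, 1]: {p}")
        for s in (self.skip_true, self.skip_false):
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"skip probability outside [0, 1]: {s}")

    def button_prob(self, button: str, veracity: bool, party: str) -> float:
        base = (self.p_true if veracity else self.p_false).get(button, 0.0)
        mult = self.party_multipliers.get(party, {}).get(button, 1.0)
        return float(np.clip(base * mult, 0.0, 1.0))

    def skip_prob(self, veracity: bool, party: str) -> float:
        return self.skip_true if veracity else self.skip_false


# Calibration targets: reported group-mean discernment per button
# (like 0.06, dislike 0.034, trust 0.099, distrust 0.156) and usage rates
# (18.604 / 23.745 / 28.057 / 34.085 percent of trials).  With a skip gate
# s, usage = (1 - s)(p_t + p_f)/2 and discernment = +-(1 - s)(p_t - p_f),
# so the probabilities follow in closed form.
_CALIBRATION = {
    #  button: (mean usage, signed discernment: + favours true)
    "like": (0.18604, +0.060),
    "dislike": (0.23745, -0.034),
    "trust": (0.28057, +0.099),
    "distrust": (0.34085, -0.156),
}
_DEFAULT_SKIP = 0.10


def default_reaction_profile(skip: float = _DEFAULT_SKIP) -> ReactionProfile:
    """Closed-form calibration to the reported button usage and discernment
    group means, symmetric across parties."""
    p_true, p_false = {}, {}
    for b, (usage, disc) in _CALIBRATION.items():
        s = usage / (1.0 - skip)
        d = disc / (1.0 - skip)
        p_true[b] = s + d / 2.0
        p_false[b] = s - d / 2.0
    return ReactionProfile(p_true=p_true, p_false=p_false, skip_true=skip, skip_false=skip)


def partisan_reaction_profile(
    trust_gap: float = 0.35, skip: float = _DEFAULT_SKIP
) -> ReactionProfile:
    """Variant with a party-asymmetric trust button, used to exercise the
    partisan post-selection path."""
    base = default_reaction_profile(skip)
    mult = {
        "Democrat": {"trust": 1.0 + trust_gap},
        "Republican": {"trust": 1.0 - trust_gap},
    }
    return replace(base, party_multipliers=mult)


# ---------------------------------------------------------------------------
# posts and participants


def generate_posts(
    n_true: int,
    n_false: int,
    topic_weights: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Post set with a stated veracity split, sampled topics and zeroed
    feedback counts."""
    if n_true < 0 or n_false < 0:
        raise ValueError("post counts must be non-negative")
    rng = np.random.default_rng(seed)
    if topic_weights is None:
        topic_weights = {t: 1.0 for t in TOPICS}
    topics = list(topic_weights)
    w = np.asarray([topic_weights[t] for t in topics], float)
    if w.sum() <= 0 or (w < 0).any():
        raise ValueError("topic weights must be non-negative and normalizable")
    w = w / w.sum()
    n = n_true + n_false
    df = pd.DataFrame(
        {
            "post_id": [f"p{i:03d}" for i in range(n)],
            "veracity": [True] * n_true + [False] * n_false,
            "topic": rng.choice(topics, size=n, p=w) if n else np.array([], dtype=object),
        }
    )
    for b in BUTTONS:
        df[f"n_{b}"] = 0
    return df


def generate_participants(
    n: int,
    environment: str = "baseline",
    hyper: GroupHyperParams | None = None,
    p_fail: float = 0.17,
    seed: int = 0,
    prefix: str = "sub",
) -> list[ParticipantProfile]:
    """Cohort for one environment; individual diffusion parameters are drawn
    from ``hyper`` when given, and memory-check failures are Binomial(5, p_fail)
    (P(failures > 2) at the default is ~3.7%, so roughly 3-4% of a cohort
    gets excluded)."""
    rng = np.random.default_rng(seed)
    params = hyper.sample_subjects(n, rng) if hyper is not None else None
    parties = rng.choice(PARTIES, size=n)
    fails = rng.binomial(N_MEMORY_CHECKS, p_fail, size=n)
    out = []
    for i in range(n):
        ddm = None
        if params is not None:
            r = params.iloc[i]
            ddm = DDMParams(float(r.v), float(r.a), float(r.z), float(r.t0))
        out.append(
            ParticipantProfile(
                participant_id=f"{prefix}{i:04d}",
                party=str(parties[i]),
                environment=environment,
                individual_ddm=ddm,
                memory_checks_failed=int(fails[i]),
            )
        )
    return out


def exclude_failed_checks(participants: list[ParticipantProfile]) -> list[ParticipantProfile]:
    """Drop participants failing more than two of the five memory checks."""
    for p in participants:
        if not 0 <= p.memory_checks_failed <= N_MEMORY_CHECKS:
            raise ValueError(f"memory_checks_failed out of range for {p.participant_id}")
    return [p for p in participants if p.memory_checks_failed <= 2]


# ---------------------------------------------------------------------------
# experiment 1: reactions and feedback


def simulate_reaction_study(
    posts: pd.DataFrame,
    participants: list[ParticipantProfile],
    profile: ReactionProfile,
    seed: int = 0,
    partisan_posts=None,
) -> pd.DataFrame:
    """One row per (participant, post): multi-select button indicators plus a
    ``skipped`` flag that suppresses all buttons.

    ``partisan_posts`` optionally restricts the profile's party multipliers
    to a subset of post ids; on the remaining posts both parties react with
    the base probabilities.  ``None`` applies the multipliers everywhere.
    """
    rng = np.random.default_rng(seed)
    n_posts = len(posts)
    ver = posts["veracity"].to_numpy(bool)
    if partisan_posts is None:
        partisan = np.ones(n_posts, bool)
    else:
        partisan = posts["post_id"].isin(set(partisan_posts)).to_numpy()
    frames = []
    for part in participants:
        skip_p = np.where(
            ver,
            profile.skip_prob(True, part.party),
            profile.skip_prob(False, part.party),
        )
        skipped = rng.random(n_posts) < skip_p
        row = {
            "participant_id": part.participant_id,
            "party": part.party,
            "post_id": posts["post_id"].to_numpy(),
            "skipped": skipped,
        }
        for b in BUTTONS:
            p_party = np.where(
                ver,
                profile.button_prob(b, True, part.party),
                profile.button_prob(b, False, part.party),
            )
            p_base = np.where(
                ver,
                profile.p_true.get(b, 0.0),
                profile.p_false.get(b, 0.0),
            )
            pb = np.where(partisan, p_party, p_base)
            row[b] = (~skipped) & (rng.random(n_posts) < pb)
        frames.append(pd.DataFrame(row))
    cols = ["participant_id", "party", "post_id", *BUTTONS, "skipped"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]


def derive_feedback(reactions: pd.DataFrame, posts: pd.DataFrame) -> pd.DataFrame:
    """Accumulate per-post button counts from a reaction table."""
    unknown = set(reactions["post_id"]) - set(posts["post_id"])
    if unknown:
        raise ValueError(f"reactions reference unknown posts: {sorted(unknown)[:5]}")
    out = posts.copy()
    if len(reactions) == 0:
        for b in BUTTONS:
            out[f"n_{b}"] = 0
        return out
    counts = reactions.groupby("post_id")[list(BUTTONS)].sum()
    for b in BUTTONS:
        out[f"n_{b}"] = out["post_id"].map(counts[b]).fillna(0).astype(int)
    return out


# ---------------------------------------------------------------------------
# experiments 2/3: sharing trials, ratings


def simulate_sharing_study(
    posts: pd.DataFrame,
    participants: list[ParticipantProfile],
    seed: int = 0,
) -> pd.DataFrame:
    """Diffusion-generated share/skip choices with log-scale response times.

    The diffusion's upper bound is the veracity-promoting response: for a
    true post it maps to "share", for a false post to "skip".  Feedback
    counts are shown only on share trials in feedback environments.
    """
    rng = np.random.default_rng(seed)
    n_posts = len(posts)
    ver = posts["veracity"].to_numpy(bool)
    frames = []
    for part in participants:
        if part.individual_ddm is None:
            raise ValueError(f"participant {part.participant_id} lacks diffusion parameters")
        p = part.individual_ddm
        kseed = int(rng.integers(0, 2**31 - 1))
        rt, up = _sim_kernel(p.v, p.a, p.z, p.t0, n_posts, SIM_DT, kseed)
        share = np.where(ver, up, ~up)
        fb_buttons = ENV_BUTTONS[part.environment]
        if fb_buttons:
            shown = posts[[f"n_{b}" for b in fb_buttons]].sum(axis=1).to_numpy(float)
            shown = np.where(share, shown, np.nan)
        else:
            shown = np.full(n_posts, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": part.participant_id,
                    "post_id": posts["post_id"].to_numpy(),
                    "environment": part.environment,
                    "veracity": ver,
                    "choice": np.where(share, "share", "skip"),
                    "response": up,  # upper bound = veracity-promoting
                    "rt": rt,
                    "feedback_shown": shown,
                }
            )
        )
    cols = [
        "participant_id",
        "post_id",
        "environment",
        "veracity",
        "choice",
        "response",
        "rt",
        "feedback_shown",
    ]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]


def simulate_belief_ratings(
    posts: pd.DataFrame,
    participants: list[ParticipantProfile],
    accuracy_weight: float = 0.2,
    noise_sd: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """0-100 accuracy ratings: a veracity signal (100 true / 0 false) mixed
    with an uninformative 50 plus Gaussian noise, clipped to the scale."""
    if not 0.0 <= accuracy_weight <= 1.0:
        raise ValueError("accuracy_weight must lie in [0, 1]")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    ver = posts["veracity"].to_numpy(bool)
    signal = np.where(ver, 100.0, 0.0)
    frames = []
    for part in participants:
        raw = accuracy_weight * signal + (1 - accuracy_weight) * 50.0
        raw = raw + rng.normal(0.0, noise_sd, len(posts))
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": part.participant_id,
                    "post_id": posts["post_id"].to_numpy(),
                    "rating": np.clip(raw, 0.0, 100.0),
                }
            )
        )
    cols = ["participant_id", "post_id", "rating"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]
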