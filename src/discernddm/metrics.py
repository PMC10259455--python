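"""Behavioral statistics: discernment scores, belief error, engagement,
non-partisan post selection, and the group tests used to compare
environments (one-sample t, fixed-effects ANOVA from explicit sums of
squares)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synth import BUTTONS

__all__ = [
    "reaction_discernment",
    "sharing_discernment",
    "veracity_coded_discernment",
    "belief_error",
    "engagement_rate",
    "reaction_use_rate",
    "select_nonpartisan_posts",
    "one_sample_t",
    "oneway_anova",
    "twoway_within_anova",
]

#: positive buttons score Prop(button|true) - Prop(button|false);
#: negative buttons score the reverse so higher always means more discerning
POSITIVE_BUTTONS = ("like", "trust")


def _merge_veracity(table: pd.DataFrame, posts: pd.DataFrame) -> pd.DataFrame:
    return table.merge(posts[["post_id", "veracity"]], on="post_id", how="left")


def reaction_discernment(
    reactions: pd.DataFrame, posts: pd.DataFrame, button: str
) -> pd.DataFrame:
    """Per-participant discernment for one reaction button.

    Denominators are all true posts seen and all false posts seen (skipped
    trials count).  Participants lacking posts of either veracity get NaN.
    """
    if button not in BUTTONS:
        raise ValueError(f"unknown button {button!r}")
    df = _merge_veracity(reactions, posts)
    grp = df.groupby(["participant_id", "veracity"])[button].agg(["mean", "size"]).unstack("veracity")
    prop = grp["mean"]
    for col in (True, False):
        if col not in prop.columns:
            prop[col] = np.nan
    value = prop[True] - prop[False]
    if button not in POSITIVE_BUTTONS:
        value = -value
    out = value.rename("value").reset_index()
    out["context"] = button
    out["missing"] = out["value"].isna()
    return out[["participant_id", "context", "value", "missing"]]


def sharing_discernment(trials: pd.DataFrame) -> pd.DataFrame:
    """Prop(share | true) - Prop(share | false), per participant."""
    if "veracity" not in trials.columns:
        raise ValueError("trial table lacks a veracity column")
    df = trials.assign(share=trials["choice"].eq("share"))
    prop = df.groupby(["participant_id", "veracity"])["share"].mean().unstack("veracity")
    for col in (True, False):
        if col not in prop.columns:
            prop[col] = np.nan
    out = (prop[True] - prop[False]).rename("value").reset_index()
    out["context"] = "sharing"
    out["missing"] = out["value"].isna()
    return out[["participant_id", "context", "value", "missing"]]


def veracity_coded_discernment(trials: pd.DataFrame) -> pd.DataFrame:
    """Prop(veracity-promoting) - Prop(veracity-obstructing) per participant;
    identically ``2 * Prop(promoting) - 1`` since the two proportions sum to
    one."""
    if "response" in trials.columns:
        promoting = trials["response"].astype(bool)
    else:
        promoting = trials["choice"].eq("share") == trials["veracity"]
    df = trials.assign(promoting=promoting)
    p = df.groupby("participant_id")["promoting"].mean()
    out = (2.0 * p - 1.0).rename("value").reset_index()
    out["context"] = "veracity_coded"
    out["missing"] = out["value"].isna()
    return out[["participant_id", "context", "value", "missing"]]


def belief_error(ratings: pd.DataFrame, posts: pd.DataFrame) -> pd.DataFrame:
    """Mean per-participant belief error: the rating itself for false posts,
    100 minus the rating for true posts."""
    r = ratings["rating"].to_numpy(float)
    if np.any((r < 0) | (r > 100)) or not np.all(np.isfinite(r)):
        raise ValueError("ratings must lie in [0, 100]")
    df = _merge_veracity(ratings, posts)
    err = np.where(df["veracity"].to_numpy(bool), 100.0 - r, r)
    out = df.assign(error=err).groupby("participant_id")["error"].mean()
    return out.rename("mean_error").reset_index()


def engagement_rate(trials: pd.DataFrame) -> pd.DataFrame:
    """Percentage of trials shared, per participant."""
    if len(trials) == 0:
        raise ValueError("empty trial table: engagement undefined")
    df = trials.assign(share=trials["choice"].eq("share"))
    out = (100.0 * df.groupby("participant_id")["share"].mean()).rename("share_rate")
    return out.reset_index()


def reaction_use_rate(reactions: pd.DataFrame) -> pd.DataFrame:
    """Percentage use of each reaction button out of all trials, per
    participant (wide layout, one column per button)."""
    if len(reactions) == 0:
        raise ValueError("empty reaction table: usage undefined")
    out = 100.0 * reactions.groupby("participant_id")[list(BUTTONS)].mean()
    return out.reset_index()


def select_nonpartisan_posts(
    reactions: pd.DataFrame,
    posts: pd.DataFrame,
    alpha: float = 0.05,
    button: str = "trust",
) -> pd.DataFrame:
    """Retain posts whose party x button-use 2x2 Pearson chi-square p-value
    is at least ``alpha`` (no continuity correction; degenerate margins give
    statistic 0 and are retained)."""
    if "party" not in reactions.columns:
        raise ValueError("reaction table lacks a party column")
    parties = sorted(reactions["party"].unique())
    if len(parties) < 2:
        raise ValueError("need participants from two parties")
    keep = []
    for post_id, grp in reactions.groupby("post_id"):
        tab = pd.crosstab(grp["party"], grp[button].astype(bool))
        tab = tab.reindex(index=parties, columns=[False, True], fill_value=0)
        obs = tab.to_numpy(float)
        if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
            keep.append(post_id)  # zero margin: no detectable difference
            continue
        _, p, _, _ = stats.chi2_contingency(obs, correction=False)
        if p >= alpha:
            keep.append(post_id)
    return posts[posts["post_id"].isin(keep)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# group tests


def one_sample_t(values, popmean: float = 0.0) -> dict:
    """Two-sided one-sample t-test; zero-variance input is flagged rather
    than raising."""
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.allclose(x.std(ddof=1), 0.0):
        return {"statistic": np.nan, "df": x.size - 1, "p": np.nan,
                "cohens_d": np.nan, "flag": "zero_variance"}
    res = stats.ttest_1samp(x, popmean)
    d = (x.mean() - popmean) / x.std(ddof=1)
    return {"statistic": float(res.statistic), "df": x.size - 1,
            "p": float(res.pvalue), "cohens_d": float(d), "flag": None}


def oneway_anova(values, groups) -> dict:
    """One-way fixed-effects ANOVA from explicit sums of squares, with
    partial eta squared."""
    df = pd.DataFrame({"y": np.asarray(values, float), "g": np.asarray(groups)})
    df = df.dropna()
    levels = df["g"].unique()
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    grand = df["y"].mean()
    ss_between = sum(
        len(sub) * (sub["y"].mean() - grand) ** 2 for _, sub in df.groupby("g")
    )
    ss_within = sum(
        ((sub["y"] - sub["y"].mean()) ** 2).sum() for _, sub in df.groupby("g")
    )
    df_b = len(levels) - 1
    df_w = len(df) - len(levels)
    if df_w <= 0 or ss_within == 0:
        raise ValueError("within-group variance undefined")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    eta = ss_between / (ss_between + ss_within)
    return {"statistic": float(f), "df": (df_b, df_w), "p": p,
            "partial_eta_sq": float(eta), "design": "oneway_between"}


def twoway_within_anova(data: pd.DataFrame, dv: str, factor_a: str, factor_b: str,
                        subject: str) -> dict:
    """Balanced 2x2 within-subject ANOVA (explicit sums of squares); returns
    the F, df, p and partial eta squared for both main effects and the
    interaction, each tested against its factor-by-subject error term."""
    wide = data.pivot_table(index=subject, columns=[factor_a, factor_b], values=dv)
    if wide.isna().any().any():
        raise ValueError("within-subject design must be complete")
    arr = wide.to_numpy(float)
    n = arr.shape[0]
    la = wide.columns.get_level_values(0).unique()
    lb = wide.columns.get_level_values(1).unique()
    if len(la) != 2 or len(lb) != 2:
        raise ValueError("both factors must have exactly two levels")
    cube = arr.reshape(n, 2, 2)  # subject x A x B
    grand = cube.mean()
    a_means = cube.mean(axis=(0, 2))
    b_means = cube.mean(axis=(0, 1))
    subj_means = cube.mean(axis=(1, 2))
    ss_a = 2 * n * np.sum((a_means - grand) ** 2)
    ss_b = 2 * n * np.sum((b_means - grand) ** 2)
    ab_means = cube.mean(axis=0)
    ss_ab = n * np.sum((ab_means - grand) ** 2) - ss_a - ss_b
    out = {}
    for name, ss_eff, eff_means in (
        (factor_a, ss_a, cube.mean(axis=2)),
        (factor_b, ss_b, cube.mean(axis=1)),
        (f"{factor_a}:{factor_b}", ss_ab, None),
    ):
        if eff_means is not None:  # factor x subject interaction error term
            ss_err = 2 * np.sum((eff_means - eff_means.mean(axis=0, keepdims=True)
                                 - subj_means[:, None] + grand) ** 2)
        else:
            # interaction error: residual after all lower-order strata
            am = cube.mean(axis=2)
            bm = cube.mean(axis=1)
            resid = (cube
                     - am[:, :, None] - bm[:, None, :] + subj_means[:, None, None]
                     - ab_means[None] + a_means[None, :, None] + b_means[None, None, :]
                     - grand)
            ss_err = np.sum(resid ** 2)
        df_eff, df_err = 1, n - 1
        if ss_err <= 0:
            raise ValueError("zero error variance")
        f = (ss_eff / df_eff) / (ss_err / df_err)
        out[name] = {
            "statistic": float(f),
            "df": (df_eff, df_err),
            "p": float(stats.f.sf(f, df_eff, df_err)),
            "partial_eta_sq": float(ss_eff / (ss_eff + ss_err)),
        }
    out["design"] = "2x2_within"
    return out
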