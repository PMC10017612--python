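"""N-2 repetition costs conditioned on N-2 error type and N-1 speed.

A target trial N is an ABA (``n2_repetition``) trial when its cued task
equals the task of trial N-2, otherwise CBA (``n2_switch``).  The N-2
repetition cost in a stratum is the participant's mean RT difference
ABA - CBA.  Costs are analysed with a fully-within repeated-measures
ANOVA on participant cell means, with partial and generalized
eta-squared effect sizes, plus paired contrasts (Cohen's dz) and an
independent-samples permutation test for between-experiment comparisons.
"""

from __future__ import annotations

import itertools
import math
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "N2_REPETITION",
    "N2_SWITCH",
    "label_sequences",
    "median_split",
    "cost_table",
    "rm_anova",
    "paired_t",
    "permutation_test",
]

N2_REPETITION = "n2_repetition"
N2_SWITCH = "n2_switch"


def label_sequences(
    trials: pd.DataFrame,
    n2_col: str = "category",
    require_n1_correct: bool = True,
) -> pd.DataFrame:
    """Extract one row per eligible target trial N.

    The input must be a trimmed trial table (see
    :func:`switcherr.trim.trim_trials`), ordered within participant and
    block.  A target needs an N-1 and N-2 trial in the same block, must
    be flagged ``eligible_as_target``, and (by default) its N-1 trial
    must be observed correct with a recorded RT — otherwise no N-1 speed
    can be assigned.

    ``n2_col`` names the column whose lag-2 value becomes the
    ``n2_category`` stratum (the observed category by default; a latent
    label column can be passed for simulation ground-truth analyses).
    """
    req = {"participant", "block", "trial", "task", "rt_ms", "eligible_as_target"}
    missing = req - set(trials.columns)
    if missing:
        raise ValueError(f"trials table lacks columns {sorted(missing)} (run trim first)")

    df = trials
    g = df.groupby(["participant", "block"], sort=False)
    pos = g.cumcount().to_numpy()
    task = df["task"].to_numpy()
    n = len(df)

    task2 = np.roll(task, 2)
    n2_cat = np.roll(df[n2_col].to_numpy(), 2)
    n1_rt = np.roll(df["rt_ms"].to_numpy(dtype=float), 1)
    has_context = pos >= 2

    if "category" in df.columns:
        n1_ok = np.roll(df["category"].to_numpy() == "correct", 1)
    elif "correct" in df.columns:
        n1_ok = np.roll(df["correct"].to_numpy(dtype=bool), 1)
    else:
        raise ValueError("trials need a 'category' or 'correct' column")

    mask = has_context & df["eligible_as_target"].to_numpy(dtype=bool)
    if require_n1_correct:
        mask &= n1_ok & ~np.isnan(n1_rt)

    out = pd.DataFrame(
        {
            "participant": df["participant"].to_numpy()[mask],
            "block": df["block"].to_numpy()[mask],
            "trial": df["trial"].to_numpy()[mask],
            "task": task[mask],
            "triplet": np.where(task[mask] == task2[mask], N2_REPETITION, N2_SWITCH),
            "n2_category": n2_cat[mask],
            "n1_rt_ms": n1_rt[mask],
            "rt_ms": df["rt_ms"].to_numpy(dtype=float)[mask],
            "target_correct": df["eligible_rt_target"].to_numpy(dtype=bool)[mask]
            if "eligible_rt_target" in df.columns
            else np.ones(int(mask.sum()), dtype=bool),
        }
    )
    if "congruent" in df.columns:
        out["n2_congruent"] = np.roll(df["congruent"].to_numpy(), 2)[mask]
    return out.reset_index(drop=True)


def median_split(labels: pd.DataFrame) -> pd.DataFrame:
    """Assign each target an N-1 speed by participant-level median split.

    The median is computed per participant over all included targets;
    ``n1_rt < median`` is fast, ties and above are slow.
    """
    if labels.groupby("participant").size().min() < 2:
        raise ValueError("median split needs at least 2 labelled targets per participant")
    out = labels.copy()
    med = out.groupby("participant")["n1_rt_ms"].transform("median")
    out["n1_speed"] = np.where(out["n1_rt_ms"].to_numpy() < med.to_numpy(), "fast", "slow")
    return out


def cost_table(
    labels: pd.DataFrame,
    strata: tuple[str, ...] = ("n2_category", "n1_speed"),
    correct_only: bool = True,
) -> pd.DataFrame:
    """Per-participant cell means and N-2 repetition costs.

    One row per participant x stratum with the ABA and CBA mean RTs,
    their trial counts, and ``cost = mean(ABA) - mean(CBA)`` (NaN when a
    cell is empty).  RT analyses use correct targets only by default.
    """
    df = labels
    strata = tuple(s for s in strata if s in df.columns)
    if correct_only and "target_correct" in df.columns:
        df = df[df["target_correct"]]
    grouped = df.groupby(["participant", *strata, "triplet"], observed=True)["rt_ms"].agg(
        ["mean", "count"]
    )
    wide = grouped.unstack("triplet")
    for trip in (N2_REPETITION, N2_SWITCH):
        if ("mean", trip) not in wide.columns:
            wide[("mean", trip)] = np.nan
            wide[("count", trip)] = 0
    out = pd.DataFrame(
        {
            "mean_rt_aba": wide[("mean", N2_REPETITION)],
            "mean_rt_cba": wide[("mean", N2_SWITCH)],
            "n_aba": wide[("count", N2_REPETITION)].fillna(0).astype(int),
            "n_cba": wide[("count", N2_SWITCH)].fillna(0).astype(int),
        }
    )
    out["cost"] = out["mean_rt_aba"] - out["mean_rt_cba"]
    return out.reset_index()


def _effect_name(within, axes):
    return ":".join(within[a - 1] for a in sorted(axes))


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "participant",
) -> pd.DataFrame:
    """Fully-within repeated-measures ANOVA on cell means.

    Expects one observation per subject x cell; subjects with missing
    cells are dropped.  Returns one row per within effect (main effects
    and all interactions) with F, dfs, p, partial eta-squared
    (SS_effect / (SS_effect + SS_error)) and generalized eta-squared
    (SS_effect over SS_effect plus all subject-involving sums of
    squares).  No sphericity correction is applied.
    """
    pivot = data.pivot_table(index=subject, columns=list(within), values=dv)
    level_values = [sorted(data[f].dropna().unique().tolist()) for f in within]
    full_cols = (
        pd.Index(level_values[0], name=within[0])
        if len(within) == 1
        else pd.MultiIndex.from_product(level_values, names=list(within))
    )
    pivot = pivot.reindex(columns=full_cols).dropna()
    n_subj = len(pivot)
    if n_subj < 2:
        raise ValueError("rm_anova needs at least 2 subjects with complete cells")
    shape = (n_subj, *[len(lv) for lv in level_values])
    # pivot columns are a (multi-)index over factor level combinations in
    # sorted order, matching itertools.product over sorted levels.
    arr = pivot.to_numpy().reshape(shape)

    n_axes = arr.ndim
    grand = arr.mean()
    effects: dict[frozenset, np.ndarray] = {}
    ss: dict[frozenset, float] = {}
    all_axes = tuple(range(n_axes))
    for r in range(1, n_axes + 1):
        for axes in itertools.combinations(all_axes, r):
            aset = frozenset(axes)
            rest = tuple(a for a in all_axes if a not in aset)
            marg = arr.mean(axis=rest, keepdims=True)
            e = marg - grand
            for bset, be in effects.items():
                if bset < aset:
                    e = e - be
            effects[aset] = e
            mult = float(np.prod([shape[a] for a in rest])) if rest else 1.0
            ss[aset] = float((e**2).sum()) * mult

    ss_subject_all = sum(v for k, v in ss.items() if 0 in k)
    rows = []
    for r in range(1, n_axes):
        for axes in itertools.combinations(range(1, n_axes), r):
            aset = frozenset(axes)
            eset = aset | {0}
            df_num = int(np.prod([shape[a] - 1 for a in axes]))
            df_den = df_num * (n_subj - 1)
            ss_eff, ss_err = ss[aset], ss[eset]
            ms_eff = ss_eff / df_num
            ms_err = ss_err / df_den
            F = ms_eff / ms_err if ms_err > 0 else (0.0 if ss_eff == 0 else np.inf)
            p = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
            rows.append(
                {
                    "effect": _effect_name(within, axes),
                    "F": F,
                    "df_num": df_num,
                    "df_den": df_den,
                    "p": p,
                    "eta_p2": ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0,
                    "eta_g2": ss_eff / (ss_eff + ss_subject_all)
                    if ss_eff + ss_subject_all > 0
                    else 0.0,
                    "ss_effect": ss_eff,
                    "ss_error": ss_err,
                }
            )
    return pd.DataFrame(rows).set_index("effect")


def paired_t(x, y=None) -> dict:
    """Paired t test with Cohen's dz (mean difference over its SD)."""
    x = np.asarray(x, dtype=float)
    diffs = x if y is None else x - np.asarray(y, dtype=float)
    n = len(diffs)
    if n < 2:
        raise ValueError("paired_t needs at least 2 difference scores")
    sd = diffs.std(ddof=1)
    mean = diffs.mean()
    dz = mean / sd if sd > 0 else np.inf * np.sign(mean)
    t, p = stats.ttest_1samp(diffs, 0.0)
    return {"t": float(t), "df": n - 1, "p": float(p), "dz": float(dz), "mean": float(mean)}


def permutation_test(group_a, group_b, n_perm: int = 10000, seed=None) -> dict:
    """Two-sided permutation test on the difference of group means.

    All ``C(n_a + n_b, n_a)`` relabellings are enumerated when there are
    at most 20,000 of them (the observed labelling counts itself);
    otherwise ``n_perm`` Monte-Carlo draws are used with the add-one
    estimator.  Returns the p-value, the observed mean difference, and
    the method used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    na, ntot = len(a), len(pooled)
    obs = abs(a.mean() - b.mean())
    tol = 1e-9 * max(1.0, float(np.abs(pooled).max()))

    total = comb(ntot, na)
    if total <= 20000:
        psum = pooled.sum()
        count = 0
        for idx in itertools.combinations(range(ntot), na):
            sa = pooled[list(idx)].sum()
            diff = abs(sa / na - (psum - sa) / (ntot - na))
            if diff >= obs - tol:
                count += 1
        p = count / total
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            diff = abs(perm[:na].mean() - perm[na:].mean())
            if diff >= obs - tol:
                count += 1
        p = (1 + count) / (1 + n_perm)
        method = "monte_carlo"
    return {"p": float(p), "observed_diff": float(a.mean() - b.mean()), "method": method}
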