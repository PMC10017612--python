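"""Observable response categories and per-participant count tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import (
    CORRECT,
    MIXED,
    RESPONSE_CONFUSION,
    TASK_CONFUSION,
    TIMEOUT,
    ParadigmSpec,
)

__all__ = [
    "CATEGORIES",
    "classify_response",
    "classify_trials",
    "tabulate_categories",
]

CATEGORIES = (CORRECT, TASK_CONFUSION, RESPONSE_CONFUSION, MIXED, TIMEOUT)


def classify_response(
    paradigm: ParadigmSpec,
    task: str,
    stim_id: str,
    pressed,
    timeout: bool = False,
) -> str:
    """Map one key press onto its response category.

    Classification is a pure function of (paradigm, cued task, stimulus,
    pressed key); timeouts form their own category and carry no key.
    """
    if timeout:
        return TIMEOUT
    try:
        km = paradigm.key_map[(task, stim_id)]
    except KeyError:
        raise ValueError(
            f"stimulus {stim_id!r} does not afford task {task!r} "
            f"under paradigm {paradigm.paradigm_id!r}"
        ) from None
    try:
        return km[pressed]
    except KeyError:
        raise ValueError(
            f"key {pressed!r} is not part of paradigm {paradigm.paradigm_id!r}"
        ) from None


def classify_trials(trials: pd.DataFrame, paradigm: ParadigmSpec) -> pd.DataFrame:
    """Add a ``category`` column to a trial table."""
    out = trials.copy()
    timeouts = (
        out["timeout"].to_numpy(dtype=bool)
        if "timeout" in out.columns
        else np.zeros(len(out), dtype=bool)
    )
    cats = np.empty(len(out), dtype=object)
    key_maps = paradigm.key_map
    for i, (task, sid, pressed, to) in enumerate(
        zip(out["task"].to_numpy(), out["stim_id"].to_numpy(), out["pressed"].to_numpy(), timeouts)
    ):
        if to:
            cats[i] = TIMEOUT
            continue
        try:
            cats[i] = key_maps[(task, sid)][pressed]
        except KeyError:
            raise ValueError(
                f"cannot classify trial {i}: task={task!r} stim={sid!r} key={pressed!r}"
            ) from None
    out["category"] = cats
    return out


def tabulate_categories(trials: pd.DataFrame, paradigm: ParadigmSpec) -> pd.DataFrame:
    """Per-participant response-category counts (timeouts kept apart).

    Under ``bivalent_congruency`` the counts are stratified by congruency
    into the four observable cells the Experiment-2 tree is fitted on
    (``correct_congruent``, ``error_congruent``, ``correct_incongruent``,
    ``error_incongruent``); other paradigms count the categories
    directly.  ``n_trials`` excludes timeouts, ``n_timeout`` reports
    them.
    """
    if "category" not in trials.columns:
        trials = classify_trials(trials, paradigm)
    df = trials[trials["category"] != TIMEOUT]
    n_timeout = (
        trials[trials["category"] == TIMEOUT].groupby("participant").size()
    )
    if paradigm.congruency_defined:
        cong = df["congruent"].astype(bool)
        strat = np.where(cong, "congruent", "incongruent")
        ok = np.where(df["category"] == CORRECT, "correct", "error")
        cells = pd.Series([f"{a}_{b}" for a, b in zip(ok, strat)], index=df.index)
        counts = (
            df.assign(cell=cells)
            .groupby(["participant", "cell"])
            .size()
            .unstack(fill_value=0)
        )
        cols = [
            "correct_congruent",
            "error_congruent",
            "correct_incongruent",
            "error_incongruent",
        ]
    else:
        counts = df.groupby(["participant", "category"]).size().unstack(fill_value=0)
        cols = [CORRECT, TASK_CONFUSION, RESPONSE_CONFUSION]
        if paradigm.paradigm_id == "univalent":
            cols.append(MIXED)
    for c in cols:
        if c not in counts.columns:
            counts[c] = 0
    counts = counts[cols]
    counts["n_trials"] = counts.sum(axis=1)
    counts["n_timeout"] = n_timeout.reindex(counts.index, fill_value=0).astype(int)
    return counts
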