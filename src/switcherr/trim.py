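"""Trial-level trimming and participant-level exclusion.

Trimming never drops rows: it annotates each trial with a removal reason
and eligibility flags, so that removed trials stay available as N-1/N-2
context for the sequence analyses while being barred from serving as the
analysed trial N.  Re-running the trimmer on its own output therefore
reproduces the same flags (the rules only read the raw event columns).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = ["TrimConfig", "trim_trials", "exclude_participants", "REMOVAL_REASONS"]

REMOVAL_REASONS = (
    "block_start",
    "timeout",
    "fast_guess",
    "slow_response",
    "post_timeout",
    "post_fast_guess",
    "post_slow",
    "post_error",
    "error_rt_only",
    "none",
)


@dataclass(frozen=True)
class TrimConfig:
    """Thresholds and window lengths of the trimming rules.

    ``fast_guess_ms`` is 300 for laboratory designs and 100 for online
    ones; ``slow_cutoff_ms`` applies only to the no-deadline group (3000)
    and is otherwise ``None``.
    """

    fast_guess_ms: float = 300.0
    slow_cutoff_ms: float | None = None
    n_block_start: int = 2
    post_error_window: int = 1
    post_timeout_window: int = 2
    post_fast_guess_window: int = 2
    post_slow_window: int = 2
    min_trials_per_cell: int = 10
    max_fast_guess_rate: float = 0.10
    max_error_rate: float = 0.33

    def __post_init__(self):
        if self.fast_guess_ms <= 0:
            raise ValueError("fast_guess_ms must be positive")
        if self.slow_cutoff_ms is not None and self.slow_cutoff_ms <= 0:
            raise ValueError("slow_cutoff_ms must be positive when set")
        for name in ("max_fast_guess_rate", "max_error_rate"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "TrimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _event_columns(trials: pd.DataFrame):
    """Observed error / timeout indicators from whichever columns exist."""
    if "timeout" in trials.columns:
        timeout = trials["timeout"].to_numpy(dtype=bool)
    else:
        timeout = np.zeros(len(trials), dtype=bool)
    if "category" in trials.columns:
        cat = trials["category"].to_numpy()
        error = (cat != "correct") & (cat != "timeout") & ~timeout
    elif "correct" in trials.columns:
        error = ~trials["correct"].to_numpy(dtype=bool) & ~timeout
    else:
        raise ValueError("trials need a 'category' or 'correct' column")
    return error, timeout


def _check_ordered(trials: pd.DataFrame) -> None:
    g = trials.groupby(["participant", "block"], sort=False)["trial"]
    if not g.apply(lambda s: s.is_monotonic_increasing).all():
        raise ValueError("trials must be ordered by trial within participant and block")


def _window_after(flag: np.ndarray, window: int, block_id: np.ndarray) -> np.ndarray:
    """True within `window` trials after a flagged trial, same block only."""
    out = np.zeros(len(flag), dtype=bool)
    for lag in range(1, window + 1):
        shifted = np.zeros(len(flag), dtype=bool)
        shifted[lag:] = flag[:-lag] & (block_id[lag:] == block_id[:-lag])
        out |= shifted
    return out


def trim_trials(trials: pd.DataFrame, config: TrimConfig) -> pd.DataFrame:
    """Annotate each trial with removal reason and eligibility flags.

    Added columns: ``removed_reason`` (highest-priority matching rule),
    ``eligible_as_target`` (may serve as the analysed trial N) and
    ``eligible_rt_target`` (additionally requires an observed correct
    response, for RT analyses).  Removal windows never cross block
    boundaries.
    """
    _check_ordered(trials)
    out = trials.copy()
    n = len(out)
    error, timeout = _event_columns(out)
    rt = (
        out["rt_ms"].to_numpy(dtype=float)
        if "rt_ms" in out.columns
        else np.full(n, np.nan)
    )

    # Unique block identity for window containment.
    block_id = (
        out["participant"].astype(str) + "/" + out["block"].astype(str)
    ).to_numpy()
    pos = out.groupby(["participant", "block"], sort=False).cumcount().to_numpy()

    block_start = pos < config.n_block_start
    fast = ~timeout & (rt < config.fast_guess_ms)
    if config.slow_cutoff_ms is not None:
        slow = ~timeout & (rt > config.slow_cutoff_ms)
    else:
        slow = np.zeros(n, dtype=bool)

    post_error = _window_after(error, config.post_error_window, block_id)
    post_timeout = _window_after(timeout, config.post_timeout_window, block_id)
    post_fast = _window_after(fast, config.post_fast_guess_window, block_id)
    post_slow = _window_after(slow, config.post_slow_window, block_id)

    reason = np.select(
        [block_start, timeout, fast, slow, post_timeout, post_fast, post_slow, post_error, error],
        [
            "block_start",
            "timeout",
            "fast_guess",
            "slow_response",
            "post_timeout",
            "post_fast_guess",
            "post_slow",
            "post_error",
            "error_rt_only",
        ],
        default="none",
    )
    out["removed_reason"] = reason
    out["eligible_as_target"] = np.isin(reason, ("none", "error_rt_only"))
    out["eligible_rt_target"] = reason == "none"
    return out


def exclude_participants(
    trials: pd.DataFrame,
    config: TrimConfig,
    labels: pd.DataFrame | None = None,
    cell_factors: tuple[str, ...] = ("n2_category", "n1_speed"),
) -> pd.DataFrame:
    """Participant-level exclusion report.

    Rates are computed on the raw (pre-trim) trial counts.  When a
    sequence-label table is supplied, participants must hold at least
    ``config.min_trials_per_cell`` labelled targets in every cell of the
    triplet-type x ``cell_factors`` design (cell levels are pooled across
    participants).

    Returns one row per participant with ``kept`` and
    ``exclusion_reason`` in priority order fast_guess_rate > error_rate >
    cell_count.
    """
    error, timeout = _event_columns(trials)
    rt = (
        trials["rt_ms"].to_numpy(dtype=float)
        if "rt_ms" in trials.columns
        else np.full(len(trials), np.nan)
    )
    fast = ~timeout & (rt < config.fast_guess_ms)
    per = pd.DataFrame(
        {
            "participant": trials["participant"].to_numpy(),
            "error": error,
            "fast": fast,
        }
    ).groupby("participant").agg(n=("error", "size"), error_rate=("error", "mean"), fast_rate=("fast", "mean"))

    reasons = pd.Series("", index=per.index, dtype=object)
    reasons[per["error_rate"] > config.max_error_rate] = "error_rate"
    reasons[per["fast_rate"] > config.max_fast_guess_rate] = "fast_guess_rate"

    if labels is not None and len(labels):
        factors = ["triplet", *[f for f in cell_factors if f in labels.columns]]
        # the triplet factor always has its two canonical levels, even if a
        # participant (or the whole sample) lacks one of them
        levels = [
            ["n2_repetition", "n2_switch"]
            if f == "triplet"
            else sorted(labels[f].dropna().unique())
            for f in factors
        ]
        n_cells = int(np.prod([len(lv) for lv in levels]))
        cell_counts = labels.groupby(["participant", *factors]).size()
        for p in per.index:
            if reasons.loc[p]:
                continue
            if p not in labels["participant"].values:
                reasons.loc[p] = "cell_count"
                continue
            counts = cell_counts.loc[p]
            if len(counts) < n_cells or counts.min() < config.min_trials_per_cell:
                reasons.loc[p] = "cell_count"

    report = per.reset_index()[["participant"]]
    report["kept"] = (reasons == "").to_numpy()
    report["exclusion_reason"] = np.where(reasons == "", "none", reasons)
    return report
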