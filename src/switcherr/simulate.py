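"""Synthetic participants from the latent selection/execution process.

Responses are produced in two latent stages: the cued task is selected
with probability ``T`` (otherwise a wrong task takes over), then the
selected task's correct key is pressed with probability ``R`` (otherwise
one of the remaining keys of the selected task's afforded set is pressed
uniformly at random, which realises the fixed 0.5 random-execution
splits of the processing trees).

Reaction times follow a lognormal baseline with additive shifts for
post-error slowing and for an injectable N-2 repetition cost.  The cost
applies on trial N when the cued task repeats from trial N-2 (an ABA
triplet) and either task selection succeeded at N-2 or a slow
error-correction event occurred on trial N-1; the correction event is a
Bernoulli draw whose probability increases with the N-1 reaction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import ParadigmSpec, _mix_seed

__all__ = ["LatentParams", "simulate_responses", "simulate_rts", "simulate_dataset"]


@dataclass(frozen=True)
class LatentParams:
    """Parameters of the generating process.

    T, R and re are probabilities; ``re`` is the random-execution
    probability and should stay at 0.5 except for sensitivity analyses.
    ``tau`` (correction threshold on the N-1 RT, ms) defaults to the
    median of the baseline RT distribution, ``exp(rt_mu)``.  ``kappa``
    may be ``inf`` for a deterministic threshold.
    """

    T: float
    R: float
    re: float = 0.5
    rt_mu: float = math.log(550.0)
    rt_sigma: float = 0.25
    delta_n2: float = 30.0
    pes: float = 60.0
    tau: float | None = None
    kappa: float = 0.01
    timeout_ms: float | None = None

    def __post_init__(self):
        for name in ("T", "R", "re"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.rt_sigma <= 0:
            raise ValueError("rt_sigma must be positive")
        if self.timeout_ms is not None and self.timeout_ms <= 0:
            raise ValueError("timeout_ms must be positive when set")

    @property
    def tau_ms(self) -> float:
        return math.exp(self.rt_mu) if self.tau is None else self.tau


def simulate_responses(
    design: pd.DataFrame,
    paradigm: ParadigmSpec,
    params: LatentParams,
    seed,
) -> pd.DataFrame:
    """Draw a pressed key for every trial of *design*.

    Returns a copy of the design with columns ``pressed``, ``correct``
    (observed accuracy), ``latent_selected_task`` and
    ``latent_response_correct``.
    """
    n = len(design)
    rng = np.random.default_rng(_mix_seed(seed, 11))
    key_index = {k: i for i, k in enumerate(paradigm.keys)}
    keys_arr = np.asarray(paradigm.keys, dtype=object)

    tasks = design["task"].to_numpy()
    stims = design["stim_id"].to_numpy()
    pairs = list(zip(tasks, stims))
    ck_cued = np.array([key_index[paradigm.correct_key[p]] for p in pairs])

    # Wrong-task choice: the distractor's task captures attention under
    # three_key; otherwise one of the two irrelevant tasks, uniformly.
    if paradigm.paradigm_id == "three_key":
        alt1 = np.array([paradigm.distractor_task[p] for p in pairs], dtype=object)
        alt2 = alt1
    else:
        alts = {t: paradigm.alternative_tasks(t) for t in paradigm.tasks}
        alt1 = np.array([alts[t][0] for t in tasks], dtype=object)
        alt2 = np.array([alts[t][1] for t in tasks], dtype=object)

    sel_ok = rng.random(n) < params.T
    pick2 = rng.random(n) < 0.5
    selected = np.where(sel_ok, tasks, np.where(pick2, alt1, alt2))
    ck_sel = np.array(
        [key_index[paradigm.correct_key[(t, s)]] for t, s in zip(selected, stims)]
    )

    resp_ok = rng.random(n) < params.R
    if paradigm.paradigm_id == "univalent":
        # Keys come in task pairs (2i, 2i+1): the wrong key of the selected
        # task is the pair partner.
        wrong = ck_sel ^ 1
    else:
        # Uniform over the two non-correct keys of the shared 3-key set.
        offset = np.where(rng.random(n) < params.re, 1, 2)
        wrong = (ck_sel + offset) % 3
    pressed_idx = np.where(resp_ok, ck_sel, wrong)

    out = design.copy()
    out["pressed"] = keys_arr[pressed_idx]
    out["correct"] = pressed_idx == ck_cued
    out["latent_selected_task"] = selected
    out["latent_response_correct"] = resp_ok
    return out


def _sigmoid_prob(rt: np.ndarray, kappa: float, tau: float) -> np.ndarray:
    if math.isinf(kappa):
        return (rt > tau).astype(float)
    x = np.clip(kappa * (rt - tau), -700, 700)
    return 1.0 / (1.0 + np.exp(-x))


def simulate_rts(
    trials: pd.DataFrame,
    params: LatentParams,
    seed,
) -> pd.DataFrame:
    """Fill ``rt_ms``, ``timeout`` and ``latent_correction`` columns.

    Requires the latent columns written by :func:`simulate_responses` and
    a table sorted by participant, block, trial.
    """
    required = {"participant", "task", "correct", "latent_selected_task"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trials table lacks columns {sorted(missing)}")

    out = trials.copy()
    rng = np.random.default_rng(_mix_seed(seed, 23))
    n = len(out)
    base = rng.lognormal(params.rt_mu, params.rt_sigma, n)
    u_corr = rng.random(n)
    tau = params.tau_ms

    part = out["participant"].to_numpy()
    new_part = np.empty(n, dtype=bool)
    new_part[0] = True
    np.not_equal(part[1:], part[:-1], out=new_part[1:])

    task = out["task"].to_numpy()
    err = (~out["correct"].to_numpy()).astype(bool)
    sel_ok = (out["latent_selected_task"].to_numpy() == task)

    # Trial-N context, computed within participant.
    prev_err = np.roll(err, 1)
    prev_err[new_part] = False
    aba = np.empty(n, dtype=bool)
    aba[:2] = False
    aba[2:] = task[2:] == task[:-2]
    n2_ok = np.roll(sel_ok, 2)
    two_back_same = ~new_part & ~np.roll(new_part, 1)
    aba &= two_back_same
    n2_ok &= two_back_same

    delta, kappa = params.delta_n2, params.kappa
    if delta == 0.0:
        rt = base + params.pes * prev_err
        corr = u_corr < _sigmoid_prob(rt, kappa, tau)
    elif math.isinf(kappa) and (tau <= 0 or math.isinf(tau)):
        corr_all = tau <= 0
        prev_corr = np.full(n, corr_all)
        prev_corr[new_part] = False
        inhib = aba & (n2_ok | prev_corr)
        rt = base + params.pes * prev_err + delta * inhib
        corr = u_corr < _sigmoid_prob(rt, kappa, tau)
    else:
        rt = np.empty(n)
        corr = np.empty(n, dtype=bool)
        prev_c = False
        for i in range(n):
            if new_part[i]:
                prev_c = False
            inhib = aba[i] and (n2_ok[i] or prev_c)
            rt[i] = base[i] + params.pes * prev_err[i] + delta * inhib
            prev_c = u_corr[i] < _sigmoid_prob(rt[i : i + 1], kappa, tau)[0]
            corr[i] = prev_c

    timeout = np.zeros(n, dtype=bool)
    if params.timeout_ms is not None:
        timeout = rt > params.timeout_ms
        if timeout.any():
            # A timeout leaves no key press and is not an observed error;
            # re-run once with the corrected post-error context (cascades
            # beyond one pass are negligible and ignored).
            err2 = err & ~timeout
            prev_err2 = np.roll(err2, 1)
            prev_err2[new_part] = False
            rt = rt + params.pes * (prev_err2.astype(float) - prev_err.astype(float))
            timeout = rt > params.timeout_ms
            rt = np.where(timeout, np.nan, rt)
            corr = corr & ~timeout
            out.loc[timeout, "pressed"] = pd.NA
            out.loc[timeout, "correct"] = False

    out["rt_ms"] = np.where(timeout, np.nan, rt)
    out["timeout"] = timeout
    out["latent_correction"] = corr
    return out


def simulate_dataset(
    design: pd.DataFrame,
    paradigm: ParadigmSpec,
    params: LatentParams,
    seed,
) -> pd.DataFrame:
    """Convenience wrapper: responses then reaction times, one seed."""
    trials = simulate_responses(design, paradigm, params, seed)
    return simulate_rts(trials, params, _mix_seed(seed, 37))
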