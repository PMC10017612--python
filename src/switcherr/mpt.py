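"""Multinomial processing tree models of the error taxonomy.

Two saturated two-parameter trees are provided.  ``exp2_congruency``
describes the congruency methodology as a product of two multinomials
(congruent and incongruent trial strata) sharing the task-selection
probability ``T`` and the response-selection probability ``R``:

    p(correct | congruent)     = T*R + (1-T)*R
    p(error   | congruent)     = T*(1-R) + (1-T)*(1-R)
    p(correct | incongruent)   = T*R + (1-T)*(1-R)*RE
    p(error   | incongruent)   = T*(1-R) + (1-T)*R + (1-T)*(1-R)*(1-RE)

``exp3_three_key`` describes the target/distractor methodology with three
observable categories:

    p(correct)            = T*R + (1-T)*(1-R)*RE
    p(task confusion)     = T*(1-R)*0.5 + (1-T)*R
    p(response confusion) = T*(1-R)*0.5 + (1-T)*(1-R)*(1-RE)

``RE`` is the random-execution probability, fixed at 0.5.  Note that the
combined-failure branch mass is split between the correct key (weight
``RE``) and the erroneous key (weight ``1 - RE``) so that the three
category probabilities sum to one for every (T, R); a variant that sends
weight ``RE`` of that branch to both outcomes would not normalise.

Maximum-likelihood fitting is done per participant; because both models
are saturated (two free parameters against two independent observable
proportions), an interior optimum reproduces the observed proportions
exactly and the likelihood-ratio statistic G-squared is ~0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "MODEL_IDS",
    "MPTFit",
    "category_probabilities",
    "log_likelihood",
    "fit_mpt",
    "conditional_failure_probs",
    "exp1_failure_probs",
]

MODEL_IDS = ("exp2_congruency", "exp3_three_key")

EXP2_CATEGORIES = (
    "correct_congruent",
    "error_congruent",
    "correct_incongruent",
    "error_incongruent",
)
EXP3_CATEGORIES = ("correct", "task_confusion", "response_confusion")

_MULTISTARTS = ((0.5, 0.5), (0.9, 0.9), (0.99, 0.8), (0.8, 0.99), (0.7, 0.7))
_BOUNDARY_TOL = 1e-6


@dataclass(frozen=True)
class MPTFit:
    """Per-participant maximum-likelihood estimate."""

    model_id: str
    T_hat: float
    R_hat: float
    loglik: float
    g_squared: float
    df: int
    converged: bool
    boundary: bool


def _check_params(T, R):
    T = np.asarray(T, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(T < 0) or np.any(T > 1) or np.any(R < 0) or np.any(R > 1):
        raise ValueError("T and R must lie in [0, 1]")
    return T, R


def category_probabilities(model_id: str, T, R, re: float = 0.5) -> dict:
    """Observable category probabilities of one tree.

    Accepts scalars or broadcastable arrays for ``T`` and ``R``.  Within
    each trial-type stratum the probabilities sum to one.
    """
    T, R = _check_params(T, R)
    if not 0.0 <= re <= 1.0:
        raise ValueError("re must lie in [0, 1]")
    if model_id == "exp2_congruency":
        return {
            "correct_congruent": T * R + (1 - T) * R,
            "error_congruent": T * (1 - R) + (1 - T) * (1 - R),
            "correct_incongruent": T * R + (1 - T) * (1 - R) * re,
            "error_incongruent": T * (1 - R) + (1 - T) * R + (1 - T) * (1 - R) * (1 - re),
        }
    if model_id == "exp3_three_key":
        return {
            "correct": T * R + (1 - T) * (1 - R) * re,
            "task_confusion": T * (1 - R) * 0.5 + (1 - T) * R,
            "response_confusion": T * (1 - R) * 0.5 + (1 - T) * (1 - R) * (1 - re),
        }
    raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")


def _strata(model_id: str) -> list[tuple[str, ...]]:
    if model_id == "exp2_congruency":
        return [EXP2_CATEGORIES[:2], EXP2_CATEGORIES[2:]]
    return [EXP3_CATEGORIES]


def _counts_vector(counts, categories) -> np.ndarray:
    try:
        vec = np.array([float(counts[c]) for c in categories])
    except (KeyError, IndexError):
        missing = [c for c in categories if c not in counts]
        raise ValueError(f"counts lack categories {missing}") from None
    if np.any(vec < 0):
        raise ValueError("counts must be nonnegative")
    return vec


def log_likelihood(counts, model_id: str, T, R, re: float = 0.5):
    """Product-multinomial log-likelihood (up to the multinomial constant)."""
    probs = category_probabilities(model_id, T, R, re=re)
    total = 0.0
    for cats in _strata(model_id):
        vec = _counts_vector(counts, cats)
        for c, k in zip(cats, vec):
            if k > 0:
                total = total + k * np.log(np.maximum(probs[c], 1e-300))
    return total


def fit_mpt(counts, model_id: str, re: float = 0.5) -> MPTFit:
    """Maximum-likelihood (T, R) on [0,1]^2 from category counts.

    ``counts`` is any mapping (dict, pandas Series or row) holding the
    model's category labels.  The optimiser runs bounded L-BFGS-B from
    five deterministic starting points and keeps the best solution.
    """
    strata = _strata(model_id)
    vecs = [_counts_vector(counts, cats) for cats in strata]
    if sum(v.sum() for v in vecs) == 0:
        raise ValueError("all-zero counts: nothing to fit")
    if model_id == "exp2_congruency" and any(v.sum() == 0 for v in vecs):
        raise ValueError("exp2_congruency requires counts in both congruency strata")

    def neg_loglik(x):
        return -float(log_likelihood(counts, model_id, x[0], x[1], re=re))

    best = None
    converged = False
    for x0 in _MULTISTARTS:
        res = optimize.minimize(
            neg_loglik,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, 1.0), (0.0, 1.0)],
            options={"ftol": 1e-10, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        converged = converged or bool(res.success)
    T_hat, R_hat = float(best.x[0]), float(best.x[1])
    loglik = -float(best.fun)

    probs = category_probabilities(model_id, T_hat, R_hat, re=re)
    g2 = 0.0
    for cats, vec in zip(strata, vecs):
        n = vec.sum()
        if n == 0:
            continue
        expected = np.array([float(probs[c]) for c in cats]) * n
        obs = vec
        mask = obs > 0
        g2 += 2.0 * float(
            np.sum(obs[mask] * np.log(obs[mask] / np.maximum(expected[mask], 1e-300)))
        )
    g2 = max(g2, 0.0)
    boundary = bool(
        min(T_hat, 1 - T_hat, R_hat, 1 - R_hat) <= _BOUNDARY_TOL
    )
    return MPTFit(
        model_id=model_id,
        T_hat=T_hat,
        R_hat=R_hat,
        loglik=loglik,
        g_squared=g2,
        df=0,
        converged=converged,
        boundary=boundary,
    )


def conditional_failure_probs(model_id: str, T, R, re: float = 0.5) -> dict:
    """Share of each observed error category caused by task-selection failure.

    Each entry is the (1 - T)-branch mass of the category divided by the
    category's total probability.  ``p_tsf_given_tc`` conditions on the
    task-confusion category (incongruent-trial errors under
    ``exp2_congruency``), ``p_tsf_given_rc`` on the response-confusion
    category (congruent-trial errors), for which the ratio reduces
    algebraically to ``1 - T``.  Zero-probability categories yield NaN.
    """
    T, R = _check_params(T, R)
    if model_id == "exp2_congruency":
        num_tc = (1 - T) * R + (1 - T) * (1 - R) * (1 - re)
        den_tc = T * (1 - R) + (1 - T) * R + (1 - T) * (1 - R) * (1 - re)
        num_rc = (1 - T) * (1 - R)
        den_rc = T * (1 - R) + (1 - T) * (1 - R)
    elif model_id == "exp3_three_key":
        num_tc = (1 - T) * R
        den_tc = T * (1 - R) * 0.5 + (1 - T) * R
        num_rc = (1 - T) * (1 - R) * (1 - re)
        den_rc = T * (1 - R) * 0.5 + (1 - T) * (1 - R) * (1 - re)
    else:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    with np.errstate(divide="ignore", invalid="ignore"):
        p_tc = np.where(den_tc > 0, num_tc / np.where(den_tc > 0, den_tc, 1.0), np.nan)
        p_rc = np.where(den_rc > 0, num_rc / np.where(den_rc > 0, den_rc, 1.0), np.nan)
    if p_tc.ndim == 0:
        p_tc, p_rc = float(p_tc), float(p_rc)
    return {"p_tsf_given_tc": p_tc, "p_tsf_given_rc": p_rc}


def exp1_failure_probs(counts) -> dict:
    """Direct failure-probability estimators for the univalent set-up.

    With a private key pair per task every observed category maps to a
    unique processing path, so no model fitting is needed: the
    task-selection failure probability is the (task-confusion + mixed)
    share of all trials, and the task-execution failure probability is
    the (response-confusion + mixed) share; mixed errors imply both
    failures and count in both.
    """
    cats = ("correct", "response_confusion", "task_confusion", "mixed")
    vec = _counts_vector(counts, cats)
    n = vec.sum()
    if n == 0:
        raise ValueError("empty counts")
    _, rc, tc, mixed = vec
    return {
        "p_task_selection_failure": (tc + mixed) / n,
        "p_task_execution_failure": (rc + mixed) / n,
    }
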