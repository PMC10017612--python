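"""Experimental paradigms and lawful task/stimulus sequence generation.

Three cued task-switching set-ups are supported, differing in how a key
press maps onto observable response categories:

``univalent``
    Three tasks on three binary stimulus dimensions, each task owning a
    private pair of keys (6 keys total).  For any stimulus, one key is
    correct, one is the wrong key of the cued task (response confusion),
    two are the correct keys of the other tasks (task confusion), and the
    remaining two are both wrong task and wrong response (mixed).

``bivalent_congruency``
    Three tasks on three ternary dimensions sharing one set of 3 keys.
    Stimuli are either congruent (all dimensions point at the same key)
    or incongruent (each dimension points at a different key).  Errors on
    congruent trials are read as response confusions, errors on
    incongruent trials as task confusions.

``three_key``
    Two-element stimuli (a target and a distractor from different
    categories) answered on 3 shared keys.  The distractor's key marks a
    task confusion, the third key a response confusion.

All sequences switch task on every trial, balance ABA against CBA
triplets exactly within each block, and never repeat a stimulus at lag 1
or lag 2.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PARADIGM_IDS",
    "CORRECT",
    "TASK_CONFUSION",
    "RESPONSE_CONFUSION",
    "MIXED",
    "TIMEOUT",
    "ParadigmSpec",
    "make_paradigm",
    "generate_task_sequence",
    "assign_stimuli",
    "generate_design",
    "DESIGN_COLUMNS",
]

PARADIGM_IDS = ("univalent", "bivalent_congruency", "three_key")

# Response-category labels (shared with :mod:`switcherr.classify`).
CORRECT = "correct"
TASK_CONFUSION = "task_confusion"
RESPONSE_CONFUSION = "response_confusion"
MIXED = "mixed"
TIMEOUT = "timeout"

DESIGN_COLUMNS = ["participant", "block", "trial", "task", "stim_id", "congruent", "csi_ms"]


@dataclass(frozen=True)
class ParadigmSpec:
    """Static description of one methodology.

    ``key_map[(task, stim_id)]`` assigns every key a response category for
    that trial type; ``correct_key[(task, stim_id)]`` is defined for every
    task the stimulus affords (all three tasks except under ``three_key``,
    where only the two element categories are afforded).
    """

    paradigm_id: str
    tasks: tuple[str, ...]
    keys: tuple[str, ...]
    stimuli: tuple[str, ...]
    levels_per_dimension: int
    congruency_defined: bool
    correct_key: dict = field(repr=False)
    key_map: dict = field(repr=False)
    congruent: dict = field(repr=False, default_factory=dict)
    distractor_task: dict = field(repr=False, default_factory=dict)
    task_keys: dict = field(repr=False, default_factory=dict)

    def stimuli_for_task(self, task: str) -> tuple[str, ...]:
        """Stimuli that afford *task* (relevant under ``three_key``)."""
        return tuple(s for s in self.stimuli if (task, s) in self.correct_key)

    def alternative_tasks(self, task: str) -> tuple[str, ...]:
        if task not in self.tasks:
            raise ValueError(f"unknown task {task!r}")
        return tuple(t for t in self.tasks if t != task)


def _make_univalent() -> ParadigmSpec:
    tasks = ("shape", "color", "orientation")
    keys = tuple(f"k{i}" for i in range(1, 7))
    task_keys = {t: (keys[2 * i], keys[2 * i + 1]) for i, t in enumerate(tasks)}
    stimuli, correct_key, key_map = [], {}, {}
    for levels in itertools.product((0, 1), repeat=3):
        sid = "s" + "".join(map(str, levels))
        stimuli.append(sid)
        for i, t in enumerate(tasks):
            correct_key[(t, sid)] = keys[2 * i + levels[i]]
        for i, t in enumerate(tasks):
            km = {}
            for j, u in enumerate(tasks):
                for v in (0, 1):
                    k = keys[2 * j + v]
                    if u == t:
                        km[k] = CORRECT if v == levels[i] else RESPONSE_CONFUSION
                    else:
                        km[k] = TASK_CONFUSION if v == levels[j] else MIXED
            key_map[(t, sid)] = km
    return ParadigmSpec(
        paradigm_id="univalent",
        tasks=tasks,
        keys=keys,
        stimuli=tuple(stimuli),
        levels_per_dimension=2,
        congruency_defined=False,
        correct_key=correct_key,
        key_map=key_map,
        task_keys=task_keys,
    )


# Congruent stimuli point every dimension at the same key; incongruent
# stimuli use the three cyclic derangement-free permutations so that every
# dimension points at a different key (3 + 3 = 6 stimuli).
_BIVALENT_LEVELS = [
    (0, 0, 0), (1, 1, 1), (2, 2, 2),
    (0, 1, 2), (1, 2, 0), (2, 0, 1),
]


def _make_bivalent() -> ParadigmSpec:
    tasks = ("shape", "color", "orientation")
    keys = ("k1", "k2", "k3")
    stimuli, correct_key, key_map, congruent = [], {}, {}, {}
    for levels in _BIVALENT_LEVELS:
        sid = "s" + "".join(map(str, levels))
        stimuli.append(sid)
        congruent[sid] = len(set(levels)) == 1
        for i, t in enumerate(tasks):
            correct_key[(t, sid)] = keys[levels[i]]
            err = RESPONSE_CONFUSION if congruent[sid] else TASK_CONFUSION
            key_map[(t, sid)] = {
                k: (CORRECT if k == keys[levels[i]] else err) for k in keys
            }
    return ParadigmSpec(
        paradigm_id="bivalent_congruency",
        tasks=tasks,
        keys=keys,
        stimuli=tuple(stimuli),
        levels_per_dimension=3,
        congruency_defined=True,
        correct_key=correct_key,
        key_map=key_map,
        congruent=congruent,
    )


def _make_three_key() -> ParadigmSpec:
    tasks = ("number", "letter", "symbol")
    keys = ("k1", "k2", "k3")
    # Elements are (category, ordinal position); the ordinal position of the
    # attended element selects the key.  A stimulus is an ordered pair
    # (left element, right element) from two different categories with two
    # different positions: 9 * 4 = 36 stimuli, all incongruent.
    elements = [(c, p) for c in tasks for p in range(3)]
    stimuli, correct_key, key_map, distractor_task = [], {}, {}, {}
    for (c1, p1), (c2, p2) in itertools.product(elements, elements):
        if c1 == c2 or p1 == p2:
            continue
        sid = f"{c1[0]}{p1}|{c2[0]}{p2}"
        stimuli.append(sid)
        for (tc, tp), (dc, dp) in (((c1, p1), (c2, p2)), ((c2, p2), (c1, p1))):
            correct_key[(tc, sid)] = keys[tp]
            distractor_task[(tc, sid)] = dc
            km = {}
            for i, k in enumerate(keys):
                if i == tp:
                    km[k] = CORRECT
                elif i == dp:
                    km[k] = TASK_CONFUSION
                else:
                    km[k] = RESPONSE_CONFUSION
            key_map[(tc, sid)] = km
    return ParadigmSpec(
        paradigm_id="three_key",
        tasks=tasks,
        keys=keys,
        stimuli=tuple(stimuli),
        levels_per_dimension=3,
        congruency_defined=False,
        correct_key=correct_key,
        key_map=key_map,
        distractor_task=distractor_task,
    )


_FACTORIES = {
    "univalent": _make_univalent,
    "bivalent_congruency": _make_bivalent,
    "three_key": _make_three_key,
}


def make_paradigm(paradigm_id: str) -> ParadigmSpec:
    """Build the full :class:`ParadigmSpec` for one of the three set-ups."""
    try:
        factory = _FACTORIES[paradigm_id]
    except KeyError:
        raise ValueError(
            f"unknown paradigm_id {paradigm_id!r}; expected one of {PARADIGM_IDS}"
        ) from None
    return factory()


def generate_task_sequence(
    n_blocks: int,
    block_length: int,
    seed,
    tasks: tuple[str, str, str] = ("shape", "color", "orientation"),
) -> list[list[str]]:
    """Generate one task sequence per block.

    Every adjacent pair of trials switches task, and within each block the
    number of ABA triplets (task N equals task N-2) equals the number of
    CBA triplets exactly.  Requires ``block_length - 2`` to be even so the
    balance is attainable.

    Returns a list of ``n_blocks`` lists of task labels.
    """
    if len(tasks) != 3 or len(set(tasks)) != 3:
        raise ValueError("exactly three distinct task labels are required")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if block_length < 3:
        raise ValueError("block_length must be >= 3")
    if (block_length - 2) % 2:
        raise ValueError(
            "block_length - 2 must be even so ABA and CBA triplet counts can be equal"
        )
    rng = random.Random(_mix_seed(seed))
    n_triplets = block_length - 2
    blocks = []
    for _ in range(n_blocks):
        seq = [rng.choice(tasks)]
        seq.append(rng.choice([t for t in tasks if t != seq[0]]))
        # Each subsequent trial is a forced binary choice: return to the
        # task of two trials back (ABA) or go to the third task (CBA).
        flags = [True] * (n_triplets // 2) + [False] * (n_triplets // 2)
        rng.shuffle(flags)
        for aba in flags:
            if aba:
                seq.append(seq[-2])
            else:
                seq.append(next(t for t in tasks if t not in (seq[-1], seq[-2])))
        blocks.append(seq)
    return blocks


def assign_stimuli(
    task_blocks: list[list[str]],
    paradigm: ParadigmSpec,
    seed,
) -> list[list[str]]:
    """Draw a stimulus for every trial of a per-block task sequence.

    A stimulus identity never recurs at lag 1 or 2 (tracked across block
    boundaries), and each stimulus must afford the cued task.
    """
    rng = random.Random(_mix_seed(seed, 1))
    per_task = {t: list(paradigm.stimuli_for_task(t)) for t in paradigm.tasks}
    for t, pool in per_task.items():
        if len(pool) < 3:
            raise ValueError(
                f"stimulus inventory for task {t!r} too small for lag-1/2 exclusion"
            )
    last1 = last2 = None
    out = []
    for block in task_blocks:
        sids = []
        for task in block:
            pool = per_task[task]
            sid = pool[rng.randrange(len(pool))]
            while sid == last1 or sid == last2:
                sid = pool[rng.randrange(len(pool))]
            sids.append(sid)
            last2, last1 = last1, sid
        out.append(sids)
    return out


def generate_design(
    paradigm: ParadigmSpec,
    n_participants: int,
    n_blocks: int,
    block_length: int,
    seed,
    csi_ms: int = 400,
) -> pd.DataFrame:
    """Build a complete multi-participant design table.

    Columns: ``participant, block, trial, task, stim_id, congruent,
    csi_ms``; ``trial`` restarts within each block, ``congruent`` is only
    populated when the paradigm defines congruency.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    frames = []
    root = np.random.SeedSequence(_mix_seed(seed))
    for p, ss in enumerate(root.spawn(n_participants), start=1):
        sub_seed = int(ss.generate_state(1)[0])
        blocks = generate_task_sequence(
            n_blocks, block_length, sub_seed, tasks=paradigm.tasks
        )
        stims = assign_stimuli(blocks, paradigm, sub_seed)
        rows = {
            "participant": np.repeat(p, n_blocks * block_length),
            "block": np.repeat(np.arange(1, n_blocks + 1), block_length),
            "trial": np.tile(np.arange(block_length), n_blocks),
            "task": np.concatenate([np.asarray(b, dtype=object) for b in blocks]),
            "stim_id": np.concatenate([np.asarray(s, dtype=object) for s in stims]),
        }
        df = pd.DataFrame(rows)
        if paradigm.congruency_defined:
            df["congruent"] = df["stim_id"].map(paradigm.congruent)
        else:
            df["congruent"] = pd.NA
        df["csi_ms"] = csi_ms
        frames.append(df)
    return pd.concat(frames, ignore_index=True)[DESIGN_COLUMNS]


def _mix_seed(seed, salt: int = 0) -> int:
    """Deterministically fold (seed, salt) into a non-negative int."""
    ss = np.random.SeedSequence([int(seed), salt])
    return int(ss.generate_state(1)[0])
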