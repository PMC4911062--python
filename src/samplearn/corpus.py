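"""Training-sequence generation under blocked/cyclic randomization.

Reproduces each language's presentation-frequency matrix *exactly* while
honoring the sequencing constraints of the training phase:

* word-order family — trials are organized into blocks containing each verb
  once; where the totals allow it (exp1: 3 grammatical + 1 ungrammatical per
  block of 4) the per-block grammatical ratio is enforced exactly, otherwise
  the grammatical:ungrammatical split is enforced per cycle.  Each verb
  cycles through its slot distribution with fixed quotas per cycle of blocks
  (exp1: 3/3/2 across an 8-block cycle).
* contraction family — modifiers are presented cyclically (each modifier once
  per cycle, order randomized within cycles), with each modifier's
  position/label sequence shuffled within fixed-quota chunks.

Noun pairs are drawn uniformly over ordered pairs of distinct nouns,
independently per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .language import (
    CONTRACTION_POSITIONS,
    WORD_ORDERS,
    Gram,
    LanguageSpec,
    Sentence,
    SlotMapping,
    realize_sentence,
)

__all__ = [
    "TrainingTrial",
    "SequencePolicy",
    "InfeasibleSequenceError",
    "generate_training_sequence",
    "cell_counts",
    "sample_mapping",
    "trials_to_frame",
]


class InfeasibleSequenceError(ValueError):
    """The frequency matrix cannot be partitioned under the given policy."""


@dataclass(frozen=True)
class TrainingTrial:
    """One realized training presentation."""

    index: int
    block: int
    sentence: Sentence

    @property
    def label(self) -> Gram:
        return self.sentence.label


@dataclass(frozen=True)
class SequencePolicy:
    """Block/cycle structure for sequence generation.

    ``cycle_blocks`` is the number of blocks per quota cycle: within each
    cycle every item works through exactly ``frequency / n_cycles``
    presentations of each of its slots.  ``grammatical_per_block`` is
    enforced exactly when set; when ``None`` it is derived from the totals
    if they divide evenly and otherwise only the per-cycle split is kept.
    """

    cycle_blocks: int = 8
    block_size: int | None = None  # default: one trial per item
    grammatical_per_block: int | None = None

    def resolved_block_size(self, spec: LanguageSpec) -> int:
        return self.block_size if self.block_size is not None else len(spec.items)


def sample_mapping(spec: LanguageSpec, seed: int | np.random.Generator) -> SlotMapping:
    """Uniformly sample the participant's slot→realization bijection."""
    rng = np.random.default_rng(seed)
    targets = WORD_ORDERS if spec.family == "word_order" else CONTRACTION_POSITIONS
    perm = rng.permutation(len(targets))
    return SlotMapping(spec.family, {s: targets[perm[i]] for i, s in enumerate(spec.slots)})


def _cycle_quota(spec: LanguageSpec, n_cycles: int) -> dict[tuple[str, str], int]:
    quota = {}
    for cell, f in spec.frequency.items():
        if f % n_cycles:
            raise InfeasibleSequenceError(
                f"frequency {f} of cell {cell} not divisible into {n_cycles} cycles"
            )
        quota[cell] = f // n_cycles
    return quota


def _random_pair(nouns: Sequence[str], rng: np.random.Generator) -> tuple[str, str]:
    i, j = rng.choice(len(nouns), size=2, replace=False)
    return nouns[i], nouns[j]


def _assign_ungrammatical_blocks(
    ungram_count: dict[str, int], n_blocks: int, rng: np.random.Generator
) -> dict[str, set[int]]:
    """Choose, per item, the blocks of a cycle in which it is ungrammatical.

    If the total ungrammatical count divides evenly over the blocks, each
    block receives exactly that share (no item twice in a block); otherwise
    each item's blocks are sampled uniformly without replacement.
    """
    total = sum(ungram_count.values())
    if total and total % n_blocks == 0:
        per_block = total // n_blocks
        tokens = [it for it, c in ungram_count.items() for _ in range(c)]
        for _ in range(1000):
            order = rng.permutation(len(tokens))
            blocks = [
                [tokens[k] for k in order[b * per_block : (b + 1) * per_block]]
                for b in range(n_blocks)
            ]
            if all(len(set(b)) == len(b) for b in blocks):
                out: dict[str, set[int]] = {it: set() for it in ungram_count}
                for b, members in enumerate(blocks):
                    for it in members:
                        out[it].add(b)
                return out
        raise InfeasibleSequenceError("could not place ungrammatical trials into blocks")
    out = {}
    for it, c in ungram_count.items():
        if c > n_blocks:
            raise InfeasibleSequenceError(
                f"item {it} has {c} ungrammatical trials per cycle but only "
                f"{n_blocks} blocks"
            )
        out[it] = set(rng.choice(n_blocks, size=c, replace=False).tolist())
    return out


def _generate_word_order(
    spec: LanguageSpec,
    policy: SequencePolicy,
    mapping: SlotMapping,
    rng: np.random.Generator,
) -> list[TrainingTrial]:
    n_items = len(spec.items)
    total = spec.total_trials()
    if total == 0:
        return []
    if total % n_items:
        raise InfeasibleSequenceError(
            f"{total} trials cannot form blocks with each of {n_items} items once"
        )
    n_blocks = total // n_items
    if n_blocks % policy.cycle_blocks:
        raise InfeasibleSequenceError(
            f"{n_blocks} blocks not divisible into cycles of {policy.cycle_blocks}"
        )
    n_cycles = n_blocks // policy.cycle_blocks
    quota = _cycle_quota(spec, n_cycles)
    for item in spec.items:
        per_cycle = sum(quota[(item, s)] for s in spec.slots)
        if per_cycle != policy.cycle_blocks:
            raise InfeasibleSequenceError(
                f"item {item} has {per_cycle} presentations per cycle; once-per-block "
                f"structure needs exactly {policy.cycle_blocks}"
            )

    trials: list[TrainingTrial] = []
    index = 0
    for cycle in range(n_cycles):
        gram_slots: dict[str, list[str]] = {}
        ungram_slots: dict[str, list[str]] = {}
        for item in spec.items:
            g, u = [], []
            for slot in spec.slots:
                bucket = (
                    g
                    if spec.grammaticality[(item, slot)] is Gram.GRAMMATICAL
                    else u
                )
                bucket.extend([slot] * quota[(item, slot)])
            rng.shuffle(g)
            rng.shuffle(u)
            gram_slots[item], ungram_slots[item] = g, u
        ungram_blocks = _assign_ungrammatical_blocks(
            {it: len(ungram_slots[it]) for it in spec.items}, policy.cycle_blocks, rng
        )
        for b in range(policy.cycle_blocks):
            block_idx = cycle * policy.cycle_blocks + b
            members = list(spec.items)
            rng.shuffle(members)
            for item in members:
                slot = (
                    ungram_slots[item].pop()
                    if b in ungram_blocks[item]
                    else gram_slots[item].pop()
                )
                subj, obj = _random_pair(spec.nouns, rng)
                sent = realize_sentence(spec, mapping, item, slot, subj, obj)
                trials.append(TrainingTrial(index, block_idx, sent))
                index += 1
    return trials


def _generate_contraction(
    spec: LanguageSpec,
    policy: SequencePolicy,
    mapping: SlotMapping,
    rng: np.random.Generator,
) -> list[TrainingTrial]:
    n_items = len(spec.items)
    total = spec.total_trials()
    if total == 0:
        return []
    if total % n_items:
        raise InfeasibleSequenceError(
            f"{total} trials cannot form cycles with each of {n_items} items once"
        )
    n_cycles = total // n_items
    # each item cycles through its (slot, label) distribution in fixed-quota
    # chunks of `cycle_blocks` presentations when the totals divide evenly
    chunk = policy.cycle_blocks
    sequences: dict[str, list[str]] = {}
    for item in spec.items:
        if n_cycles % chunk == 0 and all(
            spec.frequency[(item, s)] % (n_cycles // chunk) == 0 for s in spec.slots
        ):
            n_chunks = n_cycles // chunk
            seq: list[str] = []
            for _ in range(n_chunks):
                part = [
                    s
                    for s in spec.slots
                    for _ in range(spec.frequency[(item, s)] // n_chunks)
                ]
                rng.shuffle(part)
                seq.extend(part)
        else:
            seq = [s for s in spec.slots for _ in range(spec.frequency[(item, s)])]
            rng.shuffle(seq)
        sequences[item] = seq

    trials: list[TrainingTrial] = []
    index = 0
    for cycle in range(n_cycles):
        members = list(spec.items)
        rng.shuffle(members)
        for item in members:
            slot = sequences[item][cycle]
            subj, obj = _random_pair(spec.nouns, rng)
            sent = realize_sentence(spec, mapping, item, slot, subj, obj)
            trials.append(TrainingTrial(index, cycle, sent))
            index += 1
    return trials


def generate_training_sequence(
    spec: LanguageSpec,
    policy: SequencePolicy | None = None,
    mapping: SlotMapping | None = None,
    seed: int | np.random.Generator = 0,
) -> list[TrainingTrial]:
    """Generate one participant's ordered training sequence.

    Per-cell trial counts equal ``spec.frequency`` exactly for every seed;
    only the ordering and the noun pairings are random.

    Raises
    ------
    InfeasibleSequenceError
        If the frequency matrix cannot be partitioned under the policy.
    """
    rng = np.random.default_rng(seed)
    if policy is None:
        policy = SequencePolicy()
    if mapping is None:
        mapping = sample_mapping(spec, rng)
    if spec.family == "word_order":
        return _generate_word_order(spec, policy, mapping, rng)
    return _generate_contraction(spec, policy, mapping, rng)


def cell_counts(
    trials: Iterable[TrainingTrial],
) -> dict[tuple[str, str, str], int]:
    """Tally trials by (item, slot, label)."""
    out: dict[tuple[str, str, str], int] = {}
    for t in trials:
        key = (t.sentence.item, t.sentence.slot, t.label.value)
        out[key] = out.get(key, 0) + 1
    return out


def trials_to_frame(
    trials: Iterable[TrainingTrial],
    participant: int | None = None,
    condition: str | None = None,
) -> pd.DataFrame:
    """Tidy DataFrame view of a trial list (one row per presentation)."""
    rows = []
    for t in trials:
        rows.append(
            {
                "index": t.index,
                "block": t.block,
                "item": t.sentence.item,
                "slot": t.sentence.slot,
                "subject": t.sentence.subject,
                "object": t.sentence.object,
                "surface": t.sentence.surface,
                "label": t.label.value,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "index",
            "block",
            "item",
            "slot",
            "subject",
            "object",
            "surface",
            "label",
        ],
    )
    if condition is not None:
        df.insert(0, "condition", condition)
    if participant is not None:
        df.insert(0, "participant", participant)
    return df
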