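"""Synthetic behavioral datasets on the experiments' test schedules.

Stands in for the undeposited human data: each simulated participant's
response probabilities come from a fitted learner (strong-condition
participants follow the strong model's grammaticality scores, weak-condition
participants the weak model's probabilities), passed through a two-parameter
noise model:

    P(respond grammatical) = lambda/2 + (1 - lambda) * sharpen(p, gamma)

where ``lambda`` is a lapse rate (uniform guessing) and ``gamma`` a
sharpening exponent, sharpen(p, gamma) = p^gamma / (p^gamma + (1-p)^gamma).
Productions in both conditions sample slots from the empirical input
distribution, reflecting the finding that usage frequencies — unlike
grammaticality judgments — do not differ across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TestSchedule",
    "NoiseModel",
    "simulate_judgments",
    "simulate_judgment_experiment",
    "simulate_productions",
    "simulate_completions",
    "simulate_from_logit",
]


@dataclass(frozen=True)
class TestSchedule:
    """Repetition counts of the test phase.

    Every item×slot cell is judged ``judgment_reps`` times; the exception
    cell receives ``exception_extra`` additional judgments (the critical
    generalization is probed four times in total by default).  Productions:
    ``productions_per_item`` free-generation prompts per item.  Completions
    (contraction family): ``completions_per_cell`` forced choices per cell.
    """

    judgment_reps: int = 2
    exception_extra: int = 2
    productions_per_item: int = 4
    completions_per_cell: int = 2

    __test__ = False  # not a pytest collection target despite the name

    def __post_init__(self) -> None:
        if min(
            self.judgment_reps,
            self.exception_extra,
            self.productions_per_item,
            self.completions_per_cell,
        ) < 0:
            raise ValueError("schedule counts must be non-negative")


@dataclass(frozen=True)
class NoiseModel:
    """Lapse + sharpening response noise.

    ``lapse`` in [0, 1] is the probability of a uniform random response
    (1 is pure guessing); ``gamma`` >= 0 sharpens (gamma > 1) or flattens
    (gamma < 1) the model probability; ``np.inf`` gives deterministic
    responding away from p = 0.5.
    """

    lapse: float = 0.1
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse rate must be in [0, 1]")
        if self.gamma < 0:
            raise ValueError("sharpening exponent must be non-negative")

    def response_prob(self, p: float) -> float:
        return self.lapse / 2.0 + (1.0 - self.lapse) * _sharpen(p, self.gamma)

    def mix_dist(self, dist: np.ndarray) -> np.ndarray:
        d = np.asarray(dist, dtype=float)
        if np.isinf(self.gamma):
            sharp = (d == d.max()).astype(float)
        elif self.gamma == 0:
            sharp = np.ones_like(d)
        else:
            sharp = np.where(d > 0, d**self.gamma, 0.0)
        sharp = sharp / sharp.sum()
        uniform = np.full_like(d, 1.0 / len(d))
        return self.lapse * uniform + (1.0 - self.lapse) * sharp


def _sharpen(p: float, gamma: float) -> float:
    if np.isinf(gamma):
        return 0.5 if p == 0.5 else float(p > 0.5)
    if gamma == 0:
        return 0.5
    a, b = p**gamma, (1.0 - p) ** gamma
    return a / (a + b)


def _check_probs(cell_probs: Mapping[tuple[str, str], float]) -> None:
    for cell, p in cell_probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} for cell {cell} outside [0, 1]")


def simulate_judgments(
    cell_probs: Mapping[tuple[str, str], float],
    n_participants: int,
    schedule: TestSchedule,
    noise: NoiseModel,
    seed: int | np.random.Generator,
    condition: str = "strong",
    exception_cell: tuple[str, str] | None = None,
    participant_offset: int = 0,
) -> pd.DataFrame:
    """Simulate binary grammaticality judgments for one condition.

    Returns a tidy frame with one row per judgment: participant, condition,
    item, slot, repetition, response ("grammatical"/"ungrammatical").
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    _check_probs(cell_probs)
    if exception_cell is not None and exception_cell not in cell_probs:
        raise ValueError(f"exception cell {exception_cell} has no probability")
    rng = np.random.default_rng(seed)
    rows = []
    for p_id in range(participant_offset, participant_offset + n_participants):
        for cell in sorted(cell_probs):
            reps = schedule.judgment_reps
            if exception_cell is not None and cell == exception_cell:
                reps += schedule.exception_extra
            rp = noise.response_prob(cell_probs[cell])
            draws = rng.random(reps) < rp
            for rep, grammatical in enumerate(draws):
                rows.append(
                    (
                        p_id,
                        condition,
                        cell[0],
                        cell[1],
                        rep,
                        "grammatical" if grammatical else "ungrammatical",
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["participant", "condition", "item", "slot", "repetition", "response"],
    )


def simulate_judgment_experiment(
    cell_probs_by_condition: Mapping[str, Mapping[tuple[str, str], float]],
    n_per_condition: int,
    schedule: TestSchedule,
    noise: NoiseModel,
    seed: int | np.random.Generator,
    exception_cell: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Balanced two-condition judgment dataset (equal n per condition)."""
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for condition in sorted(cell_probs_by_condition):
        frames.append(
            simulate_judgments(
                cell_probs_by_condition[condition],
                n_per_condition,
                schedule,
                noise,
                rng,
                condition=condition,
                exception_cell=exception_cell,
                participant_offset=offset,
            )
        )
        offset += n_per_condition
    return pd.concat(frames, ignore_index=True)


def simulate_productions(
    slot_dists: Mapping[str, np.ndarray],
    n_participants: int,
    schedule: TestSchedule,
    noise: NoiseModel,
    seed: int | np.random.Generator,
    slots: tuple[str, ...],
    condition: str = "strong",
    participant_offset: int = 0,
) -> pd.DataFrame:
    """Simulate the production test: sample a slot per prompted item."""
    rng = np.random.default_rng(seed)
    for item, d in slot_dists.items():
        d = np.asarray(d, dtype=float)
        if d.min() < 0 or not np.isclose(d.sum(), 1.0):
            raise ValueError(f"slot distribution for item {item!r} is not a distribution")
    rows = []
    for p_id in range(participant_offset, participant_offset + n_participants):
        for item in sorted(slot_dists):
            mixed = noise.mix_dist(np.asarray(slot_dists[item], dtype=float))
            choices = rng.choice(len(slots), size=schedule.productions_per_item, p=mixed)
            for trial, c in enumerate(choices):
                rows.append((p_id, condition, item, trial, slots[c]))
    return pd.DataFrame(
        rows, columns=["participant", "condition", "item", "trial", "slot"]
    )


def simulate_completions(
    contract_probs: Mapping[tuple[str, str], float],
    n_participants: int,
    schedule: TestSchedule,
    noise: NoiseModel,
    seed: int | np.random.Generator,
    condition: str = "strong",
    participant_offset: int = 0,
) -> pd.DataFrame:
    """Simulate the sentence-completion test (contract vs not, per cell)."""
    if n_participants < 1:
        raise ValueError("need at least one participant")
    _check_probs(contract_probs)
    rng = np.random.default_rng(seed)
    rows = []
    for p_id in range(participant_offset, participant_offset + n_participants):
        for cell in sorted(contract_probs):
            rp = noise.response_prob(contract_probs[cell])
            draws = rng.random(schedule.completions_per_cell) < rp
            for rep, contracted in enumerate(draws):
                rows.append(
                    (
                        p_id,
                        condition,
                        cell[0],
                        cell[1],
                        rep,
                        "contracted" if contracted else "uncontracted",
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["participant", "condition", "item", "slot", "repetition", "response"],
    )


def simulate_from_logit(
    cells: list[tuple[str, str]],
    exception_cell: tuple[str, str],
    coefs: Mapping[str, float],
    n_per_condition: int,
    schedule: TestSchedule,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Generate judgments from a known logit model (calibration studies).

    The response probability for a participant in ``condition`` judging
    ``cell`` is sigma(intercept + condition*[strong] + exception*[cell is the
    exception] + interaction*[both]), with ``coefs`` holding the four
    log-odds coefficients.  Responses are independent Bernoulli draws, so a
    correctly specified binomial GLM should recover the coefficients.
    """
    rng = np.random.default_rng(seed)
    b0 = coefs.get("intercept", 0.0)
    bc = coefs.get("condition", 0.0)
    be = coefs.get("exception", 0.0)
    bi = coefs.get("condition:exception", 0.0)
    rows = []
    p_id = 0
    for condition in ("strong", "weak"):
        is_strong = 1.0 if condition == "strong" else 0.0
        for _ in range(n_per_condition):
            for cell in cells:
                is_exc = 1.0 if cell == exception_cell else 0.0
                eta = b0 + bc * is_strong + be * is_exc + bi * is_strong * is_exc
                p = 1.0 / (1.0 + np.exp(-eta))
                reps = schedule.judgment_reps + (
                    schedule.exception_extra if is_exc else 0
                )
                for rep, hit in enumerate(rng.random(reps) < p):
                    rows.append(
                        (
                            p_id,
                            condition,
                            cell[0],
                            cell[1],
                            rep,
                            "grammatical" if hit else "ungrammatical",
                        )
                    )
            p_id += 1
    return pd.DataFrame(
        rows,
        columns=["participant", "condition", "item", "slot", "repetition", "response"],
    )
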