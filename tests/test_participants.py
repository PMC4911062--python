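"""Synthetic-participant simulator: schedule fidelity and noise-model limits."""

import numpy as np
import pytest

from samplearn.participants import (
    NoiseModel,
    TestSchedule,
    simulate_completions,
    simulate_from_logit,
    simulate_judgment_experiment,
    simulate_judgments,
    simulate_productions,
)

SCHEDULE = TestSchedule()


def _flat_probs(spec, p):
    return {cell: p for cell in spec.cells()}


def test_judgment_schedule_fidelity(exp1):
    probs = _flat_probs(exp1, 0.5)
    data = simulate_judgments(
        probs, 5, SCHEDULE, NoiseModel(0.1, 1.0), 0, exception_cell=exp1.exception_cell
    )
    per_participant = data.groupby("participant").size()
    assert (per_participant == 2 * 12 + 2).all()  # 26 judgments each
    exc = data[(data["item"] == "V4") & (data["slot"] == "C2")]
    assert (exc.groupby("participant").size() == 4).all()


def test_deterministic_limit_all_grammatical(exp1):
    probs = _flat_probs(exp1, 0.9)
    data = simulate_judgments(
        probs, 3, SCHEDULE, NoiseModel(lapse=0.0, gamma=np.inf), 1
    )
    assert (data["response"] == "grammatical").all()


def test_pure_guessing_rate():
    probs = {("i", "s"): 0.9}
    sched = TestSchedule(judgment_reps=10_000, exception_extra=0)
    data = simulate_judgments(probs, 1, sched, NoiseModel(lapse=1.0), 2)
    rate = (data["response"] == "grammatical").mean()
    se = np.sqrt(0.25 / 10_000)
    assert abs(rate - 0.5) < 3 * se


def test_noiseless_rate_matches_probability():
    probs = {("i", "s"): 0.75}
    sched = TestSchedule(judgment_reps=10_000, exception_extra=0)
    data = simulate_judgments(probs, 1, sched, NoiseModel(lapse=0.0, gamma=1.0), 3)
    rate = (data["response"] == "grammatical").mean()
    se = np.sqrt(0.75 * 0.25 / 10_000)
    assert abs(rate - 0.75) < 3 * se


def test_judgment_experiment_balanced(exp1, predictions):
    data = simulate_judgment_experiment(
        predictions["exp1"]["probs"],
        10,
        SCHEDULE,
        NoiseModel(),
        4,
        exception_cell=exp1.exception_cell,
    )
    sizes = data.groupby("condition")["participant"].nunique()
    assert sizes["strong"] == sizes["weak"] == 10
    # participant ids do not overlap across conditions
    strong_ids = set(data[data["condition"] == "strong"]["participant"])
    weak_ids = set(data[data["condition"] == "weak"]["participant"])
    assert not strong_ids & weak_ids


def test_seed_determinism(exp1):
    probs = _flat_probs(exp1, 0.6)
    a = simulate_judgments(probs, 4, SCHEDULE, NoiseModel(), 9)
    b = simulate_judgments(probs, 4, SCHEDULE, NoiseModel(), 9)
    assert a.equals(b)
    c = simulate_judgments(probs, 4, SCHEDULE, NoiseModel(), 10)
    assert not a.equals(c)


def test_productions_counts_and_degenerate_dist(exp1):
    dists = {item: np.array([1.0, 0.0, 0.0]) for item in exp1.items}
    data = simulate_productions(
        dists, 6, SCHEDULE, NoiseModel(lapse=0.0), 5, slots=exp1.slots
    )
    assert (data.groupby(["participant", "item"]).size() == 4).all()
    assert (data["slot"] == "C1").all()


def test_production_exception_rate_is_lapse_floor(exp1):
    # V4's input distribution is 18:0:6 over C1:C2:C3 -> C2 only via lapse
    lapse = 0.3
    dists = {"V4": np.array([18.0, 0.0, 6.0]) / 24.0}
    sched = TestSchedule(productions_per_item=4)
    data = simulate_productions(
        dists, 2500, sched, NoiseModel(lapse=lapse, gamma=1.0), 6, slots=exp1.slots
    )
    rate = (data["slot"] == "C2").mean()
    expected = lapse / 3.0
    n = len(data)
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(rate - expected) < 3 * se


@pytest.mark.parametrize("p,want", [(1.0, 1.0), (0.0, 0.0)])
def test_completions_deterministic_extremes(p, want):
    data = simulate_completions(
        {("M1", "P1"): p}, 5, SCHEDULE, NoiseModel(lapse=0.0), 7
    )
    assert (data["response"] == "contracted").mean() == want


def test_completions_binomial_rate():
    sched = TestSchedule(completions_per_cell=10_000)
    data = simulate_completions({("M1", "P1"): 0.5}, 1, sched, NoiseModel(0.0), 8)
    rate = (data["response"] == "contracted").mean()
    assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / 10_000)


def test_invalid_inputs_rejected(exp1):
    with pytest.raises(ValueError):
        NoiseModel(lapse=1.2)
    with pytest.raises(ValueError):
        simulate_judgments({("i", "s"): 1.5}, 2, SCHEDULE, NoiseModel(), 0)
    with pytest.raises(ValueError):
        simulate_judgments({("i", "s"): 0.5}, 0, SCHEDULE, NoiseModel(), 0)
    with pytest.raises(ValueError):
        simulate_productions(
            {"i": np.array([0.5, 0.2])}, 2, SCHEDULE, NoiseModel(), 0, slots=("a", "b")
        )


def test_logit_generator_rates(exp1):
    coefs = {"intercept": 0.0, "condition": -1.0, "exception": 0.0}
    data = simulate_from_logit(
        exp1.cells(), exp1.exception_cell, coefs, 400, TestSchedule(), 11
    )
    strong = data[data["condition"] == "strong"]
    weak = data[data["condition"] == "weak"]
    p_strong = (strong["response"] == "grammatical").mean()
    p_weak = (weak["response"] == "grammatical").mean()
    assert abs(p_weak - 0.5) < 0.02
    assert abs(p_strong - 1 / (1 + np.e)) < 0.02
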