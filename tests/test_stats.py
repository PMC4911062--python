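"""Analysis chain: fractional tallies, Pearson chi-square, ANOVA, GLM."""

import numpy as np
import pandas as pd
import pytest

from samplearn.participants import NoiseModel, TestSchedule, simulate_from_logit
from samplearn.stats import (
    FractionalTable,
    SeparationError,
    chi_square_test,
    fractional_tally,
    repeated_logit_glm,
    two_way_anova,
)


def _judgment_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["participant", "condition", "item", "slot", "repetition", "response"],
    )


def _single_cell_data(counts):
    """counts: {condition: [(k, m), ...]} per-participant grammatical counts."""
    rows = []
    p_id = 0
    for condition, entries in counts.items():
        for k, m in entries:
            for rep in range(m):
                resp = "grammatical" if rep < k else "ungrammatical"
                rows.append((p_id, condition, "V4", "C2", rep, resp))
            p_id += 1
    return _judgment_frame(rows)


def test_fractional_contribution_three_of_four():
    data = _single_cell_data({"strong": [(3, 4)], "weak": [(4, 4)]})
    table = fractional_tally(data, ("V4", "C2"))
    assert table.table[0].tolist() == [0.75, 0.25]
    assert table.table[1].tolist() == [1.0, 0.0]


def test_fractional_rows_sum_to_participant_counts():
    data = _single_cell_data(
        {"strong": [(2, 4)] * 10, "weak": [(1, 4), (3, 4), (4, 4)]}
    )
    table = fractional_tally(data, ("V4", "C2"))
    assert table.table[0].tolist() == [5.0, 5.0]
    assert table.row_sums().tolist() == [10.0, 3.0]


def test_fractional_tally_requires_responses_for_cell():
    data = _single_cell_data({"strong": [(1, 2)], "weak": [(1, 2)]})
    with pytest.raises(ValueError, match="no responses"):
        fractional_tally(data, ("V1", "C1"))


@pytest.mark.parametrize(
    "table,expected",
    [
        ([[10.0, 0.0], [0.0, 10.0]], 20.0),
        ([[5.0, 5.0], [5.0, 5.0]], 0.0),
        ([[7.5, 2.5], [2.5, 7.5]], 5.0),
    ],
)
def test_chi_square_hand_values(table, expected):
    res = chi_square_test(FractionalTable(np.array(table)))
    assert res.statistic == pytest.approx(expected, abs=1e-12)
    assert res.df == 1


def test_chi_square_matches_textbook_formula_on_integer_tables():
    rng = np.random.default_rng(0)
    for _ in range(20):
        t = rng.integers(1, 30, size=(2, 2)).astype(float)
        res = chi_square_test(FractionalTable(t))
        expected_counts = np.outer(t.sum(1), t.sum(0)) / t.sum()
        stat = ((t - expected_counts) ** 2 / expected_counts).sum()
        assert res.statistic == pytest.approx(stat, abs=1e-12)


def test_chi_square_label_swap_invariance():
    t = np.array([[8.0, 2.0], [3.0, 7.0]])
    a = chi_square_test(FractionalTable(t))
    b = chi_square_test(FractionalTable(t[::-1, ::-1]))
    assert a.statistic == pytest.approx(b.statistic, abs=1e-12)


def test_chi_square_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        chi_square_test(FractionalTable(np.array([[0.0, 5.0], [0.0, 5.0]])))


def _balanced_null_data(seed, n_per_condition=11, p=0.6, items=4, slots=3):
    cells = [(f"V{i+1}", f"C{s+1}") for i in range(items) for s in range(slots)]
    return simulate_from_logit(
        cells,
        cells[-2],
        {"intercept": float(np.log(p / (1 - p)))},
        n_per_condition,
        TestSchedule(),
        seed,
    )


def test_anova_exp1_shaped_dfs():
    data = _balanced_null_data(0)
    res = two_way_anova(data)
    assert res.condition_df[0] == 1
    assert res.interaction_df[0] == 11
    assert res.mse > 0


def test_anova_degenerate_data_flagged():
    data = _balanced_null_data(0)
    data["response"] = "grammatical"
    res = two_way_anova(data)
    assert res.zero_residual
    assert res.mse == 0.0


def test_anova_type_one_error_calibrated():
    """With no condition effect, the condition test rejects at about the
    nominal 5% rate."""
    reps = 400
    rejections = 0
    for seed in range(reps):
        res = two_way_anova(_balanced_null_data(seed))
        rejections += res.condition_p < 0.05
    rate = rejections / reps
    assert abs(rate - 0.05) <= 0.03


def test_glm_zero_effect_interaction_centered_on_zero():
    cells = [(f"V{i+1}", f"C{s+1}") for i in range(4) for s in range(3)]
    estimates = []
    for seed in range(60):
        data = simulate_from_logit(
            cells, ("V4", "C2"), {"intercept": 0.5}, 40, TestSchedule(), seed
        )
        res = repeated_logit_glm(data, ("V4", "C2"))
        estimates.append(res.params["condition:exception"])
    assert abs(np.mean(estimates)) < 0.1


def test_glm_needs_both_conditions():
    data = _balanced_null_data(1)
    with pytest.raises(ValueError, match="both conditions"):
        repeated_logit_glm(data[data["condition"] == "strong"], ("V4", "C2"))


def test_glm_separation_detected_and_ridge_recovers():
    rows = []
    for p_id in range(8):
        condition = "strong" if p_id < 4 else "weak"
        for cell in [("V1", "C1"), ("V4", "C2")]:
            # responses perfectly determined by condition -> separation
            resp = "grammatical" if condition == "weak" else "ungrammatical"
            for rep in range(2):
                rows.append((p_id, condition, cell[0], cell[1], rep, resp))
    data = _judgment_frame(rows)
    with pytest.raises(SeparationError):
        repeated_logit_glm(data, ("V4", "C2"))
    res = repeated_logit_glm(data, ("V4", "C2"), ridge=1.0)
    assert np.isfinite(res.params["condition"])
    assert res.params["condition"] < 0
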