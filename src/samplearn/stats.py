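"""The analysis chain applied to judgment datasets.

Three tests, mirroring the experiments' reporting conventions:

* fractional-tally 2×2 contingency tables with Pearson's χ² — each
  participant contributes their response *proportions* (summing to 1) to
  their condition's row rather than raw counts, a conservative correction
  for repeated judgments (equivalent to assuming responses are completely
  dependent); the χ² reference distribution is then used as-is, without a
  continuity correction;
* a fixed-effects two-way ANOVA over sentence cells × conditions on
  participant-level judgment proportions;
* a binomial GLM with logit link — predictors condition, exception-cell
  indicator, and their interaction — with repeated measures handled by
  participant-cluster-robust standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "FractionalTable",
    "ChiSquareResult",
    "AnovaResult",
    "GlmResult",
    "SeparationError",
    "fractional_tally",
    "chi_square_test",
    "two_way_anova",
    "repeated_logit_glm",
]

CONDITIONS = ("strong", "weak")


class SeparationError(RuntimeError):
    """Perfect separation in the GLM design; consider the ridge fallback."""


@dataclass(frozen=True)
class FractionalTable:
    """2×2 fractional contingency table: rows conditions, columns responses."""

    table: np.ndarray  # rows: (strong, weak); cols: (grammatical, ungrammatical)
    conditions: tuple[str, str] = CONDITIONS
    responses: tuple[str, str] = ("grammatical", "ungrammatical")

    def row_sums(self) -> np.ndarray:
        return self.table.sum(axis=1)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class AnovaResult:
    condition_F: float
    condition_df: tuple[int, int]
    interaction_F: float
    interaction_df: tuple[int, int]
    mse: float
    condition_p: float
    interaction_p: float
    zero_residual: bool = False


@dataclass(frozen=True)
class GlmResult:
    params: dict[str, float]
    bse: dict[str, float]
    p_values: dict[str, float]
    cov_type: str


def _proportions(data: pd.DataFrame, positive: str = "grammatical") -> pd.DataFrame:
    work = data.assign(_pos=(data["response"] == positive).astype(int))
    out = (
        work.groupby(["participant", "condition", "item", "slot"], sort=True)
        .agg(successes=("_pos", "sum"), trials=("_pos", "size"))
        .reset_index()
    )
    out["prop"] = out["successes"] / out["trials"]
    return out


def fractional_tally(
    data: pd.DataFrame,
    cell: tuple[str, str],
    positive: str = "grammatical",
) -> FractionalTable:
    """Fractional 2×2 table for one item×slot cell.

    A participant with k positive responses out of m contributes
    (k/m, (m-k)/m) to their condition's row, so each row sums to that
    condition's participant count.
    """
    item, slot = cell
    sub = data[(data["item"] == item) & (data["slot"] == slot)]
    participants = data["participant"].unique()
    present = sub["participant"].unique()
    missing = set(participants) - set(present)
    if missing:
        raise ValueError(
            f"participants {sorted(missing)} have no responses for cell {cell}"
        )
    table = np.zeros((2, 2))
    for (participant, condition), grp in sub.groupby(["participant", "condition"]):
        m = len(grp)
        k = int((grp["response"] == positive).sum())
        row = CONDITIONS.index(condition)
        table[row, 0] += k / m
        table[row, 1] += (m - k) / m
    return FractionalTable(table)


def chi_square_test(table: FractionalTable | np.ndarray) -> ChiSquareResult:
    """Pearson χ² of independence on a (possibly fractional) 2×2 table.

    No continuity correction; expected counts from the margins.
    """
    t = table.table if isinstance(table, FractionalTable) else np.asarray(table, float)
    if np.any(t.sum(axis=0) <= 0) or np.any(t.sum(axis=1) <= 0):
        raise ValueError("chi-square test undefined: a margin is zero")
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return ChiSquareResult(float(stat), int(df), float(p))


def two_way_anova(data: pd.DataFrame) -> AnovaResult:
    """Fixed-effects sentence-cell × condition ANOVA on judgment proportions.

    The response is each participant's proportion of "grammatical" judgments
    per cell, so an exp1-shaped balanced design yields numerator dfs of
    1 (condition) and n_cells - 1 (interaction).
    """
    props = _proportions(data)
    props = props.assign(cell=props["item"] + ":" + props["slot"])
    if props["cell"].nunique() < 2 or props["condition"].nunique() < 2:
        raise ValueError("two-way ANOVA needs >= 2 levels of cell and condition")
    model = ols("prop ~ C(cell) * C(condition)", data=props).fit()
    if model.ssr < 1e-12:
        return AnovaResult(
            condition_F=float("nan"),
            condition_df=(1, int(model.df_resid)),
            interaction_F=float("nan"),
            interaction_df=(props["cell"].nunique() - 1, int(model.df_resid)),
            mse=0.0,
            condition_p=float("nan"),
            interaction_p=float("nan"),
            zero_residual=True,
        )
    tab = anova_lm(model, typ=2)
    cond = tab.loc["C(condition)"]
    inter = tab.loc["C(cell):C(condition)"]
    df_resid = int(tab.loc["Residual", "df"])
    return AnovaResult(
        condition_F=float(cond["F"]),
        condition_df=(int(cond["df"]), df_resid),
        interaction_F=float(inter["F"]),
        interaction_df=(int(inter["df"]), df_resid),
        mse=float(tab.loc["Residual", "sum_sq"] / df_resid),
        condition_p=float(cond["PR(>F)"]),
        interaction_p=float(inter["PR(>F)"]),
    )


def repeated_logit_glm(
    data: pd.DataFrame,
    exception_cell: tuple[str, str],
    ridge: float = 0.0,
) -> GlmResult:
    """Binomial GLM (logit link) of judgments on condition × exception-cell.

    Aggregates to per-participant-per-cell success counts and fits
    grammatical ~ condition + exception + condition:exception with
    participant-cluster-robust covariance (the repeated-measures
    correction).  Detects separation and, with ``ridge > 0``, falls back to
    an L2-penalized fit (robust standard errors are then unavailable).
    """
    props = _proportions(data)
    if props["condition"].nunique() < 2:
        raise ValueError("GLM needs both conditions present")
    cond = (props["condition"] == "strong").astype(float)
    exc = (
        (props["item"] == exception_cell[0]) & (props["slot"] == exception_cell[1])
    ).astype(float)
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "condition": cond,
            "exception": exc,
            "condition:exception": cond * exc,
        }
    )
    endog = np.column_stack(
        [props["successes"], props["trials"] - props["successes"]]
    )
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    if ridge > 0:
        fit = model.fit_regularized(alpha=ridge, L1_wt=0.0)
        params = dict(zip(X.columns, map(float, fit.params)))
        return GlmResult(
            params=params,
            bse={k: float("nan") for k in X.columns},
            p_values={k: float("nan") for k in X.columns},
            cov_type=f"ridge(alpha={ridge})",
        )
    try:
        fit = model.fit(
            cov_type="cluster", cov_kwds={"groups": props["participant"].to_numpy()}
        )
    except Exception as err:  # statsmodels signals separation in several ways
        raise SeparationError(
            "GLM fit failed (likely perfect separation); refit with ridge > 0 "
            f"for a penalized estimate [{err}]"
        ) from err
    if not np.all(np.isfinite(fit.params)) or np.any(np.abs(fit.params) > 15):
        raise SeparationError(
            "quasi-separation detected (non-finite or extreme coefficients); "
            "refit with ridge > 0 for a penalized estimate"
        )
    return GlmResult(
        params=dict(zip(X.columns, map(float, fit.params))),
        bse=dict(zip(X.columns, map(float, fit.bse))),
        p_values=dict(zip(X.columns, map(float, fit.pvalues))),
        cov_type="cluster(participant)",
    )
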