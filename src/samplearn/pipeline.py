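"""End-to-end orchestration: language → corpus → learners → synthetic
participants → statistics, with every artifact written to a results bundle.

A run is fully determined by its :class:`RunConfig`; rerunning with the same
config reproduces byte-identical CSV/JSON payloads.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import corpus as corpus_mod
from .language import Gram, LanguageSpec, build_language
from .participants import (
    NoiseModel,
    TestSchedule,
    simulate_completions,
    simulate_judgment_experiment,
    simulate_productions,
)
from .stats import (
    SeparationError,
    chi_square_test,
    fractional_tally,
    repeated_logit_glm,
    two_way_anova,
)
from .strong import StrongHyper, fit_strong, grammaticality_score_strong
from .weak import WeakPrior, fit_weak, grammaticality_prob_weak

__all__ = ["RunConfig", "run_pipeline", "export_figure_tables", "model_cell_predictions"]

#: Overall propensity to contract a grammatical contraction (completion test).
CONTRACTION_PROPENSITY = 0.5


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulated experiment."""

    experiment: str = "exp1"  # fixture id or path to a language config
    seed: int = 0
    n_per_condition: int = 25
    lapse: float = 0.1
    gamma: float = 1.0
    judgment_reps: int = 2
    exception_extra: int = 2
    productions_per_item: int = 4
    completions_per_cell: int = 2
    out_dir: str = "results"

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
        NoiseModel(self.lapse, self.gamma)  # bounds check

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def model_cell_predictions(
    spec: LanguageSpec,
    seed: int = 0,
    strong_hyper: StrongHyper | None = None,
    weak_prior: WeakPrior | None = None,
):
    """Fit both learners on one generated corpus; return per-cell predictions.

    Returns (strong_posterior, weak_posterior, cell_probs) where cell_probs
    maps condition → {(item, slot): grammaticality measure}.  The per-cell
    trial counts are seed-independent by construction, so the fits depend on
    the seed only through nothing at all — any seed gives the same counts.
    """
    rng = np.random.default_rng(seed)
    trials = corpus_mod.generate_training_sequence(spec, seed=rng)
    positive = [t for t in trials if t.label is Gram.GRAMMATICAL]
    strong_post = fit_strong(positive, strong_hyper, spec=spec)
    weak_post = fit_weak(trials, weak_prior, spec=spec)
    cell_probs = {
        "strong": {
            cell: grammaticality_score_strong(strong_post, *cell)
            for cell in spec.cells()
        },
        "weak": {
            cell: grammaticality_prob_weak(weak_post, *cell) for cell in spec.cells()
        },
    }
    return strong_post, weak_post, cell_probs


def _input_slot_dists(spec: LanguageSpec) -> dict[str, np.ndarray]:
    dists = {}
    for item in spec.items:
        f = np.array([spec.frequency[(item, s)] for s in spec.slots], dtype=float)
        dists[item] = f / f.sum()
    return dists


def run_pipeline(config: RunConfig) -> dict:
    """Run the full simulated experiment and write the results bundle.

    Returns a manifest dict (also written to ``manifest.json``) whose
    ``artifacts`` entry maps artifact names to file paths.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = build_language(config.experiment)
    root = np.random.default_rng(config.seed)
    seeds = {
        name: int(root.integers(2**31))
        for name in ("training", "models", "judgments", "productions", "completions")
    }

    # per-participant training sequences (both conditions see identical input
    # statistics; sequences differ only in randomization)
    train_rng = np.random.default_rng(seeds["training"])
    frames = []
    n_total = 2 * config.n_per_condition
    for p_id in range(n_total):
        condition = "strong" if p_id < config.n_per_condition else "weak"
        mapping = corpus_mod.sample_mapping(spec, train_rng)
        trials = corpus_mod.generate_training_sequence(
            spec, mapping=mapping, seed=train_rng
        )
        frames.append(corpus_mod.trials_to_frame(trials, p_id, condition))
    training = pd.concat(frames, ignore_index=True)
    training_path = out / "training_trials.csv"
    training.to_csv(training_path, index=False)

    strong_post, weak_post, cell_probs = model_cell_predictions(
        spec, seed=seeds["models"]
    )
    (out / "strong_model.json").write_text(strong_post.to_json())
    (out / "weak_model.json").write_text(weak_post.to_json())

    schedule = TestSchedule(
        judgment_reps=config.judgment_reps,
        exception_extra=config.exception_extra,
        productions_per_item=config.productions_per_item,
        completions_per_cell=config.completions_per_cell,
    )
    noise = NoiseModel(config.lapse, config.gamma)
    judgments = simulate_judgment_experiment(
        cell_probs,
        config.n_per_condition,
        schedule,
        noise,
        seeds["judgments"],
        exception_cell=spec.exception_cell,
    )
    judgments_path = out / "judgments.csv"
    judgments.to_csv(judgments_path, index=False)

    artifacts = {
        "training_trials": str(training_path),
        "judgments": str(judgments_path),
        "strong_model": str(out / "strong_model.json"),
        "weak_model": str(out / "weak_model.json"),
    }

    input_dists = _input_slot_dists(spec)
    if spec.family == "word_order":
        prod_rng = np.random.default_rng(seeds["productions"])
        prods = []
        offset = 0
        for condition in ("strong", "weak"):
            prods.append(
                simulate_productions(
                    input_dists,
                    config.n_per_condition,
                    schedule,
                    noise,
                    prod_rng,
                    slots=spec.slots,
                    condition=condition,
                    participant_offset=offset,
                )
            )
            offset += config.n_per_condition
        productions = pd.concat(prods, ignore_index=True)
        productions_path = out / "productions.csv"
        productions.to_csv(productions_path, index=False)
        artifacts["productions"] = str(productions_path)
    else:
        comp_rng = np.random.default_rng(seeds["completions"])
        comps = []
        offset = 0
        for condition in ("strong", "weak"):
            contract_probs = {
                cell: CONTRACTION_PROPENSITY * p
                for cell, p in cell_probs[condition].items()
            }
            comps.append(
                simulate_completions(
                    contract_probs,
                    config.n_per_condition,
                    schedule,
                    noise,
                    comp_rng,
                    condition=condition,
                    participant_offset=offset,
                )
            )
            offset += config.n_per_condition
        completions = pd.concat(comps, ignore_index=True)
        completions_path = out / "completions.csv"
        completions.to_csv(completions_path, index=False)
        artifacts["completions"] = str(completions_path)

    # analysis chain
    table = fractional_tally(judgments, spec.exception_cell)
    chi2 = chi_square_test(table)
    anova = two_way_anova(judgments)
    try:
        glm = repeated_logit_glm(judgments, spec.exception_cell)
        glm_fallback = False
    except SeparationError:
        # small samples with near-deterministic cells can separate; report
        # the penalized estimate and flag it
        glm = repeated_logit_glm(judgments, spec.exception_cell, ridge=1.0)
        glm_fallback = True
    stats_payload = {
        "exception_cell": list(spec.exception_cell),
        "fractional_table": {
            "rows": list(table.conditions),
            "cols": list(table.responses),
            "values": table.table.tolist(),
        },
        "chi_square": {
            "test": "pearson_chi2_fractional",
            "statistic": chi2.statistic,
            "df": chi2.df,
            "p": chi2.p_value,
            "decision_threshold": 0.05,
        },
        "anova": {
            "test": "two_way_anova_cells_x_condition",
            "condition_F": anova.condition_F,
            "condition_df": list(anova.condition_df),
            "condition_p": anova.condition_p,
            "interaction_F": anova.interaction_F,
            "interaction_df": list(anova.interaction_df),
            "interaction_p": anova.interaction_p,
            "mse": anova.mse,
        },
        "glm": {
            "test": "binomial_logit_cluster_robust",
            "params": glm.params,
            "bse": glm.bse,
            "p": glm.p_values,
            "cov_type": glm.cov_type,
            "separation_fallback": glm_fallback,
        },
    }
    stats_path = out / "stats.json"
    stats_path.write_text(json.dumps(stats_payload, indent=2, sort_keys=True))
    artifacts["stats"] = str(stats_path)

    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seeds": seeds,
        "experiment_name": spec.name,
        "exception_cell": list(spec.exception_cell),
        "n_training_trials_per_participant": int(spec.total_trials()),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def export_figure_tables(bundle_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Per-cell judgment/production proportion tables from a results bundle.

    One row per (condition, item, slot) with the proportion of "grammatical"
    judgments (resp. productions in each slot, plus an "X" category for
    out-of-pattern productions, always 0 for simulated data).  Tables are
    written next to the bundle's other artifacts.
    """
    bundle = Path(bundle_dir)
    manifest_path = bundle / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {bundle}")
    manifest = json.loads(manifest_path.read_text())
    out: dict[str, pd.DataFrame] = {}

    judgments = pd.read_csv(manifest["artifacts"]["judgments"])
    jt = (
        judgments.assign(grammatical=judgments["response"] == "grammatical")
        .groupby(["condition", "item", "slot"], sort=True)
        .agg(proportion=("grammatical", "mean"), n=("grammatical", "size"))
        .reset_index()
    )
    jt.to_csv(bundle / "judgment_proportions.csv", index=False)
    out["judgments"] = jt

    prod_path = manifest["artifacts"].get("productions")
    if prod_path:
        productions = pd.read_csv(prod_path)
        slots = sorted(productions["slot"].unique())
        rows = []
        for (condition, item), grp in productions.groupby(["condition", "item"]):
            n = len(grp)
            for slot in slots:
                rows.append(
                    {
                        "condition": condition,
                        "item": item,
                        "slot": slot,
                        "proportion": float((grp["slot"] == slot).mean()),
                        "n": n,
                    }
                )
            rows.append(
                {"condition": condition, "item": item, "slot": "X", "proportion": 0.0, "n": n}
            )
        pt = pd.DataFrame(rows)
        pt.to_csv(bundle / "production_proportions.csv", index=False)
        out["productions"] = pt

    comp_path = manifest["artifacts"].get("completions")
    if comp_path:
        completions = pd.read_csv(comp_path)
        ct = (
            completions.assign(contracted=completions["response"] == "contracted")
            .groupby(["condition", "item", "slot"], sort=True)
            .agg(proportion=("contracted", "mean"), n=("contracted", "size"))
            .reset_index()
        )
        ct.to_csv(bundle / "completion_proportions.csv", index=False)
        out["completions"] = ct
    return out
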