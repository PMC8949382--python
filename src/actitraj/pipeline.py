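"""Config-driven end-to-end runner.

Executes synthetic-data generation (or CSV ingest), epoch processing,
feature construction, the class-count sweep and selection, profile
assignment, and the baseline-predictor regression, writing CSV/JSON result
surfaces: a fit-index table, a baseline-characteristics-by-profile table,
a predictor table, and per-profile mean z-value trajectories with 95%
confidence intervals per wave.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import features as features_mod
from . import predictors as predictors_mod
from . import selection as selection_mod
from .lclmm import LclmmSpec
from .processing import (
    ProcessingRules,
    filter_valid_waves,
    process_epochs,
    wave_guidelines,
)

logger = logging.getLogger("actitraj")

STAGES = ("simulate", "process", "features", "fit", "predict")
CSV_FLOAT_FORMAT = "%.10g"


class PipelineStageError(RuntimeError):
    """Raised when a stage fails; carries a machine-readable record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.record = {"stage": stage, "error": message}


def percent(count: int, denominator: int) -> int:
    """Integer percent, rounded half away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return int(math.floor(100.0 * count / denominator + 0.5))


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "out"
    synthetic: dict | None = None
    inputs: dict | None = None
    rules: dict = field(default_factory=dict)
    pruning: dict = field(default_factory=lambda: {"policy": "preset", "threshold": 0.9})
    lclmm: dict = field(default_factory=dict)
    predictors: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' or 'inputs' must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def processing_rules(self) -> ProcessingRules:
        return ProcessingRules(**self.rules)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def _synthetic_cohort(cfg: PipelineConfig):
    params = dict(cfg.synthetic or {})
    preset = params.pop("preset", "high_separation")
    n = int(params.pop("n_participants", 100))
    seed = int(params.pop("seed", cfg.seed))
    if params:
        raise ValueError(f"unknown synthetic options: {sorted(params)}")
    if preset == "high_separation":
        spec, profiles = cohort_mod.high_separation_preset(n=n, seed=seed)
    elif preset == "zero_separation":
        spec, profiles = cohort_mod.zero_separation_preset(n=n, seed=seed)
    else:
        raise ValueError(f"unknown synthetic preset: {preset!r}")
    return cohort_mod.generate_cohort(spec, profiles)


def summarize_by_profile(
    covariates: pd.DataFrame,
    assignments: pd.DataFrame,
    baseline_guideline: pd.DataFrame | None = None,
    n_classes: int | None = None,
) -> pd.DataFrame:
    """Baseline characteristics for all participants and per profile.

    Continuous variables as mean (SD); categorical as n (%) with the column
    size as denominator and percents rounded to the nearest integer (half
    away from zero).  Empty profiles yield a flagged empty column.
    """
    df = covariates.merge(assignments, on="participant_id", how="inner")
    if baseline_guideline is not None:
        df = df.merge(
            baseline_guideline[["participant_id", "meets_guideline"]],
            on="participant_id", how="left",
        )
    observed = sorted(df["assigned_class"].unique())
    labels = list(range(1, n_classes + 1)) if n_classes else observed
    empty = [g for g in labels if g not in observed]
    if empty:
        logger.warning("profiles with no members: %s", empty)
    groups: list[tuple[str, pd.DataFrame]] = [("all", df)]
    for g in labels:
        groups.append((f"profile_{g}", df[df["assigned_class"] == g]))

    rows = []

    def add_categorical(variable: str, level: str, indicator: pd.Series) -> None:
        for name, grp in groups:
            mask = indicator.loc[grp.index]
            count = int(mask.sum())
            rows.append(
                {
                    "variable": variable, "level": level, "group": name,
                    "n_group": len(grp), "count": count,
                    "pct": percent(count, len(grp)) if len(grp) else None,
                    "mean": None, "sd": None,
                }
            )

    def add_continuous(variable: str, series: pd.Series) -> None:
        for name, grp in groups:
            vals = series.loc[grp.index].astype(float)
            rows.append(
                {
                    "variable": variable, "level": "", "group": name,
                    "n_group": len(grp), "count": None, "pct": None,
                    "mean": round(float(vals.mean()), 4) if len(grp) else None,
                    "sd": round(float(vals.std(ddof=1)), 4) if len(grp) > 1 else None,
                }
            )

    add_categorical("gender", "female", df["gender"] == "F")
    add_continuous("age", df["age"])
    add_continuous("bmi", df["bmi"])
    for level in ("multi", "single", "control"):
        add_categorical("randomisation", level, df["randomisation"] == level)
    for var in ("hypertension", "copd", "other_disease"):
        add_categorical(var, "yes", df[var] == 1)
    if "meets_guideline" in df.columns:
        add_categorical("baseline_guideline", "yes", df["meets_guideline"] == True)  # noqa: E712
    return pd.DataFrame(rows)


def trajectory_table(z_panel: pd.DataFrame, assignments: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Per-profile mean z-value per wave with normal-approximation 95% CI."""
    merged = z_panel.merge(assignments, on="participant_id", how="inner")
    rows = []
    for (g, wave), grp in merged.groupby(["assigned_class", "wave_month"], sort=True):
        for feat in features:
            vals = grp[feat].astype(float)
            n = len(vals)
            mean = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            rows.append(
                {
                    "profile": int(g), "wave_month": wave, "feature": feat,
                    "n": n, "mean_z": mean,
                    "ci_low": mean - 1.96 * se if n > 1 else None,
                    "ci_high": mean + 1.96 * se if n > 1 else None,
                }
            )
    return pd.DataFrame(rows)


def run(config: PipelineConfig, upto: str = "predict") -> dict:
    """Execute the pipeline through stage ``upto``; returns artefact paths.

    Any stage failure raises :class:`PipelineStageError` naming the stage,
    after writing its machine-readable record to ``error.json``.
    """
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config, outdir)
    last = STAGES.index(upto)
    artefacts: dict[str, Path] = {}
    state: dict = {}
    for stage in STAGES[: last + 1]:
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, outdir, state, artefacts)
        except Exception as exc:
            err = PipelineStageError(stage, str(exc))
            _write_json(err.record, outdir / "error.json")
            logger.error("stage %s failed: %s", stage, exc)
            raise err from exc
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
    return {k: str(v) for k, v in artefacts.items()}


def _setup_logging(config: PipelineConfig, outdir: Path) -> None:
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    if not any(isinstance(h, logging.FileHandler) for h in logger.handlers):
        fh = logging.FileHandler(outdir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    if not any(type(h) is logging.StreamHandler for h in logger.handlers):
        logger.addHandler(logging.StreamHandler())


def _stage_simulate(config, outdir, state, artefacts):
    if config.synthetic is not None:
        epochs, covariates, truth = _synthetic_cohort(config)
        paths = cohort_mod.write_cohort(outdir, epochs, covariates, truth)
        artefacts.update(paths)
        state.update(epochs=epochs, covariates=covariates, truth=truth)
    else:
        state["epochs"] = pd.read_csv(config.inputs["epochs"])
        state["covariates"] = pd.read_csv(config.inputs["covariates"])
        state["truth"] = None


def _stage_process(config, outdir, state, artefacts):
    rules = config.processing_rules()
    days = process_epochs(state["epochs"], rules)
    retained, waves, accounting = filter_valid_waves(days, rules)
    guidelines = wave_guidelines(retained, rules)
    state.update(days=days, retained_days=retained, waves=waves,
                 guidelines=guidelines, accounting=accounting)
    _write_csv(days, outdir / "day_summaries.csv")
    _write_csv(waves.merge(guidelines, on=["participant_id", "wave_month"], how="left"),
               outdir / "wave_summaries.csv")
    _write_json(accounting, outdir / "accounting.json")
    artefacts["day_summaries"] = outdir / "day_summaries.csv"
    artefacts["wave_summaries"] = outdir / "wave_summaries.csv"
    logger.info("exclusions: %s", accounting)


def _stage_features(config, outdir, state, artefacts):
    panel = features_mod.build_feature_vectors(state["retained_days"])
    if panel.empty:
        raise ValueError("no retained participant-waves")
    std = features_mod.standardize(panel)
    report = features_mod.prune_collinear(
        panel,
        threshold=float(config.pruning.get("threshold", 0.9)),
        policy=config.pruning.get("policy", "preset"),
    )
    state.update(panel=panel, standardized=std, pruning=report)
    long = panel.melt(
        id_vars=["participant_id", "wave_month"],
        value_vars=features_mod.FEATURE_NAMES,
        var_name="feature", value_name="raw_value",
    ).merge(
        std.z.melt(
            id_vars=["participant_id", "wave_month"],
            value_vars=features_mod.FEATURE_NAMES,
            var_name="feature", value_name="z_value",
        ),
        on=["participant_id", "wave_month", "feature"],
    ).sort_values(["participant_id", "wave_month", "feature"], kind="stable")
    _write_csv(long, outdir / "features.csv")
    report.to_json(outdir / "pruning.json")
    artefacts["features"] = outdir / "features.csv"
    artefacts["pruning"] = outdir / "pruning.json"


def _stage_fit(config, outdir, state, artefacts):
    opts = dict(config.lclmm)
    G_list = [int(g) for g in opts.pop("G_list", [1, 2, 3, 4, 5])]
    outcomes = tuple(opts.pop("outcomes", state["pruning"].retained))
    min_share = float(opts.pop("min_class_share", 0.05))
    z = state["standardized"].z.copy()
    z["time_years"] = z["wave_month"] / 12.0
    spec = LclmmSpec(
        n_classes=2, outcomes=outcomes, seed=int(opts.pop("seed", config.seed)), **opts
    )
    table = selection_mod.sweep(z, spec, G_list)
    rationale = selection_mod.select(table.table, min_class_share=min_share)
    chosen = rationale["chosen_G"]
    best = table.fits[chosen]
    assignments = best.posterior_frame()
    state.update(fit_table=table, selection=rationale, best_fit=best,
                 assignments=assignments[["participant_id", "assigned_class"]],
                 z_panel=z)
    out_cols = [c for c in selection_mod.TABLE_COLUMNS if c in table.table.columns]
    _write_csv(table.table[out_cols], outdir / "fit_table.csv")
    selection_mod.write_selection(rationale, outdir / "selection.json")
    best.to_json(outdir / "lclmm_fit.json")
    _write_csv(assignments, outdir / "posteriors.csv")
    traj = trajectory_table(z, state["assignments"], list(features_mod.FEATURE_NAMES))
    _write_csv(traj, outdir / "trajectories.csv")
    artefacts.update(
        fit_table=outdir / "fit_table.csv",
        selection=outdir / "selection.json",
        lclmm_fit=outdir / "lclmm_fit.json",
        posteriors=outdir / "posteriors.csv",
        trajectories=outdir / "trajectories.csv",
    )


def _increased_class(best_fit) -> int:
    """1-based label of the class with the steepest mean-MVPA slope."""
    outcomes = list(best_fit.spec.outcomes)
    k = outcomes.index("mean_mvpa") if "mean_mvpa" in outcomes else 0
    return int(np.argmax(best_fit.params.beta[:, k, 1])) + 1


def _stage_predict(config, outdir, state, artefacts):
    best = state["best_fit"]
    assignments = state["assignments"]
    guidelines = state["guidelines"]
    baseline_wave = guidelines["wave_month"].min()
    baseline = guidelines[guidelines["wave_month"] == baseline_wave][
        ["participant_id", "meets_guideline"]
    ]
    chars = summarize_by_profile(
        state["covariates"], assignments, baseline, n_classes=best.spec.n_classes
    )
    _write_csv(chars, outdir / "characteristics.csv")
    artefacts["characteristics"] = outdir / "characteristics.csv"

    increased = _increased_class(best)
    df = state["covariates"].merge(assignments, on="participant_id", how="inner")
    df = df.merge(baseline, on="participant_id", how="inner")
    n_dropped = len(assignments) - len(df)
    if n_dropped:
        logger.info("predictors: %d participants without a baseline wave dropped", n_dropped)
    df["increased"] = (df["assigned_class"] == increased).astype(int)
    df["guideline"] = df["meets_guideline"].astype(int)
    opts = dict(config.predictors)
    criterion = opts.pop("criterion", "aic")
    candidates = opts.pop("candidates", ["bmi", "hypertension", "copd", "other_disease", "guideline"])
    if opts:
        raise ValueError(f"unknown predictor options: {sorted(opts)}")
    fit = predictors_mod.backward_eliminate(
        df, "increased", candidate_terms=list(candidates), criterion=criterion
    )
    report = predictors_mod.diagnostics(fit, df, "increased")
    fit.to_csv(outdir / "predictors.csv")
    _write_json(
        {
            "increased_class": increased,
            "intercept": fit.intercept,
            "criterion": criterion,
            "elimination_trace": fit.elimination_trace,
            "separation_flags": fit.separation_flags,
            "diagnostics": report,
        },
        outdir / "predictor_diagnostics.json",
    )
    artefacts["predictors"] = outdir / "predictors.csv"
    artefacts["predictor_diagnostics"] = outdir / "predictor_diagnostics.json"
    state["predictor_fit"] = fit


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "process": _stage_process,
    "features": _stage_features,
    "fit": _stage_fit,
    "predict": _stage_predict,
}
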