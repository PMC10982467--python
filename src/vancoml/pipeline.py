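"""Three-step pipeline: simulate a cohort, learn the hybrid model, evaluate.

``run_all`` executes the full workflow from a :class:`RunConfig`:

1. **simulate** — draw the virtual cohort, sample per-patient random
   effects, realize each patient's individual clearance from the PK model;
2. **learn** — split 1:3 test:train, cross-validate and fit the four tree
   ensembles on covariates → realized clearance, select the best by
   test-partition R²;
3. **evaluate** — draw the evaluation patients (by default from the same
   pool the models were trained on; optionally a fresh holdout cohort),
   score hybrid vs PPK population predictions, write the comparison table,
   error summary and diagnostic figures.

Each stage derives its own seed from the master seed hashed with the stage
name, so stages are individually reproducible and the whole run is
deterministic: identical config + master seed ⇒ byte-identical CSV/JSON
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cohort as cohort_mod
from . import evaluate as eval_mod
from . import ml as ml_mod
from . import ppk as ppk_mod
from .errors import ConfigurationError

logger = logging.getLogger("vancoml")

EVAL_MODES = ("overlap", "holdout")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SHA-256 of ``"<master>:<stage>"`` mod 2³¹."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass(frozen=True)
class SamplingConfig:
    method: str = "direct"
    hmc: ppk_mod.HMCOptions = field(default_factory=ppk_mod.HMCOptions)

    def __post_init__(self) -> None:
        if self.method not in ("direct", "hmc"):
            raise ConfigurationError(f"sampling method must be direct|hmc, got {self.method!r}")


@dataclass(frozen=True)
class MLConfig:
    """ML stage settings.

    ``final_model`` names the algorithm whose predictions are carried into
    the evaluation stage. The default is extreme gradient boosting — the
    study design this package replicates fixes that as its final model — and
    ``"auto"`` instead applies :func:`vancoml.ml.select_model` (highest
    test-partition R²). Auto-selection is computed and reported either way.
    """

    algorithms: tuple[str, ...] = ml_mod.ALGORITHMS
    split_ratio: str = "1:3"
    cv_folds: int = 5
    final_model: str = "extreme_gradient_boosting"

    def __post_init__(self) -> None:
        for alg in self.algorithms:
            if alg not in ml_mod.ALGORITHMS:
                raise ConfigurationError(f"unknown algorithm {alg!r}")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if self.final_model != "auto" and self.final_model not in ml_mod.ALGORITHMS:
            raise ConfigurationError(
                f"final_model must be 'auto' or one of {ml_mod.ALGORITHMS}"
            )
        if self.final_model != "auto" and self.final_model not in self.algorithms:
            raise ConfigurationError(
                f"final_model {self.final_model!r} is not among the configured algorithms"
            )


@dataclass(frozen=True)
class EvalConfig:
    n_eval: int = 250
    mode: str = "overlap"

    def __post_init__(self) -> None:
        if self.n_eval <= 0:
            raise ConfigurationError("n_eval must be > 0")
        if self.mode not in EVAL_MODES:
            raise ConfigurationError(f"evaluation mode must be one of {EVAL_MODES}")


@dataclass(frozen=True)
class RunConfig:
    cohort: cohort_mod.CohortSpec = field(default_factory=cohort_mod.CohortSpec)
    ppk: ppk_mod.PPKParams = field(default_factory=ppk_mod.PPKParams)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    ml: MLConfig = field(default_factory=MLConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    master_seed: int = 0
    output_dir: str = "runs/default"


@dataclass(frozen=True)
class RunArtifacts:
    """Paths to everything a completed run wrote."""

    cohort_csv: str
    etas_csv: str
    metrics_json: str
    cv_table_csv: str
    comparison_csv: str
    summary_json: str
    figures: dict[str, str]
    log_file: str
    config_snapshot: str
    manifest_json: str
    selected_algorithm: str


# ---------------------------------------------------------------------------
# Config parsing
# ---------------------------------------------------------------------------

def _build(cls, data: dict, context: str):
    """Instantiate a (frozen) dataclass from a dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigurationError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ConfigurationError(f"{context}: unknown keys {unknown}")
    return cls(**data)


def _tupled(value, context: str) -> tuple[float, float]:
    if not isinstance(value, (list, tuple)) or len(value) != 2:
        raise ConfigurationError(f"{context}: expected [min, max]")
    return (float(value[0]), float(value[1]))


def config_from_dict(data: dict) -> RunConfig:
    """Build a validated :class:`RunConfig` from a plain nested dict."""
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    known = {"cohort", "ppk", "sampling", "ml", "evaluation", "master_seed", "output_dir"}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigurationError(f"config: unknown keys {unknown}")

    cohort_data = dict(data.get("cohort", {}))
    for key in ("age_range", "weight_range", "scr_range"):
        if key in cohort_data:
            cohort_data[key] = _tupled(cohort_data[key], f"cohort.{key}")
    spec = _build(cohort_mod.CohortSpec, cohort_data, "cohort")

    params = _build(ppk_mod.PPKParams, dict(data.get("ppk", {})), "ppk")

    sampling_data = dict(data.get("sampling", {}))
    if "hmc" in sampling_data:
        sampling_data["hmc"] = _build(ppk_mod.HMCOptions, dict(sampling_data["hmc"]), "sampling.hmc")
    sampling = _build(SamplingConfig, sampling_data, "sampling")

    ml_data = dict(data.get("ml", {}))
    if "algorithms" in ml_data:
        ml_data["algorithms"] = tuple(ml_data["algorithms"])
    ml_cfg = _build(MLConfig, ml_data, "ml")

    eval_cfg = _build(EvalConfig, dict(data.get("evaluation", {})), "evaluation")

    return RunConfig(
        cohort=spec,
        ppk=params,
        sampling=sampling,
        ml=ml_cfg,
        evaluation=eval_cfg,
        master_seed=int(data.get("master_seed", 0)),
        output_dir=str(data.get("output_dir", "runs/default")),
    )


def validate_config(path) -> RunConfig:
    """Parse, default and range-check a YAML/JSON config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}  # YAML is a JSON superset
    return config_from_dict(data)


def config_to_dict(config: RunConfig) -> dict:
    out = dataclasses.asdict(config)
    out["ml"]["algorithms"] = list(config.ml.algorithms)
    for key in ("age_range", "weight_range", "scr_range"):
        out["cohort"][key] = list(out["cohort"][key])
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _resolve_seeds(config: RunConfig) -> dict[str, int]:
    return {
        stage: stage_seed(config.master_seed, stage)
        for stage in ("cohort", "etas", "split", "fit", "cv", "evaluate")
    }


def replicate_study(config: RunConfig | None = None, master_seed: int | None = None) -> dict:
    """One in-memory pass of simulate → learn → evaluate; summary numbers only.

    Runs the same stages and seed fan-out as :func:`run_all` but skips
    cross-validation, file artifacts and figures, returning the evaluation
    summary: improvement fraction and count, mean absolute/relative errors
    of the PPK population prediction and of the hybrid model, plus which
    algorithm the evaluation used. Intended for replication sweeps over many
    master seeds.
    """
    config = config or RunConfig()
    if master_seed is not None:
        config = dataclasses.replace(config, master_seed=master_seed)
    seeds = _resolve_seeds(config)

    spec = dataclasses.replace(config.cohort, seed=seeds["cohort"])
    cohort = cohort_mod.generate_cohort(spec)
    etas = ppk_mod.sample_etas(
        len(cohort), config.sampling.method, seeds["etas"], config.ppk, config.sampling.hmc
    )
    cohort = ppk_mod.simulate_individual_cl(cohort, etas, config.ppk)

    plan = ml_mod.split(cohort, config.ml.split_ratio, seed=seeds["split"])
    train = cohort[cohort["id"].isin(plan.train_ids)]
    test = cohort[cohort["id"].isin(plan.test_ids)]
    reports, fitted = {}, {}
    for alg in config.ml.algorithms:
        fitted[alg] = ml_mod.fit(ml_mod.ModelSpec(alg, seed=seeds["fit"]), train)
        reports[alg] = ml_mod.evaluate_fit(fitted[alg], train, test)
    auto_selected = ml_mod.select_model(reports)
    final = auto_selected if config.ml.final_model == "auto" else config.ml.final_model

    rng = np.random.default_rng(seeds["evaluate"])
    if config.evaluation.mode == "overlap":
        idx = np.sort(rng.choice(len(cohort), config.evaluation.n_eval, replace=False))
        eval_cohort = cohort.iloc[idx].reset_index(drop=True)
    else:
        hold = dataclasses.replace(config.cohort, n=config.evaluation.n_eval, seed=seeds["evaluate"])
        eval_cohort = cohort_mod.generate_cohort(hold)
        hold_etas = ppk_mod.sample_etas(
            len(eval_cohort),
            config.sampling.method,
            stage_seed(config.master_seed, "evaluate-etas"),
            config.ppk,
            config.sampling.hmc,
        )
        eval_cohort = ppk_mod.simulate_individual_cl(eval_cohort, hold_etas, config.ppk)

    comparison = eval_mod.compare(eval_cohort, fitted[final], config.ppk)
    summary = eval_mod.summarize_errors(comparison)
    return {
        "improvement_fraction": eval_mod.improvement_fraction(comparison),
        "n_improved": int(comparison["improved"].sum()),
        "n_eval": len(comparison),
        "ppk_mean_abs_err": summary.ppk.mean_abs_err,
        "ppk_mean_rel_err": summary.ppk.mean_rel_err,
        "hybrid_mean_abs_err": summary.hybrid.mean_abs_err,
        "hybrid_mean_rel_err": summary.hybrid.mean_rel_err,
        "final_model": final,
        "auto_selected": auto_selected,
    }


def run_all(config: RunConfig, output_dir=None) -> RunArtifacts:
    """Execute simulate → learn → evaluate and write all artifacts."""
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(exist_ok=True)

    log_file = out / "run.log"
    handler = logging.FileHandler(log_file, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    seeds = _resolve_seeds(config)
    manifest: dict = {"master_seed": config.master_seed, "stage_seeds": seeds, "stages": {}}
    t_start = time.time()
    try:
        # -- stage 1: simulate ------------------------------------------------
        t0 = time.time()
        spec = dataclasses.replace(config.cohort, seed=seeds["cohort"])
        cohort = cohort_mod.generate_cohort(spec)
        etas = ppk_mod.sample_etas(
            len(cohort),
            method=config.sampling.method,
            seed=seeds["etas"],
            params=config.ppk,
            hmc_opts=config.sampling.hmc,
        )
        cohort = ppk_mod.simulate_individual_cl(cohort, etas, config.ppk)
        cohort_mod.write_cohort(cohort, out / "cohort.csv")
        etas.to_frame().to_csv(out / "etas.csv", index=False, float_format="%.17g")
        logger.info("simulate: n=%d method=%s seed=%d", len(cohort), etas.method, seeds["etas"])
        manifest["stages"]["simulate"] = {"n": len(cohort), "seconds": time.time() - t0}

        # -- stage 2: learn ---------------------------------------------------
        t0 = time.time()
        plan = ml_mod.split(cohort, config.ml.split_ratio, seed=seeds["split"])
        train = cohort[cohort["id"].isin(plan.train_ids)]
        test = cohort[cohort["id"].isin(plan.test_ids)]
        reports: dict[str, ml_mod.MetricsReport] = {}
        fitted: dict[str, ml_mod.FittedModel] = {}
        cv_rows = []
        for alg in config.ml.algorithms:
            mspec = ml_mod.ModelSpec(alg, seed=seeds["fit"])
            model = ml_mod.fit(mspec, train)
            fitted[alg] = model
            reports[alg] = ml_mod.evaluate_fit(model, train, test)
            folds, mean = ml_mod.cross_validate(mspec, cohort, config.ml.cv_folds, seeds["cv"])
            for i, m in enumerate(folds):
                cv_rows.append({"algorithm": alg, "fold": i, **dataclasses.asdict(m)})
            cv_rows.append({"algorithm": alg, "fold": "mean", **dataclasses.asdict(mean)})
        auto_selected = ml_mod.select_model(reports)
        selected = auto_selected if config.ml.final_model == "auto" else config.ml.final_model
        ml_mod.metrics_to_json(reports, out / "metrics.json")
        import pandas as pd

        pd.DataFrame(cv_rows).to_csv(out / "cv_table.csv", index=False, float_format="%.17g")
        logger.info(
            "learn: train=%d test=%d final=%s (auto pick: %s)",
            len(train), len(test), selected, auto_selected,
        )
        manifest["stages"]["learn"] = {
            "train": len(train),
            "test": len(test),
            "final_model": selected,
            "auto_selected": auto_selected,
            "seconds": time.time() - t0,
        }

        # -- stage 3: evaluate ------------------------------------------------
        t0 = time.time()
        rng = np.random.default_rng(seeds["evaluate"])
        if config.evaluation.mode == "overlap":
            idx = rng.choice(len(cohort), size=config.evaluation.n_eval, replace=False)
            eval_cohort = cohort.iloc[np.sort(idx)].reset_index(drop=True)
        else:
            hold_spec = dataclasses.replace(
                config.cohort, n=config.evaluation.n_eval, seed=seeds["evaluate"]
            )
            eval_cohort = cohort_mod.generate_cohort(hold_spec)
            hold_etas = ppk_mod.sample_etas(
                len(eval_cohort),
                method=config.sampling.method,
                seed=stage_seed(config.master_seed, "evaluate-etas"),
                params=config.ppk,
                hmc_opts=config.sampling.hmc,
            )
            eval_cohort = ppk_mod.simulate_individual_cl(eval_cohort, hold_etas, config.ppk)
        comparison = eval_mod.compare(eval_cohort, fitted[selected], config.ppk)
        comparison.to_csv(out / "comparison.csv", index=False, float_format="%.17g")
        summary = eval_mod.summarize_errors(comparison)
        eval_mod.summary_to_json(summary, out / "error_summary.json")
        figures = eval_mod.make_diagnostics(comparison, out / "figures")
        frac = eval_mod.improvement_fraction(comparison)
        logger.info(
            "evaluate: n=%d mode=%s improved=%.3f", len(comparison), config.evaluation.mode, frac
        )
        manifest["stages"]["evaluate"] = {
            "n": len(comparison),
            "mode": config.evaluation.mode,
            "improvement_fraction": frac,
            "seconds": time.time() - t0,
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n", encoding="utf-8")
        logger.exception("pipeline failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    snapshot = out / "config_resolved.yaml"
    snapshot.write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=True), encoding="utf-8"
    )
    manifest["total_seconds"] = time.time() - t_start
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", "utf-8")

    return RunArtifacts(
        cohort_csv=str(out / "cohort.csv"),
        etas_csv=str(out / "etas.csv"),
        metrics_json=str(out / "metrics.json"),
        cv_table_csv=str(out / "cv_table.csv"),
        comparison_csv=str(out / "comparison.csv"),
        summary_json=str(out / "error_summary.json"),
        figures=figures,
        log_file=str(log_file),
        config_snapshot=str(snapshot),
        manifest_json=str(manifest_path),
        selected_algorithm=selected,
    )
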