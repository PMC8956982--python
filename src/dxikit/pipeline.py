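"""Config-driven end-to-end orchestration.

A single YAML/dict config drives simulate -> build-cohort -> fit ->
evaluate -> compare; each stage writes reusable artifacts under the output
directory plus a run manifest (config hash, seed, row counts per stage,
tool version). Unknown config keys fail validation before any work runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    OutcomeSpec,
    build_enrollee_years,
    count_outcome_specs,
    default_outcome_specs,
    split_sample,
)
from .estimation import StepwiseWLS, WeightedLeastSquares
from .evaluation import compare_models, compute_code_frequencies, evaluate_model
from .features import DesignMatrixBuilder, ModelSpec
from .synth import SimConfig, simulate, write_dataset

log = logging.getLogger("dxikit")

_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}
_TOP_KEYS = {"seed", "out_dir", "sim", "cohort", "models", "evaluate"}
_COHORT_KEYS = {"deflators", "validation_share", "include_counts"}
_MODEL_KEYS = {"name", "systems", "stepwise", "entry_p", "outcome",
               "include_modifiers", "include_scales"}
_EVAL_KEYS = {"percentile_edges", "frequency_residuals"}


class ConfigError(ValueError):
    """Invalid pipeline configuration (a user error)."""


DEFAULT_MODELS = [
    {"name": "age_sex", "systems": []},
    {"name": "hcc", "systems": ["hcc_like"]},
    {"name": "ccsr", "systems": ["ccsr_like"]},
    {"name": "dxi", "systems": ["ccsr_like", "dxi"]},
]


def load_config(source: str | Path | Mapping[str, Any]) -> dict:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            config = yaml.safe_load(handle) or {}
    else:
        config = dict(source)
    validate_config(config)
    return config


def validate_config(config: Mapping[str, Any]) -> None:
    def check(mapping: Mapping, allowed: set, where: str) -> None:
        unknown = set(mapping) - allowed
        if unknown:
            raise ConfigError(f"unknown config key(s) {sorted(unknown)} in {where}")

    check(config, _TOP_KEYS, "top level")
    check(config.get("sim", {}) or {}, _SIM_KEYS, "sim")
    check(config.get("cohort", {}) or {}, _COHORT_KEYS, "cohort")
    check(config.get("evaluate", {}) or {}, _EVAL_KEYS, "evaluate")
    for i, model in enumerate(config.get("models", []) or []):
        check(model, _MODEL_KEYS, f"models[{i}]")


def config_hash(config: Mapping[str, Any]) -> str:
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_enrollee_years(table: pd.DataFrame, path: str | Path) -> None:
    out = table.reset_index().copy()
    out["diagnosis_set"] = [";".join(codes) for codes in out["diagnosis_set"]]
    out.to_csv(path, index=False)


def read_enrollee_years(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, keep_default_na=False, na_values=[])
    table["diagnosis_set"] = [
        tuple(c for c in str(cell).split(";") if c)
        for cell in table["diagnosis_set"]
    ]
    for col in ("newborn",):
        table[col] = table[col].astype(str).str.lower().isin(("true", "1"))
    return table.set_index(["person_id", "year"])


def run_pipeline(
    config: str | Path | Mapping[str, Any],
    out_dir: Optional[str | Path] = None,
    seed: Optional[int] = None,
) -> dict:
    """Execute the full pipeline; returns artifact paths plus the manifest."""
    config = load_config(config)
    if seed is not None:
        config["seed"] = int(seed)
    out = Path(out_dir or config.get("out_dir") or "dxikit_run")
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "dxikit",
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": int(config.get("seed", 0)),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    # -- simulate -------------------------------------------------------
    sim_kwargs = dict(config.get("sim", {}) or {})
    if "years" in sim_kwargs:
        sim_kwargs["years"] = tuple(sim_kwargs["years"])
    sim_config = SimConfig(seed=int(config.get("seed", 0)), **sim_kwargs)
    data = simulate(sim_config)
    paths = write_dataset(data, out / "data")
    manifest["stages"]["simulate"] = {
        "n_enrollment_rows": int(len(data.enrollment)),
        "n_claim_lines": int(len(data.claims)),
    }
    log.info("simulate: %d enrollment rows, %d claim lines",
             len(data.enrollment), len(data.claims))

    # -- build cohort ---------------------------------------------------
    cohort_cfg = config.get("cohort", {}) or {}
    years = sorted(data.enrollment["year"].unique())
    deflators = {
        int(y): float(f)
        for y, f in (cohort_cfg.get("deflators") or {int(y): 1.0 for y in years}).items()
    }
    specs: list[OutcomeSpec] = default_outcome_specs()
    if cohort_cfg.get("include_counts", True):
        specs += count_outcome_specs()
    table, report = build_enrollee_years(
        data.enrollment, data.claims, specs, deflators,
        filter_rules=data.maps.default_filter_rules,
    )
    write_enrollee_years(table, out / "enrollee_years.csv")
    (out / "cohort_report.json").write_text(
        json.dumps(report, indent=1), encoding="utf-8"
    )
    share = float(cohort_cfg.get("validation_share", 0.10))
    development, validation = split_sample(
        table, share, seed=int(config.get("seed", 0))
    )
    manifest["stages"]["build_cohort"] = {
        "n_enrollee_years": int(len(table)),
        "n_development": int(len(development)),
        "n_validation": int(len(validation)),
        **{k: v for k, v in report.items() if isinstance(v, int)},
    }
    log.info("cohort: %d enrollee-years (%d dev / %d val)",
             len(table), len(development), len(validation))

    # -- fit and evaluate ----------------------------------------------
    eval_cfg = config.get("evaluate", {}) or {}
    frequencies = (
        compute_code_frequencies(table)
        if eval_cfg.get("frequency_residuals", True) else None
    )
    reports = []
    models_cfg = config.get("models") or DEFAULT_MODELS
    for model_cfg in models_cfg:
        name = model_cfg.get("name") or "+".join(model_cfg.get("systems", []))
        spec = ModelSpec(
            outcome=model_cfg.get("outcome", "total_topcoded"),
            systems=tuple(model_cfg.get("systems", [])),
            include_modifiers=bool(model_cfg.get("include_modifiers", False)),
            include_scales=bool(model_cfg.get("include_scales", False)),
        )
        builder = DesignMatrixBuilder(mappings=data.maps.tables, spec=spec)
        X_dev = builder.fit_transform(development)
        X_val = builder.transform(validation)
        if model_cfg.get("stepwise", False):
            est = StepwiseWLS(entry_p=float(model_cfg.get("entry_p", 1e-4)))
        else:
            est = WeightedLeastSquares()
        est.fit(X_dev)
        fitted = est.result()
        fitted.to_json(out / f"model_{name}.json")
        report = evaluate_model(
            fitted,
            X_val,
            model_id=name,
            percentile_edges=tuple(
                eval_cfg.get("percentile_edges", (50, 75, 90, 95, 99))
            ),
            frequencies=frequencies,
            diagnosis_sets=validation["diagnosis_set"].to_list(),
        )
        (out / f"evaluation_{name}.json").write_text(
            report.to_json(), encoding="utf-8"
        )
        if report.frequency_residuals is not None:
            report.frequency_residuals.to_csv(out / f"freq_residuals_{name}.csv")
        reports.append(report)
        manifest["stages"][f"fit_{name}"] = {
            "n_columns": len(fitted.columns),
            "weighted_r2_train": fitted.weighted_r2,
            "weighted_r2_valid": report.weighted_r2,
        }
        log.info("model %s: %d columns, train R2=%.4f valid R2=%.4f",
                 name, len(fitted.columns), fitted.weighted_r2, report.weighted_r2)

    comparison = compare_models(reports)
    comparison.to_csv(out / "comparison.csv")
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=float), encoding="utf-8"
    )
    return {"out_dir": out, "manifest": manifest, "comparison": comparison,
            "paths": paths}
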