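"""Pipeline orchestration, result tables and run metadata.

``run_pipeline`` drives the four stages — reformulate, build-scenarios,
estimate-impact, report — over synthetic inputs, writing paper-shaped
output tables (stratum intake table, per-cause impact tables, a summary
table) and a run manifest (seed, config hash, stage list, row counts).
``render_summary`` and ``render_cause_table`` are the standalone
formatters for scenario results.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .core import (
    CAUSES,
    STUDY_SCENARIOS,
    ScenarioDefinition,
    load_parameters,
)
from .cra import ScenarioResult, monte_carlo_ui
from .intake import (
    assemble_scenario_table,
    build_proportional_scenario,
    build_reformulation_scenario,
    estimate_usual_distribution,
)
from .reformulation import aggregate_profiles, cap_to_targets, daily_sodium
from .synthetic import (
    SyntheticConfig,
    generate_demography,
    generate_food_supply,
    generate_recalls,
)

logger = logging.getLogger(__name__)

STAGES = ("reformulate", "build-scenarios", "estimate-impact", "report")


class PipelineError(RuntimeError):
    """A stage failed; the message names the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


class PipelineConfig(BaseModel):
    """End-to-end run configuration (synthetic mode)."""

    seed: int = 0
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    scenario_targets: dict[str, float] = Field(
        default_factory=lambda: {"A": 2300.0, "B": 2000.0, "C": 1500.0})
    iterations: int = Field(default=10_000, ge=2)
    parameter_path: str | None = None
    population_baseline_mean: float | None = None
    exposure_form: str = "normal"

    def model_post_init(self, __context):
        # one seed drives everything; the synthetic block inherits it
        self.synthetic = self.synthetic.model_copy(update={"seed": self.seed})


def percent_one_decimal(x: float) -> float:
    """Round half-up to one decimal, the convention for printed percentages."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), ROUND_HALF_UP))


# --------------------------------------------------------------------------
# Renderers
# --------------------------------------------------------------------------

_SEX_LABEL = {"male": "Men", "female": "Women", "all": "Total"}


def render_summary(results: list[ScenarioResult]) -> pd.DataFrame:
    """Sex x scenario summary: deaths averted (95% UI) and % of reference
    CVD deaths to one decimal."""
    if not results:
        raise ValueError("at least one scenario result required")
    rows = []
    for sex_key in ("male", "female", "all"):
        row: dict = {"sex": _SEX_LABEL[sex_key]}
        for res in results:
            gtype = "total" if sex_key == "all" else "sex"
            gname = "all" if sex_key == "all" else sex_key
            averted = res.averted(gtype, gname)
            row[f"{res.scenario}_deaths_averted"] = averted
            try:
                lo, hi = res.ui(gtype, gname)
                row[f"{res.scenario}_ui_low"] = lo
                row[f"{res.scenario}_ui_high"] = hi
            except ValueError:
                pass
            row[f"{res.scenario}_pct"] = percent_one_decimal(
                averted / res.reference_deaths * 100.0 if res.reference_deaths else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def render_cause_table(result: ScenarioResult) -> pd.DataFrame:
    """Per-cause impact table for one scenario, shaped like the published
    cause-of-death tables: totals, per-cause rows, under-75 subtotal, for
    all/men/women, with UIs when present."""
    has_ui = "ui_low" in result.summary.columns

    def block(gtype: str, gname: str) -> dict:
        out = {"deaths_averted": result.averted(gtype, gname)}
        if has_ui:
            out["ui_low"], out["ui_high"] = result.ui(gtype, gname)
        return out

    rows = []
    total = result.total_averted

    # total row
    row = {"row": "Cardiovascular diseases"}
    for sex_key, (gt, gn) in {
        "total": ("total", "all"), "male": ("sex", "male"), "female": ("sex", "female"),
    }.items():
        b = block(gt, gn)
        row[f"{sex_key}_n"] = b["deaths_averted"]
        if has_ui:
            row[f"{sex_key}_ui_low"], row[f"{sex_key}_ui_high"] = b["ui_low"], b["ui_high"]
        row[f"{sex_key}_pct"] = 100.0
    rows.append(row)

    sex_totals = {s: result.averted("sex", s) for s in ("male", "female")}
    for cause, label in CAUSES.items():
        if cause not in set(result.cells["cause"]):
            continue
        row = {"row": f"{label} ({cause})"}
        for sex_key in ("total", "male", "female"):
            if sex_key == "total":
                gt, gn, denom = "cause", cause, total
            else:
                gt, gn, denom = "cause_sex", f"{cause}|{sex_key}", sex_totals[sex_key]
            b = block(gt, gn)
            row[f"{sex_key}_n"] = b["deaths_averted"]
            if has_ui:
                row[f"{sex_key}_ui_low"], row[f"{sex_key}_ui_high"] = b["ui_low"], b["ui_high"]
            row[f"{sex_key}_pct"] = (
                percent_one_decimal(b["deaths_averted"] / denom * 100.0) if denom else 0.0
            )
        rows.append(row)

    row = {"row": "Total deaths prevented under age 75"}
    for sex_key in ("total", "male", "female"):
        gn = "all" if sex_key == "total" else sex_key
        denom = total if sex_key == "total" else sex_totals[sex_key]
        b = block("under75", gn)
        row[f"{sex_key}_n"] = b["deaths_averted"]
        if has_ui:
            row[f"{sex_key}_ui_low"], row[f"{sex_key}_ui_high"] = b["ui_low"], b["ui_high"]
        row[f"{sex_key}_pct"] = (
            percent_one_decimal(b["deaths_averted"] / denom * 100.0) if denom else 0.0
        )
    rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Manifest
# --------------------------------------------------------------------------

def _sha256_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def write_manifest(
    out_dir: Path,
    config: PipelineConfig,
    stages: list[dict],
    input_hashes: dict[str, str],
    started: str,
    finished: str,
) -> Path:
    manifest = {
        "tool_version": __version__,
        "config_hash": _sha256_bytes(
            json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
        ),
        "input_hashes": input_hashes,
        "seed": config.seed,
        "iterations": config.iterations,
        "started": started,
        "finished": finished,
        "stages": stages,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return path


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run reformulate -> build-scenarios -> estimate-impact -> report on
    synthetic inputs and write result tables plus a manifest to ``out_dir``.

    Returns a dict with the in-memory artefacts: ``scenario_table`` (long
    stratum intake table), ``results`` ({scenario: ScenarioResult}) and
    ``summary``.  A stage failure raises :class:`PipelineError` naming the
    stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = _dt.datetime.now(_dt.timezone.utc).isoformat()
    stages: list[dict] = []
    input_hashes: dict[str, str] = {}

    # ---- stage 1: reformulate -------------------------------------------
    try:
        rng = np.random.default_rng(config.seed)
        products, targets, match_map, generic = generate_food_supply(
            config.synthetic, rng)
        capped = cap_to_targets(products, targets)
        profiles_base = aggregate_profiles(products, match_map, generic)
        profiles_capped = aggregate_profiles(capped, match_map, generic)
        products.to_csv(out / "products.csv", index=False)
        capped.to_csv(out / "products_capped.csv", index=False)
        profiles_capped.to_csv(out / "profiles_capped.csv", index=False)
        stages.append({"stage": "reformulate", "n_products": len(products),
                       "n_capped": int(capped["capped"].sum())})
    except Exception as exc:  # noqa: BLE001 - stage contract names the stage
        raise PipelineError("reformulate", exc) from exc

    # ---- stage 2: build-scenarios ---------------------------------------
    try:
        respondents, items, _truth = generate_recalls(config.synthetic,
                                                      profiles_base, rng)
        days_base = daily_sodium(items, profiles_base)
        baseline = estimate_usual_distribution(days_base, respondents)
        scen_tables: dict[str, pd.DataFrame] = {}
        for name, target in config.scenario_targets.items():
            if name == "A":
                scen_tables[name] = build_reformulation_scenario(
                    items, profiles_capped, respondents)
            else:
                scen_tables[name] = build_proportional_scenario(
                    baseline, target,
                    population_baseline_mean=config.population_baseline_mean)
        scenario_table = assemble_scenario_table(baseline, scen_tables)
        scenario_table.to_csv(out / "intake_scenarios.csv", index=False)
        stages.append({"stage": "build-scenarios",
                       "n_respondents": len(respondents),
                       "n_recall_days": int(len(days_base)),
                       "scenarios": sorted(scen_tables)})
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("build-scenarios", exc) from exc

    # ---- stage 3: estimate-impact ---------------------------------------
    try:
        params = load_parameters(config.parameter_path)
        mortality = generate_demography(config.synthetic)
        mortality.to_csv(out / "mortality.csv", index=False)
        adult = baseline[baseline["age_group"] != "1-18"]
        results: dict[str, ScenarioResult] = {}
        for name, tab in scen_tables.items():
            results[name] = monte_carlo_ui(
                mortality, adult, tab[tab["age_group"] != "1-18"], params,
                iterations=config.iterations, seed=config.seed,
                scenario=name, form=config.exposure_form)
        stages.append({"stage": "estimate-impact",
                       "n_mortality_cells": len(mortality),
                       "iterations": config.iterations})
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("estimate-impact", exc) from exc

    # ---- stage 4: report -------------------------------------------------
    try:
        ordered = [results[k] for k in sorted(results)]
        summary = render_summary(ordered)
        summary.to_csv(out / "summary.csv", index=False)
        for name, res in results.items():
            render_cause_table(res).to_csv(
                out / f"impact_scenario_{name}.csv", index=False)
        for f in ("products.csv", "mortality.csv", "intake_scenarios.csv"):
            input_hashes[f] = _sha256_bytes((out / f).read_bytes())
        finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
        write_manifest(out, config, stages + [{"stage": "report"}],
                       input_hashes, started, finished)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("report", exc) from exc

    logger.info("pipeline complete: %d stages, outputs in %s", len(STAGES), out)
    return {"scenario_table": scenario_table, "results": results,
            "summary": summary, "baseline": baseline, "mortality": mortality}
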