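"""End-to-end orchestration: simulate or ingest endpoints, budget, test, fit.

``run`` takes a :class:`RunConfig` and produces a :class:`RunReport`:

* ``simulate`` — generate a seeded synthetic bioassay and write the
  endpoint and latent-truth tables;
* ``analyze`` — validate an endpoint CSV, compute per-replicate carbon
  budgets and per-condition mean ± SE summaries, run the
  assumption-driven statistics per response variable and leachate, and fit
  the LL.2 dose-response with its lack-of-fit test;
* ``full`` — simulate then analyze in one run.

Reports are written as deterministic JSON (sorted keys, no timestamps)
plus CSVs, so identical configs yield byte-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .budget import (
    BACTERIAL_COLUMNS,
    ENDPOINT_COLUMNS,
    BudgetConstants,
    budget_table,
    summarize_budgets,
)
from .simulate import ExperimentDesign, SimulatedDataset, generate
from .stats import (
    DoseResponseFit,
    StatsError,
    TestReport,
    fit_ll2,
    lack_of_fit,
    select_and_run,
)

__all__ = [
    "EndpointValidationError",
    "RunConfig",
    "run",
    "validate_endpoints",
    "load_config",
]

log = logging.getLogger("leachflux")

#: Response variables the statistics stage analyses, mapped to budget columns.
RESPONSE_VARIABLES = {
    "growth_rate": "growth_rate",
    "c_assimilation": "c_assimilation",
    "pcu": "pcu",
    "bacterial_abundance": "bact_final_cells_ml",
}


class EndpointValidationError(ValueError):
    """Aggregated, row-addressed schema violations in an endpoint table."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__(
            "endpoint table failed validation:\n" + "\n".join(errors)
        )


@dataclass(frozen=True)
class RunConfig:
    """One pipeline invocation.

    ``design_overrides`` patches :class:`ExperimentDesign` fields,
    ``constants_overrides`` patches :class:`BudgetConstants` fields; both
    are type-checked by the respective dataclasses.
    """

    mode: str = "full"
    input_csv: str | None = None
    out_dir: str = "leachflux_out"
    alpha: float = 0.05
    seed: int = 0
    noise: bool = True
    design_overrides: dict = field(default_factory=dict)
    constants_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.mode == "analyze" and not self.input_csv:
            raise ValueError("analyze mode requires input_csv")

    def design(self) -> ExperimentDesign:
        overrides = dict(self.design_overrides)
        overrides.setdefault("seed", self.seed)
        return ExperimentDesign(**overrides)

    def constants(self) -> BudgetConstants:
        return BudgetConstants().with_overrides(**self.constants_overrides)


def load_config(path) -> RunConfig:
    """Read a RunConfig from YAML; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_endpoints(source) -> pd.DataFrame:
    """Validate an endpoint CSV (path or DataFrame) into a typed table.

    Errors are aggregated and row-addressed; dilution-0 rows are tagged as
    the control treatment.
    """
    frame = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    errors: list[str] = []
    missing = [c for c in ENDPOINT_COLUMNS if c not in frame.columns]
    if missing:
        raise EndpointValidationError([f"missing required column(s): {missing}"])

    numeric = [
        "dilution_pct",
        "c_initial_cells_ml",
        "c_final_cells_ml",
        "esd_um",
        "duration_h",
        "temperature_c",
        "doc_ug_ml",
    ] + [c for c in BACTERIAL_COLUMNS if c in frame.columns]
    for col in numeric:
        frame[col] = pd.to_numeric(frame[col], errors="coerce")

    for idx, row in frame.iterrows():
        where = f"row {idx}"
        for col in numeric:
            if col in BACTERIAL_COLUMNS and pd.isna(row[col]):
                continue  # bacterial data optional
            if pd.isna(row[col]):
                errors.append(f"{where}: {col} is missing or non-numeric")
        if pd.notna(row["c_initial_cells_ml"]) and row["c_initial_cells_ml"] <= 0:
            errors.append(f"{where}: c_initial_cells_ml must be > 0")
        if pd.notna(row["c_final_cells_ml"]) and row["c_final_cells_ml"] < 0:
            errors.append(f"{where}: c_final_cells_ml must be >= 0")
        for col in BACTERIAL_COLUMNS:
            if col in frame.columns and pd.notna(row[col]) and row[col] < 0:
                errors.append(f"{where}: {col} must be >= 0")
        if pd.notna(row["doc_ug_ml"]) and row["doc_ug_ml"] <= 0:
            errors.append(f"{where}: doc_ug_ml must be > 0")

    key = ["experiment_id", "treatment", "dilution_pct", "replicate"]
    dupes = frame[frame.duplicated(subset=key, keep=False)]
    for label, _ in dupes.groupby(key):
        errors.append(f"duplicated endpoint key {label}")

    if errors:
        raise EndpointValidationError(errors)

    frame.loc[frame["dilution_pct"] == 0, "treatment"] = "control"
    return frame


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None  # strict JSON has no Infinity/NaN
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _test_report_dict(report: TestReport) -> dict:
    d = _jsonable(report)
    d["posthoc"] = [_jsonable(c) for c in report.posthoc]
    return d


def _fit_dict(fit: DoseResponseFit, lof: tuple[float, float] | None) -> dict:
    d = {
        "slope_b": fit.slope_b,
        "midpoint_e": fit.midpoint_e,
        "residual_ss": fit.residual_ss,
        "converged": fit.converged,
        "norm_min": fit.norm_min,
        "norm_max": fit.norm_max,
    }
    if lof is not None:
        d["lof_f"], d["lof_p"] = lof
    return d


def _leachate_subtable(budgets: pd.DataFrame, treatment: str, column: str) -> pd.DataFrame:
    """Control + one leachate's dilution series as a TreatmentTable."""
    mask = (budgets["treatment"] == treatment) | (budgets["dilution_pct"] == 0)
    sub = budgets.loc[mask, ["treatment", "dilution_pct", "replicate", column]]
    return sub.rename(columns={column: "response"})


def _analyze(
    endpoints: pd.DataFrame, config: RunConfig
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    constants = config.constants()
    merged = budget_table(endpoints, constants)
    if "bact_final_cells_ml" in endpoints.columns:
        merged = merged.merge(
            endpoints[
                ["experiment_id", "treatment", "dilution_pct", "replicate"]
                + [c for c in BACTERIAL_COLUMNS if c in endpoints.columns]
            ],
            on=["experiment_id", "treatment", "dilution_pct", "replicate"],
            how="left",
        )
    summary = summarize_budgets(merged)

    leachates = sorted(
        t for t in endpoints["treatment"].unique() if t != "control"
    )
    stats_section: dict = {}
    fits_section: dict = {}
    for treatment in leachates:
        stats_section[treatment] = {}
        for name, column in RESPONSE_VARIABLES.items():
            if column not in merged.columns:
                continue
            table = _leachate_subtable(merged, treatment, column)
            try:
                report = select_and_run(table, config.alpha)
            except StatsError as err:
                log.warning("stats[%s/%s]: %s", treatment, name, err)
                stats_section[treatment][name] = {"error": str(err)}
                continue
            log.info(
                "stats[%s/%s]: branch=%s omnibus_p=%.4g",
                treatment, name, report.branch, report.omnibus_p,
            )
            stats_section[treatment][name] = _test_report_dict(report)

        growth = _leachate_subtable(merged, treatment, "growth_rate")
        try:
            fit = fit_ll2(
                growth["dilution_pct"].to_numpy(float),
                growth["response"].to_numpy(float),
            )
            if not fit.converged:
                log.warning("fit[%s]: LL.2 optimizer did not converge", treatment)
            try:
                lof = lack_of_fit(fit, growth)
            except StatsError as err:
                log.warning("fit[%s]: lack-of-fit unavailable: %s", treatment, err)
                lof = None
            fits_section[treatment] = _fit_dict(fit, lof)
        except StatsError as err:
            log.warning("fit[%s]: %s", treatment, err)
            fits_section[treatment] = {"error": str(err)}

    report = {
        "budget_summary": summary.to_dict(orient="records"),
        "statistics": stats_section,
        "dose_response": fits_section,
    }
    return report, merged, summary


def run(config: RunConfig) -> dict:
    """Execute one pipeline run and write its artifacts to ``out_dir``.

    Returns the report dict (also written to ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_blob = json.dumps(_jsonable(dataclasses.asdict(config)), sort_keys=True)
    provenance = {
        "config": json.loads(config_blob),
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "seed": config.seed,
        "leachflux_version": __version__,
    }
    report: dict = {"provenance": provenance}

    dataset: SimulatedDataset | None = None
    if config.mode in ("simulate", "full"):
        dataset = generate(config.design(), noise=config.noise)
        dataset.endpoints.to_csv(out / "endpoints.csv", index=False)
        dataset.latent.to_csv(out / "latent_truth.csv", index=False)
        report["simulation"] = {
            "n_rows": int(len(dataset.endpoints)),
            "design": _jsonable(dataclasses.asdict(dataset.design)),
            "noise": config.noise,
        }

    if config.mode in ("analyze", "full"):
        if config.mode == "analyze":
            endpoints = validate_endpoints(config.input_csv)
        else:
            endpoints = validate_endpoints(dataset.endpoints)
        analysis, budgets, summary = _analyze(endpoints, config)
        report.update(analysis)
        budgets.to_csv(out / "budgets.csv", index=False)
        summary.to_csv(out / "budget_summary.csv", index=False)

    (out / "report.json").write_text(
        json.dumps(_jsonable(report), sort_keys=True, indent=2) + "\n"
    )
    return report
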