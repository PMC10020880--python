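"""End-to-end pipeline: cohort -> out-of-fold risks -> validation -> policy tables.

`run_pipeline` executes the full analysis on a CSV cohort or a synthetic one:
fits the requested risk models, produces k-fold out-of-fold risks, evaluates
discrimination and calibration, runs the interval-assignment decision
analysis, and writes model-performance ("table2"), Lung-RADS comparator
("table3"), delay-target and tradeoff-curve CSVs plus fitted-model JSON and a
run log.  Identical config and seeds give byte-identical CSVs; every output
names the config hash and seed on its first line.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from contextlib import contextmanager
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import decision, evaluation, recalibration
from .data_model import Cohort, LungRadsCategory, read_cohort, write_cohort
from .errors import LungIntervalError
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline"]

ModelKind = Literal["recalibrated", "recalibrated_slope", "combined", "comparator"]


class RunConfig(BaseModel):
    """Configuration of one pipeline run.

    Exactly one of ``input_csv`` and ``synthetic`` supplies the cohort.
    ``model_kinds`` may include "comparator", which uses the precomputed
    comparator risks carried in the data instead of fitting anything.
    ``n_boot`` of 0 skips the optimism adjustment.
    """

    input_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    model_kinds: list[ModelKind] = Field(default_factory=lambda: ["recalibrated"])
    k: int = 8
    cv_unit: Literal["screen", "person"] = "screen"
    seed: int = 0
    n_boot: int = 0
    target_fractions: list[float] = Field(default_factory=lambda: [0.66, 0.80, 0.90])
    delay_fractions: list[float] = Field(default_factory=lambda: [0.05, 0.10, 0.20, 0.35])
    lungrads_table: bool = True
    one_screen_only: bool = False
    lungrads2_only: bool = False
    save_cohort: bool = False
    output_dir: str = "results"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_csv and synthetic must be set")
        for f in self.target_fractions + self.delay_fractions:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fractions must lie in [0, 1]; got {f}")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.model_validate(data)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (where outputs go is excluded)."""
        payload = self.model_dump(exclude={"output_dir"})
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


@contextmanager
def _stage(name: str):
    try:
        yield
    except LungIntervalError as exc:
        raise type(exc)(f"stage '{name}': {exc}") from exc
    except Exception as exc:
        raise LungIntervalError(f"stage '{name}': {exc}") from exc


def _fmt(x: float, digits: int) -> float | str:
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else round(float(x), digits)


def _write_csv(frame: pd.DataFrame, path: Path, header_line: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(header_line + "\n")
        frame.to_csv(fh, index=False)


def _risks_for(cohort: Cohort, kind: str, k: int, unit: str, seed: int) -> np.ndarray:
    if kind == "comparator":
        risks = cohort.comparator_risks
        if np.isnan(risks).any():
            raise LungIntervalError("comparator model requested but comparator_risk is missing")
        return risks
    folds = recalibration.make_folds(cohort, k=k, unit=unit, seed=seed)
    return recalibration.crossval_risks(cohort, folds, model_kind=kind)


def _fit_full(cohort: Cohort, kind: str):
    if kind == "recalibrated":
        return recalibration.fit_recalibration(cohort, slope_free=False)
    if kind == "recalibrated_slope":
        return recalibration.fit_recalibration(cohort, slope_free=True)
    if kind == "combined":
        return recalibration.fit_combined(cohort)
    return None  # comparator: nothing to fit


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the report bundle (also written to
    ``config.output_dir``)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stamp = f"# config={chash} seed={config.seed}"

    with _stage("load-cohort"):
        if config.input_csv is not None:
            cohort = read_cohort(config.input_csv)
        else:
            cohort = generate_cohort(config.synthetic)
    with _stage("restrict"):
        if config.one_screen_only:
            cohort = decision.one_screen_per_person(cohort, seed=config.seed)
        if config.lungrads2_only:
            cohort = decision.restrict_lungrads2(cohort)
    if config.save_cohort:
        write_cohort(cohort, out / "cohort.csv")

    bundle: dict = {"config_hash": chash, "n_screens": len(cohort), "n_cancers": cohort.n_cases}
    outcomes = cohort.outcomes

    models: dict[str, object] = {}
    risks: dict[str, np.ndarray] = {}
    with _stage("crossval-risks"):
        for kind in config.model_kinds:
            risks[kind] = _risks_for(cohort, kind, config.k, config.cv_unit, config.seed)
            models[kind] = _fit_full(cohort, kind)

    table2_rows = []
    assignments: dict[str, dict[float, decision.AssignmentResult]] = {}
    with _stage("evaluation"):
        for kind in config.model_kinds:
            r = risks[kind]
            a = evaluation.auc(r, outcomes)
            adj = None
            if config.n_boot > 0 and kind != "comparator":
                fitter = lambda c, _kind=kind: _fit_full(c, _kind)
                adj = evaluation.optimism_adjusted_auc(
                    cohort, fitter, n_boot=config.n_boot, seed=config.seed
                )
            cal = evaluation.expected_observed(r, outcomes)
            row = {
                "model": kind,
                "n_screens": len(cohort),
                "n_cancers": int(outcomes.sum()),
                "auc": _fmt(a, 4),
                "optimism_adjusted_auc": _fmt(adj.auc, 4) if adj else "",
                "expected": _fmt(cal.expected, 2),
                "observed": cal.observed,
                "eo_ratio": _fmt(cal.ratio, 2),
                "eo_ci_low": _fmt(cal.ci_low, 2),
                "eo_ci_high": _fmt(cal.ci_high, 2),
            }
            table2_rows.append(row)

    with _stage("decision"):
        for kind in config.model_kinds:
            assignments[kind] = {}
            for f in config.target_fractions:
                res = decision.assign_by_fraction(risks[kind], outcomes, f)
                assignments[kind][f] = res
                pct = int(round(100 * f))
                row = next(r for r in table2_rows if r["model"] == kind)
                row[f"delayed_at_{pct}"] = f"{res.n_delayed}/{res.n_assigned}"
                row[f"risk_pct_at_{pct}"] = _fmt(res.absolute_risk, 2)

        delay_rows = []
        for kind in config.model_kinds:
            for d in config.delay_fractions:
                res = decision.fraction_assigned_at_delay(risks[kind], outcomes, d)
                delay_rows.append(
                    {
                        "model": kind,
                        "delay_fraction": d,
                        "n_assigned": res.n_assigned,
                        "n_delayed": res.n_delayed,
                        "pct_noncases_assigned": _fmt(res.pct_noncases_assigned, 1),
                        "pct_cancers_delayed": _fmt(res.pct_cancers_delayed, 1),
                        "absolute_risk_pct": _fmt(res.absolute_risk, 2),
                    }
                )

        curves = {kind: decision.tradeoff_curve(risks[kind], outcomes) for kind in config.model_kinds}

        table3_rows = []
        if config.lungrads_table:
            for cat in sorted(LungRadsCategory, key=lambda c: -c.nested_rank):
                res = decision.assign_by_lungrads(cohort, cat)
                table3_rows.append(
                    {
                        "threshold": res.label,
                        "cancers_delayed": res.n_delayed,
                        "pct_cancers_delayed": _fmt(res.pct_cancers_delayed, 1),
                        "noncases_assigned": res.n_assigned - res.n_delayed,
                        "pct_noncases_assigned": _fmt(res.pct_noncases_assigned, 1),
                        "absolute_risk_pct": _fmt(res.absolute_risk, 2),
                    }
                )

    with _stage("report"):
        table2 = pd.DataFrame(table2_rows)
        _write_csv(table2, out / "table2.csv", stamp)
        delays = pd.DataFrame(delay_rows)
        _write_csv(delays, out / "delay_targets.csv", stamp)
        for kind, curve in curves.items():
            frame = pd.DataFrame(
                {
                    "n_assigned": curve.n_assigned,
                    "pct_noncases_assigned": np.round(curve.pct_noncases_assigned, 4),
                    "pct_cancers_delayed": np.round(curve.pct_cancers_delayed, 4),
                }
            )
            _write_csv(frame, out / f"tradeoff_{kind}.csv", stamp)
        if table3_rows:
            _write_csv(pd.DataFrame(table3_rows), out / "table3.csv", stamp)

        model_json = {
            "config_hash": chash,
            "k": config.k,
            "unit": config.cv_unit,
            "seed": config.seed,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "models": {k: (m.to_dict() if m is not None else None) for k, m in models.items()},
        }
        (out / "models.json").write_text(json.dumps(model_json, indent=2))

        run_log = {
            "config": config.model_dump(),
            "config_hash": chash,
            "seed": config.seed,
            "n_screens": len(cohort),
            "n_cancers": int(outcomes.sum()),
            "timestamp": model_json["timestamp"],
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))

    bundle.update(
        {
            "table2": table2_rows,
            "table3": table3_rows,
            "delay_targets": delay_rows,
            "curves": curves,
            "models": models,
            "risks": risks,
            "assignments": assignments,
        }
    )
    return bundle
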