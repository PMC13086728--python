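"""CSV/TOML input-output, study configuration, and the end-to-end pipeline.

The pipeline mirrors a quality-by-design formulation workflow: read the
design/response table, fit a response-surface model per response (order
taken from the config or chosen by the sequential F-test ladder), run the
desirability optimization, and report coefficients, diagnostics, the optimal
formulation and — when actual measurements of the fabricated optimum are
given — percent prediction errors.
"""

from __future__ import annotations

import json
import logging
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .design import DesignTable, FactorSpec, code_factors
from .desirability import (
    DesirabilityGoal,
    OptimizationResult,
    optimize,
    prediction_error,
)
from .rsm import ORDERS, FittedModel, fit_model, select_model

__all__ = [
    "StudyConfig",
    "read_design_csv",
    "write_design_csv",
    "load_config",
    "run_pipeline",
    "PipelineReport",
]

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Validated study configuration (factors, goals, geometry, settings)."""

    factors: list[FactorSpec]
    goals: dict[str, dict] = field(default_factory=dict)
    models: dict[str, str] = field(default_factory=dict)
    geometry: dict[str, float] = field(default_factory=dict)
    alpha: float = 0.05
    seed: int = 0
    bounds: tuple[float, float] = (-1.0, 1.0)


_TOP_KEYS = {"factors", "goals", "models", "geometry", "optimizer", "alpha", "seed"}
_FACTOR_KEYS = {"name", "low", "high", "units"}
_GOAL_KEYS = {"direction", "lower", "upper", "target", "weight", "importance"}
_GEOMETRY_KEYS = {
    "area",
    "receptor_volume",
    "sample_volume",
    "donor_dose",
    "donor_volume",
    "donor_concentration",
    "dose_ug",
}
_OPTIMIZER_KEYS = {"bounds"}


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_config(path: str | Path) -> StudyConfig:
    """Parse and schema-validate a TOML study configuration."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    _check_keys(raw, _TOP_KEYS, "config")

    factors = []
    for block in raw.get("factors", []):
        _check_keys(block, _FACTOR_KEYS, f"factor {block.get('name', '?')!r}")
        factors.append(
            FactorSpec(block["name"], float(block["low"]), float(block["high"]),
                       units=block.get("units", ""))
        )
    goals = {}
    for name, block in raw.get("goals", {}).items():
        _check_keys(block, _GOAL_KEYS, f"goal {name!r}")
        goals[name] = dict(block)
    models = {}
    for name, order in raw.get("models", {}).items():
        if order not in ORDERS:
            raise ValueError(f"model order for {name!r} must be one of {ORDERS}, got {order!r}")
        models[name] = order
    geometry = dict(raw.get("geometry", {}))
    _check_keys(geometry, _GEOMETRY_KEYS, "geometry")
    optimizer = dict(raw.get("optimizer", {}))
    _check_keys(optimizer, _OPTIMIZER_KEYS, "optimizer")
    bounds = tuple(optimizer.get("bounds", (-1.0, 1.0)))

    return StudyConfig(
        factors=factors,
        goals=goals,
        models=models,
        geometry=geometry,
        alpha=float(raw.get("alpha", 0.05)),
        seed=int(raw.get("seed", 0)),
        bounds=bounds,  # type: ignore[arg-type]
    )


def read_design_csv(
    path: str | Path,
    factors: list[FactorSpec],
    response_columns: list[str] | None = None,
) -> DesignTable:
    """Read a natural-units design/response CSV into a DesignTable.

    Expects a ``run_id`` column plus one column per factor; remaining numeric
    columns are responses (``*_sd`` columns become metadata); non-numeric
    extras are ignored with a warning.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: design file is empty")
    if "run_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'run_id' column")
    df = df.set_index("run_id")

    names = [s.name for s in factors]
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing factor column(s) {missing}")

    rest = [c for c in df.columns if c not in names]
    numeric, dropped = [], []
    for col in names + rest:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad) and col in names:
            raise ValueError(f"{path}: non-numeric cell in column {col!r} at run(s) {list(bad)}")
        if len(bad):
            dropped.append(col)
        else:
            df[col] = converted
            if col in rest:
                numeric.append(col)
    if dropped:
        warnings.warn(f"ignoring non-numeric column(s) {dropped}", stacklevel=2)

    if response_columns is None:
        response_columns = [c for c in numeric if not c.endswith("_sd")]
    sd_cols = [c for c in numeric if c.endswith("_sd")]

    coded = pd.DataFrame(
        {s.name: code_factors(df[s.name].to_numpy(), s) for s in factors}, index=df.index
    )
    responses = df[response_columns] if response_columns else None
    metadata = df[sd_cols] if sd_cols else None
    logger.info("read %d runs, responses: %s", len(df), response_columns)
    return DesignTable(specs=list(factors), coded=coded, responses=responses, metadata=metadata)


def write_design_csv(table: DesignTable, path: str | Path) -> None:
    """Write the natural-units view (run_id, factors, responses) to CSV."""
    table.to_frame().to_csv(path, index=False, float_format="%.10g")


@dataclass
class PipelineReport:
    orders: dict[str, str]
    fits: dict[str, FittedModel]
    optimization: OptimizationResult
    prediction_errors: dict[str, float] | None = None

    def to_dict(self) -> dict:
        out: dict = {"models": {}, "optimum": {}}
        for name, fit in self.fits.items():
            s = fit.stats
            out["models"][name] = {
                "order": fit.order,
                "coefficients": {k: round(v, 6) for k, v in fit.coefficients.items()},
                "r2": round(s.r2, 6),
                "adj_r2": round(s.adj_r2, 6),
                "pred_r2": round(s.pred_r2, 6),
                "press": round(s.press, 6),
                "adequate_precision": round(s.adequate_precision, 6),
            }
        opt = self.optimization
        out["optimum"] = {
            "coded": [round(float(x), 6) for x in opt.coded_optimum],
            "natural": {k: round(v, 6) for k, v in opt.natural_optimum.items()},
            "predicted_responses": {k: round(v, 6) for k, v in opt.predicted_responses.items()},
            "per_response_desirability": {k: round(v, 6) for k, v in opt.per_response_d.items()},
            "composite_desirability": round(opt.composite_D, 6),
        }
        if self.prediction_errors is not None:
            out["prediction_errors_pct"] = {
                k: round(v, 4) for k, v in self.prediction_errors.items()
            }
        return out

    def to_text(self) -> str:
        lines = []
        for name, fit in self.fits.items():
            s = fit.stats
            lines.append(f"== {name} ({fit.order}) ==")
            for term, beta in fit.coefficients.items():
                lines.append(f"  {term:<12s} {beta:12.4f}")
            lines.append(
                f"  R2={s.r2:.4f}  adjR2={s.adj_r2:.4f}  predR2={s.pred_r2:.4f}  "
                f"AP={s.adequate_precision:.3f}"
            )
        opt = self.optimization
        lines.append("== optimum ==")
        nat = ", ".join(f"{k}={v:.4f}" for k, v in opt.natural_optimum.items())
        lines.append(f"  factors: {nat}")
        for k, v in opt.predicted_responses.items():
            lines.append(f"  predicted {k:<12s} {v:10.3f}  (d={opt.per_response_d[k]:.4f})")
        lines.append(f"  composite desirability D = {opt.composite_D:.4f}")
        if self.prediction_errors is not None:
            lines.append("== validation ==")
            for k, v in self.prediction_errors.items():
                lines.append(f"  {k:<12s} error {v:+.2f} %")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def run_pipeline(
    config: StudyConfig,
    design: DesignTable | str | Path,
    actuals: dict[str, float] | None = None,
) -> PipelineReport:
    """Fit all goal responses, optimize, and assemble the study report."""
    if not isinstance(design, DesignTable):
        design = read_design_csv(design, config.factors)

    goal_objs = []
    for name, block in config.goals.items():
        y = design.response(name)
        goal_objs.append(
            DesirabilityGoal(
                response_name=name,
                direction=block["direction"],
                lower=float(block.get("lower", y.min())),
                upper=float(block.get("upper", y.max())),
                target=block.get("target"),
                weight=float(block.get("weight", 1.0)),
                importance=float(block.get("importance", 1.0)),
            )
        )
    if not goal_objs:
        raise ValueError("config defines no goals")

    orders, fits = {}, {}
    for goal in goal_objs:
        name = goal.response_name
        order = config.models.get(name) or select_model(design, name, alpha=config.alpha)
        orders[name] = order
        fits[name] = fit_model(design, name, order)
        logger.info("fitted %s as %s (R2=%.4f)", name, order, fits[name].stats.r2)

    result = optimize(list(fits.values()), goal_objs, bounds=config.bounds, specs=config.factors)

    errors = None
    if actuals is not None:
        errors = {
            name: prediction_error(actuals[name], result.predicted_responses[name])
            for name in actuals
            if name in result.predicted_responses
        }
    return PipelineReport(orders=orders, fits=fits, optimization=result, prediction_errors=errors)
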