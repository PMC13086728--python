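"""Bundled study data: a dapoxetine-loaded PLGA nanoparticle formulation study.

The packaged tables come from a published quality-by-design study of
dapoxetine hydrochloride PLGA nanoparticles for intranasal delivery:

* ``load_formulation_study`` — the 15-run, 3-factor Box-Behnken design
  (PLGA amount 25-75 mg, PVA concentration 1-2 % w/v, internal aqueous
  volume 0.5-1 ml) with its four measured responses: entrapment efficiency
  (EE_pct, %), particle size (size_nm, nm), 8-h cumulative release
  (Q8h_pct, %) and 24-h cumulative permeation (Q24_ug_cm2, ug/cm^2).
  Per-run SDs of the triplicate measurements ride along as metadata.
* ``load_permeation_parameters`` — the reported Franz-cell parameters (lag
  time, Jss, Kp, enhancement index) for each run and the control drug
  solution. The flux value of run P15 was reconstructed from its printed
  Kp (0.0301 cm/h at 1 mg/ml donor concentration); the source row is
  corrupt.
* ``load_optimal_validation`` — actual vs model-predicted responses of the
  fabricated optimal formulation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .design import DesignTable, FactorSpec, code_factors
from .desirability import DesirabilityGoal

__all__ = [
    "factor_specs",
    "load_formulation_study",
    "response_goals",
    "default_model_orders",
    "load_permeation_parameters",
    "load_optimal_validation",
    "RESPONSES",
]

RESPONSES = ["EE_pct", "size_nm", "Q8h_pct", "Q24_ug_cm2"]

_GOAL_DIRECTIONS = {
    "EE_pct": "maximize",
    "size_nm": "minimize",
    "Q8h_pct": "maximize",
    "Q24_ug_cm2": "maximize",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("qbd.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def factor_specs() -> list[FactorSpec]:
    """The study's three formulation factors and their low/high levels."""
    return [
        FactorSpec("PLGA", 25.0, 75.0, units="mg"),
        FactorSpec("PVA", 1.0, 2.0, units="% w/v"),
        FactorSpec("Vaq", 0.5, 1.0, units="ml"),
    ]


def load_formulation_study() -> DesignTable:
    """The 15-run Box-Behnken design with measured responses."""
    df = _read("formulation_bbd.csv").set_index("run_id")
    specs = factor_specs()
    coded = pd.DataFrame(
        {s.name: code_factors(df[s.name].to_numpy(), s) for s in specs}, index=df.index
    )
    responses = df[RESPONSES]
    metadata = df[[f"{r}_sd" for r in RESPONSES]]
    return DesignTable(specs=specs, coded=coded, responses=responses, metadata=metadata)


def response_goals(table: DesignTable | None = None) -> list[DesirabilityGoal]:
    """The study's optimization goals: maximize EE, Q8h, Q24; minimize size.

    Ramp bounds default to the observed response range in ``table``
    (the bundled study if omitted), the standard DoE-software convention.
    """
    if table is None:
        table = load_formulation_study()
    goals = []
    for name, direction in _GOAL_DIRECTIONS.items():
        y = table.response(name)
        goals.append(
            DesirabilityGoal(name, direction, lower=float(y.min()), upper=float(y.max()))
        )
    return goals


def default_model_orders() -> dict[str, str]:
    """Per-response polynomial orders used by the study's analysis."""
    return {
        "EE_pct": "quadratic",
        "size_nm": "linear",
        "Q8h_pct": "quadratic",
        "Q24_ug_cm2": "linear",
    }


def load_permeation_parameters() -> pd.DataFrame:
    """Reported Franz-cell permeation parameters per run plus control."""
    return _read("permeation_parameters.csv").set_index("formulation")


def load_optimal_validation() -> pd.DataFrame:
    """Actual vs predicted responses of the fabricated optimal formulation."""
    return _read("optimal_validation.csv").set_index("response")
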