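"""Box-Behnken designs and natural/coded factor conversion.

A three-level Box-Behnken design (BBD) for k factors places runs at the
midpoints of the edges of the factor cube: for every pair of factors all
four (+/-1, +/-1) combinations are run with the remaining factors at their
center (coded 0), plus replicated center points. For k = 3 this gives
12 edge runs + n_center centers. Main-effect columns are balanced
(sum to zero) and mutually orthogonal, which is what makes the coded
least-squares coefficients simple orthogonal contrasts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "DesignReport",
    "code_factors",
    "decode_factors",
    "build_bbd",
    "validate_design",
]


@dataclass(frozen=True)
class FactorSpec:
    """A formulation factor with its low/high natural levels.

    The coded scale maps ``low -> -1``, ``center -> 0``, ``high -> +1``
    by the affine transform ``coded = (natural - center) / half_range``.
    """

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError(f"factor {self.name!r}: levels must be finite")
        if not self.low < self.high:
            raise ValueError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    @property
    def center(self) -> float:
        return (self.low + self.high) / 2.0

    @property
    def half_range(self) -> float:
        return (self.high - self.low) / 2.0


def code_factors(natural_value, spec: FactorSpec):
    """Convert natural factor value(s) to the coded -1..+1 scale."""
    x = np.asarray(natural_value, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"factor {spec.name!r}: non-finite natural value {natural_value!r}")
    coded = (x - spec.center) / spec.half_range
    return float(coded) if coded.ndim == 0 else coded


def decode_factors(coded_value, spec: FactorSpec):
    """Exact inverse of :func:`code_factors`."""
    x = np.asarray(coded_value, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"factor {spec.name!r}: non-finite coded value {coded_value!r}")
    natural = x * spec.half_range + spec.center
    return float(natural) if natural.ndim == 0 else natural


@dataclass
class DesignTable:
    """An experimental design: runs x coded factors, plus response columns.

    ``coded`` holds the canonical factor values; natural values are derived
    through the factor specs. Response columns live in ``responses`` (one
    row per run); per-run standard deviations or other annotations can be
    carried in ``metadata`` and are never used in fitting.
    """

    specs: list[FactorSpec]
    coded: pd.DataFrame  # columns = factor names, index = run ids
    responses: pd.DataFrame | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if list(self.coded.columns) != names:
            raise ValueError(
                f"coded columns {list(self.coded.columns)} do not match factor specs {names}"
            )
        if self.responses is not None and not self.responses.index.equals(self.coded.index):
            raise ValueError("responses index does not match design runs")

    @property
    def run_ids(self) -> list[str]:
        return [str(r) for r in self.coded.index]

    @property
    def factor_names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def n_runs(self) -> int:
        return len(self.coded)

    @property
    def natural(self) -> pd.DataFrame:
        cols = {
            s.name: decode_factors(self.coded[s.name].to_numpy(), s) for s in self.specs
        }
        return pd.DataFrame(cols, index=self.coded.index)

    def response(self, name: str) -> np.ndarray:
        if self.responses is None or name not in self.responses.columns:
            have = [] if self.responses is None else list(self.responses.columns)
            raise KeyError(f"response {name!r} not in table (have {have})")
        return self.responses[name].to_numpy(dtype=float)

    def with_responses(self, responses: pd.DataFrame) -> "DesignTable":
        responses = responses.set_axis(self.coded.index, axis=0)
        return DesignTable(self.specs, self.coded.copy(), responses, self.metadata)

    def to_frame(self) -> pd.DataFrame:
        """Natural-units view with run_id, factors, responses (for CSV export)."""
        out = self.natural.copy()
        if self.responses is not None:
            out = pd.concat([out, self.responses], axis=1)
        if self.metadata is not None:
            out = pd.concat([out, self.metadata], axis=1)
        out.insert(0, "run_id", self.run_ids)
        return out.reset_index(drop=True)


def build_bbd(
    specs: list[FactorSpec],
    n_center: int = 3,
    randomize: bool = False,
    seed: int | None = None,
) -> DesignTable:
    """Construct a Box-Behnken design for the given factors.

    Edge runs iterate over factor pairs in declaration order (AB, AC, BC
    for three factors), each pair contributing the four (+/-1, +/-1)
    combinations with all other factors at 0; ``n_center`` center runs
    follow. Run order is fixed unless ``randomize`` is set.
    """
    k = len(specs)
    if k < 3:
        raise ValueError(f"a Box-Behnken design needs at least 3 factors, got {k}")
    if n_center < 1:
        raise ValueError(f"n_center must be >= 1, got {n_center}")

    rows: list[np.ndarray] = []
    for i, j in itertools.combinations(range(k), 2):
        for a, b in ((-1, -1), (1, -1), (-1, 1), (1, 1)):
            row = np.zeros(k)
            row[i], row[j] = a, b
            rows.append(row)
    rows.extend(np.zeros(k) for _ in range(n_center))
    coded = np.vstack(rows)

    if randomize:
        rng = np.random.default_rng(seed)
        coded = coded[rng.permutation(len(coded))]

    run_ids = [f"R{i + 1}" for i in range(len(coded))]
    frame = pd.DataFrame(coded, columns=[s.name for s in specs], index=run_ids)
    return DesignTable(specs=list(specs), coded=frame)


@dataclass
class DesignReport:
    """Read-only validation summary of a coded design."""

    n_runs: int
    n_center: int
    column_sums: dict[str, float]
    out_of_range: list[tuple[str, str, float]] = field(default_factory=list)
    imbalance: list[str] = field(default_factory=list)
    orthogonality_violations: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def n_violations(self) -> int:
        return len(self.out_of_range) + len(self.imbalance) + len(self.orthogonality_violations)

    @property
    def ok(self) -> bool:
        return self.n_violations == 0


def validate_design(table: DesignTable, atol: float = 1e-9) -> DesignReport:
    """Check balance, orthogonality and coded range; never mutates the table."""
    X = table.coded.to_numpy(dtype=float)
    names = table.factor_names

    center_mask = np.all(np.abs(X) <= atol, axis=1)
    sums = {name: float(X[:, i].sum()) for i, name in enumerate(names)}

    out_of_range = [
        (str(table.coded.index[r]), names[c], float(X[r, c]))
        for r, c in zip(*np.where(np.abs(X) > 1 + atol))
    ]
    imbalance = [name for name, s in sums.items() if abs(s) > atol]
    ortho = []
    for i, j in itertools.combinations(range(len(names)), 2):
        dot = float(X[:, i] @ X[:, j])
        if abs(dot) > atol:
            ortho.append((names[i], names[j], dot))

    return DesignReport(
        n_runs=len(X),
        n_center=int(center_mask.sum()),
        column_sums=sums,
        out_of_range=out_of_range,
        imbalance=imbalance,
        orthogonality_violations=ortho,
    )
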