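"""Synthetic formulation studies for parameter-recovery testing.

Emulates the data-generating processes the analysis stages assume: design
responses drawn from a known quadratic surface plus Gaussian noise, release
profiles from an exact kinetic model, and permeation profiles from a
flat-then-linear (lag, then steady-state flux) curve. All generators are
deterministic for a fixed seed. Simulated cumulative series are clipped to
their physical range and monotonized by running maximum — a simulator
artifact, never applied to measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignTable, FactorSpec, build_bbd
from .release import KINETIC_MODELS, ReleaseProfile
from .permeation import PermeationProfile
from .rsm import model_terms, term_matrix

__all__ = [
    "TrueSurface",
    "simulate_bbd_study",
    "simulate_release",
    "simulate_permeation",
]


@dataclass(frozen=True)
class TrueSurface:
    """A known response surface: coded-scale coefficients plus noise level.

    Coefficient keys use the same term names as fitted models
    ("Intercept", factor names, "A:B" interactions, "A^2" squares); missing
    terms are zero.
    """

    coefficients: dict[str, float]
    noise_sd: float = 0.0
    seed: int = 0
    response_name: str = "Y"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def evaluate(self, coded: np.ndarray, factor_names: list[str]) -> np.ndarray:
        all_terms = model_terms(factor_names, "quadratic")
        unknown = set(self.coefficients) - set(all_terms)
        if unknown:
            raise ValueError(f"surface terms {sorted(unknown)} not valid for factors {factor_names}")
        X, terms = term_matrix(coded, factor_names, "quadratic")
        beta = np.array([self.coefficients.get(t, 0.0) for t in terms])
        return X @ beta


def simulate_bbd_study(
    specs: list[FactorSpec],
    n_center: int,
    surface: TrueSurface,
) -> DesignTable:
    """Box-Behnken design with responses from ``surface`` plus seeded noise."""
    table = build_bbd(specs, n_center=n_center)
    names = table.factor_names
    mean = surface.evaluate(table.coded.to_numpy(), names)
    rng = np.random.default_rng(surface.seed)
    y = mean + rng.normal(0.0, surface.noise_sd, size=len(mean))
    responses = pd.DataFrame({surface.response_name: y}, index=table.coded.index)
    return table.with_responses(responses)


def simulate_release(
    model: str,
    rate: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ReleaseProfile:
    """Exact kinetic curve plus seeded noise, clipped to [0, 100], monotonized."""
    if model not in KINETIC_MODELS:
        raise ValueError(f"model must be one of {KINETIC_MODELS}, got {model!r}")
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.asarray(times, dtype=float)
    if model == "zero_order":
        q = rate * t
    elif model == "first_order":
        q = 100.0 * (1.0 - np.exp(-rate * t))
    else:  # higuchi
        q = rate * np.sqrt(t)
    rng = np.random.default_rng(seed)
    q = q + rng.normal(0.0, noise_sd, size=t.shape)
    q = np.maximum.accumulate(np.clip(q, 0.0, 100.0))
    return ReleaseProfile(times=t, cum_release=q)


def simulate_permeation(
    jss: float,
    lag_min: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
    **profile_kwargs,
) -> PermeationProfile:
    """Flat-then-linear permeation: Q(t) = max(0, jss * (t - lag)), noised."""
    if jss < 0:
        raise ValueError("jss must be >= 0")
    if lag_min < 0:
        raise ValueError("lag must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.asarray(times, dtype=float)
    q = np.maximum(0.0, jss * (t - lag_min / 60.0))
    rng = np.random.default_rng(seed)
    q = q + rng.normal(0.0, noise_sd, size=t.shape)
    q = np.maximum.accumulate(np.maximum(q, 0.0))
    return PermeationProfile(times=t, cum_amount_per_area=q, **profile_kwargs)
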