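"""Entrapment efficiency and in vitro release kinetics.

Release profiles (cumulative % of dose vs time) are fitted to the three
classical dissolution models on their linearizing axes:

* zero order:  Q = k0 * t            (Q vs t)
* first order: ln(100 - Q) = ln(100) - k1 * t   (percent-remaining form)
* Higuchi:     Q = kH * sqrt(t)      (Q vs sqrt(t))

Each fit is an ordinary linear regression with intercept; the winning model
is the one with the largest coefficient of determination on its own
transformed axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ReleaseProfile",
    "KineticsFit",
    "entrapment_efficiency",
    "withdrawal_corrected_concentration",
    "cumulative_percent_released",
    "fit_release_kinetics",
]

KINETIC_MODELS = ("zero_order", "first_order", "higuchi")


def entrapment_efficiency(total_drug: float, free_drug: float) -> float:
    """Percent of added drug entrapped: 100 * (total - free) / total."""
    if total_drug <= 0:
        raise ValueError(f"total drug amount must be > 0, got {total_drug}")
    if free_drug < 0 or free_drug > total_drug:
        raise ValueError(f"free drug ({free_drug}) must lie in [0, total ({total_drug})]")
    return 100.0 * (total_drug - free_drug) / total_drug


@dataclass
class ReleaseProfile:
    """Cumulative release (% of dose) at strictly increasing times (h)."""

    times: np.ndarray
    cum_release: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cum_release = np.asarray(self.cum_release, dtype=float)
        if self.times.shape != self.cum_release.shape:
            raise ValueError("times and cum_release must have equal length")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be nonnegative and strictly increasing")
        if np.any(np.diff(self.cum_release) < 0):
            warnings.warn("cumulative release series is non-monotone", stacklevel=2)


def withdrawal_corrected_concentration(
    raw_conc: np.ndarray, receptor_volume: float, sample_volume: float
) -> np.ndarray:
    """Correct measured concentrations for sampled-and-replaced medium.

    At each withdrawal, ``sample_volume`` of medium (and drug) leaves the
    vessel and is replaced by fresh medium, so later measurements understate
    the cumulative amount; the standard additive correction is
    C_n' = C_n + (V_s / V_r) * sum_{i<n} C_i.
    """
    if receptor_volume <= 0 or sample_volume <= 0:
        raise ValueError("volumes must be > 0")
    if sample_volume >= receptor_volume:
        raise ValueError("sample volume must be smaller than receptor volume")
    c = np.asarray(raw_conc, dtype=float)
    prior = np.concatenate([[0.0], np.cumsum(c)[:-1]])
    return c + (sample_volume / receptor_volume) * prior


def cumulative_percent_released(
    raw_conc: np.ndarray,
    times: np.ndarray,
    dose_ug: float,
    receptor_volume: float = 30.0,
    sample_volume: float = 3.0,
) -> ReleaseProfile:
    """Build a percent-of-dose release profile from raw concentrations (ug/ml)."""
    if dose_ug <= 0:
        raise ValueError("dose must be > 0")
    corrected = withdrawal_corrected_concentration(raw_conc, receptor_volume, sample_volume)
    percent = 100.0 * corrected * receptor_volume / dose_ug
    return ReleaseProfile(times=np.asarray(times, dtype=float), cum_release=percent)


@dataclass
class KineticsFit:
    model: str
    rate_constant: float  # %/h, 1/h, %/sqrt(h) for zero/first/Higuchi
    intercept: float
    r2: float
    best: bool = False


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_release_kinetics(profile: ReleaseProfile) -> list[KineticsFit]:
    """Fit zero-order, first-order and Higuchi models; flag the best by R^2.

    The first-order regression uses ln(100 - Q) and is skipped with a
    warning when any point has Q >= 100 (nothing left to release); a t = 0
    point with zero release is excluded from that transform.
    """
    t, q = profile.times, profile.cum_release
    if len(t) < 3:
        raise ValueError("need at least 3 time points to fit kinetics")

    fits: list[KineticsFit] = []

    slope, icept, r2 = _linfit(t, q)
    fits.append(KineticsFit("zero_order", slope, icept, r2))

    if np.any(q >= 100):
        warnings.warn("release reaches 100%; first-order fit skipped", stacklevel=2)
    else:
        keep = ~((t == 0) & (q == 0))
        slope, icept, r2 = _linfit(t[keep], np.log(100.0 - q[keep]))
        fits.append(KineticsFit("first_order", -slope, icept, r2))

    slope, icept, r2 = _linfit(np.sqrt(t), q)
    fits.append(KineticsFit("higuchi", slope, icept, r2))

    best = max(range(len(fits)), key=lambda i: fits[i].r2)
    fits[best].best = True
    return fits
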