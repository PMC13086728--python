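"""Franz-diffusion-cell permeation analytics.

From a cumulative-permeation profile (amount per unit membrane area vs time)
the steady-state flux Jss is the slope of the terminal linear regime, the
lag time is that line's x-intercept, the permeability coefficient is
Kp = Jss / C_donor, and the enhancement index is the ratio of a test
formulation's Kp to the control solution's Kp.

The donor concentration behind Kp must come from study geometry; the default
of 1 mg/ml is a documented sentinel, not a measured value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PermeationProfile",
    "PermeationParams",
    "correct_for_sampling",
    "flux_and_lag",
    "permeability_coefficient",
    "enhancement_index",
    "permeation_parameters",
    "DEFAULT_DONOR_CONCENTRATION",
]

#: Sentinel donor concentration (ug/ml) used when geometry is not supplied.
DEFAULT_DONOR_CONCENTRATION = 1000.0


@dataclass
class PermeationProfile:
    """Cumulative amount permeated per unit area (ug/cm^2) over time (h)."""

    times: np.ndarray
    cum_amount_per_area: np.ndarray
    area: float = 5.0  # cm^2
    donor_dose: float = 3000.0  # ug
    receptor_volume: float = 100.0  # ml
    sample_volume: float = 3.0  # ml

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cum_amount_per_area = np.asarray(self.cum_amount_per_area, dtype=float)
        if self.times.shape != self.cum_amount_per_area.shape:
            raise ValueError("times and amounts must have equal length")
        if self.area <= 0:
            raise ValueError("membrane area must be > 0")
        if np.any(np.diff(self.cum_amount_per_area) < -1e-9):
            raise ValueError("cumulative permeation series must be nondecreasing")


@dataclass
class PermeationParams:
    jss: float  # ug/cm^2/h
    lag_time_min: float
    kp: float  # cm/h
    ei: float | None = None  # dimensionless; None for the control itself


def correct_for_sampling(
    raw_conc,
    times,
    receptor_volume: float = 100.0,
    sample_volume: float = 3.0,
    area: float = 5.0,
    **profile_kwargs,
) -> PermeationProfile:
    """Cumulative permeated amount per area from receptor concentrations.

    Each withdrawal removes ``sample_volume`` of receptor fluid (replaced
    with fresh medium), so the cumulative amount at step n is
    V_r * C_n + V_s * sum_{i<n} C_i, divided by the diffusion area.
    """
    if receptor_volume <= 0 or sample_volume <= 0:
        raise ValueError("volumes must be > 0")
    if sample_volume >= receptor_volume:
        raise ValueError("sample volume must be smaller than receptor volume")
    c = np.asarray(raw_conc, dtype=float)
    prior = np.concatenate([[0.0], np.cumsum(c)[:-1]])
    amount = receptor_volume * c + sample_volume * prior
    return PermeationProfile(
        times=np.asarray(times, dtype=float),
        cum_amount_per_area=amount / area,
        area=area,
        receptor_volume=receptor_volume,
        sample_volume=sample_volume,
        **profile_kwargs,
    )


def _local_slopes(t: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Centred 3-point regression slope at each sample (2-point at the ends)."""
    n = len(t)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - 1), min(n, i + 2)
        res = stats.linregress(t[lo:hi], q[lo:hi])
        out[i] = res.slope
    return out


def flux_and_lag(
    profile: PermeationProfile, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Steady-state flux (ug/cm^2/h) and lag time (min).

    The steady-state window defaults to all points from the first time the
    local 3-point slope reaches 80% of the terminal 3-point slope; an
    explicit ``window`` of times overrides the rule. Jss is the regression
    slope over the window, lag time the x-intercept (-intercept/slope).
    """
    t, q = profile.times, profile.cum_amount_per_area
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
    else:
        if len(t) < 3:
            raise ValueError("need at least 3 points to locate steady state")
        slopes = _local_slopes(t, q)
        terminal = stats.linregress(t[-3:], q[-3:]).slope
        idx = np.where(slopes >= 0.8 * terminal)[0]
        start = idx[0] if len(idx) else 0
        start = min(start, len(t) - 3)  # keep >= 3 points
        mask = np.zeros(len(t), dtype=bool)
        mask[start:] = True
    if mask.sum() < 3:
        raise ValueError("fewer than 3 points in the steady-state window")

    res = stats.linregress(t[mask], q[mask])
    if res.slope <= 0:
        raise ValueError("no positive flux in the steady-state window")
    lag_h = -res.intercept / res.slope
    return float(res.slope), float(lag_h * 60.0)


def permeability_coefficient(
    jss: float,
    donor_dose: float | None = None,
    donor_volume: float | None = None,
    donor_concentration: float | None = None,
) -> float:
    """Kp = Jss / C_donor (cm/h), with C_donor in ug/ml.

    Give either ``donor_concentration`` directly or ``donor_dose`` (ug) with
    ``donor_volume`` (ml); with neither, the sentinel 1 mg/ml is used.
    """
    if donor_concentration is None:
        if donor_dose is not None and donor_volume is not None:
            if donor_volume <= 0:
                raise ValueError("donor volume must be > 0")
            donor_concentration = donor_dose / donor_volume
        else:
            donor_concentration = DEFAULT_DONOR_CONCENTRATION
    if donor_concentration <= 0:
        raise ValueError("donor concentration must be > 0")
    return jss / donor_concentration


def enhancement_index(kp_test: float, kp_control: float) -> float:
    """Ratio of the formulation's permeability coefficient to the control's."""
    if kp_control <= 0:
        raise ValueError("control permeability coefficient must be > 0")
    return kp_test / kp_control


def permeation_parameters(
    profile: PermeationProfile,
    donor_concentration: float | None = None,
    kp_control: float | None = None,
    window: tuple[float, float] | None = None,
) -> PermeationParams:
    """Full parameter set (Jss, lag, Kp and optionally EI) for one profile."""
    jss, lag = flux_and_lag(profile, window=window)
    kp = permeability_coefficient(jss, donor_concentration=donor_concentration)
    ei = enhancement_index(kp, kp_control) if kp_control is not None else None
    return PermeationParams(jss=jss, lag_time_min=lag, kp=kp, ei=ei)
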