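"""Virtual linear PAR ceptometer (AccuPAR LP-80 style).

The instrument estimates LAI from the ratio of below- to above-canopy PAR
using the LP-80's documented simplification of the Norman–Jarvis radiation
transmission model:

    LAI = [((1 - 1/(2K))·fb - 1) · ln τ] / [A · (1 - 0.47·fb)]

where τ = PAR_below / PAR_above, fb the beam fraction, K the ellipsoidal
canopy extinction coefficient for leaf-angle parameter χ at the solar
zenith angle, and A = 0.283 + 0.785·a - 0.159·a² with a the leaf PAR
absorptivity.  The forward model is the algebraic inversion of the same
equation, so forward and inverse are exact mutual inverses.

Defaults: χ = 1 (spherical leaf-angle distribution), a = 0.9, fb = 0.8
(clear-sky midday surveys), zenith 30°.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CeptometerReading",
    "ellipsoidal_extinction",
    "transmittance_from_lai",
    "lai_from_transmittance",
    "simulate_ground_survey",
]

DEFAULT_ZENITH_DEG = 30.0
DEFAULT_FB = 0.8
DEFAULT_CHI = 1.0
DEFAULT_ABSORPTIVITY = 0.9
DEFAULT_PAR_ABOVE = 1800.0  # µmol m⁻² s⁻¹, clear-sky midday


def _check_params(zenith_deg: float, fb: float, chi: float, absorptivity: float) -> None:
    if not 0 <= zenith_deg < 90:
        raise ValueError("zenith angle must be in [0, 90) degrees")
    if not 0 <= fb <= 1:
        raise ValueError("beam fraction fb must be in [0, 1]")
    if chi <= 0:
        raise ValueError("leaf angle parameter chi must be positive")
    if not 0 < absorptivity <= 1:
        raise ValueError("absorptivity must be in (0, 1]")


def ellipsoidal_extinction(zenith_deg: float, chi: float = DEFAULT_CHI) -> float:
    """Ellipsoidal canopy extinction coefficient K(χ, θ) (Campbell form)."""
    theta = np.radians(zenith_deg)
    num = np.sqrt(chi**2 + np.tan(theta) ** 2)
    den = chi + 1.744 * (chi + 1.182) ** (-0.733)
    return float(num / den)


def _lai_per_lntau(zenith_deg: float, fb: float, chi: float, absorptivity: float) -> float:
    """The (negative) factor g with LAI = g · ln τ."""
    K = ellipsoidal_extinction(zenith_deg, chi)
    A = 0.283 + 0.785 * absorptivity - 0.159 * absorptivity**2
    return ((1.0 - 1.0 / (2.0 * K)) * fb - 1.0) / (A * (1.0 - 0.47 * fb))


def transmittance_from_lai(
    lai,
    zenith_deg: float = DEFAULT_ZENITH_DEG,
    fb: float = DEFAULT_FB,
    chi: float = DEFAULT_CHI,
    absorptivity: float = DEFAULT_ABSORPTIVITY,
):
    """Canopy PAR transmittance τ for a given LAI (forward model).

    τ = 1 at LAI = 0 and decreases strictly with LAI and with path length
    (increasing zenith angle).
    """
    _check_params(zenith_deg, fb, chi, absorptivity)
    arr = np.asarray(lai, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("lai must be non-negative")
    g = _lai_per_lntau(zenith_deg, fb, chi, absorptivity)
    tau = np.exp(arr / g)  # g < 0 so tau in (0, 1]
    return float(tau) if np.isscalar(lai) else tau


def lai_from_transmittance(
    tau,
    zenith_deg: float = DEFAULT_ZENITH_DEG,
    fb: float = DEFAULT_FB,
    chi: float = DEFAULT_CHI,
    absorptivity: float = DEFAULT_ABSORPTIVITY,
):
    """Invert canopy PAR transmittance to LAI (the instrument's retrieval)."""
    _check_params(zenith_deg, fb, chi, absorptivity)
    arr = np.asarray(tau, dtype=np.float64)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("transmittance must be in (0, 1]")
    g = _lai_per_lntau(zenith_deg, fb, chi, absorptivity)
    lai = g * np.log(arr)
    return float(lai) if np.isscalar(tau) else lai


@dataclass
class CeptometerReading:
    """One above/below PAR pair with the geometry it was taken under."""

    par_above: float
    par_below: float
    zenith_deg: float = DEFAULT_ZENITH_DEG
    fb: float = DEFAULT_FB
    chi: float = DEFAULT_CHI
    absorptivity: float = DEFAULT_ABSORPTIVITY

    def __post_init__(self) -> None:
        if self.par_above <= 0:
            raise ValueError("par_above must be positive")
        if self.par_below < 0:
            raise ValueError("par_below must be non-negative")
        # 5% headroom for sensor noise pushing below-readings above incident
        if self.par_below > self.par_above * 1.05:
            raise ValueError("par_below exceeds par_above beyond noise allowance")
        _check_params(self.zenith_deg, self.fb, self.chi, self.absorptivity)

    @property
    def transmittance(self) -> float:
        """τ = below/above, clamped into (0, 1]."""
        tau = self.par_below / self.par_above
        return float(min(max(tau, 1e-9), 1.0))

    @property
    def lai(self) -> float:
        return lai_from_transmittance(
            self.transmittance, self.zenith_deg, self.fb, self.chi, self.absorptivity
        )


def simulate_ground_survey(
    true_lai_by_plot: dict[str, float],
    points_per_plot: int = 2,
    readings_per_point: int = 3,
    submeasurements_per_reading: int = 5,
    par_noise_sd_frac: float = 0.02,
    seed: int | np.random.Generator = 0,
    date: str = "",
    zenith_deg: float = DEFAULT_ZENITH_DEG,
    fb: float = DEFAULT_FB,
    chi: float = DEFAULT_CHI,
    absorptivity: float = DEFAULT_ABSORPTIVITY,
    par_above: float = DEFAULT_PAR_ABOVE,
) -> pd.DataFrame:
    """Simulate a plot-wise ceptometer survey with the field protocol.

    At each sampling point, ``readings_per_point`` averaged readings are
    taken, each itself the mean of ``submeasurements_per_reading``
    individual probe measurements (defaults 3 × 5, the field protocol).
    Each sub-measurement perturbs the below-canopy PAR with multiplicative
    Gaussian noise of relative sd ``par_noise_sd_frac`` before the LP-80
    inversion, so averaging attenuates reading variance roughly by the
    number of sub-measurements.

    Returns a long table with one row per (plot, point): columns
    ``date, plot_id, point_id, lai_cept``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    n_sub = readings_per_point * submeasurements_per_reading
    for plot_id, lai_true in true_lai_by_plot.items():
        if lai_true < 0:
            raise ValueError(f"plot {plot_id}: true LAI must be non-negative")
        tau_true = transmittance_from_lai(lai_true, zenith_deg, fb, chi, absorptivity)
        below_true = tau_true * par_above
        for point in range(points_per_plot):
            noise = rng.normal(0.0, par_noise_sd_frac, size=n_sub)
            below = np.clip(below_true * (1.0 + noise), 1e-6, par_above)
            tau = below / par_above
            lai_sub = lai_from_transmittance(tau, zenith_deg, fb, chi, absorptivity)
            # mean over 5 sub-measurements per reading, then over readings
            per_reading = lai_sub.reshape(readings_per_point, submeasurements_per_reading).mean(axis=1)
            rows.append(
                {
                    "date": date,
                    "plot_id": plot_id,
                    "point_id": point + 1,
                    "lai_cept": float(per_reading.mean()),
                }
            )
    return pd.DataFrame(rows)
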