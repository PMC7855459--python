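"""Instantaneous carbon balance Θ, its propagated error, and sink shares.

During balanced exponential growth the carbon taken up as d-glucose
(6 C per molecule) flows into exactly two measured sinks — biomass and
CO₂ — so the instantaneous carbon balance is

    Θ = (µ·ω_C/M_C + π_CO2) / (6·π_GLC)

with µ the specific growth rate (1/h), ω_C the carbon mass fraction of
dry biomass (gC/gCDW), M_C the molar mass of carbon (g/mmol) and π_GLC,
π_CO2 the specific uptake / formation rates (mmol/gCDW/h).  Θ < 1 means
carbon is missing from the measured sinks; dissolved CO₂/bicarbonate
that never reaches the off-gas detector is the usual culprit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CarbonParams


@dataclass
class CarbonBalance:
    """Θ with its carbon-equivalent sink decomposition (all mmolC/gCDW/h)."""

    theta: float
    biomass_carbon_rate: float
    co2_carbon_rate: float
    uptake_carbon_rate: float
    sd_theta: float = np.nan


def instantaneous_theta(
    mu: float, pi_glc: float, pi_co2: float, cp: CarbonParams | None = None
) -> CarbonBalance:
    """Compute Θ and the carbon-equivalent rates from specific rates.

    Raises ``ValueError`` on non-positive π_GLC (no uptake, Θ undefined).
    """
    cp = cp or CarbonParams()
    if pi_glc <= 0:
        raise ValueError("pi_glc must be > 0 for a carbon balance")
    biomass_c = mu * cp.omega_c / cp.M_c
    uptake_c = 6.0 * pi_glc
    return CarbonBalance(
        theta=(biomass_c + pi_co2) / uptake_c,
        biomass_carbon_rate=biomass_c,
        co2_carbon_rate=pi_co2,
        uptake_carbon_rate=uptake_c,
    )


def theta_partials(mu, pi_glc, pi_co2, cp: CarbonParams):
    """Analytic partial derivatives of Θ w.r.t. (µ, π_GLC, π_CO2, ω_C)."""
    u = 6.0 * pi_glc
    theta = (mu * cp.omega_c / cp.M_c + pi_co2) / u
    return (
        cp.omega_c / (cp.M_c * u),  # dΘ/dµ
        -theta / pi_glc,            # dΘ/dπ_GLC
        1.0 / u,                    # dΘ/dπ_CO2
        mu / (cp.M_c * u),          # dΘ/dω_C
    )


def propagate_theta_error(
    mu: float,
    pi_glc: float,
    pi_co2: float,
    sd_mu: float,
    sd_pi_glc: float,
    sd_pi_co2: float,
    cp: CarbonParams | None = None,
) -> float:
    """First-order (Gaussian) error propagation for Θ.

    Treats µ, π_GLC, π_CO2 and ω_C as independent — no covariance
    information is assumed — so the result is the quadrature sum of the
    four partial-derivative terms, with sd(ω_C) taken from ``cp``.
    """
    cp = cp or CarbonParams()
    d_mu, d_glc, d_co2, d_wc = theta_partials(mu, pi_glc, pi_co2, cp)
    var = (
        (d_mu * sd_mu) ** 2
        + (d_glc * sd_pi_glc) ** 2
        + (d_co2 * sd_pi_co2) ** 2
        + (d_wc * cp.sd_omega_c) ** 2
    )
    return float(np.sqrt(var))


def sink_decomposition(cb: CarbonBalance) -> tuple[float, float, float]:
    """Fractions of the uptake carbon flowing into each sink.

    Returns ``(biomass_fraction, co2_fraction, gap_fraction)`` with
    biomass + co2 = Θ and gap = 1 − Θ by construction.
    """
    bio = cb.biomass_carbon_rate / cb.uptake_carbon_rate
    co2 = cb.co2_carbon_rate / cb.uptake_carbon_rate
    return bio, co2, 1.0 - (bio + co2)
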