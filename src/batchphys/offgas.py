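"""Off-gas CO₂ balancing: total and biomass-specific CO₂ formation rates.

The total CO₂ formation rate (mol/h) follows from an inert-gas balance
over the reactor head space:

    π_CO2,tot = F·p/(R·T) · [ (100 − Φ_O2^in − Φ_CO2^in)
                              / (100 − Φ_O2^out − Φ_CO2^out)
                              · Φ_CO2^out/100  −  Φ_CO2^in/100 ]

with F the inlet air flow in m³/h at the reference state (p, T).  The
biomass-specific rate divides by the *fitted* biomass model X(t) times
the reactor volume — the model is smoother than the raw biomass points
and keeps the specific rate consistent with the fitted growth curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GasConditions, RateFit
from .fitting import model_biomass
from .phase import PhaseWindow


@dataclass
class GasBalanceResult:
    """CO₂ formation rates over the fitting window.

    ``pi_co2_tot`` is mol/h; ``pi_co2_specific`` is mmol per biomass
    unit (gCDW or mL BV) per hour; ``pi_co2_mean`` is the window-mean
    specific rate, the scalar reported alongside µ and π_GLC.
    """

    times: np.ndarray
    pi_co2_tot: np.ndarray
    pi_co2_specific: np.ndarray
    pi_co2_mean: float
    sd_pi_co2_mean: float = np.nan


def co2_formation_rate(
    gas: GasConditions, phi_o2_out, phi_co2_out
) -> np.ndarray | float:
    """Total CO₂ formation rate (mol/h) from inlet/outlet gas fractions.

    Vectorised over the outlet fractions.  Raises on a non-physical gas
    composition (outlet O₂ + CO₂ ≥ 100 vol%).
    """
    o2w = np.asarray(phi_o2_out, dtype=float)
    co2w = np.asarray(phi_co2_out, dtype=float)
    denom = 100.0 - o2w - co2w
    if np.any(denom <= 0):
        raise ValueError("outlet O2 + CO2 fractions >= 100 vol%: non-physical")
    inert_in = 100.0 - gas.phi_o2_in - gas.phi_co2_in
    bracket = inert_in / denom * co2w / 100.0 - gas.phi_co2_in / 100.0
    out = gas.molar_inflow * bracket
    return out if out.ndim else float(out)


def co2_rate_sd(
    gas: GasConditions, phi_o2_out, phi_co2_out, sd_o2, sd_co2
) -> np.ndarray:
    """First-order propagated sd of the total CO₂ rate from analyzer sds."""
    o2w = np.asarray(phi_o2_out, dtype=float)
    co2w = np.asarray(phi_co2_out, dtype=float)
    inert_in = 100.0 - gas.phi_o2_in - gas.phi_co2_in
    denom = 100.0 - o2w - co2w
    # d/dCO2w of bracket: inert_in * [1/denom + co2w/denom^2] / 100
    d_co2 = inert_in * (1.0 / denom + co2w / denom**2) / 100.0
    d_o2 = inert_in * co2w / denom**2 / 100.0
    var = (d_co2 * np.asarray(sd_co2)) ** 2 + (d_o2 * np.asarray(sd_o2)) ** 2
    return gas.molar_inflow * np.sqrt(var)


def specific_co2_rate(
    times,
    pi_co2_tot,
    fit: RateFit,
    reactor_volume: float,
    window: PhaseWindow,
    sd_pi_co2_tot=None,
) -> GasBalanceResult:
    """Biomass-specific CO₂ formation rate over the fitting window.

    specific(t) = 1000 · π_CO2,tot(t) / (X(t) · V)   [mmol/biomass/h]

    and the reported scalar is the arithmetic mean over window points.
    When per-point sds of the total rate are supplied, the sd of the
    mean is propagated assuming independent points.
    """
    if reactor_volume <= 0:
        raise ValueError("reactor volume must be > 0")
    times = np.asarray(times, dtype=float)
    tot = np.asarray(pi_co2_tot, dtype=float)
    m = (times >= window.t_start) & (times <= window.t_end)
    t_w, tot_w = times[m], tot[m]
    X = model_biomass(fit.X0, fit.mu, t_w)
    if np.any(X <= 0):
        raise ValueError("biomass model is zero inside the window")
    spec = 1000.0 * tot_w / (X * reactor_volume)

    sd_mean = np.nan
    if sd_pi_co2_tot is not None:
        sd_tot_w = np.asarray(sd_pi_co2_tot, dtype=float)[m]
        sd_spec = 1000.0 * sd_tot_w / (X * reactor_volume)
        sd_mean = float(np.sqrt(np.sum(sd_spec**2)) / len(sd_spec))

    return GasBalanceResult(
        times=t_w,
        pi_co2_tot=tot_w,
        pi_co2_specific=spec,
        pi_co2_mean=float(spec.mean()),
        sd_pi_co2_mean=sd_mean,
    )


def balance_offgas(ds, fit: RateFit, window: PhaseWindow) -> GasBalanceResult:
    """Convenience wrapper: Eq-style gas balance over a dataset's off-gas series."""
    tot = co2_formation_rate(ds.gas, ds.offgas_o2.values, ds.offgas_co2.values)
    sd_tot = co2_rate_sd(
        ds.gas,
        ds.offgas_o2.values,
        ds.offgas_co2.values,
        ds.offgas_o2.sds,
        ds.offgas_co2.sds,
    )
    return specific_co2_rate(
        ds.offgas_co2.times, tot, fit, ds.reactor_volume, window, sd_tot
    )
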