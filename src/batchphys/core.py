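"""Domain types and unit conventions shared by all analysis stages.

Conventions
-----------
* Time is hours since inoculation (0-based); all rates are per hour.
* Biomass may be carried either as biovolume (BV, µL/mL) or cell dry
  weight (CDW, g/L).  The unit travels with the series as a tag; every
  downstream biomass-specific rate inherits the corresponding
  denominator (mmol/gCDW/h or mmol/mL_BV/h).
* Gas fractions are volume percent (vol%), flows m³/h, pressure Pa,
  temperature K.

Types are deliberately permissive on construction: invariants are
checked by :func:`validate_dataset`, which reports violations as a list
of human-readable issues instead of raising, so that malformed inputs
can be diagnosed in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Universal gas constant, J/(mol K)
R_GAS = 8.314

#: Molar mass of carbon, g/mmol (12.011 g/mol)
M_CARBON = 0.012011

#: Recognised measurement kinds and their units
QUANTITY_UNITS = {
    "biomass_bv": "uL/mL",
    "biomass_cdw": "g/L",
    "glucose": "mmol/L",
    "o2_out": "vol%",
    "co2_out": "vol%",
}


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class MeasurementSeries:
    """A measured time course with per-point standard deviations.

    Parameters
    ----------
    times : array-like
        Sampling times, hours since inoculation; strictly increasing.
    values : array-like
        Measured quantity in the unit declared by ``quantity_tag``.
    sds : array-like
        Per-point standard deviation, same unit; strictly positive.
    quantity_tag : str
        One of ``biomass_bv``, ``biomass_cdw``, ``glucose``, ``o2_out``,
        ``co2_out``.
    """

    times: np.ndarray
    values: np.ndarray
    sds: np.ndarray
    quantity_tag: str

    def __post_init__(self):
        self.times = _as_float_array(self.times)
        self.values = _as_float_array(self.values)
        self.sds = _as_float_array(self.sds)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def unit(self) -> str:
        return QUANTITY_UNITS.get(self.quantity_tag, "?")

    def window(self, t_start: float, t_end: float) -> "MeasurementSeries":
        """Return the sub-series with t_start <= t <= t_end."""
        m = (self.times >= t_start) & (self.times <= t_end)
        return MeasurementSeries(
            self.times[m], self.values[m], self.sds[m], self.quantity_tag
        )


@dataclass
class GasConditions:
    """Inlet gas composition and the physical state used in gas balancing.

    ``F`` is the inlet air flow in m³/h; ``p`` (Pa) and ``T`` (K) are the
    reference state at which that flow is expressed.  Mass-flow
    controllers are commonly calibrated at norm conditions, hence the
    defaults 101325 Pa / 273.15 K; both are configurable because they
    set the absolute scale of every gas-balance rate.
    """

    F: float
    p: float = 101325.0
    T: float = 273.15
    phi_o2_in: float = 20.95
    phi_co2_in: float = 0.04
    R: float = R_GAS

    @property
    def molar_inflow(self) -> float:
        """Total molar gas inflow F·p/(R·T), mol/h."""
        return self.F * self.p / (self.R * self.T)


@dataclass
class BatchDataset:
    """All measured time series plus conditions for one batch cultivation."""

    biomass: MeasurementSeries
    glucose: MeasurementSeries
    offgas_o2: MeasurementSeries
    offgas_co2: MeasurementSeries
    gas: GasConditions
    reactor_volume: float  # L
    strain_label: str = ""

    @property
    def biomass_unit(self) -> str:
        return self.biomass.unit


@dataclass
class RateFit:
    """Jointly fitted parameters of the exponential-growth / glucose model.

    ``X0`` carries the unit of the biomass series; ``pi_glc`` is per
    gCDW (or per mL BV) and hour; ``C`` absorbs the integration constant
    and the initial substrate concentration.
    """

    X0: float
    mu: float
    pi_glc: float
    C: float
    window: tuple = (0.0, 0.0)
    sse: float = np.nan
    biomass_tag: str = "biomass_cdw"
    n_obs: int = 0


@dataclass
class CarbonParams:
    """Carbon content of biomass used in the carbon balance.

    ``omega_c`` is the carbon mass fraction of dry biomass (gC/gCDW);
    reported values for C. glutamicum range roughly 0.41–0.51, and the
    default 0.45 ± 0.05 spans that literature interval.
    """

    omega_c: float = 0.45
    sd_omega_c: float = 0.05
    M_c: float = M_CARBON


def _check_series(name: str, s: MeasurementSeries, issues: list, min_len: int = 2):
    n_t, n_v, n_s = len(s.times), len(s.values), len(s.sds)
    if not (n_t == n_v == n_s):
        issues.append(
            f"{name}: times/values/sds lengths differ ({n_t}/{n_v}/{n_s})"
        )
        return
    if n_t < min_len:
        issues.append(f"{name}: fewer than {min_len} points ({n_t})")
    if n_t and np.any(s.times < 0):
        issues.append(f"{name}: negative times present")
    if n_t > 1 and np.any(np.diff(s.times) <= 0):
        issues.append(f"{name}: times not strictly increasing")
    if n_t and np.any(s.sds <= 0):
        issues.append(f"{name}: non-positive standard deviation(s)")
    if s.quantity_tag not in QUANTITY_UNITS:
        issues.append(f"{name}: unknown quantity tag {s.quantity_tag!r}")


def validate_dataset(ds: BatchDataset) -> list[str]:
    """Check every invariant of a :class:`BatchDataset`.

    Returns an empty list iff the dataset is well-formed, otherwise one
    human-readable issue per violation.  Never mutates ``ds`` and never
    raises: callers decide whether issues are fatal.
    """
    issues: list[str] = []
    _check_series("biomass", ds.biomass, issues)
    _check_series("glucose", ds.glucose, issues)
    _check_series("offgas_o2", ds.offgas_o2, issues)
    _check_series("offgas_co2", ds.offgas_co2, issues)

    if ds.biomass.quantity_tag not in ("biomass_bv", "biomass_cdw"):
        issues.append("biomass: tag must be biomass_bv or biomass_cdw")
    if ds.glucose.quantity_tag != "glucose":
        issues.append("glucose: tag must be glucose")

    if not ds.reactor_volume > 0:
        issues.append(f"reactor_volume must be > 0, got {ds.reactor_volume}")

    g = ds.gas
    if not g.F > 0:
        issues.append(f"gas.F must be > 0, got {g.F}")
    if not g.p > 0:
        issues.append(f"gas.p must be > 0, got {g.p}")
    if not g.T > 0:
        issues.append(f"gas.T must be > 0, got {g.T}")
    if g.phi_o2_in < 0 or g.phi_co2_in < 0:
        issues.append("inlet gas fractions must be non-negative")
    if g.phi_o2_in + g.phi_co2_in >= 100:
        issues.append("inlet O2 + CO2 fractions must be < 100 vol%")

    # biomass and glucose must overlap in time for a joint fit
    if len(ds.biomass) and len(ds.glucose):
        lo = max(ds.biomass.times[0], ds.glucose.times[0])
        hi = min(ds.biomass.times[-1], ds.glucose.times[-1])
        if lo > hi:
            issues.append("biomass and glucose series do not overlap in time")

    return issues
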