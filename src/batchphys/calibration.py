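"""Biovolume from particle-size distributions and BV ↔ CDW interconversion.

A Coulter-counter size distribution gives particle counts per diameter
bin.  Assuming spherical cells, the biovolume concentration is the total
spherical volume of all counted particles, scaled by the dilution factor
and the analyzed sample volume, in µL of cells per mL of culture.
A linear calibration then interconverts biovolume (µL/mL) and cell dry
weight (g/L); converted CDW values carry the conventional 5 % relative
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import MeasurementSeries


@dataclass
class SizeDistribution:
    diameters: np.ndarray      # µm bin centers, strictly increasing
    counts: np.ndarray         # particles per bin
    analyzed_volume: float     # mL of diluted sample measured
    dilution_factor: float = 1.0

    def __post_init__(self):
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)


@dataclass
class BvCdwCalibration:
    """Linear map CDW [g/L] = slope · BV [µL/mL] + intercept."""

    slope: float
    intercept: float
    rel_sd_cdw: float = 0.05
    r_squared: float = np.nan
    slope_stderr: float = np.nan


def biovolume_from_distribution(sd: SizeDistribution) -> float:
    """Biovolume concentration (µL/mL) as the first moment of the
    size distribution under a spherical cell-shape assumption.

    Sums per-particle sphere volumes (π/6)·d³ over bins (µm³), converts
    to µL (1 µm³ = 1e-9 µL) and scales by dilution and analyzed volume.
    """
    if len(sd.diameters) == 0:
        raise ValueError("empty size distribution")
    if np.any(sd.diameters <= 0):
        raise ValueError("diameters must be positive")
    if np.any(np.diff(sd.diameters) <= 0):
        raise ValueError("diameters must be strictly increasing")
    if np.any(sd.counts < 0):
        raise ValueError("counts must be non-negative")
    if sd.analyzed_volume <= 0:
        raise ValueError("analyzed_volume must be positive")
    vol_um3 = np.sum(sd.counts * (np.pi / 6.0) * sd.diameters**3)
    return float(sd.dilution_factor * vol_um3 * 1e-9 / sd.analyzed_volume)


def fit_bv_cdw(bv_points, cdw_points) -> BvCdwCalibration:
    """Ordinary least-squares line through paired (BV, CDW) observations.

    The intercept is fitted (not forced through the origin) and reported
    so users can check it is ≈ 0.  Requires ≥ 3 pairs and non-degenerate
    BV values.
    """
    bv = np.asarray(bv_points, dtype=float)
    cdw = np.asarray(cdw_points, dtype=float)
    if len(bv) != len(cdw):
        raise ValueError("bv and cdw point lists must have equal length")
    if len(bv) < 3:
        raise ValueError("need at least 3 paired calibration points")
    if np.ptp(bv) == 0:
        raise ValueError("zero variance in BV points: slope undefined")
    res = stats.linregress(bv, cdw)
    return BvCdwCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_stderr=float(res.stderr),
    )


def bv_to_cdw(cal: BvCdwCalibration, series: MeasurementSeries) -> MeasurementSeries:
    """Map a biovolume series through the calibration line.

    Output sds are ``rel_sd_cdw`` (default 5 %) of the converted value.
    Raises if the series is not tagged ``biomass_bv`` or a mapped value
    is negative.
    """
    if series.quantity_tag != "biomass_bv":
        raise ValueError(f"expected a biomass_bv series, got {series.quantity_tag}")
    values = cal.slope * series.values + cal.intercept
    if np.any(values < 0):
        raise ValueError("calibration maps a biovolume to negative CDW")
    return MeasurementSeries(
        series.times.copy(), values, cal.rel_sd_cdw * values, "biomass_cdw"
    )


def cdw_to_bv(cal: BvCdwCalibration, series: MeasurementSeries) -> MeasurementSeries:
    """Inverse of :func:`bv_to_cdw` (exact round-trip up to float error)."""
    if series.quantity_tag != "biomass_cdw":
        raise ValueError(f"expected a biomass_cdw series, got {series.quantity_tag}")
    if cal.slope == 0:
        raise ValueError("zero slope: inverse calibration undefined")
    values = (series.values - cal.intercept) / cal.slope
    if np.any(values < 0):
        raise ValueError("calibration maps a CDW to negative biovolume")
    return MeasurementSeries(
        series.times.copy(), values, cal.rel_sd_cdw * values, "biomass_bv"
    )
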