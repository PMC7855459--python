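"""Exponential-phase window detection from the exhaust-gas CO₂ trace.

In a batch cultivation the exhaust CO₂ volume fraction rises with the
exponentially growing culture and collapses when the substrate is
depleted, so the end of the exponential phase is taken as the peak of
the (lightly smoothed) CO₂ trace.  The window start excludes the lag
phase: the earliest time at which biomass exceeds a small fraction of
its end-of-window value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MeasurementSeries


@dataclass
class PhaseWindow:
    """Fitting window [t_start, t_end] in hours."""

    t_start: float
    t_end: float
    peak_co2_volpct: float = np.nan
    n_points_in_window: int = 0


class PhaseDetectionError(RuntimeError):
    pass


def moving_average(values: np.ndarray, halfwidth: int) -> np.ndarray:
    """Centered moving average with window shrunk at the edges."""
    v = np.asarray(values, dtype=float)
    if halfwidth <= 0:
        return v.copy()
    n = len(v)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - halfwidth)
        hi = min(n, i + halfwidth + 1)
        out[i] = v[lo:hi].mean()
    return out


def detect_window(
    co2_out: MeasurementSeries,
    biomass: MeasurementSeries,
    smooth_halfwidth: int = 2,
    start_threshold_rel: float = 0.05,
    glucose: MeasurementSeries | None = None,
) -> PhaseWindow:
    """Locate the exponential-phase fitting window.

    The window end is the time of the global maximum of the
    moving-average-smoothed CO₂ trace (earliest index on ties), refined
    to the raw-trace maximum within the smoothing neighbourhood so the
    smoothing does not shift a sharp depletion peak; a peak at the last
    sample means the culture was still growing and is an error.  The window start is the earliest time at which biomass
    exceeds ``start_threshold_rel`` times the biomass at the window end,
    excluding the lag phase.  The start is relaxed earlier if fewer than
    4 biomass (and glucose, when given) points would remain.

    Raises
    ------
    PhaseDetectionError
        If the CO₂ series is too short, the peak falls on the last
        sample, or fewer than 4 points remain in the window.
    """
    if len(co2_out) < 5:
        raise PhaseDetectionError("need at least 5 off-gas CO2 points")

    smoothed = moving_average(co2_out.values, smooth_halfwidth)
    i_smooth = int(np.argmax(smoothed))  # argmax returns the earliest tie
    # the moving average biases the argmax of an asymmetric peak early;
    # refine to the raw-trace maximum in its neighbourhood
    lo = max(0, i_smooth - smooth_halfwidth)
    hi = min(len(smoothed), i_smooth + smooth_halfwidth + 1)
    i_peak = lo + int(np.argmax(co2_out.values[lo:hi]))
    if i_peak == len(smoothed) - 1:
        raise PhaseDetectionError(
            "CO2 peak at series end: exponential phase not finished"
        )
    t_end = float(co2_out.times[i_peak])

    bio_end = float(np.interp(t_end, biomass.times, biomass.values))
    above = biomass.times[biomass.values >= start_threshold_rel * bio_end]
    t_start = float(above[0]) if len(above) else float(biomass.times[0])
    t_start = min(t_start, t_end)

    def n_in(series: MeasurementSeries, lo: float) -> int:
        return int(np.sum((series.times >= lo) & (series.times <= t_end)))

    # relax the start earlier until enough points remain for the joint fit
    candidates = np.sort(biomass.times[biomass.times <= t_start])[::-1]
    for lo in candidates:
        ok = n_in(biomass, lo) >= 4 and (glucose is None or n_in(glucose, lo) >= 4)
        if ok:
            t_start = float(lo)
            break
    else:
        t_start = float(biomass.times[0])

    n_pts = n_in(biomass, t_start)
    if n_pts < 4 or (glucose is not None and n_in(glucose, t_start) < 4):
        raise PhaseDetectionError("fewer than 4 points remain in the window")

    return PhaseWindow(
        t_start=t_start,
        t_end=t_end,
        peak_co2_volpct=float(co2_out.values[i_peak]),
        n_points_in_window=n_pts,
    )
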