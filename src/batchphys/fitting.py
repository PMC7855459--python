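"""Joint variance-weighted fit of exponential growth and glucose depletion.

The model assumes exponentially growing cells taking up d-glucose at a
constant biomass-specific rate π_GLC:

    X(t)      = X0 · exp(µ t)
    c_GLC(t)  = C − (π_GLC/µ) · X0 · exp(µ t)

where C absorbs the integration constant and the initial substrate
concentration.  Both equations are fitted *jointly* to the biomass and
glucose time courses inside the exponential-phase window, each residual
weighted by the reciprocal of its measurement standard deviation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .core import BatchDataset, MeasurementSeries, RateFit
from .phase import PhaseWindow


def model_biomass(X0: float, mu: float, t) -> np.ndarray:
    """Exponential biomass model X(t) = X0 · exp(µ t)."""
    return X0 * np.exp(mu * np.asarray(t, dtype=float))


def model_glucose(C: float, pi_glc: float, mu: float, X0: float, t) -> np.ndarray:
    """Integrated glucose model c(t) = C − (π_GLC/µ)·X0·exp(µ t)."""
    return C - (pi_glc / mu) * X0 * np.exp(mu * np.asarray(t, dtype=float))


class FitError(RuntimeError):
    """Raised when the joint fit cannot be carried out or does not converge."""


def _log_linear_start(bio: MeasurementSeries) -> tuple[float, float]:
    """OLS on ln(biomass) vs t -> (X0, mu) starting values."""
    v = np.clip(bio.values, 1e-12, None)
    slope, intercept = np.polyfit(bio.times, np.log(v), 1)
    mu0 = max(slope, 1e-6)
    X00 = float(np.exp(intercept))
    return X00, mu0


def initial_guess(bio: MeasurementSeries, glc: MeasurementSeries) -> np.ndarray:
    """Closed-form starting values (X0, mu, pi_glc, C).

    µ and X0 come from a log-linear regression of biomass on time;
    π_GLC from total glucose consumed over the window divided by the
    biomass formed, times µ; C from the first glucose observation plus
    the implied model offset at that time.
    """
    X00, mu0 = _log_linear_start(bio)
    dX = model_biomass(X00, mu0, glc.times[-1]) - model_biomass(X00, mu0, glc.times[0])
    dS = glc.values[0] - glc.values[-1]
    pi0 = max(dS * mu0 / dX, 1e-6) if dX > 0 else 1.0
    C0 = glc.values[0] + (pi0 / mu0) * model_biomass(X00, mu0, glc.times[0])
    return np.array([X00, mu0, pi0, C0])


def weighted_residuals(params, bio: MeasurementSeries, glc: MeasurementSeries):
    X0, mu, pi_glc, C = params
    rb = (bio.values - model_biomass(X0, mu, bio.times)) / bio.sds
    rg = (glc.values - model_glucose(C, pi_glc, mu, X0, glc.times)) / glc.sds
    return np.concatenate([rb, rg])


def objective(params, bio: MeasurementSeries, glc: MeasurementSeries) -> float:
    """Weighted sum of squared residuals over both series."""
    r = weighted_residuals(params, bio, glc)
    return float(r @ r)


def fit_rates(
    ds: BatchDataset,
    window: PhaseWindow,
    x0: np.ndarray | None = None,
    max_iter: int = 500,
) -> RateFit:
    """Jointly fit (X0, µ, π_GLC, C) inside the exponential-phase window.

    Minimises the variance-weighted SSE over both time courses with a
    bounded trust-region least-squares routine, subject to X0 > 0,
    µ > 0, π_GLC ≥ 0.  Deterministic given the data and starting point.

    Parameters
    ----------
    ds : BatchDataset
    window : PhaseWindow
        Fitting window, typically from :func:`batchphys.phase.detect_window`.
    x0 : array, optional
        Starting point (X0, mu, pi_glc, C); defaults to the closed-form
        heuristics of :func:`initial_guess`.  Bootstrap refits warm-start
        at the point estimate through this argument.

    Raises
    ------
    FitError
        If fewer than 4 biomass or glucose points fall inside the
        window, or the optimizer fails to converge.
    """
    bio = ds.biomass.window(window.t_start, window.t_end)
    glc = ds.glucose.window(window.t_start, window.t_end)
    if len(bio) < 4 or len(glc) < 4:
        raise FitError(
            f"need >= 4 biomass and glucose points in window, got "
            f"{len(bio)} biomass / {len(glc)} glucose"
        )
    if np.any(bio.sds <= 0) or np.any(glc.sds <= 0):
        raise FitError("all measurement standard deviations must be > 0")

    start = initial_guess(bio, glc) if x0 is None else np.asarray(x0, dtype=float)
    tiny = 1e-12
    lower = np.array([tiny, tiny, 0.0, -np.inf])
    upper = np.array([np.inf, np.inf, np.inf, np.inf])
    start = np.clip(start, lower + tiny, None)

    res = least_squares(
        weighted_residuals,
        start,
        args=(bio, glc),
        bounds=(lower, upper),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=max_iter * 10,
    )
    if not res.success:
        raise FitError(f"joint fit did not converge: {res.message}")

    X0, mu, pi_glc, C = res.x
    return RateFit(
        X0=float(X0),
        mu=float(mu),
        pi_glc=float(pi_glc),
        C=float(C),
        window=(window.t_start, window.t_end),
        sse=float(2.0 * res.cost),
        biomass_tag=ds.biomass.quantity_tag,
        n_obs=len(bio) + len(glc),
    )
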