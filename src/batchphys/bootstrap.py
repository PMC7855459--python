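"""Parametric Monte-Carlo bootstrap of the joint fit.

Every in-window biomass and glucose measurement is perturbed within the
normal distribution defined by its value and standard deviation; the
variance-weighted fit is then re-performed on each perturbed replicate.
The perturbations form a Latin-Hypercube sample — one draw per
equal-probability stratum per measurement dimension — which spreads the
replicates evenly through the perturbation space at small sample sizes.
Confidence bounds are the α-th and (1−α)-th percentiles of the
parameter sample; with the default α = 0.25 the interval is the
interquartile range (IQR).

Off-gas measurements are not perturbed here: the gas balance is applied
to the observed gas data, and its uncertainty is propagated analytically
(see :mod:`batchphys.offgas` and :mod:`batchphys.carbon`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .core import BatchDataset, MeasurementSeries, RateFit
from .fitting import FitError, fit_rates
from .phase import PhaseWindow

PARAM_NAMES = ("X0", "mu", "pi_glc", "C")


@dataclass
class BootstrapResult:
    """Parameter sample and percentile confidence bounds.

    ``samples`` is (n_success × 4) in the order (X0, µ, π_GLC, C);
    ``lower``/``upper`` are the α-th and (1−α)-th percentiles per
    parameter (linear interpolation between closest ranks).
    """

    n_samples: int
    alpha: float
    samples: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_failed: int = 0

    def interval(self, name: str) -> tuple[float, float]:
        i = PARAM_NAMES.index(name)
        return float(self.lower[i]), float(self.upper[i])

    def half_widths(self) -> np.ndarray:
        """(upper − lower)/2 per parameter, a symmetric sd-like summary."""
        return (self.upper - self.lower) / 2.0


def lhs_normal_perturb(
    means, sds, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Latin-Hypercube sample of independent normals.

    Per dimension the unit interval is split into ``n`` equal strata,
    one uniform draw is taken per stratum, the stratum order is randomly
    permuted, and the draws are mapped through the normal inverse CDF
    with that dimension's mean and sd.  Deterministic given the seed.

    Returns an (n × dim) matrix.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    dim = len(means)
    u = np.empty((n, dim))
    for j in range(dim):
        strata = rng.permutation(n)
        u[:, j] = (strata + rng.uniform(size=n)) / n
    return means + sds * norm.ppf(u)


def bootstrap_fit(
    ds: BatchDataset,
    window: PhaseWindow,
    n: int = 1000,
    alpha: float = 0.25,
    seed: int = 0,
    point_fit: RateFit | None = None,
    max_failed_frac: float = 0.10,
) -> BootstrapResult:
    """Bootstrap the joint fit by LHS perturbation of the measurements.

    Each replicate replaces every in-window biomass and glucose value by
    its perturbed value and refits, warm-started at the point estimate.
    Failed refits are dropped and counted; more than
    ``max_failed_frac`` failures is an error (silent dropping at that
    rate would bias the intervals).
    """
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    point = point_fit or fit_rates(ds, window)
    warm = np.array([point.X0, point.mu, point.pi_glc, point.C])

    bio = ds.biomass.window(window.t_start, window.t_end)
    glc = ds.glucose.window(window.t_start, window.t_end)
    n_bio = len(bio)
    means = np.concatenate([bio.values, glc.values])
    sds = np.concatenate([bio.sds, glc.sds])
    perturbed = lhs_normal_perturb(means, sds, n, seed)

    rows, n_failed = [], 0
    for k in range(n):
        ds_k = replace(
            ds,
            biomass=MeasurementSeries(
                bio.times, perturbed[k, :n_bio], bio.sds, bio.quantity_tag
            ),
            glucose=MeasurementSeries(
                glc.times, perturbed[k, n_bio:], glc.sds, glc.quantity_tag
            ),
        )
        try:
            f = fit_rates(ds_k, window, x0=warm)
            rows.append([f.X0, f.mu, f.pi_glc, f.C])
        except FitError:
            n_failed += 1

    if n_failed > max_failed_frac * n:
        raise FitError(
            f"{n_failed}/{n} bootstrap refits failed to converge "
            f"(> {max_failed_frac:.0%} tolerated)"
        )
    samples = np.asarray(rows)
    lower = np.percentile(samples, 100.0 * alpha, axis=0)
    upper = np.percentile(samples, 100.0 * (1.0 - alpha), axis=0)
    return BootstrapResult(
        n_samples=n,
        alpha=alpha,
        samples=samples,
        lower=lower,
        upper=upper,
        n_failed=n_failed,
    )
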