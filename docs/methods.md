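# Methods

## Scope and model

`batchphys` analyzes single batch cultivations of an exponentially
growing microbe on a single limiting substrate (d-glucose).  The
physiological model is deliberately minimal:

* biomass: X(t) = X₀·e^(µt) — constant specific growth rate µ over the
  fitting window;
* glucose: constant biomass-specific uptake π_GLC, so
  c_GLC(t) = C − (π_GLC/µ)·X₀·e^(µt), where C absorbs the integration
  constant and the initial concentration (c_GLC,0 is *not* a free
  parameter);
* CO₂: the total formation rate π_CO2,tot(t) (mol/h) from an inert-gas
  balance over the head space, divided by the fitted biomass amount
  X(t)·V to give the specific rate.

Monod/substrate-limited kinetics, maintenance coefficients, fed-batch
and by-product formation are out of scope.

## Units

Time is hours since inoculation; all rates per hour.  Biomass may be
biovolume (µL/mL) or cell dry weight (g/L); the unit travels with the
series as a tag and every specific rate inherits the corresponding
denominator.  Gas fractions are vol%, flow m³/h, pressure Pa,
temperature K, R = 8.314 J/(mol·K), M_C = 0.012011 g/mmol.

## Fitting

The two model equations are fitted jointly by variance-weighted least
squares: residuals (obs − model)/sd over both the biomass and glucose
series, minimized over (X₀, µ, π_GLC, C) with a bounded trust-region
least-squares routine (scipy `least_squares`, TRF) under X₀ > 0, µ > 0,
π_GLC ≥ 0.  Starting values are closed-form: µ and X₀ from OLS on
ln(biomass) vs t, π_GLC from glucose consumed over biomass formed times
µ, C from the first glucose observation plus the implied offset.
Tolerances are set near machine precision (xtol = ftol = gtol = 1e-14)
so noiseless synthetic data is recovered to better than 1e-6 relative;
non-convergence raises rather than returning silently.  Scaling all sds
by a common factor leaves the optimum unchanged (SSE scales by 1/k²),
and shifting time by Δ maps X₀ → X₀·e^(−µΔ) with µ, π_GLC unchanged;
both properties are tested.

## Window detection

The window end is the peak of the exhaust CO₂ trace: a centered moving
average (half-width 2 samples, shrunk at edges) locates the global
maximum robustly under analyzer noise, and the end point is then
refined to the raw-trace maximum within the smoothing neighbourhood —
without this refinement the asymmetric depletion peak is biased early
by up to the smoothing half-width.  Ties resolve to the earliest index
(conservative: never includes post-exponential decline); a peak on the
last sample is an error (culture unfinished).  The window *start* has
no standard criterion; the package uses the earliest time at which
biomass exceeds 5 % of its end-of-window value (excluding the lag
phase), relaxed earlier if fewer than 4 biomass or glucose points would
remain, and overridable by the user (`--t-start/--t-end`).

## Gas balance

The reference state (p, T) at which the inlet flow F is expressed is
the single largest absolute-scale uncertainty of the CO₂ rates.  Mass
flow controllers are typically calibrated at norm conditions, so the
defaults are p = 101325 Pa, T = 273.15 K; both are configurable and
logged on every run.  The specific rate divides by the *fitted* biomass
model rather than the raw noisy biomass points.  The reported scalar
π_CO2 is the arithmetic window mean of the per-time specific rates (an
endpoint value or regression slope would be defensible alternatives;
the mean is the documented choice).  Analyzer sds are propagated
first-order through the balance to an sd of that mean.

## Bootstrap

Parametric Monte-Carlo bootstrap, 1000 replicates by default: each
in-window biomass and glucose measurement is perturbed within
N(value, sd²).  The joint perturbation is a Latin-Hypercube sample —
per measurement dimension the unit interval is split into n equal
strata, one uniform draw per stratum, stratum order permuted, mapped
through the normal inverse CDF — which stratifies the replicate set and
stabilizes percentile estimates at moderate n.  Refits warm-start at
the point estimate.  Bounds are the α-th and (1−α)-th percentiles of
the parameter sample with linear interpolation between closest ranks
(numpy's default); α = 0.25 gives the IQR.  Failed refits are dropped
and counted; above 10 % the run errors out.  Off-gas measurements are
not perturbed in the bootstrap — the gas balance is applied to observed
data and carries an analytic error instead; perturbing them as well
would double-count gas uncertainty in Θ.

## Carbon balance and error propagation

Θ = (µ·ω_C/M_C + π_CO2)/(6·π_GLC) with ω_C = 0.45 ± 0.05 gC/gCDW by
default — literature values for C. glutamicum span roughly 0.41–0.51,
and the ±0.05 interval covers them.  Biomass and CO₂ are the only
sinks; exometabolome carbon is negligible (µmolC/gCDW against a gap of
several mmolC/gCDW/h) and excluded.  sd(Θ) is first-order propagation
with analytic partials, treating µ, π_GLC, π_CO2 and ω_C as
independent: no covariance information is available from published rate
tables.  For the wild-type reference point this independent propagation
gives ≈ 0.097 where the published uncertainty is 0.089 — consistent
with the published value incorporating parameter covariances from the
joint fit; both numbers are reported and no attempt is made to force
agreement.  Reported Θ values are rounded half-even to 2 decimals for
comparison against published tables.  Recomputation from published
2-decimal rates reproduces the published Θ exactly for five of the nine
panel strains; for the other four the rounding of the printed *inputs*
shifts the second decimal by one (e.g. Δpck: 0.8027 vs printed 0.81),
so the tests assert exactness only where the printed precision permits
it and ±0.015 elsewhere.

## Synthetic data generator

The generator is first-class, tested code; it emulates exactly the
structure the analysis assumes:

* exponential growth after a hard lag switch (the fit window excludes
  the lag anyway), growth arrest at glucose depletion;
* glucose per the integrated model, sampling of biomass/glucose stops
  at depletion while off-gas traces continue (the CO₂ collapse after
  the peak is what window detection keys on);
* off-gas CO₂ constructed by inverting the gas balance from the
  gas-phase CO₂ release (1−ρ)·π_CO2·X·V, with ρ the dissolved
  CO₂/bicarbonate retention fraction (default 0.2 — reproduces the
  ~80 % carbon closure observed in practice).  The O₂ trace assumes a
  respiratory quotient of 1; only the inert-gas correction sees it, so
  the RQ choice perturbs the recovered rates well below noise level;
* independent Gaussian noise per point (biomass 5 % relative, glucose
  3 % relative, gas 0.02 vol% absolute), matching the bootstrap's
  perturbation assumption; recorded per-point sds equal the noise
  magnitudes used.  When a noise component is exactly zero a tiny
  positive placeholder sd (1e-6 of the series scale) is recorded so
  1/sd² weights stay defined.

Default preset: X₀ = 0.1 g/L, µ = 0.45 1/h, π_GLC = 4.82 mmol/gCDW/h,
glc₀ = 55.5 mmol/L (1 % w/v), π_CO2 = 8.675 mmol/gCDW/h so the detector
at ρ = 0.2 sees ≈ 6.94; gassing 1 vvm on 1 L (0.06 m³/h), sampling
every 0.25 h for 48 points (depletion at ≈ 8.8 h).
`StrainPreset.with_full_closure()` instead sets π_CO2 so the true
balance closes (Θ = 1), which is the right baseline for demonstrating
that the retention fraction alone opens the 20 % gap.

What the generator does **not** emulate: pH/carbonate equilibrium
dynamics (retention is a constant fraction), O₂ limitation, diauxie,
by-product formation, autocorrelated analyzer drift.  Passing tests
therefore validate the estimators under the model's own assumptions,
not robustness to real-world deviations from them.

## Numerical and design notes

* Domain types are plain dataclasses; invariants are checked by
  `validate_dataset`, which returns one readable issue per violation
  instead of raising, so malformed inputs are diagnosed in one pass.
* Biovolume: first moment of the size distribution interpreted as the
  *total* spherical particle volume per mL (only this yields µL/mL);
  BV↔CDW calibration is OLS with a fitted intercept, reported so users
  can check it is ≈ 0.
* Monte-Carlo problem sizes in the test suite (e.g. 50 synthetic
  datasets × 200 bootstrap replicates for the coverage check, replicate
  means of 5 reactors for the closure check) were chosen so Monte-Carlo
  error is comfortably below the tolerances being asserted.
* Replicate summaries use the envelope rule (min lower bound, max upper
  bound across replicates), recorded verbatim in the output metadata.
* Determinism: every stochastic step takes an explicit seed; identical
  seeds give byte-identical outputs.
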