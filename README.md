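# batchphys

Quantitative physiology of batch bioreactor cultivations: model-based
estimation of specific growth and substrate-uptake rates, off-gas CO₂
balancing, the instantaneous carbon balance with Gaussian error
propagation, and parametric bootstrap confidence intervals — plus a
synthetic bioreactor data generator so the whole pipeline can be
exercised and validated without wet-lab data.

It is written for bioprocess and systems-biology groups who phenotype
microbial strains (the bundled reference panel is the *Corynebacterium
glutamicum* anaplerosis deletion set) in controlled batch reactors and
need defensible rates with uncertainties, not just slopes from a
spreadsheet.

## The model

During the exponential phase, biomass and residual d-glucose follow

```
X(t)      = X₀ · exp(µ t)
c_GLC(t)  = C − (π_GLC/µ) · X₀ · exp(µ t)
```

with µ the specific growth rate (1/h), π_GLC the biomass-specific
glucose uptake rate (mmol gCDW⁻¹ h⁻¹) and C an offset absorbing the
integration constant and the initial substrate concentration.  Both
equations are fitted **jointly** by variance-weighted least squares to
the biomass and glucose time courses; the fitting window ends at the
peak of the exhaust-gas CO₂ fraction and starts after the lag phase.

The total CO₂ formation rate comes from an inert-gas balance over the
head space,

```
π_CO2,tot = F·p/(R·T) · [ (100 − Φ_O2^in − Φ_CO2^in)/(100 − Φ_O2^out − Φ_CO2^out) · Φ_CO2^out/100 − Φ_CO2^in/100 ]   [mol/h]
```

and is divided by the fitted biomass X(t)·V to give π_CO2
(mmol gCDW⁻¹ h⁻¹).  The **instantaneous carbon balance**

```
Θ = (µ·ω_C/M_C + π_CO2) / (6·π_GLC)
```

compares carbon flowing into the two measured sinks (biomass with
carbon mass fraction ω_C = 0.45 ± 0.05 gC/gCDW, and CO₂) with the
carbon taken up as glucose.  Θ ≈ 0.8 in aerobic batch cultures; the gap
is the produced CO₂ that stays dissolved as bicarbonate and never
reaches the off-gas analyzer.

Parameter uncertainty is quantified by a parametric Monte-Carlo
bootstrap: every in-window measurement is perturbed within its own
normal distribution (as a Latin-Hypercube sample, 1000 replicates by
default), the fit is re-performed, and the α/(1−α) percentiles of the
parameter sample are reported (α = 0.25, i.e. the interquartile range,
by default).  Uncertainty of derived quantities such as Θ uses
first-order Gaussian error propagation.

## Worked example

```python
from batchphys import (StrainPreset, NoiseModel, simulate_batch,
                       detect_window, fit_rates, bootstrap_fit,
                       balance_offgas, instantaneous_theta)

ds = simulate_batch(StrainPreset(), NoiseModel(seed=1))   # WT-like batch
w  = detect_window(ds.offgas_co2, ds.biomass, glucose=ds.glucose)
f  = fit_rates(ds, w)
g  = balance_offgas(ds, f, w)
cb = instantaneous_theta(f.mu, f.pi_glc, g.pi_co2_mean)
print(f"mu={f.mu:.3f} 1/h  pi_GLC={f.pi_glc:.3f}  pi_CO2={g.pi_co2_mean:.2f}  theta={cb.theta:.3f}")
```

prints

```
mu=0.454 1/h  pi_GLC=4.760  pi_CO2=6.86  theta=0.836
```

— the fitted growth rate and glucose uptake sit within ~1 % of the
preset truth (µ = 0.45, π_GLC = 4.82), the off-gas balance sees 80 % of
the produced CO₂ (the preset retains ρ = 0.2 as dissolved bicarbonate,
so the detector expectation is 6.94), and the carbon balance
consequently closes at Θ ≈ 0.84 rather than 1.

The `examples/` scripts walk through each capability: rate fitting,
the reference-panel Θ recomputation, bootstrap intervals, and how the
carbon gap scales with the dissolved-CO₂ retention fraction.  A thin
CLI (`batchphys simulate|calibrate|fit|summarize|report`) wraps the
same functions for shell use.

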