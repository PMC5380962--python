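# oceanpatch

Tools for studying how horizontal turbulent dispersion regulates
fine-scale (~1–100 km) phytoplankton blooms in low-nutrient (oligotrophic)
oceans.  The package is aimed at biological oceanographers who want to

- track a bloom patch through time at an equal-chlorophyll contour and
  build Lagrangian series of its area, mean concentration and
  mixed-layer-integrated biomass,
- estimate the effective eddy diffusivity `k_e` and the horizontal
  dilution rate `β` from the patch's area growth,
- advect particle ensembles through gridded surface currents (RK4, 6 h
  step, bilinear-in-space / linear-in-time velocity interpolation),
- diagnose mixed-layer depth from temperature profiles with a 0.2 °C
  threshold criterion, and
- simulate a nutrient–phytoplankton–zooplankton (NPZ) ecosystem inside a
  water patch whose volume grows by dilution.

Everything runs on synthetic fields with known ground truth, generated by
the package itself, so every stage is testable without satellite or float
data downloads.

## The model

When a tracer patch is dispersed by eddies smaller than itself, its area
grows linearly and the growth rate measures the effective eddy
diffusivity:

    dA_p/dt = 8π k_e,          β(t) = (1/V) dV/dt = β₀ / (1 + β₀ t),

with β₀ = (dA_p/dt)/A₀ the initial horizontal dilution rate (the patch
occupies a mixed layer of constant depth `H_ml`, so relative volume and
area change coincide).  The patch's ecosystem obeys

    dN/dt = −μ P N/(k_N+N)               − (F/V) N
    dP/dt =  μ P N/(k_N+N) − G Z P/(k_P+P) − (F/V) P
    dZ/dt =  G Z P/(k_P+P)               − (F/V) Z
    dV/dt =  F = 8π k_e H_ml (constant),

Monod nutrient uptake, Holling type II grazing, and dilution by inflow of
water free of N, P and Z.  Total nitrogen `V·(N+P+Z)` is conserved and
equals the carrying capacity `C = V₀(N₀+P₀+Z₀)`, which normalizes
steady-state biomass.  The key control parameter is γ = β₀/μ: zooplankton
absorb the bloom when γ ≪ 1, dilution starves it when γ ≫ 1, and
phytoplankton accumulation peaks at γ ~ 1.

## Worked example

Run the demo scenario (an expanding bloom patch with ground-truth
k_e = 1,100 m² s⁻¹, drifting through an eddying velocity field, tracked at
the 0.13 mg m⁻³ chlorophyll contour over a 40 m mixed layer):

```sh
oceanpatch run-scenario --config examples/demo.yaml --outdir demo_out
```

The JSON report (also written to `demo_out/report.json`) contains, among
others:

```
"area_first_km2":  9993.9,      # initial patch area (truth 10^4 km^2)
"area_last_km2":   153185.6,    # after 60 days of dispersion
"area_rate_km2_d": 2383.6,      # OLS slope of area vs time
"k_e_m2_s":        1097.7,      # recovered eddy diffusivity (truth 1100)
"beta0_per_d":     0.239,       # initial horizontal dilution rate
"gamma":           0.149,       # beta0 / mu for mu = 1.6 /d
"mean_conc_first_mg_m3": 0.1564,
"mean_conc_last_mg_m3":  0.1591 # ~constant while biomass grows 15x
```

The patch area grows from ~10⁴ to ~1.5×10⁵ km² at ~2,400 km² d⁻¹; divided
by 8π this recovers the generator's eddy diffusivity to 0.2%.  Mean
concentration stays nearly constant while total biomass grows linearly —
the signature of a bloom whose dilution losses are compensated by growth.
The report ends with the steady-state biomass partitioning of the NPZ run
driven by the estimated β₀.

Library use mirrors the CLI, e.g.:

```python
from oceanpatch import dispersion
k_e = dispersion.eddy_diffusivity(28_000.0)   # m^2/s -> 1114.1 (~1,100)
beta0, beta = dispersion.dilution_rate(1.0e4, 2_400.0)  # -> 0.24 /d
```

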