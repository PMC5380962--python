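# Methods

## Scope and data model

The package analyses the dispersion/dilution of fine-scale
nutrient-enriched water patches and its effect on plankton ecosystems.
All inputs are synthetic, generated with known ground truth: gridded
velocity and tracer fields (`GridField`: lon/lat/time axes, variables,
missing-data mask), particle ensembles, temperature-depth profiles, and
patch-area time series.  Areas are handled internally in m² and presented
in km²; time axes are days since scenario start; spherical geometry uses
R = 6,371 km, with cell areas R²·Δλ·(sin φ_top − sin φ_bot).

## Dispersion relation and dilution rate

In the large-time dispersion regime — patch larger than the local eddies —
patch area grows linearly and the growth rate is proportional to the
effective eddy diffusivity, dA/dt = 8π·k_e.  The constant 8π is the
single named definition `AREA_GROWTH_PER_DIFFUSIVITY`; it corresponds to
a patch "area" of 4πσ² with per-axis variance growing at 2·k_e·t, and is
consistent with the printed observational pair it reproduces
(28,000 m² s⁻¹ → 1,100 m² s⁻¹).  Since the patch occupies a mixed layer
of constant depth, relative volume change equals relative area change,
giving the horizontal dilution rate β(t) = (dA/dt)/A(t) = β₀/(1+β₀t) with
β₀ = (dA/dt)/A₀.  Area growth is fitted by ordinary least squares; the
reported uncertainty is the OLS standard error of the slope, and the
contour-sensitivity scan additionally exposes the spread across contour
levels so either reading of a quoted ±uncertainty can be checked.

## Patch tracking

A patch at time t is the 8-connected component of unmasked cells with
tracer ≥ level, chosen as the largest component at the first time step
(ties broken by row-major order of first encounter) and thereafter as the
component containing — or nearest within one equivalent radius
√(A_prev/π) of — the previous patch centroid.  Cloud-masked cells
enclosed by the component are counted in the area but excluded from the
concentration mean: a cloud gap is unobserved water, not zero
concentration.  Total biomass is mean concentration × area × MLD,
assuming the mixed layer homogeneous in the tracer; the identity is
preserved exactly in every output row.  MLD is a single scalar per
scenario.  If no component is found near the previous centroid the series
is truncated with a logged reason; multi-patch tracking and
merge/split detection are out of scope.

## Mixed-layer depth

MLD is the depth at which temperature first differs from the surface
value (the shallowest measurement) by ΔT = 0.2 °C, linearly interpolated
between the bracketing levels.  The absolute difference |ΔT| is used so
both cooling and warming departures count; the criterion is invariant
under any depth-uniform temperature offset.  A crossing within float
round-off of a sampled level returns that level's depth exactly.
Profiles that never reach the threshold raise an error rather than
returning a lower bound.

## Synthetic generators

- **Velocity.** A streamfunction summing `n_modes` random-phase Fourier
  modes with wavelengths within ±30% of the eddy length scale and phases
  drifting on the evolution timescale.  u = −∂ψ/∂y, v = +∂ψ/∂x are taken
  with the same centred finite differences a diagnostic would use;
  because mixed partial operators along different axes commute, the
  discrete divergence vanishes to round-off (an analytically
  differentiated field would leave O(Δ²) finite-difference divergence).
  The field is rescaled to the requested RMS speed exactly.  Uniform flow
  and solid-body rotation are available as analytic special cases.
- **Stirred tracer.** Semi-Lagrangian advection (unconditionally stable,
  midpoint departure points, bilinear sampling) plus explicit diffusion
  with a CFL guard that reports the maximum stable step.  Diffusion uses
  a Neumann-boundary five-point Laplacian and conserves mass; an i.i.d.
  per-cell, per-slice Bernoulli cloud mask emulates cloud cover.
- **Expanding patch tracer.** A disk of prescribed area
  A(t) = A₀ + 8π·k_e·t with uniform interior concentration and a smooth
  edge about one cell wide; the half-way contour sits exactly on the
  prescribed radius.  The centre can follow any trajectory (in the demo
  scenario it is advected through the eddy field).  This is the
  controlled stand-in for a bloom dispersed in the large-time regime —
  constant mean concentration, linear area and biomass growth — and
  provides the ground-truth k_e for recovery tests.  A stirred Gaussian
  blob does *not* serve this purpose: its contour area growth depends
  strongly on the chosen level, which is a property of smooth diffusing
  profiles, not of stirred patches homogenized inside a sharp boundary.
- **Profiles.** Two layers: uniform temperature above the true MLD, a
  linear (negative-gradient) thermocline below, optional Gaussian noise.
  With gradient −0.1 °C m⁻¹ the 0.2 °C criterion crosses exactly 2 m
  below the true MLD.

What the generators do not emulate: real spectra of ocean currents,
coherent-vortex statistics, correlated (frontal) cloud structure,
chlorophyll patchiness inside the bloom, salinity effects on MLD.
Passing recovery tests therefore demonstrates correctness of the
estimators under their stated assumptions, not skill on real satellite
fields.

## Particle advection

Fixed-step RK4 in longitude/latitude with metric conversion
dlon/dt = u/(R cos φ), dlat/dt = v/R; default step 6 h, output stride
1 day.  Velocity is sampled bilinearly in space and linearly in time;
masked velocity cells act as zero velocity with a logged warning.
Particles whose RK4 stages sample outside the grid are frozen in place
and flagged — never dropped — so the ensemble size is invariant.
Longitude wraps only on near-global grids.  One caveat found while
validating: a bilinearly interpolated streamfunction-derived field is not
pointwise divergence-free inside grid cells, so material-area
conservation checks hold at the ~1% level only over about one eddy
turnover; beyond that a sampled material polygon also winds around eddies
faster than any practical point density can resolve.  The area
conservation property is therefore verified exactly in an affine
(solid-body) flow over a full period and at 1% over one turnover in a
steady eddy field.

## NPZ dilution model

State (N, P, Z, V) with Monod uptake μ·N/(k_N+N), Holling type II grazing
G·P/(k_P+P), constant inflow F = 8π·k_e·H_ml of water carrying no N, P or
Z, and dilution −(F/V)·X applied to all three concentrations.  Either k_e
(with A₀, H_ml) or β₀ parameterizes the inflow — exactly one must be
given.  With grazing routed to zooplankton, total nitrogen V·(N+P+Z) is
exactly conserved; the optional `recycle_grazing` flag reroutes the
grazing flux to the nutrient pool instead (the conservation law holds
either way).  Carrying capacity defaults to C = V₀(N₀+P₀+Z₀)
("total"), with C = V₀N₀ available by configuration; with trace initial
P and Z the two are numerically indistinguishable.

Defaults (overridable): μ = 1.6 d⁻¹, G = 0.12 d⁻¹, H_ml = 40 m,
A₀ = 10⁴ km², N₀ = 1 mmol N m⁻³, P₀ = Z₀ = 10⁻³·N₀,
k_N = k_P = 0.5 mmol N m⁻³.  The half-saturations are stand-ins in the
range used by contemporary ocean ecosystem models.  k_N deserves a note:
with k_N ≪ N₀ nutrient uptake never becomes limiting under dilution
(the integrated Monod growth diverges logarithmically even as N is
diluted like 1/t), phytoplankton eventually consume the whole reservoir
at any dilution rate, and the dilution-dominated regime disappears from
the steady state.  k_N comparable to a few tenths of the nutrient pulse
is required for the three-regime structure to exist, and 0.5 mmol N m⁻³
achieves it; β₀_opt scales roughly inversely with k_N (a regression test
pins this), while its sensitivity to k_P is weak (<50% for two-fold
changes).

### Numerics

LSODA via `scipy.integrate.solve_ivp`; the solver runs one decade tighter
than the requested tolerance (default rtol 10⁻⁸, atol 10⁻¹¹) so that the
conservation bound 10·rtol holds with margin.  Volume is integrated in
units of V₀ as a fourth state.  Concentrations are clamped at zero inside
the RHS; post-hoc negatives beyond 100·atol raise.  Steady state is the
first time all three extensive totals change by less than 10⁻⁴ of the
carrying capacity over a 10-day look-ahead — normalizing by C rather than
by the (possibly vanishing) total keeps the criterion meaningful for
emptying pools.  Typical convergence is a few hundred days near the
optimal dilution rate.

### Regime scans

`scan_beta0` simulates a grid of β₀ (or γ = β₀/μ) values to a default
horizon of 2,000 days.  Around the phytoplankton maximum the approach to
steady state is only logarithmic — dilution thins P and Z together, so
the grazing transfer decays like 1/t — and points there may not meet the
strict convergence tolerance at any practical horizon.  Such points
record their end-of-run totals as quasi-steady readouts, flagged
`converged=False`; they participate in locating β₀_opt (excluding them
would systematically move the optimum off the peak), while outright
integration failures are excluded.  β₀_opt is refined by golden-section
search between the bracketing grid points.  `scan_mu_G` repeats the scan
over a (μ, G) grid and reports per-G OLS fits of β₀_opt against μ; the
fits are linear to R² > 0.99 with slopes increasing with G.

## Scenario sizes and determinism

The demo scenario uses a 24°×14° domain at 0.125°, 60 daily time steps, a
10⁴ km² initial patch and k_e = 1,100 m² s⁻¹ — the bloom grows to
~1.5×10⁵ km², the scale regime of interest.  Scans use 25–40 log-spaced γ
points in [0.01, 10].  Every generator and the full scenario are
bit-reproducible under a fixed seed; the seed is recorded in the scenario
report.

## Known limitations

- No light, temperature, sinking, lysis or phytoplankton mortality terms;
  grazing is the only biological loss channel, which is also why the
  γ ≪ 1 limit sends all biomass to zooplankton.
- The NPZ model is a single well-mixed box; no spatially explicit
  reaction–advection–diffusion counterpart.
- Patch tracking follows one patch; simultaneous multi-patch tracking and
  merge/split events are not modelled.
- The dilution framework assumes linear area growth; strongly non-linear
  area histories make β₀ from an OLS slope a crude summary.
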