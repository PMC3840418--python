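# Methods

## Scope and model

`reefdiss` couples three small models:

1. a statistical description of bench-scale passive dissolution of coral
   skeleton at pH 7.8 vs pH 8.2;
2. an exact unit bridge from areal CaCO₃ fluxes to vertical framework change;
3. a forward ODE for reef elevation compared against sea-level trajectories.

The guiding assumption throughout is that dead skeleton dominates the
dissolving surface of a reef: live tissue can regulate its internal
carbonate chemistry, bare skeleton cannot, so bulk framework responds
directly to ambient pH.

## Dissolution statistics

Losses are stored signed, `Δw = w1 − w0 ≤ 0` for dissolution, matching the
negative ordinate convention of surface-area–loss plots (field prose often
quotes "loss" as a positive magnitude; the mapping is a sign flip).
Normalized loss is `Δw / w0`; the areal rate is `Δw / (SA · t)` in
g cm⁻² d⁻¹. Displacement volume is carried through and summarized but enters
no model: dissolution shows no volume relationship, consistent with exchange
happening at surfaces rather than in bulk.

The omnibus comparison is a classical one-way fixed-effects ANOVA over the
acidified groups — by default the four perforate growth forms plus the
imperforate genus, with controls summarized separately; the grouping is a
parameter. When every group has zero internal variance the F ratio
degenerates; the result is then flagged (`degenerate=True`) with F = ∞,
p = 0 (or F = 0, p = 1 when the between-group spread also vanishes) instead
of raising.

The post-hoc procedure is Tukey's HSD with the pooled within-group variance
and the studentized-range distribution (Tukey–Kramer standard errors for
unequal group sizes). Adjusted p values are conservative relative to
pooled-variance pairwise t tests by construction; this is property-tested.

### Exponential surface-area curve

`loss(SA) = −k_amp·exp(k_exp·SA)` is fitted by Gauss–Newton with step
halving: initialization from an ordinary regression of `ln(−loss)` on SA
over the strictly negative losses (at least two required), then iterative
refinement on **all** points — samples that gained weight cannot seed the
log fit but remain informative in the nonlinear stage. Convergence when the
largest relative parameter change falls below 1e-10; cap 200 iterations,
with the last iterate attached to the failure for diagnosis. Step halving
also enforces `k_amp > 0`. Standard errors come from the usual Gauss–Newton
covariance `s²(JᵀJ)⁻¹` with `s² = RSS/(n − 2)`; confidence intervals are
t-based. A two-parameter exponential needs nothing heavier; the fit is
cross-checked in the tests against an independent nonlinear least-squares
routine.

## Unit bridge

Fluxes convert exactly between {g, kg} × {cm², m²} × {d, y} with a fixed
365-day year — adequate for order-of-magnitude extrapolation from a 7-day
incubation to annual budgets. Mass ↔ thickness uses

    v [mm y⁻¹] = F [kg m⁻² y⁻¹] / (ρ·(1 − φ)) · 1000,

defaults ρ = 2.9 g cm⁻³ (bulk aragonite) and φ = 0.5 (field-average
framework porosity), both configurable. These defaults make
15.3 kg m⁻² y⁻¹ ↔ 10.55 mm y⁻¹, and 10 / 4 / 1 kg m⁻² y⁻¹ ↔ 6.9 / 2.8 /
0.7 mm y⁻¹, i.e. the conventional integer coefficients 7 / 3 / 0.75 after
rounding.

**A documented inconsistency.** The bench-scale chain
0.000042 g cm⁻² d⁻¹ → 0.42 g m⁻² d⁻¹ → annualized is 0.1533 kg m⁻² y⁻¹,
two orders of magnitude below the reef-scale dissolution input of
15.3 kg m⁻² y⁻¹ quoted alongside it in the source analysis. The package
performs only exact conversions and does **not** reproduce the ×100 step as
a conversion; 15.3 kg m⁻² y⁻¹ (−10.5 mm y⁻¹) is treated as the stated model
input for perforate dissolution, because the downstream model and its
conclusions are built on it. Pipeline outputs name units in every column
header to keep such slips visible.

## Reef accretion–dissolution ODE

The governing form `dA/dt = (a·A)/A + b·S − (c·D)/A` contains one term that
reduces algebraically to `a` and one whose division by `A` is dimensionally
ambiguous (it makes `c` carry units of mm). Two modes are therefore
implemented and labelled:

* **constant** (default): `dA/dt = a + b·S − c·D`, `c = 1`. This is the only
  reading that reproduces the narrative magnitudes (e.g. net
  7 + 1 − 10.5 = −2.5 mm y⁻¹ for the densest perforate reef).
* **literal**: `dA/dt = a + b·S − c·D/A`, with `A` floored at a configurable
  ε (default 1 mm). No headline number is claimed for this mode; reaching
  the floor flags the trajectory `framework_exhausted` rather than aborting.

`A0` defaults to 100 mm of antecedent framework in literal mode (the initial
condition is otherwise unstated and only shifts constant-mode trajectories).
Integration is fixed-step classical RK4, default step 0.1 y reported
annually — cheap, and verified fourth-order against the closed form
`A(t) = √(A0² − 2cD·t)` of the a = b = 0 literal case. Constant-mode
trajectories are linear and RK4 reproduces them to machine precision.

## Sea level

Scenario warming endpoints: B1 +1.8 °C, A2 +3.4 °C, A1FI +4.0 °C above 1990
(the occasional "A1F1" spelling is normalized). Temperature ramps are linear
by default (a zero-initial-slope monotone cubic is available); the baseline
year 1990 is anchored at zero anomaly and H(1990) = 0.

Two sea-level modes:

* **semi-empirical**: `dH/dt = a_sl(T − T0) + b_sl·dT/dt`, integrated with
  the same RK4 scheme. Defaults a_sl = 5.6 mm y⁻¹ K⁻¹, b_sl = −49 mm K⁻¹,
  T0 = −0.41 °C follow the published dual-term calibration of this model
  class; they are explicit and overridable because the projections this
  package compares against name the approach without printing constants.
  For a linear ramp with b_sl = 0 the integral has the closed form
  `a·ΔT·(t−t0)²/(2(t1−t0))`, matched to 0.1% in tests.
* **parametric**: `H(t) = rise_2100·s^p`, s ∈ [0,1], p ≥ 1. Defaults
  750 / 850 / 900 mm for B1 / A2 / A1FI with p = 2, spanning the quoted
  75–90 cm-by-2100 range with an accelerating shape. Decelerating curves
  (p < 1) are out of scope. This mode is the pipeline default because the
  plotted scenario curves are not tabulated anywhere; no figure-derived
  numbers are asserted.

Keep-up bookkeeping: on the common annual grid, `gap(t) = (H(t) − H(t₀)) −
(A(t) − A(t₀))`. A reef keeps up while the gap never exceeds a threshold
(default 0 mm). Two events are reported because either could underlie a
"mid-century" statement: the **rate crossover** (first year the sea-level
rise rate, by centered differences, exceeds the reef's) and the
**submergence year** (first year the cumulative gap exceeds the threshold).
Under the default A1FI curve the densest imperforate reef (net 8 mm y⁻¹)
crosses over in 2044 — the closed form `2·900·(t−1990)/110² = 8` gives
t ≈ 2043.8 — and submerges only near 2100.

## Synthetic experiment generator

The generator emulates the study design: 15 perforate *Montipora* fragments
cycled across submassive / branching / encrusting / foliose forms and 15
imperforate foliose *Pectinia*, 7-day exposure, wax-dip surface areas drawn
uniformly from [20, 250] cm² (not reported; chosen so the exponential term
spans ~1.4×–70× its base, giving the observed curvature). Acidified
perforate losses follow `−k_amp·exp(k_exp·SA)` (defaults 0.005 g,
0.017 cm⁻²) plus additive Gaussian noise (sd 0.01 g); acidified imperforate
and all control losses are Gaussian with mean exactly 0 (sd 0.01 g),
encoding "no consistent passive dissolution" and no surface-area dependence.
Additive Gaussian noise is the least-structured choice; true balance and
wax-dip measurement errors are unreported, so these defaults are
placeholders, not estimates.

Initial dry weight is bulk skeletal density × displacement volume, with
volume tied loosely (sub-linearly) to surface area and perforate skeletons
drawn less dense (1.1–1.6 g mL⁻¹) than imperforate ones (1.5–2.1 g mL⁻¹) —
bigger fragments are heavier, as for real coral rubble; weights are clipped
to [5, 70] g. Final weights are clipped positive, with a warning when more
than 5% of samples need clipping. `paired-control` assignment (default)
gives every colony a control twin with identical geometry; `split` divides
each genus between arms, halving group sizes.

What passing tests show — and do not. Under these defaults the pipeline
recovers the generating curve (k_exp within 10%, k_amp within 25%), the
omnibus ANOVA is significant in ≥ 90% of 100 seeds, the imperforate subset
shows no surface-area relationship in ≥ 90% of seeds, and the mean perforate
areal rate lands within a factor of two of 4.2 × 10⁻⁵ g cm⁻² d⁻¹ (an
order-of-magnitude calibration, not an equality claim). These are checks of
internal consistency and statistical power against a generator built from
the analysis model itself; they do not validate the model against real
water-chemistry dynamics, flow effects (which can more than double
dissolution through advection), or cementation differences between reefs.

Temperature paths for stress-testing the sea-level integrator add stationary
AR(1) jitter (coefficient 0.8) to the scenario ramps; jitter sd 0 reduces
exactly to the deterministic ramps.

## Numerical and design choices

* Year length 365 d; no leap handling.
* Annual grids are built by index, not by accumulating the step, so the 2100
  endpoint is hit exactly.
* Unit round trips are exact to 1e-12 relative error (property-tested).
* Strict CSV schemas: unknown or missing columns and non-numeric or
  non-positive measurements are rejected with row-addressed messages; no
  silent coercion. Configs reject unknown keys.
* Pipeline runs are deterministic given the seed; the JSON manifest records
  every effective parameter, a config hash, and the derived perforate
  dissolution input (so a D given as 15.3 kg m⁻² y⁻¹ is visible as
  −10.55 mm y⁻¹).
* Problem sizes: the default pipeline analyses 60 synthetic samples and
  integrates 6 reef configurations × 3 scenarios at a 0.1 y step; the
  parameter-recovery simulation uses n = 50. All desk-scale.

## Known limitations

* No carbonate-system chemistry (pH ↔ Ω speciation), no alkalinity: pH
  enters only as a treatment label.
* No flow/advection, spatial topography, wave forcing, or separate
  bioerosion term (folded into `a`); no regional sea-level effects
  (isostasy, tectonics, land use) or probabilistic ensembles.
* The intended semantics of the literal mode's `D/A` damping is unresolved;
  both interpretations are exposed, and only constant mode backs quantitative
  statements.
* The post-hoc contrast set for growth forms is ambiguous in the source
  analysis; the grouping is a parameter, and no specific pairwise p is
  asserted.
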