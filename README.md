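# reefdiss

Analysis of passive coral-skeleton dissolution under ocean acidification, and
a reef accretion–dissolution model compared against 1990–2100 sea-level-rise
scenarios.

## The problem

By 2100 the surface ocean pH is expected to fall to about 7.8. Dead coral
skeleton — which makes up most of the framework of modern reefs — has no
biological buffering and dissolves passively at that pH. How fast it
dissolves depends on skeletal architecture: *perforate* corals (e.g.
*Montipora*, *Acropora*, *Porites*) have porous walls that expose a large
internal surface area to seawater, while *imperforate* corals (e.g.
*Pectinia*, faviids) have fused, solid walls. `reefdiss` implements the full
analysis chain for a bench experiment on this question and the forward model
it feeds:

1. **Dissolution experiment analysis.** For a table of coral fragments
   (initial/final dry weight, wax-dip surface area `SA`, displacement volume,
   pH 7.8 treatment vs pH 8.2 control, 7-day exposure) it computes normalized
   losses `(w1 − w0)/w0`, areal rates `(w1 − w0)/(SA · t)` in
   g CaCO₃ cm⁻² d⁻¹, one-way ANOVA with a Tukey HSD post-hoc across groups,
   and the exponential surface-area–dissolution curve

   ```
   loss(SA) = −k_amp · exp(k_exp · SA)        (k_amp in g, k_exp in cm⁻²)
   ```

   fitted by Gauss–Newton nonlinear least squares.

2. **Unit conversion.** Exact, unit-checked conversion between areal
   carbonate fluxes (g cm⁻² d⁻¹ ↔ kg m⁻² y⁻¹) and vertical framework change,
   `v [mm y⁻¹] = F / (ρ (1 − φ)) · 1000` with aragonite density
   ρ = 2.9 g cm⁻³ and framework porosity φ = 0.5 by default. A reef-scale
   dissolution flux of 15.3 kg CaCO₃ m⁻² y⁻¹ equates to ≈ −10.5 mm y⁻¹ of
   vertical framework loss; production of 10 and 4 kg m⁻² y⁻¹ equate to
   ≈ 7 and ≈ 3 mm y⁻¹ of growth.

3. **Reef accretion–dissolution ODE.**

   ```
   dA/dt = a + b·S − c·D                      (mm y⁻¹)
   ```

   with accretion coefficient `a` ∈ {7, 3, 0.75} mm y⁻¹ for high / medium /
   low carbonate production (10 / 4 / 1 kg m⁻² y⁻¹), sedimentation
   `b·S = 1 mm y⁻¹`, and dissolution `D` = 10.5 mm y⁻¹ (perforate) or 0
   (imperforate). A state-damped variant `dA/dt = a + b·S − c·D/A` is
   available as the explicitly labelled *literal* mode. Integration is
   fixed-step classical RK4.

4. **Sea-level scenarios.** B1 (+1.8 °C), A2 (+3.4 °C) and A1FI (+4.0 °C)
   warming by 2100, turned into sea-level curves either semi-empirically
   (`dH/dt = a_sl (T − T0) + b_sl dT/dt`) or as an accelerating power law
   anchored at a 2100 endpoint (defaults 750 / 850 / 900 mm). A reef "keeps
   up" while the cumulative sea-level-minus-reef-growth gap stays below a
   threshold; the rate-crossover year marks when sea level starts rising
   faster than the reef grows.

Because no raw experimental table is distributed, a seeded synthetic
generator (`reefdiss.synth`) reproduces the study design — 15 perforate
*Montipora* fragments across four growth forms plus 15 imperforate foliose
*Pectinia*, paired controls — so the whole pipeline is testable end to end.

## Worked example

```python
import reefdiss as rd

df = rd.simulate_dissolution_experiment(rd.ExperimentDesign(seed=0))
res = rd.DissolutionExperiment(df).fit()
print(res.loss_fit.summary())
```

```
Exponential surface-area dissolution fit
  loss(SA) = -k_amp * exp(k_exp * SA)
  n = 15, RSS = 0.00166022
  k_amp = 0.00486506 g      se 0.00101  95% CI [0.00267577, 0.00705436]
  k_exp = 0.0172173 cm^-2  se 0.000959  95% CI [0.0151454, 0.0192892]
```

The fit recovers the generating curve (k_amp = 0.005 g, k_exp = 0.017 cm⁻²)
from 15 noisy samples; the omnibus ANOVA over the five acidified groups gives
`F(4, 25) = 5.272, p = 0.0032`, and the mean perforate areal rate is
−7.7 × 10⁻⁵ g cm⁻² d⁻¹. Feeding the vertical dissolution equivalent into the
reef model:

```python
reef = rd.integrate_reef(rd.ReefModelParams(a=7.0, D=10.5))   # best perforate case
sea  = rd.scenario_sea_level("A1FI")
rd.keep_up_report(reef, sea)
```

shows the densest perforate reef shrinking 275 mm by 2100 (net
7 + 1 − 10.5 = −2.5 mm y⁻¹), while the same reef without dissolution
(imperforate, net +8 mm y⁻¹) keeps pace only until its rate crossover in
2044 under the A1FI curve. `rd.scenario_matrix()` tabulates all 18
density × porosity × scenario combinations.

A CLI wraps the same functions:

```
reefdiss simulate-experiment --seed 0 --out samples.csv
reefdiss analyze-dissolution samples.csv
reefdiss all --seed 0 --out run/        # full pipeline + manifest.json
```

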