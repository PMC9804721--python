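# Methods

## Model structure and assumptions

The consumer follows the Yodzis–Innes biomass formalism: per-unit growth is
assimilated ingestion minus respiration, `dC/(C dt) = (1−δ) f(R,T) − m(T)`.
Assumptions inherited from that tradition and kept here:

* **Respiration** rises monotonically with temperature.  The
  Boltzmann–Arrhenius form is approximated by a plain exponential
  `m(T) = m_a e^{m_b T} + m_c` over the biologically relevant range — no
  1/kT (inverse-temperature) parameterisation, and all temperatures are in
  °C throughout (no Kelvin conversion anywhere).
* **Ingestion** is type II with a symmetric Gaussian peak
  `Imax(T) = exp(−(T−T_I)²/β)`.  Asymmetric (e.g. Sharpe–Schoolfield-style)
  peaks are out of scope by design; symmetry does not change the
  qualitative geometry.  The half-saturation density R₀ is
  temperature-invariant because attack rate and inverse handling time scale
  similarly with T; `Imax ≡ 1/h`, `R₀ ≡ 1/(a·h)` connect to Holling
  notation (accessors on `ConsumerParams`).
* **Assimilation fraction** (1−δ) is temperature-independent.

The logistic resource uses `dR/dt = r(T) R − γ R²`, the algebraic rewrite of
`r R (1 − R/K)` under `K = r/γ`.  This is deliberate: it removes the
removable singularity at r = 0 and enforces the sign constraint that r and K
share zeros and sign, so when thermal stress drives r below zero, density
dependence continues to push the population down rather than "rescuing" it.
A negative K is never reported as an equilibrium; the resource-only branch
exists only where r > 0.  γ is temperature-independent (no thermal effect on
the strength of density dependence).

## Parameters

Consumer (`ConsumerParams`, defaults = the reference parameterisation):
δ = 0.5, m_a = 0.01, m_b = 0.1 /°C, m_c = 0.05 (rates per unit time),
T_I = 25 °C, β = 150 °C², R₀ ∈ {0.5, 1, 2} across fixtures.  **Provenance
caveat:** the source figure caption prints the numeric values with the
symbol labels garbled; the assignment m_a = 0.01, m_b = 0.1, m_c = 0.05,
T_I = 25 is inferred from the order in which the equations introduce the
symbols.  All downstream geometry (saturated limits 7.96/33.08 °C, ZNGI
minimum at 20.45 °C) is self-consistent with that reading.

Chemostat (`ChemostatParams`): S = D = 1, temperature-independent by
assumption.  R₀ for the "efficient" panel is not printed anywhere; 0.5 is
the shipped choice ("prudent" = 2.0), and with it the persistence
boundaries land at 10.23 and 30.77 °C against the printed "approximately 10
and 30.5".

Resource (`ResourceTraits`): b_max = 1, β_r = 150 °C² (defaulting to the
consumer's breadth; stored separately so breadth mismatch is expressible),
d₀ = 0.05, d₁ = 0.005, d₂ = 0.1 /°C, γ = 0.525, ΔT = 0.  These are
**calibrated stand-ins**: the original resource parameter list is illegible
in the source, so the values were chosen once to satisfy the stated
scenario and then frozen:

1. the resource's fundamental niche (r > 0 on 4.31–38.65 °C) strictly
   contains the consumer's saturated niche (7.96–33.08 °C);
2. the efficient consumer (R₀ = 0.5) crosses the enrichment threshold —
   Hopf points at 16.283 and 28.675 °C — while R₀ = 1 and 2 produce no Hopf
   point at any mismatch in ΔT ∈ [−25, 15] °C.

Goal (2) pins γ: the coexistence trace is positive where
K(T) > R₀((1−δ)Imax+m)/((1−δ)Imax−m), and the worst case over mismatches at
any T is a resource ridge aligned there, giving a closed-form lower bound
γ_min = max_T r_ridge(T)/K_hopf(T) ≈ 0.4996 for R₀ = 1
(`calibrate.min_density_dependence`).  γ = 0.525 sits ~5 % above that bound;
values much below it put R₀ = 1 into cycles at moderate negative mismatch,
violating (2).

Mismatch fixtures: ΔT = +9 / −18 °C ship verbatim as `fig5a`/`fig5b` (the
printed scenario values).  The *calibrated* fixtures are found by
`calibrate.find_mismatch_fixtures`: the smallest integer |ΔT| whose realized
edge clears the ZNGI-minimum temperature (20.447 °C) by ≥ 2 °C —
`meltdown_calibrated` ΔT = −20 (realized Tmax 18.26 °C) and
`mirror_calibrated` ΔT = +11 (realized Tmin 23.24 °C).  Under the shipped
resource traits, fig5b (−18) is itself marginally past the meltdown
threshold (realized Tmax 20.34 °C); the calibrated fixtures are the ones
with comfortable margins and are what the tests exercise.

## Definitions with open alternatives

* **Realized TPC** — defined as consumer *invasion* growth at the
  resource-only equilibrium, `g(max(K(T),0), T)`.  The alternative
  (growth along the coexistence attractor) is identically zero at
  equilibrium and so carries no sign information; the invasion curve is the
  one whose roots are the persistence boundaries shown on the regime
  diagram, which is what the realized-niche analysis needs.
* **Turnover** — production/biomass at coexistence, computed as gross
  assimilation `(1−δ) f(R̂,T)`.  This makes the identity turnover = m(T)
  exact (it is the equilibrium condition itself).  The measured shape along
  a branch is monotone increasing in T — lowest at the cold end, rising
  roughly exponentially (fitted log-slope ≈ m_b at warm temperatures); a
  literal U-shape would require the cold-end asymptote to dominate m(T),
  which these parameters do not produce, so the package reports the
  measured shape rather than asserting one.
* **Meltdown flag** — true iff the realized Tmax is colder than
  argmin R*(T).  Edge attribution (`consumer_physiology` vs
  `resource_thermal_traits`) compares each realized edge with the
  *saturated* fundamental limit within a 0.1 °C tolerance (configurable).
  Note that with any finite unimodal K(T) the invasion boundary sits
  strictly inside the saturated limits (e.g. 29.79 vs 33.08 °C at ΔT = 0,
  R₀ = 1), so under this strict rule edges are usually attributed to
  resource traits; the meltdown flag and R̂-slope diagnostics, which are the
  substantive outputs, do not depend on the attribution tolerance.
* **Box-geometry symmetry** — the claim that at collapse the niche closes
  "midway between Tmin and Tmax" is treated as approximate: the envelope is
  measured (collapse at 20.447 °C, vs the saturated midpoint 20.52 °C),
  never assumed symmetric.

## Numerics

* Root finding: coarse scan at 0.05 °C to bracket, then Brent to 1e−8 °C
  (1e−6 °C for branch-scan bifurcation refinement, 1e−10 relative for
  closed-form oracles in tests).  All the scanned functions are smooth with
  at most two roots in the window.
* Saturated limits use the analytic R→∞ limit `(1−δ)Imax − m`, not a large
  finite R.
* Topt by bounded scalar minimisation (Brent-style golden/parabolic) inside
  (Tmin, Tmax) with 1e−10 °C tolerance; in degenerate flat cases the
  bounded minimiser's interior convention applies.
* Equilibria and Jacobians are closed-form (re-derived from the model
  equations); stability is the eigenvalue sign of the analytic 2×2
  Jacobian, and every reported equilibrium is verified against the ODE
  right-hand side to 1e−10 in tests.
* Hopf detection is numeric (sign change of the coexistence Jacobian trace,
  Brent-refined); the closed-form capacity threshold is kept as an
  *independent oracle*, never substituted for detection.
* Integration: LSODA, rtol 1e−9 / atol 1e−11; nonnegativity enforced by
  clipping round-off below zero (an excursion beyond ~1e−8 raises a typed
  error instead of being hidden).  Cycle summaries discard a 2000-time-unit
  transient and report extrema over a 500-unit window, with a convergence
  flag comparing the two half-windows at 1 % drift; the period estimate is
  the mean resource-peak spacing.  Integrations are deterministic; tests
  that use random initial states draw from a fixed-seed generator.
* Default grids: 0.05 °C on [0, 40] °C for 1-D scans; 0.25 °C × 1 °C for
  the (T, ΔT) regime lattice.  These resolve every feature of the reference
  parameterisation (narrowest structures ~2 °C wide) with comfortable
  margin.

## What the shipped scenarios do and do not show

The fixtures are idealised parameter sets, not fitted organisms: symmetric
ingestion peaks, a single consumer on a single resource, no acclimation, no
behavioural thermoregulation, no stochasticity or seasonal forcing, sessile
resources (capture rate entirely consumer-driven), and
temperature-independent δ, R₀, S, D and γ.  Passing tests therefore
demonstrate the internal logic of the framework — TPC reshaping, stability
structure, mismatch-driven limit re-setting, the meltdown dichotomy — under
those assumptions, not quantitative predictions for any real community.
Breadth mismatch (β_r ≠ β) is expressible through `ResourceTraits` but is
not part of the tested acceptance surface; multi-consumer extensions are
out of scope.
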